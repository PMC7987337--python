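"""Readers and writers for the pipeline's file formats.

Variant calls travel as VCF 4.2 with per-ALT annotations in INFO
(``GENE``, ``CSQ``, ``NFE_AF``, ``CADD``; key names configurable), subject
phenotypes and Ct plates as TSV.  Male X-chromosome genotypes are written as
hemizygous single-allele calls; on reading, any non-reference call (``1``,
``0/1``, ``1/1``, ...) marks the subject a carrier, because male X calls are
dialect-dependent across callers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .encoding import Consequence, Subject, VariantRecord, normalize_consequence

__all__ = [
    "read_variants_vcf",
    "write_variants_vcf",
    "read_subjects_tsv",
    "write_subjects_tsv",
    "subjects_from_frame",
    "read_ct_tsv",
    "write_ct_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

_SUBJECT_COLUMNS = ["subject_id", "sex", "age", "clinical_category", "cohort", "pcr_confirmed"]


def _round_info_float(x: float | None) -> float | None:
    # VCF INFO floats survive a float32 round-trip (12.28 -> 12.2799...);
    # six significant digits restore the printed value.
    if x is None:
        return None
    return float(f"{float(x):.6g}")


def read_variants_vcf(
    path: str | Path,
    gene_key: str = "GENE",
    csq_key: str = "CSQ",
    af_key: str = "NFE_AF",
    cadd_key: str = "CADD",
) -> list[VariantRecord]:
    """Read annotated variant records; multi-ALT sites are decomposed.

    Carriers are the samples with any non-reference genotype call.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for site in vcf:
            alts = site.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                carriers = frozenset(
                    s
                    for s in samples
                    if any(a == alt_index for a in (site.samples[s].get("GT") or ()) if a is not None)
                )
                info = site.info
                af = info.get(af_key)
                cadd = info.get(cadd_key)
                if isinstance(af, tuple):
                    af = af[alt_index - 1] if alt_index - 1 < len(af) else None
                if isinstance(cadd, tuple):
                    cadd = cadd[alt_index - 1] if alt_index - 1 < len(cadd) else None
                records.append(
                    VariantRecord(
                        chrom=site.chrom,
                        pos=site.pos,
                        ref=site.ref,
                        alt=alt,
                        gene=str(info.get(gene_key, "")),
                        consequence=normalize_consequence(info.get(csq_key, "other")),
                        nfe_af=_round_info_float(af),
                        cadd=_round_info_float(cadd),
                        carriers=carriers,
                        variant_id=site.id,
                    )
                )
    return records


def write_variants_vcf(
    variants: list[VariantRecord],
    subject_ids: list[str],
    path: str | Path,
) -> None:
    """Write records as VCF 4.2 with hemizygous GT columns.

    Output is deterministic: records are sorted by position, and the header
    carries no timestamps.
    """
    header = pysam.VariantHeader()
    header.add_line("##contig=<ID=X,length=156040895>")
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">')
    header.add_line(
        '##INFO=<ID=NFE_AF,Number=1,Type=Float,Description="Non-Finnish-European allele frequency">'
    )
    header.add_line('##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD phred score">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in subject_ids:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda r: (r.chrom, r.pos, r.alt)):
            rec = out.new_record(contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt))
            rec.id = v.variant_id
            rec.info["GENE"] = v.gene
            rec.info["CSQ"] = v.consequence.value
            if v.nfe_af is not None:
                rec.info["NFE_AF"] = v.nfe_af
            if v.cadd is not None:
                rec.info["CADD"] = v.cadd
            for s in subject_ids:
                rec.samples[s]["GT"] = (1,) if s in v.carriers else (0,)
            out.write(rec)


def write_subjects_tsv(subjects: pd.DataFrame, path: str | Path) -> None:
    subjects.to_csv(path, sep="\t", index=False)


def read_subjects_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    return df


def subjects_from_frame(df: pd.DataFrame) -> list[Subject]:
    """Convert a phenotype table into :class:`Subject` objects."""
    return [
        Subject(
            id=str(r.subject_id),
            sex=str(r.sex),
            age=float(r.age),
            clinical_category=int(r.clinical_category),
            cohort=str(getattr(r, "cohort", "")),
            pcr_confirmed=bool(getattr(r, "pcr_confirmed", True)),
        )
        for r in df.itertuples(index=False)
    ]


def write_ct_tsv(ct: pd.DataFrame, path: str | Path) -> None:
    ct.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_ct_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "gene", "condition", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "subject_id"
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("burden matrix entries must be 0 or 1")
    return df.astype(np.int8)
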