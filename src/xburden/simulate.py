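"""Synthetic cohort generator for the extreme-phenotype X-linked design.

Emulates the study conditions the pipeline assumes: a male-only cohort split
into severe (clinical category 3–4) and oligo-asymptomatic (category 0) arms,
sparse boolean rare-variant burden across X-chromosome genes, one planted
susceptibility gene with excess carriers among cases, variant annotations
(NFE allele frequency, CADD, consequence class), and qPCR Ct plates in which
functional-variant carriers show blunted agonist-induced expression.

Everything is driven by one integer seed; the same seed reproduces every
output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import Consequence, VariantRecord
from .io import write_subjects_tsv, write_variants_vcf

__all__ = ["SyntheticConfig", "generate_cohort", "generate_qpcr_plate", "write_cohort"]

#: qPCR panel: agonist-responsive targets plus the housekeeping reference.
TARGET_GENES = ("TLR7", "IRF7", "ISG15", "IFNA", "IFNG")
HOUSEKEEPING_GENE = "HPRT1"

_GENOTYPE_LABELS = ("functional", "neutral", "non_carrier")


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the first-wave arm sizes (79 severe vs 77 asymptomatic
    young males) and a planted susceptibility gene carried by ~6.3% of cases
    and no controls.  ``background_burden_rate`` is the per-subject,
    per-gene probability of an incidental qualifying rare variant in the
    non-planted genes; real per-gene burden rates vary widely, and 0.02 is a
    conventional sparse default.
    """

    n_cases: int = 79
    n_controls: int = 77
    n_genes: int = 300
    planted_gene_index: int = 0
    carrier_freq_cases: float = 0.0633
    carrier_freq_controls: float = 0.0
    background_burden_rate: float = 0.02
    maf_range: tuple[float, float] = (1e-6, 0.01)
    missing_maf_rate: float = 0.05
    cadd_qualifying_range: tuple[float, float] = (12.28, 30.0)
    cadd_benign_range: tuple[float, float] = (0.0, 12.27)
    consequence_mix: dict[str, float] = field(
        default_factory=lambda: {"missense": 0.70, "splicing": 0.15, "LOF": 0.15}
    )
    distractor_rate: float = 0.02
    second_variant_rate: float = 0.0
    n_aged_subjects: int = 0
    n_outlier_subjects: int = 0
    baseline_induction_log2: float = 3.0
    qpcr_effect_log2: float = 2.0
    ct_noise_sd: float = 0.2
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0 or self.n_genes <= 0:
            raise ValueError("n_cases, n_controls and n_genes must be positive")
        for name in (
            "carrier_freq_cases",
            "carrier_freq_controls",
            "background_burden_rate",
            "missing_maf_rate",
            "distractor_rate",
            "second_variant_rate",
        ):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not (0 <= self.planted_gene_index < self.n_genes):
            raise ValueError("planted_gene_index must be < n_genes")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        mix_sum = sum(self.consequence_mix.values())
        if not np.isclose(mix_sum, 1.0):
            raise ValueError(f"consequence_mix must sum to 1, got {mix_sum}")


def _gene_names(cfg: SyntheticConfig) -> list[str]:
    names = [f"XG{i:04d}" for i in range(cfg.n_genes)]
    names[cfg.planted_gene_index] = "TLR7"
    return names


_ALLELE_PAIRS = (("G", "A"), ("C", "T"), ("A", "G"), ("T", "C"))


def _sample_maf(rng: np.random.Generator, cfg: SyntheticConfig, size: int) -> np.ndarray:
    lo, hi = cfg.maf_range
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def generate_cohort(cfg: SyntheticConfig) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Draw one synthetic cohort: annotated variant records plus phenotypes.

    Each subject-gene burden is an independent Bernoulli draw at
    ``background_burden_rate``, except the planted gene, which uses
    ``carrier_freq_cases`` / ``carrier_freq_controls``.  Every burdened
    subject-gene pair is materialized as one qualifying variant record
    (optionally two, to exercise the at-least-one collapse rule); distractor
    records that fail the qualification rules (synonymous consequence, or
    common alleles) are added on top.

    Optional rows: ``n_aged_subjects`` severe males aged >= 60 (exercise the
    age filter) and ``n_outlier_subjects`` controls with extreme dense burden
    (exercise PCA outlier removal).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg)

    ids = (
        [f"CASE{i + 1:04d}" for i in range(cfg.n_cases)]
        + [f"CTRL{i + 1:04d}" for i in range(cfg.n_controls)]
        + [f"AGED{i + 1:04d}" for i in range(cfg.n_aged_subjects)]
        + [f"OUTL{i + 1:04d}" for i in range(cfg.n_outlier_subjects)]
    )
    n = len(ids)
    is_case = np.array(
        [True] * cfg.n_cases
        + [False] * cfg.n_controls
        + [True] * cfg.n_aged_subjects
        + [False] * cfg.n_outlier_subjects
    )
    ages = rng.integers(20, 60, size=n)
    if cfg.n_aged_subjects:
        aged_slice = slice(cfg.n_cases + cfg.n_controls, cfg.n_cases + cfg.n_controls + cfg.n_aged_subjects)
        ages[aged_slice] = rng.integers(60, 90, size=cfg.n_aged_subjects)
    categories = np.where(is_case, rng.integers(3, 5, size=n), 0)

    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "sex": "M",
            "age": ages,
            "clinical_category": categories,
            "cohort": "wave1",
            "pcr_confirmed": True,
        }
    )

    # burden indicator draws, planted gene overridden by arm-specific rates
    burden = rng.random((n, cfg.n_genes)) < cfg.background_burden_rate
    planted_p = np.where(is_case, cfg.carrier_freq_cases, cfg.carrier_freq_controls)
    burden[:, cfg.planted_gene_index] = rng.random(n) < planted_p
    if cfg.n_outlier_subjects:
        out_slice = slice(n - cfg.n_outlier_subjects, n)
        burden[out_slice, :] = rng.random((cfg.n_outlier_subjects, cfg.n_genes)) < 0.5

    csq_labels = list(cfg.consequence_mix)
    csq_probs = np.array([cfg.consequence_mix[c] for c in csq_labels])

    variants: list[VariantRecord] = []
    pos_counter = np.zeros(cfg.n_genes, dtype=int)

    def next_pos(g: int) -> int:
        pos_counter[g] += 1
        return 100_000 + g * 10_000 + pos_counter[g]

    def qualifying_record(g: int, carrier: str) -> VariantRecord:
        pos = next_pos(g)
        ref, alt = _ALLELE_PAIRS[pos % len(_ALLELE_PAIRS)]
        af = None if rng.random() < cfg.missing_maf_rate else float(_sample_maf(rng, cfg, 1)[0])
        csq = rng.choice(csq_labels, p=csq_probs)
        return VariantRecord(
            chrom="X",
            pos=pos,
            ref=ref,
            alt=alt,
            gene=genes[g],
            consequence=Consequence(csq),
            nfe_af=af,
            cadd=float(rng.uniform(*cfg.cadd_qualifying_range)),
            carriers=frozenset({carrier}),
        )

    for g in range(cfg.n_genes):
        for s in np.nonzero(burden[:, g])[0]:
            variants.append(qualifying_record(g, ids[s]))
            if cfg.second_variant_rate and rng.random() < cfg.second_variant_rate:
                variants.append(qualifying_record(g, ids[s]))

    # distractors: records that must NOT reach the boolean matrix
    n_distractors = rng.binomial(n * cfg.n_genes, cfg.distractor_rate)
    for _ in range(n_distractors):
        g = int(rng.integers(cfg.n_genes))
        s = int(rng.integers(n))
        pos = next_pos(g)
        ref, alt = _ALLELE_PAIRS[pos % len(_ALLELE_PAIRS)]
        if rng.random() < 0.5:
            # synonymous rare variant: wrong consequence class
            csq, af = Consequence.SYNONYMOUS, float(_sample_maf(rng, cfg, 1)[0])
        else:
            # missense but common: fails the rarity rule
            csq, af = Consequence.MISSENSE, float(rng.uniform(0.02, 0.5))
        variants.append(
            VariantRecord(
                chrom="X",
                pos=pos,
                ref=ref,
                alt=alt,
                gene=genes[g],
                consequence=csq,
                nfe_af=af,
                cadd=float(rng.uniform(*cfg.cadd_benign_range)),
                carriers=frozenset({ids[s]}),
            )
        )

    return variants, subjects


def generate_qpcr_plate(
    cfg: SyntheticConfig,
    genotype_labels: pd.Series | dict[str, str],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a Ct plate for agonist-stimulated vs medium conditions.

    ``genotype_labels`` maps subject IDs to ``functional`` (carrier of a
    signaling-impairing variant), ``neutral`` (carrier of a benign variant)
    or ``non_carrier``.  Target genes are induced by ``baseline_induction_log2``
    cycles under stimulation; functional carriers lose ``qpcr_effect_log2``
    of that induction.  The housekeeping gene is condition-independent in
    expectation.  Gaussian noise of SD ``ct_noise_sd`` is added per replicate
    measurement.
    """
    labels = pd.Series(genotype_labels, dtype=object)
    if labels.empty:
        raise ValueError("genotype_labels is empty")
    bad = set(labels) - set(_GENOTYPE_LABELS)
    if bad:
        raise ValueError(f"unknown genotype labels: {sorted(bad)}; expected {_GENOTYPE_LABELS}")
    if cfg.ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    hk_base, target_base = 24.0, 28.0
    rows = []
    for subject, label in labels.items():
        induction = cfg.baseline_induction_log2
        if label == "functional":
            induction -= cfg.qpcr_effect_log2
        for gene in (*TARGET_GENES, HOUSEKEEPING_GENE):
            for condition in ("stimulated", "medium"):
                if gene == HOUSEKEEPING_GENE:
                    mean_ct = hk_base
                else:
                    mean_ct = target_base - (induction if condition == "stimulated" else 0.0)
                noise = rng.normal(0.0, cfg.ct_noise_sd, size=cfg.replicates)
                for rep in range(1, cfg.replicates + 1):
                    rows.append((subject, gene, condition, rep, mean_ct + noise[rep - 1]))
    return pd.DataFrame(rows, columns=["subject_id", "gene", "condition", "replicate", "ct"])


def write_cohort(
    cfg: SyntheticConfig,
    out_dir: str | Path,
    with_qpcr: bool = True,
) -> dict[str, Path]:
    """Generate a cohort and write VCF + subjects TSV (+ Ct TSV) to ``out_dir``.

    The Ct plate labels planted-gene carriers among cases as functional
    carriers and everyone else as non-carriers.  Returns the paths written.
    """
    from .io import write_ct_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    variants, subjects = generate_cohort(cfg)
    vcf_path = out / "cohort.vcf"
    subj_path = out / "subjects.tsv"
    write_variants_vcf(variants, list(subjects["subject_id"]), vcf_path)
    write_subjects_tsv(subjects, subj_path)
    paths = {"vcf": vcf_path, "subjects": subj_path}

    if with_qpcr:
        from .encoding import qualifies_for_burden

        planted_gene = _gene_names(cfg)[cfg.planted_gene_index]
        carrier_ids: set[str] = set()
        for v in variants:
            if v.gene == planted_gene and qualifies_for_burden(v):
                carrier_ids |= v.carriers
        labels = pd.Series(
            {
                sid: ("functional" if sid in carrier_ids else "non_carrier")
                for sid in subjects["subject_id"]
            }
        )
        ct_path = out / "ct.tsv"
        # separate stream so the plate does not perturb cohort determinism
        write_ct_tsv(
            generate_qpcr_plate(cfg, labels, rng=np.random.default_rng(cfg.seed + 1)),
            ct_path,
        )
        paths["ct"] = ct_path
    return paths
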