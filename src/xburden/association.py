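"""Exact-test validation of a selected gene and carrier-fraction summaries.

After the regression screen nominates a gene, its association with severity
is validated on a 2x2 carrier-by-arm table with Fisher's exact test (two-
sided, point-probability convention), and carrier fractions are summarized
by age stratum and by variant qualification rule — the in-silico candidate
rule (rare + CADD) versus the experimentally determined functional classes
(loss-of-function / hypomorphic).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .encoding import FilterConfig

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "carrier_table",
    "fisher_exact_two_sided",
    "odds_ratio",
    "summarize_carriers",
    "load_tlr7_case_roster",
]

FUNCTIONAL_CLASSES = ("LOF", "HYPO", "Neutral")


@dataclass
class ContingencyTable:
    """2x2 carrier-by-severity counts.

    Layout: rows are arms (severe, asymptomatic), columns are carrier status
    (non-carrier, carrier)::

        [[severe_noncarrier,      severe_carrier],
         [asymptomatic_noncarrier, asymptomatic_carrier]]
    """

    severe_noncarrier: int
    severe_carrier: int
    asympt_noncarrier: int
    asympt_carrier: int

    def __post_init__(self) -> None:
        for v in self.counts:
            if v < 0 or int(v) != v:
                raise ValueError(f"counts must be non-negative integers, got {self.counts}")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (
            self.severe_noncarrier,
            self.severe_carrier,
            self.asympt_noncarrier,
            self.asympt_carrier,
        )

    @classmethod
    def from_array(cls, table) -> "ContingencyTable":
        (a, b), (c, d) = np.asarray(table)
        return cls(int(a), int(b), int(c), int(d))

    def to_array(self) -> np.ndarray:
        a, b, c, d = self.counts
        return np.array([[a, b], [c, d]], dtype=int)


@dataclass
class AssociationResult:
    table: ContingencyTable
    p_value: float
    odds_ratio: float
    or_corrected: bool
    carrier_fraction_severe: float
    carrier_fraction_asympt: float


def carrier_table(carrier_flags, arm_labels) -> ContingencyTable:
    """Cross-tabulate carrier status against the severe/asymptomatic arm.

    ``arm_labels`` must be binary (1/"case"/"severe" = severe arm); excluded
    subjects must be filtered before this point.
    """
    flags = pd.Series(carrier_flags).reset_index(drop=True)
    arms = pd.Series(arm_labels).reset_index(drop=True)
    if flags.empty:
        raise ValueError("empty input")
    if len(flags) != len(arms):
        raise ValueError("carrier flags and arm labels are not aligned")
    arm_map = {1: 1, 0: 0, True: 1, False: 0, "case": 1, "control": 0, "severe": 1, "asymptomatic": 0}
    try:
        arms = arms.map(arm_map).astype(int)
    except (TypeError, ValueError) as err:
        raise ValueError(f"arm labels must be binary, got {sorted(set(arms))}") from err
    if arms.isna().any():
        raise ValueError("arm labels contain excluded/unknown entries; filter upstream")
    flags = flags.astype(bool)
    return ContingencyTable(
        severe_noncarrier=int(((arms == 1) & ~flags).sum()),
        severe_carrier=int(((arms == 1) & flags).sum()),
        asympt_noncarrier=int(((arms == 0) & ~flags).sum()),
        asympt_carrier=int(((arms == 0) & flags).sum()),
    )


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p-value by the point-probability convention.

    Sums, over all 2x2 tables with the observed margins, the hypergeometric
    point probabilities that do not exceed the observed table's probability
    (within relative slack 1e-7, guarding against ties lost to rounding).
    Evaluation is exact via the hypergeometric pmf; no normal approximation.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable.from_array(table)
    a, b, c, d = table.counts
    n = a + b + c + d
    if n == 0:
        raise ValueError("zero grand total")
    row1 = a + b  # severe margin (draws)
    col_carrier = b + d  # carrier margin (successes)
    support = np.arange(max(0, row1 - (n - col_carrier)), min(row1, col_carrier) + 1)
    pmf = hypergeom.pmf(support, n, col_carrier, row1)
    p_obs = hypergeom.pmf(b, n, col_carrier, row1)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


def odds_ratio(table, correction: bool = True) -> tuple[float, bool]:
    """Carrier odds ratio, severe vs asymptomatic arm.

    OR = (severe_carrier * asympt_noncarrier) / (severe_noncarrier *
    asympt_carrier).  With ``correction`` and any zero cell, 0.5 is added to
    every cell (Haldane-Anscombe); without it a zero-cell OR is infinite.
    Returns ``(estimate, corrected)``; a doubly-degenerate margin (two zero
    cells in one column) yields ``(nan, False)``.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable.from_array(table)
    a, b, c, d = (float(v) for v in table.counts)
    if (b == 0 and d == 0) or (a == 0 and c == 0):
        return float("nan"), False
    if correction and 0.0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (b * c) / (a * d), True
    if a * d == 0:
        return float("inf"), False
    return (b * c) / (a * d), False


def associate(carrier_flags, arm_labels) -> AssociationResult:
    """One-stop exact-test validation for a gene's carrier flags."""
    table = carrier_table(carrier_flags, arm_labels)
    a, b, c, d = table.counts
    or_est, corrected = odds_ratio(table)
    return AssociationResult(
        table=table,
        p_value=fisher_exact_two_sided(table),
        odds_ratio=or_est,
        or_corrected=corrected,
        carrier_fraction_severe=b / (a + b) if a + b else float("nan"),
        carrier_fraction_asympt=d / (c + d) if c + d else float("nan"),
    )


def load_tlr7_case_roster() -> pd.DataFrame:
    """Load the packaged roster of TLR7 variant carriers among severe males.

    One row per carrier patient (shared variants are expanded), with the
    variant annotation (CADD, NFE allele frequency, experimentally determined
    functional class), clinical category and age.
    """
    ref = importlib.resources.files("xburden").joinpath("data/tlr7_case_variants.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def _percent(k: int, n: int) -> str:
    # one decimal, round-half-even, matching the reporting convention
    return f"{round(100.0 * k / n, 1):.1f}%"


def summarize_carriers(
    roster: pd.DataFrame,
    cfg: FilterConfig | None = None,
    n_young: int = 135,
    n_all: int = 261,
    functional_classes: tuple[str, ...] = ("LOF", "HYPO"),
) -> pd.DataFrame:
    """Stratified distinct-carrier counts and percentages.

    Strata cross two age windows (under the cutoff vs all ages) with two
    qualification rules: the in-silico *candidate* rule (rare or missing NFE
    AF, CADD at or above threshold) and restriction to experimentally
    determined *functional* classes.  ``n_young`` / ``n_all`` are the severe-
    arm denominators of the two age windows (cohort sizes; carriers alone do
    not determine them).  A patient with two qualifying variants counts once.
    """
    cfg = cfg or FilterConfig()
    df = roster.copy()
    unknown = set(df["function"].dropna()) - set(FUNCTIONAL_CLASSES)
    if unknown:
        raise ValueError(f"unknown functional class labels: {sorted(unknown)}")

    af = pd.to_numeric(df["nfe_af"], errors="coerce")
    rare = af.isna() if cfg.missing_maf_is_rare else pd.Series(False, index=df.index)
    rare |= af <= cfg.maf_threshold
    candidate = rare & (pd.to_numeric(df["cadd"]) >= cfg.cadd_threshold)
    functional = df["function"].isin(functional_classes)
    young = df["age"] < cfg.age_cutoff

    rows = []
    for stratum, in_stratum, denom in (
        ("young", young, n_young),
        ("all_ages", pd.Series(True, index=df.index), n_all),
    ):
        for rule, qualifies in (("candidate", candidate), ("functional", functional)):
            carriers = df.loc[in_stratum & qualifies, "patient_id"].nunique()
            rows.append(
                {
                    "stratum": stratum,
                    "rule": rule,
                    "carriers": carriers,
                    "denominator": denom,
                    "percent": _percent(carriers, denom),
                }
            )
    return pd.DataFrame(rows)
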