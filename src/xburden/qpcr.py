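"""Relative quantification of qPCR validation data (Livak 2^-ddCt method).

Fold change in target-gene expression between agonist-stimulated and medium
conditions is estimated per subject as 2^-ddCt against a housekeeping gene:
replicate Cts are averaged per (gene, condition), dCt = Ct_target -
Ct_housekeeping within each condition, ddCt = dCt_stimulated - dCt_medium.
Groups of subjects (e.g. functional-variant carriers vs healthy controls)
are compared with an unpaired t-test on the log-transformed fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FoldChangeResult",
    "fold_change_ddct",
    "fold_changes_from_table",
    "compare_groups_log_t",
    "significance_stars",
]


@dataclass
class FoldChangeResult:
    """Per subject x target gene relative quantification."""

    subject_id: str
    gene: str
    dct_stimulated: float
    dct_medium: float

    @property
    def ddct(self) -> float:
        return self.dct_stimulated - self.dct_medium

    @property
    def fold_change(self) -> float:
        return float(2.0 ** (-self.ddct))


def _mean_ct(values) -> float:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate Ct values")
    if not np.isfinite(arr).all() or (arr <= 0).any():
        raise ValueError(f"Ct values must be finite and > 0, got {arr}")
    return float(arr.mean())


def fold_change_ddct(
    target_stimulated,
    target_medium,
    housekeeping_stimulated,
    housekeeping_medium,
    subject_id: str = "",
    gene: str = "",
) -> FoldChangeResult:
    """Compute 2^-ddCt from the four replicate-Ct groups of one subject.

    Replicates are averaged on the Ct scale before differencing (standard
    Livak procedure); replicate order is immaterial.
    """
    dct_stim = _mean_ct(target_stimulated) - _mean_ct(housekeeping_stimulated)
    dct_med = _mean_ct(target_medium) - _mean_ct(housekeeping_medium)
    return FoldChangeResult(
        subject_id=subject_id, gene=gene, dct_stimulated=dct_stim, dct_medium=dct_med
    )


def fold_changes_from_table(
    ct: pd.DataFrame,
    housekeeping: str = "HPRT1",
    stimulated: str = "stimulated",
    medium: str = "medium",
) -> pd.DataFrame:
    """Per subject x target gene fold changes from a long-format Ct table.

    Expects columns ``subject_id, gene, condition, replicate, ct``.  Subjects
    or genes lacking either condition, or lacking the housekeeping gene, are
    an error.
    """
    required = {"subject_id", "gene", "condition", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    means = ct.groupby(["subject_id", "gene", "condition"])["ct"].apply(_mean_ct)

    rows = []
    for subject in ct["subject_id"].unique():
        sub = means.loc[subject]
        if housekeeping not in sub.index.get_level_values(0):
            raise ValueError(f"subject {subject} lacks housekeeping gene {housekeeping}")
        for gene in sub.index.get_level_values(0).unique():
            if gene == housekeeping:
                continue
            try:
                r = FoldChangeResult(
                    subject_id=subject,
                    gene=gene,
                    dct_stimulated=sub[gene][stimulated] - sub[housekeeping][stimulated],
                    dct_medium=sub[gene][medium] - sub[housekeeping][medium],
                )
            except KeyError as err:
                raise ValueError(
                    f"subject {subject}, gene {gene}: missing condition {err}"
                ) from err
            rows.append(
                {
                    "subject_id": subject,
                    "gene": gene,
                    "dct_stimulated": r.dct_stimulated,
                    "dct_medium": r.dct_medium,
                    "ddct": r.ddct,
                    "fold_change": r.fold_change,
                }
            )
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Conventional significance annotation at 0.05/0.01/0.001/0.0001."""
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < threshold:
            return stars
    return "ns"


def compare_groups_log_t(
    group_a,
    group_b,
    welch: bool = False,
) -> tuple[float, float, float, str]:
    """Unpaired t-test on log-transformed fold changes.

    Fold changes are log2-transformed (the t statistic and p-value are
    invariant to the log base).  The default is the pooled-variance Student
    test with df = n_a + n_b - 2; ``welch`` switches to the unequal-variance
    form.  Returns ``(t, df, two-sided p, stars)``.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 fold changes")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("fold changes must be positive to take logs")
    la, lb = np.log2(a), np.log2(b)
    if not welch and np.var(la, ddof=1) + np.var(lb, ddof=1) == 0:
        raise ValueError("zero pooled variance; t statistic undefined")
    res = stats.ttest_ind(la, lb, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else float(len(a) + len(b) - 2)
    return float(res.statistic), df, float(res.pvalue), significance_stars(float(res.pvalue))
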