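"""PCA-based cohort outlier removal.

Before the regression, subjects deviating more than ``k_sd`` standard
deviations from the average on any of the first three principal components
of the (column-centered, unscaled) burden matrix are dropped.  Flagging is a
single pass: statistics are not re-estimated after removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PCAResult", "pca_scores", "flag_outliers", "remove_outliers"]


@dataclass
class PCAResult:
    """Per-subject scores on the leading principal components."""

    scores: pd.DataFrame  # subjects x components, columns PC1..PCk
    explained_variance: np.ndarray
    outlier_flags: pd.Series | None = None


def pca_scores(matrix: pd.DataFrame, k: int = 3) -> PCAResult:
    """Project subjects onto the top-``k`` principal components.

    The boolean matrix is column-centered but not scaled (all columns share
    the {0,1} scale).  Components are ordered by decreasing explained
    variance; the sign convention makes the largest-magnitude loading of each
    component positive.
    """
    X = matrix.to_numpy(dtype=float)
    n, g = X.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} subjects for {k} components, got {n}")
    Xc = X - X.mean(axis=0)
    if not Xc.any():
        raise ValueError("no variance: burden matrix columns are all constant")

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k_eff = min(k, len(s))
    U, s, Vt = U[:, :k_eff], s[:k_eff], Vt[:k_eff]
    # fix signs: largest-|loading| entry of each component positive
    for c in range(k_eff):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores = pd.DataFrame(
        U * s,
        index=matrix.index,
        columns=[f"PC{c + 1}" for c in range(k_eff)],
    )
    explained = s**2 / max(n - 1, 1)
    return PCAResult(scores=scores, explained_variance=explained)


def flag_outliers(pca: PCAResult, k_sd: float = 5.0, n_components: int = 3) -> pd.Series:
    """Flag subjects deviating more than ``k_sd`` SDs on any leading component.

    Mean and SD (population SD) are computed over all subjects per component;
    for centered PCA scores the mean is ~0, so the rule reduces to
    ``|score| > k_sd * SD``.  Ties at exactly ``k_sd`` SDs are not flagged.
    """
    if k_sd <= 0:
        raise ValueError(f"k_sd must be positive, got {k_sd}")
    scores = pca.scores
    if len(scores) < 3:
        raise ValueError("need at least 3 subjects to flag outliers")
    use = scores.iloc[:, : min(n_components, scores.shape[1])]
    mean = use.mean(axis=0)
    sd = use.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore"):
        dev = (use - mean).abs()
        flags = (dev > k_sd * sd).any(axis=1)
    pca.outlier_flags = flags
    return flags


def remove_outliers(
    matrix: pd.DataFrame, k: int = 3, k_sd: float = 5.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Convenience wrapper: compute scores, flag, and drop flagged subjects."""
    pca = pca_scores(matrix, k=k)
    flags = flag_outliers(pca, k_sd=k_sd)
    return matrix.loc[~flags], flags
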