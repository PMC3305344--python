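"""Chemical-space statistics: descriptor summaries, between-set tests, and
Varimax-rotated factor analysis.

Between-set comparisons report per-descriptor medians, means, and two-sided
Welch (unequal-variance) t-test P values, with a Wilcoxon rank-sum
cross-check and a Bonferroni column emitted alongside the raw P values.

The factor analysis extracts the first two principal components of the
descriptor correlation matrix and applies a Kaiser-normalized Varimax
rotation.  Rotation is orthogonal, so the total variance explained by the
pair of factors is invariant; the per-factor split is recomputed after
rotation.  Scores are regression scores from the rotated loadings, and each
factor's sign is fixed so that its largest-|loading| descriptor loads
positively.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def summarize_and_test(desc_a: pd.DataFrame, desc_b: pd.DataFrame) -> pd.DataFrame:
    """Per-descriptor median/mean for each set plus Welch t-test P values.

    Descriptors constant in both sets get P = 1 with a ``zero_variance``
    flag.  A rank-sum P value and a Bonferroni-adjusted column accompany
    the raw P values.
    """
    if len(desc_a) < 2 or len(desc_b) < 2:
        raise ValueError("each set needs at least 2 rows")
    cols = [c for c in desc_a.columns if c in desc_b.columns]
    rows = []
    for c in cols:
        a, b = desc_a[c].to_numpy(float), desc_b[c].to_numpy(float)
        zero_var = a.std() == 0 and b.std() == 0
        if zero_var and a.mean() == b.mean():
            p = 1.0
            p_rank = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_rank = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            if np.isnan(p):  # identical constants edge case
                p = 1.0
        rows.append(
            {
                "descriptor": c,
                "median_a": float(np.median(a)),
                "mean_a": float(a.mean()),
                "median_b": float(np.median(b)),
                "mean_b": float(b.mean()),
                "p_value": p,
                "p_ranksum": p_rank,
                "zero_variance": bool(zero_var),
            }
        )
    df = pd.DataFrame(rows).set_index("descriptor")
    df["p_bonferroni"] = np.minimum(df["p_value"] * len(df), 1.0)
    return df


def varimax(loadings: np.ndarray, normalize: bool = True, tol: float = 1e-6,
            max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loadings matrix.

    With ``normalize`` (Kaiser normalization) rows are scaled to unit
    communality before rotation and rescaled afterward.  Returns the
    rotated loadings and the orthogonal rotation matrix.
    """
    from statsmodels.multivariate.factor_rotation import rotate_factors

    L = np.asarray(loadings, dtype=float).copy()
    comm = np.sqrt((L**2).sum(axis=1))
    if normalize:
        nz = comm > 0
        L[nz] = L[nz] / comm[nz, None]
    out, R = rotate_factors(L, "varimax", tol=tol, max_tries=max_iter)
    if normalize:
        out = out * comm[:, None]
    return out, R


@dataclass
class FactorModel:
    """Two-factor summary of a standardized descriptor matrix."""

    loadings: pd.DataFrame          # descriptors x 2, Varimax-rotated
    variance_explained: tuple[float, float]   # percent of total variance
    scores: pd.DataFrame            # rows x 2
    high_loading_descriptors: tuple[list[str], list[str]]
    dropped: list[str]

    @property
    def total_variance_explained(self) -> float:
        return sum(self.variance_explained)


def factor_analysis_varimax(
    desc: pd.DataFrame,
    n_factors: int = 2,
    loading_cutoff: float = 0.85,
) -> FactorModel:
    """Principal-component factor analysis with Kaiser-normalized Varimax.

    The input is standardized per column; constant columns are dropped with
    a warning.  Requires at least 3x more rows than descriptors.
    """
    if len(desc) < 3 * desc.shape[1]:
        raise ValueError(
            f"need >= 3x more rows ({len(desc)}) than descriptors ({desc.shape[1]})"
        )
    dropped = [c for c in desc.columns if desc[c].std() == 0]
    if dropped:
        logger.warning("dropping constant descriptor columns: %s", dropped)
    X = desc.drop(columns=dropped)
    cols = list(X.columns)
    Z = (X - X.mean()) / X.std(ddof=1)
    Zv = Z.to_numpy(float)
    p = Zv.shape[1]

    corr = np.corrcoef(Zv, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1][:n_factors]
    lam = eigval[order]
    vec = eigvec[:, order]
    loadings = vec * np.sqrt(lam)

    rotated, _R = varimax(loadings, normalize=True)

    # per-factor variance after rotation; order factors by it, descending
    var_pct = (rotated**2).sum(axis=0) / p * 100.0
    order2 = np.argsort(var_pct)[::-1]
    rotated = rotated[:, order2]
    var_pct = var_pct[order2]

    # sign convention: the largest-|loading| descriptor of each factor loads +
    for k in range(n_factors):
        j = int(np.argmax(np.abs(rotated[:, k])))
        if rotated[j, k] < 0:
            rotated[:, k] *= -1

    Ldf = pd.DataFrame(rotated, index=cols, columns=[f"factor{k+1}" for k in range(n_factors)])
    # regression scores from the rotated loadings
    S = Zv @ rotated @ np.linalg.inv(rotated.T @ rotated)
    scores = pd.DataFrame(S, index=desc.index, columns=Ldf.columns)
    high = tuple(
        [c for c in cols if abs(Ldf.loc[c, f"factor{k+1}"]) > loading_cutoff]
        for k in range(n_factors)
    )
    return FactorModel(Ldf, tuple(float(v) for v in var_pct), scores, high, dropped)


def era_comparison(
    desc: pd.DataFrame,
    era_labels: Sequence[str],
    model: Optional[FactorModel] = None,
) -> tuple[pd.DataFrame, dict]:
    """Early-vs-late comparison of descriptors and factor scores.

    Returns the summarize_and_test table for early vs. late plus a summary
    dict with the mean factor-1 score difference (early minus late) and its
    standardized effect size.  With fewer than 2 members in a class the
    tests are skipped and only means are reported.
    """
    labels = np.asarray(era_labels)
    early = desc[labels == "early"]
    late = desc[labels == "late"]
    if len(early) == 0 or len(late) == 0:
        raise ValueError("both era classes must be non-empty")
    if len(early) < 2 or len(late) < 2:
        table = pd.DataFrame(
            {
                "mean_early": early.mean(),
                "mean_late": late.mean(),
            }
        )
        table["tests_skipped"] = True
    else:
        table = summarize_and_test(early, late).rename(
            columns={
                "median_a": "median_early", "mean_a": "mean_early",
                "median_b": "median_late", "mean_b": "mean_late",
            }
        )
    summary: dict = {}
    if model is None and len(desc) >= 3 * desc.shape[1]:
        model = factor_analysis_varimax(desc)
    if model is not None:
        s1 = model.scores["factor1"].to_numpy(float)
        d_early, d_late = s1[labels == "early"], s1[labels == "late"]
        diff = float(d_early.mean() - d_late.mean())
        pooled = np.sqrt((d_early.var(ddof=1) + d_late.var(ddof=1)) / 2) if min(len(d_early), len(d_late)) > 1 else np.nan
        summary = {
            "factor1_mean_diff": diff,
            "factor1_smd": diff / pooled if pooled and pooled > 0 else np.nan,
        }
    return table, summary
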