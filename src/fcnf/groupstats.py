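"""Group-level statistics.

Covers the four analyses run across subjects:

* correlation of the group-average fc profile (and of the
  negative-correlation frequency) with the number of feedback volumes
  in the moving window at each position;
* Fisher r-to-z comparison of two independent correlation
  coefficients (e.g. the profile correlations of two feedback
  implementations);
* brain–behaviour Pearson correlations with multivariate outlier
  removal by bootstrapping the Mahalanobis distance, under a pairwise
  missing-data deletion policy;
* paired and one-sample t-tests for pre/post questionnaire change and
  for the feedback effect against zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "group_profile",
    "profile_vs_count",
    "fisher_compare",
    "mahalanobis_bootstrap_outliers",
    "correlate_measures",
    "paired_t",
    "one_sample_t",
]

#: default squared-Mahalanobis cutoff: chi-square(2 df) 0.975 quantile
DEFAULT_OUTLIER_THRESHOLD = float(stats.chi2.ppf(0.975, df=2))


@dataclass
class CorrelationResult:
    """A Pearson correlation, optionally with outlier-cleaned companion."""

    r: float
    n: int
    p: float
    zero_variance: bool = False
    outliers: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    r_after_removal: float | None = None
    p_after_removal: float | None = None
    n_after_removal: int | None = None


def group_profile(profiles: pd.DataFrame) -> pd.DataFrame:
    """Average per-subject position profiles with equal subject weight.

    ``profiles`` is the long per-subject table (columns ``subject,
    condition, position, mean_fc, n_negative, n_contributing,
    mean_n_fcnf``). Returns one row per (condition, position) with the
    across-subject mean of ``mean_fc``, the mean negative-fc frequency,
    and the mean window feedback-volume count.
    """
    grouped = profiles.groupby(["condition", "position"], sort=True)
    out = grouped.agg(
        mean_fc=("mean_fc", "mean"),
        n_negative=("n_negative", "mean"),
        mean_n_fcnf=("mean_n_fcnf", "mean"),
        n_subjects=("subject", "nunique"),
    ).reset_index()
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def profile_vs_count(profile: pd.DataFrame, outcome: str = "mean_fc") -> CorrelationResult:
    """Correlate a profile outcome with the window feedback-volume count.

    ``outcome`` is ``"mean_fc"`` or ``"n_negative"``; the abscissa is
    ``mean_n_fcnf``. Both conditions' positions enter (40 points under
    the standard design). Zero variance in either variable yields an
    undefined coefficient with the ``zero_variance`` flag set.
    """
    if outcome not in ("mean_fc", "n_negative"):
        raise ValueError("outcome must be 'mean_fc' or 'n_negative'")
    df = profile.dropna(subset=[outcome, "mean_n_fcnf"])
    if len(df) < 3:
        raise ValueError("need at least three profile points")
    x = df["mean_n_fcnf"].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=np.nan, n=len(df), p=np.nan, zero_variance=True)
    r, p = _pearson(x, y)
    return CorrelationResult(r=r, n=len(df), p=p)


def fisher_compare(
    r1: float, n1: int, r2: float, n2: int, variant: str = "z"
) -> tuple[float, float]:
    """Compare two independent Pearson correlations via Fisher's z.

    Each coefficient is transformed with ``z_i = atanh(r_i)`` (standard
    error ``1/sqrt(n_i − 3)``); the default test refers the statistic
    ``(z1 − z2) / sqrt(1/(n1−3) + 1/(n2−3))`` to the standard normal.
    ``variant="t"`` refers the same statistic to Student's t with
    ``n1 + n2 − 4`` degrees of freedom, an approximation to the
    Student-t comparison some packages implement; at the sample sizes
    used here the two are practically indistinguishable.
    """
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("transform undefined for |r| = 1")
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 per correlation")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    statistic = float((z1 - z2) / se)
    if variant == "z":
        p = float(2.0 * stats.norm.sf(abs(statistic)))
    elif variant == "t":
        p = float(2.0 * stats.t.sf(abs(statistic), df=n1 + n2 - 4))
    else:
        raise ValueError("variant must be 'z' or 't'")
    return statistic, p


def mahalanobis_bootstrap_outliers(
    points: np.ndarray,
    B: int = 1000,
    threshold: float = DEFAULT_OUTLIER_THRESHOLD,
    seed: int = 0,
) -> np.ndarray:
    """Flag multivariate outliers by bootstrapping the Mahalanobis distance.

    For each of ``B`` resamples (with replacement) of the point cloud,
    every *original* point's squared Mahalanobis distance to the
    resample's mean and covariance is computed; a point is flagged when
    its distance averaged over resamples exceeds ``threshold``
    (default: chi-square(2) 0.975 quantile ≈ 7.378). Deterministic
    given ``seed``. Returns a boolean mask over the input points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be an (n, d) array")
    n, d = pts.shape
    if n < 5:
        raise ValueError("need at least five points")
    if B < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    full_cov = np.cov(pts, rowvar=False)
    if np.linalg.matrix_rank(full_cov) < d:
        raise ValueError("singular covariance")
    rng = np.random.default_rng(seed)
    dist_sum = np.zeros(n)
    used = 0
    attempts = 0
    while used < B:
        attempts += 1
        if attempts > 20 * B:
            raise RuntimeError("too many degenerate bootstrap resamples")
        idx = rng.integers(0, n, size=n)
        sample = pts[idx]
        mu = sample.mean(axis=0)
        cov = np.cov(sample, rowvar=False)
        try:
            inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            continue  # degenerate resample; redraw
        diff = pts - mu
        dist_sum += np.einsum("ni,ij,nj->n", diff, inv, diff)
        used += 1
    return (dist_sum / B) > threshold


def correlate_measures(
    x,
    y,
    remove_outliers: bool = False,
    B: int = 1000,
    threshold: float = DEFAULT_OUTLIER_THRESHOLD,
    seed: int = 0,
) -> CorrelationResult:
    """Two-tailed Pearson correlation between two per-subject measures.

    Missing values are handled by pairwise deletion: only subjects with
    both measures present enter this particular correlation. With
    ``remove_outliers`` the bootstrapped-Mahalanobis flags are computed
    on the complete pairs and the correlation is reported both raw and
    after dropping flagged pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("fewer than three complete pairs")
    r, p = _pearson(x, y)
    result = CorrelationResult(r=r, n=int(x.size), p=p)
    if remove_outliers:
        flags = mahalanobis_bootstrap_outliers(
            np.column_stack([x, y]), B=B, threshold=threshold, seed=seed
        )
        result.outliers = np.flatnonzero(ok)[flags]
        keep = ~flags
        if keep.sum() >= 3:
            r2, p2 = _pearson(x[keep], y[keep])
            result.r_after_removal = r2
            result.p_after_removal = p2
            result.n_after_removal = int(keep.sum())
    return result


def paired_t(pre, post) -> tuple[float, int, float]:
    """Paired-samples t-test (two-tailed); returns (t, df, p)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    ok = np.isfinite(pre) & np.isfinite(post)
    pre, post = pre[ok], post[ok]
    if pre.size < 2:
        raise ValueError("need at least two complete pairs")
    diff = post - pre
    if np.ptp(diff) == 0:
        if diff[0] == 0:  # identical samples: t = 0 by convention
            return 0.0, int(pre.size - 1), 1.0
        raise ValueError("zero variance of differences")
    res = stats.ttest_rel(post, pre)
    return float(res.statistic), int(pre.size - 1), float(res.pvalue)


def one_sample_t(values, mu0: float = 0.0) -> tuple[float, int, float]:
    """One-sample t-test against ``mu0`` (two-tailed); returns (t, df, p)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least two values")
    res = stats.ttest_1samp(values, mu0)
    return float(res.statistic), int(values.size - 1), float(res.pvalue)
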