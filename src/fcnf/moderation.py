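"""Three-way moderated regression with simple slopes.

The model regresses an outcome Y (the feedback effect) on a focal
predictor X (state anxiety) and two moderators W and Z (regional GABA
concentrations), all mean-centered, together with every product term::

    Y = i_Y + b1·X + b2·W + b3·XW + b4·Z + b5·XZ + b6·WZ + b7·XWZ + e

Products are formed *after* centering the main effects and are not
re-centered — the standard mean-centering moderation convention. The
conditional effect of X at moderator values (w, z) is::

    θ(w, z) = b1 + b3·w + b5·z + b7·w·z

evaluated at w, z ∈ {−1 SD, 0, +1 SD} (sample standard deviations of
the centered moderators), with standard errors from the coefficient
covariance and t-tests on the model's residual degrees of freedom
(n − 8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["ModerationFit", "fit_model3", "simple_slopes", "specificity_batch"]

TERMS = ("X", "W", "XW", "Z", "XZ", "WZ", "XWZ")


@dataclass
class ModerationFit:
    """OLS fit of the three-way moderation model."""

    coefficients: pd.DataFrame = field(repr=False)  # term, coeff, se, t, p, llci, ulci
    intercept: float
    f_value: float
    f_p: float
    df_model: int
    df_resid: int
    r_squared: float
    n: int
    w_sd: float
    z_sd: float
    cov_params: np.ndarray = field(repr=False)  # 8x8, intercept first

    def coefficient(self, term: str) -> float:
        return float(
            self.coefficients.loc[self.coefficients["term"] == term, "coeff"].iloc[0]
        )


def _complete_cases(*cols) -> tuple[np.ndarray, ...]:
    arrs = [np.asarray(c, dtype=float) for c in cols]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("inputs must be equal length")
    ok = np.logical_and.reduce([np.isfinite(a) for a in arrs])
    return tuple(a[ok] for a in arrs)


def fit_model3(x, w, z, y) -> ModerationFit:
    """Fit the mean-centered three-way moderation model by OLS.

    Incomplete cases are dropped first; centering uses the complete-case
    means. Raises on fewer than 10 complete cases, no residual degrees
    of freedom, or a rank-deficient design.
    """
    x, w, z, y = _complete_cases(x, w, z, y)
    n = x.size
    if n <= 8:
        raise ValueError("no residual df")
    if n < 10:
        raise ValueError("need at least 10 complete cases")
    xc, wc, zc = x - x.mean(), w - w.mean(), z - z.mean()
    design = np.column_stack(
        [np.ones(n), xc, wc, xc * wc, zc, xc * zc, wc * zc, xc * wc * zc]
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design")
    fit = sm.OLS(y, design).fit()
    conf = fit.conf_int(alpha=0.05)
    coefficients = pd.DataFrame(
        {
            "term": TERMS,
            "coeff": fit.params[1:],
            "se": fit.bse[1:],
            "t": fit.tvalues[1:],
            "p": fit.pvalues[1:],
            "llci": conf[1:, 0],
            "ulci": conf[1:, 1],
        }
    )
    return ModerationFit(
        coefficients=coefficients,
        intercept=float(fit.params[0]),
        f_value=float(fit.fvalue),
        f_p=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared),
        n=n,
        w_sd=float(wc.std(ddof=1)),
        z_sd=float(zc.std(ddof=1)),
        cov_params=np.asarray(fit.cov_params()),
    )


def simple_slopes(
    fit: ModerationFit, w_sd: float | None = None, z_sd: float | None = None
) -> pd.DataFrame:
    """Conditional X→Y slopes at the nine (±1 SD, 0) moderator settings.

    Returns a table with columns ``w_level, z_level, w, z, slope, se,
    t, p, llci, ulci``; levels are labelled low/medium/high. Standard
    errors come from the linear-combination variance ``aᵀ Σ a`` with
    ``a`` picking b1, b3, b5, b7, and t-tests use the fit's residual df.
    """
    w_sd = fit.w_sd if w_sd is None else float(w_sd)
    z_sd = fit.z_sd if z_sd is None else float(z_sd)
    labels = {-1.0: "low", 0.0: "medium", 1.0: "high"}
    # indices of b1, b3, b5, b7 in the full design (intercept at 0)
    pick = np.array([1, 3, 5, 7])
    beta = np.array([fit.coefficient(t) for t in ("X", "XW", "XZ", "XWZ")])
    cov = fit.cov_params[np.ix_(pick, pick)]
    tcrit = stats.t.ppf(0.975, df=fit.df_resid)
    rows = []
    for mz in (-1.0, 0.0, 1.0):
        for mw in (-1.0, 0.0, 1.0):
            wv, zv = mw * w_sd, mz * z_sd
            a = np.array([1.0, wv, zv, wv * zv])
            slope = float(a @ beta)
            se = float(np.sqrt(a @ cov @ a))
            tval = slope / se
            p = float(2.0 * stats.t.sf(abs(tval), df=fit.df_resid))
            rows.append(
                {
                    "w_level": labels[mw],
                    "z_level": labels[mz],
                    "w": wv,
                    "z": zv,
                    "slope": slope,
                    "se": se,
                    "t": tval,
                    "p": p,
                    "llci": slope - tcrit * se,
                    "ulci": slope + tcrit * se,
                }
            )
    return pd.DataFrame(rows)


def specificity_batch(
    data: pd.DataFrame, y: str, x: str, wz_pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Re-fit the model for alternative moderator column pairs.

    Used to check whether a moderation pattern is specific to one pair
    of moderators (e.g. GABA in both regions) or reappears with others
    (glutamate, mixed sets). Returns one row per (W, Z) pair with the
    overall model F, its p, and R².
    """
    rows = []
    for wcol, zcol in wz_pairs:
        fit = fit_model3(data[x], data[wcol], data[zcol], data[y])
        rows.append(
            {
                "w": wcol,
                "z": zcol,
                "f_value": fit.f_value,
                "p": fit.f_p,
                "r_squared": fit.r_squared,
            }
        )
    return pd.DataFrame(rows)
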