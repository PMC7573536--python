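"""Moving-window partial correlation and thermometer feedback mapping.

The fed-back quantity is the partial correlation ``r_p`` between a
prefrontal (PFC) and an amygdala region-of-interest signal, controlling
for a task-unrelated corticospinal-tract (CST) signal. ``r_p`` is
recomputed over a moving window of the last ``L`` volumes at every
incoming volume, then linearly quantized onto a ten-segment thermometer
whose bounds define the feedback implementation:

===================  ===========  ===========  =================
implementation       lower bound  upper bound  segment width |Δr|
===================  ===========  ===========  =================
negative             0            −1           0.1
weighted_negative    0            −0.3         0.03
positive             0            +1           0.1
===================  ===========  ===========  =================

During no-feedback mini-blocks the thermometer is frozen at segment 6/10;
during fixation nothing is displayed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schedule import FCNF, FIXATION, NONF, RunSchedule

__all__ = [
    "DegenerateWindowError",
    "FeedbackConfig",
    "FcStream",
    "partial_correlation",
    "stream_fc",
    "windowed_partial_correlation",
    "fc_to_thermometer",
    "displayed_segment",
]

#: quantization guard: a value this close below a segment boundary is
#: treated as sitting on the boundary (absorbs float round-off such as
#: 0.15/0.3*10 -> 4.999999999999999)
_EDGE_EPS = 1e-9

IMPLEMENTATIONS = {"negative": -1.0, "weighted_negative": -0.3, "positive": 1.0}


class DegenerateWindowError(ValueError):
    """A window whose signals carry no usable variance."""


@dataclass(frozen=True)
class FeedbackConfig:
    """Thermometer mapping parameters for one feedback implementation."""

    implementation: str = "weighted_negative"
    upper_bound: float | None = None
    lower_bound: float = 0.0
    n_segments: int = 10
    frozen_segment: int = 6
    window_length: int = 20

    def __post_init__(self) -> None:
        if self.implementation not in IMPLEMENTATIONS:
            raise ValueError(
                f"unknown implementation {self.implementation!r}; "
                f"expected one of {sorted(IMPLEMENTATIONS)}"
            )
        if self.upper_bound is None:
            object.__setattr__(
                self, "upper_bound", IMPLEMENTATIONS[self.implementation]
            )
        if self.lower_bound != 0.0:
            raise ValueError("lower_bound is fixed at 0")
        if self.upper_bound == 0.0:
            raise ValueError("upper_bound must be nonzero")
        if not 1 <= self.frozen_segment <= self.n_segments:
            raise ValueError("frozen_segment must lie in 1..n_segments")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.window_length < 3:
            raise ValueError("window_length must be >= 3")

    @property
    def segment_width(self) -> float:
        """|Δr| between two consecutive thermometer segments."""
        return abs(self.upper_bound - self.lower_bound) / self.n_segments


def partial_correlation(x, y, c) -> float:
    """Partial correlation of ``x`` and ``y`` controlling for ``c``.

    Reference (residualization) form: ``x`` and ``y`` are each regressed
    on ``c`` with an intercept by least squares, and the Pearson
    correlation of the two residual series is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(c, dtype=float)
    n = x.size
    if y.size != n or c.size != n:
        raise ValueError("x, y and c must have equal length")
    if n < 3:
        raise DegenerateWindowError("window too short")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(c))):
        raise ValueError("signals must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0 or np.ptp(c) == 0:
        raise DegenerateWindowError("degenerate window")
    design = np.column_stack([np.ones(n), c - c.mean()])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    sx = float(rx @ rx)
    sy = float(ry @ ry)
    scale = max(float(x @ x), float(y @ y), 1.0)
    if sx <= scale * 1e-24 or sy <= scale * 1e-24:
        raise DegenerateWindowError("degenerate window")
    r = float(rx @ ry) / math.sqrt(sx * sy)
    return float(np.clip(r, -1.0, 1.0))


def windowed_partial_correlation(
    pfc: np.ndarray, amy: np.ndarray, cst: np.ndarray, L: int
) -> np.ndarray:
    """Per-volume moving-window partial correlation, vectorized.

    Every window is recomputed from scratch (no incremental covariance
    updates); the closed form
    ``(r_xy − r_xc·r_yc) / sqrt((1−r_xc²)(1−r_yc²))`` is applied to each
    window's pairwise Pearson correlations. Returns an array of length
    ``n`` with NaN at positions ``t < L`` (1-based) and at degenerate
    windows (a constant channel or one collinear with the control).
    """
    pfc = np.asarray(pfc, dtype=float)
    amy = np.asarray(amy, dtype=float)
    cst = np.asarray(cst, dtype=float)
    n = pfc.size
    out = np.full(n, np.nan)
    if n < L:
        return out
    stacked = np.stack([pfc, amy, cst], axis=1)  # (n, 3)
    win = np.lib.stride_tricks.sliding_window_view(stacked, L, axis=0)  # (n-L+1, 3, L)
    centered = win - win.mean(axis=2, keepdims=True)
    cov = np.einsum("wil,wjl->wij", centered, centered)  # (n-L+1, 3, 3)
    var = np.einsum("wii->wi", cov)
    flat = (win.max(axis=2) - win.min(axis=2)) == 0  # exact-constant channels
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(var)
        r_xy = cov[:, 0, 1] / (sd[:, 0] * sd[:, 1])
        r_xc = cov[:, 0, 2] / (sd[:, 0] * sd[:, 2])
        r_yc = cov[:, 1, 2] / (sd[:, 1] * sd[:, 2])
        denom = (1.0 - r_xc**2) * (1.0 - r_yc**2)
        rp = (r_xy - r_xc * r_yc) / np.sqrt(denom)
    bad = flat.any(axis=1) | ~np.isfinite(rp) | (denom <= 1e-12)
    rp = np.clip(rp, -1.0, 1.0)
    rp[bad] = np.nan
    out[L - 1 :] = rp
    return out


def fc_to_thermometer(r_p, config: FeedbackConfig):
    """Linear quantization of ``r_p`` onto thermometer segments.

    ``segment = clamp(floor(n_segments·(r_p − lower)/(upper − lower)), 0,
    n_segments)``; the upper bound maps to the full thermometer. Values
    outside the configured range clamp. Accepts scalars or arrays.
    """
    r = np.asarray(r_p, dtype=float)
    frac = (r - config.lower_bound) / (config.upper_bound - config.lower_bound)
    seg = np.floor(config.n_segments * frac + _EDGE_EPS)
    seg = np.clip(seg, 0, config.n_segments)
    if np.ndim(r_p) == 0:
        if not np.isfinite(r):
            raise ValueError("r_p must be finite")
        return int(seg)
    return seg.astype(float)


def displayed_segment(condition: str, r_p, config: FeedbackConfig):
    """Thermometer segment actually shown at one volume.

    During no-feedback mini-blocks the display is frozen at
    ``config.frozen_segment``; during fixation nothing is shown (None);
    during feedback mini-blocks the quantized ``r_p`` is shown, falling
    back to the frozen segment when ``r_p`` is undefined (a real-time
    display must render something).
    """
    if condition == FIXATION:
        return None
    if condition == NONF:
        return config.frozen_segment
    if condition == FCNF:
        if r_p is None or (isinstance(r_p, float) and not math.isfinite(r_p)):
            return config.frozen_segment
        return fc_to_thermometer(float(r_p), config)
    raise ValueError(f"unknown condition label {condition!r}")


@dataclass
class FcStream:
    """Per-volume feedback stream for one run.

    ``table`` columns: volume, condition, block, pos_in_block, r_p,
    n_fcnf, n_nonf, n_fixation, displayed. ``r_p`` is NaN where the
    window is not yet filled or degenerate; ``displayed`` is NaN during
    fixation.
    """

    table: pd.DataFrame = field(repr=False)
    window_length: int = 20

    def defined(self) -> pd.DataFrame:
        """Rows with a defined partial correlation."""
        return self.table[np.isfinite(self.table["r_p"])]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str | Path, window_length: int = 20) -> "FcStream":
        return cls(pd.read_csv(path, sep="\t"), window_length)


def stream_fc(samples: pd.DataFrame, schedule: RunSchedule, config: FeedbackConfig) -> FcStream:
    """Run the real-time feedback computation over one run of ROI samples.

    ``samples`` must provide columns ``pfc``, ``amy``, ``cst`` with one
    row per schedule volume, in acquisition order. For every volume
    ``t >= L`` the partial correlation over the window ``t−L+1..t`` is
    computed; earlier volumes are undefined. Window composition counts
    and the displayed thermometer segment are attached per volume.
    """
    for col in ("pfc", "amy", "cst"):
        if col not in samples.columns:
            raise ValueError(f"samples missing column {col!r}")
    if len(samples) != schedule.n_volumes:
        raise ValueError(
            f"sample count {len(samples)} does not match schedule "
            f"length {schedule.n_volumes}"
        )
    L = config.window_length
    rp = windowed_partial_correlation(
        samples["pfc"].to_numpy(),
        samples["amy"].to_numpy(),
        samples["cst"].to_numpy(),
        L,
    )
    labels = schedule.labels
    onehot = {
        "n_fcnf": (labels == FCNF).astype(np.int64),
        "n_nonf": (labels == NONF).astype(np.int64),
        "n_fixation": (labels == FIXATION).astype(np.int64),
    }
    counts = {}
    for name, ind in onehot.items():
        csum = np.cumsum(ind)
        full = csum[L - 1 :] - np.concatenate([[0], csum[:-L]])
        col = np.zeros(schedule.n_volumes, dtype=np.int64)
        col[L - 1 :] = full
        counts[name] = col
    displayed = np.full(schedule.n_volumes, np.nan)
    for i, lab in enumerate(labels):
        seg = displayed_segment(str(lab), None if not np.isfinite(rp[i]) else float(rp[i]), config)
        if seg is not None:
            displayed[i] = seg
    table = pd.DataFrame(
        {
            "volume": np.arange(1, schedule.n_volumes + 1),
            "condition": labels,
            "block": schedule.block_index,
            "pos_in_block": schedule.position_in_block(),
            "r_p": rp,
            **counts,
            "displayed": displayed,
        }
    )
    return FcStream(table, window_length=L)
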