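"""Subject-level summaries of the feedback stream.

Three scalar measures per subject, plus per-position profiles:

* **initial fc** — mean partial correlation over the first two
  post-fixation mini-blocks of run 1 (one of each condition under the
  alternating design, so the measure is comparable across
  counterbalancing arms);
* **practice-related change** — least-squares slope of per-run mean
  partial correlation on run index (negative slope = drift toward
  negative connectivity, the trained direction);
* **fc-NF-effect** — mean partial correlation during no-feedback
  mini-blocks minus mean during feedback mini-blocks, pooled over runs
  (positive = connectivity more negative under feedback, the desired
  effect).

Profiles average the partial correlation at each within-mini-block
position across mini-blocks and runs, and count how often it is
negative; each volume is attributed to the condition of its own
mini-block even when its window straddles a boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fc import FcStream
from .schedule import FCNF, FIXATION, NONF

__all__ = [
    "SubjectMetrics",
    "position_profile",
    "initial_fc",
    "practice_slope",
    "fcnf_effect",
    "subject_metrics",
]

SLOPE_SCOPES = ("all", "fcnf_only", "nonf_only")


@dataclass
class SubjectMetrics:
    """The per-subject reduction of one or more feedback runs."""

    initial_fc: float
    practice_slope: float
    fcnf_effect: float
    profiles: pd.DataFrame = field(repr=False)


def _as_streams(streams) -> list[FcStream]:
    if isinstance(streams, FcStream):
        return [streams]
    streams = list(streams)
    if not streams:
        raise ValueError("need at least one stream")
    return streams


def position_profile(streams) -> pd.DataFrame:
    """Mean fc and negative-fc counts per condition and block position.

    Accepts one stream or a list of per-run streams; pools defined
    partial-correlation values across mini-blocks and runs. Returns a
    long table with columns ``condition, position, mean_fc, n_negative,
    n_contributing, mean_n_fcnf`` (the last being the average number of
    feedback volumes inside the window at that position, the abscissa
    of the profile-versus-window-count analysis). Positions where no
    window is defined get NaN means and zero counts.
    """
    tables = [s.table for s in _as_streams(streams)]
    pooled = pd.concat(tables, ignore_index=True)
    pooled = pooled[pooled["condition"] != FIXATION]
    rows = []
    for (cond, pos), grp in pooled.groupby(["condition", "pos_in_block"], sort=True):
        vals = grp["r_p"].to_numpy()
        ok = np.isfinite(vals)
        rows.append(
            {
                "condition": cond,
                "position": int(pos),
                "mean_fc": float(np.mean(vals[ok])) if ok.any() else np.nan,
                "n_negative": int(np.sum(vals[ok] < 0)),
                "n_contributing": int(ok.sum()),
                "mean_n_fcnf": float(grp["n_fcnf"].mean()),
            }
        )
    return pd.DataFrame(rows).sort_values(["condition", "position"], ignore_index=True)


def initial_fc(stream: FcStream) -> float:
    """Mean defined fc over the first two post-fixation mini-blocks of run 1."""
    table = _as_streams(stream)[0].table
    mini = sorted(table.loc[table["condition"] != FIXATION, "block"].unique())
    if len(mini) < 2:
        raise ValueError("fewer than two mini-blocks")
    sel = table[table["block"].isin(mini[:2])]
    for b in mini[:2]:
        if not np.isfinite(sel.loc[sel["block"] == b, "r_p"]).any():
            warnings.warn(
                f"mini-block {b} has no defined fc values; initial fc uses the "
                "remaining block only",
                stacklevel=2,
            )
    vals = sel["r_p"].to_numpy()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no defined fc values in the first two mini-blocks")
    return float(vals.mean())


def _run_mean(stream: FcStream, scope: str) -> float:
    table = stream.table[stream.table["condition"] != FIXATION]
    if scope == "fcnf_only":
        table = table[table["condition"] == FCNF]
    elif scope == "nonf_only":
        table = table[table["condition"] == NONF]
    elif scope != "all":
        raise ValueError(f"slope scope must be one of {SLOPE_SCOPES}")
    vals = table["r_p"].to_numpy()
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else np.nan


def practice_slope(run_streams, scope: str = "all") -> float:
    """OLS slope of per-run mean fc on run index 1..n_runs.

    ``scope`` selects which mini-block volumes enter the per-run mean:
    ``all`` (default; both conditions), ``fcnf_only`` or ``nonf_only``.
    Fixation volumes never enter.
    """
    streams = _as_streams(run_streams)
    if len(streams) < 2:
        raise ValueError("practice slope needs at least two runs")
    means = np.array([_run_mean(s, scope) for s in streams])
    runs = np.arange(1, len(streams) + 1, dtype=float)
    ok = np.isfinite(means)
    if ok.sum() < 2:
        raise ValueError("fewer than two runs with defined fc")
    return float(np.polyfit(runs[ok], means[ok], 1)[0])


def fcnf_effect(run_streams) -> float:
    """Mean no-feedback fc minus mean feedback fc, pooled across runs."""
    pooled = pd.concat([s.table for s in _as_streams(run_streams)], ignore_index=True)
    out = {}
    for cond in (NONF, FCNF):
        vals = pooled.loc[pooled["condition"] == cond, "r_p"].to_numpy()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"no defined fc values in condition {cond!r}")
        out[cond] = float(vals.mean())
    return out[NONF] - out[FCNF]


def subject_metrics(run_streams, scope: str = "all") -> SubjectMetrics:
    """All subject-level measures from the per-run feedback streams."""
    streams = _as_streams(run_streams)
    return SubjectMetrics(
        initial_fc=initial_fc(streams[0]),
        practice_slope=practice_slope(streams, scope),
        fcnf_effect=fcnf_effect(streams),
        profiles=position_profile(streams),
    )
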