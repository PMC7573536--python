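"""End-to-end orchestration: simulate → stream → metrics → group stats → moderation.

``run_pipeline`` executes the full offline analysis on a synthetic
cohort, writes every intermediate table, and returns (and writes) one
JSON report with every statistic. The run is fully reproducible from
``(config, seed)``; each stage derives its own seed from the global one
(see :mod:`fcnf.config`) and log lines carry stage names, seeds, and
content digests of written tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import groupstats, moderation
from .config import PipelineConfig, stage_seed
from .fc import FcStream, stream_fc
from .metrics import position_profile, subject_metrics
from .schedule import RunSchedule, build_run_schedule
from .simulate import CohortData, simulate_cohort
from .tables import digest, write_table

log = logging.getLogger("fcnf.pipeline")

__all__ = ["run_pipeline", "compute_cohort_streams", "compute_cohort_metrics"]

#: brain–behaviour pairs examined at the group level
BRAIN_BEHAVIOUR_PAIRS = [
    ("initial_fc", "stai_t"),
    ("initial_fc", "tcaq_pre"),
    ("practice_slope", "tcaq_change"),
    ("fcnf_effect", "stai_s"),
]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def compute_cohort_streams(
    cohort: CohortData, feedback_config
) -> dict[str, list[FcStream]]:
    """Per-subject, per-run feedback streams for a simulated cohort."""
    streams: dict[str, list[FcStream]] = {}
    for subject, grp in cohort.timeseries.groupby("subject", sort=True):
        sched = cohort.schedules[subject]
        streams[subject] = [
            stream_fc(grp[grp["run"] == run], sched, feedback_config)
            for run in range(1, cohort.n_runs + 1)
        ]
    return streams


def compute_cohort_metrics(
    streams: dict[str, list[FcStream]], scope: str = "all"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject metrics table and long per-subject profile table."""
    metric_rows = []
    profile_frames = []
    for subject, runs in streams.items():
        m = subject_metrics(runs, scope)
        metric_rows.append(
            {
                "subject": subject,
                "initial_fc": m.initial_fc,
                "practice_slope": m.practice_slope,
                "fcnf_effect": m.fcnf_effect,
            }
        )
        prof = m.profiles.copy()
        prof.insert(0, "subject", subject)
        profile_frames.append(prof)
    return (
        pd.DataFrame(metric_rows),
        pd.concat(profile_frames, ignore_index=True),
    )


@_stage("groupstats")
def _group_stage(metrics, covariates, profiles, cfg, seed):
    gp = groupstats.group_profile(profiles)
    report = {"profile_correlations": {}, "brain_behaviour": [], "t_tests": {}}
    for outcome in ("mean_fc", "n_negative"):
        res = groupstats.profile_vs_count(gp, outcome)
        report["profile_correlations"][outcome] = {
            "r": res.r,
            "n": res.n,
            "p": res.p,
            "zero_variance": res.zero_variance,
        }
    merged = metrics.merge(covariates, on="subject")
    merged["tcaq_change"] = merged["tcaq_post"] - merged["tcaq_pre"]
    threshold = cfg.stats.outlier_threshold or groupstats.DEFAULT_OUTLIER_THRESHOLD
    corr_rows = []
    for i, (mx, my) in enumerate(BRAIN_BEHAVIOUR_PAIRS):
        res = groupstats.correlate_measures(
            merged[mx],
            merged[my],
            remove_outliers=True,
            B=cfg.stats.bootstrap_b,
            threshold=threshold,
            seed=seed + i,
        )
        corr_rows.append(
            {
                "measure_x": mx,
                "measure_y": my,
                "n": res.n,
                "r": res.r,
                "p": res.p,
                "n_outliers": int(res.outliers.size),
                "r_clean": res.r_after_removal,
                "p_clean": res.p_after_removal,
            }
        )
    report["brain_behaviour"] = corr_rows
    t, df, p = groupstats.paired_t(merged["tcaq_pre"], merged["tcaq_post"])
    report["t_tests"]["tcaq_pre_post"] = {"t": t, "df": df, "p": p}
    t, df, p = groupstats.one_sample_t(merged["fcnf_effect"], 0.0)
    report["t_tests"]["fcnf_effect_vs_zero"] = {"t": t, "df": df, "p": p}
    return gp, pd.DataFrame(corr_rows), report


@_stage("moderation")
def _moderation_stage(metrics, covariates):
    merged = metrics.merge(covariates, on="subject")
    fit = moderation.fit_model3(
        merged["stai_s"], merged["gaba_pfc"], merged["gaba_acc"], merged["fcnf_effect"]
    )
    slopes = moderation.simple_slopes(fit)
    report = {
        "f_value": fit.f_value,
        "p": fit.f_p,
        "df": [fit.df_model, fit.df_resid],
        "r_squared": fit.r_squared,
        "n": fit.n,
        "coefficients": fit.coefficients.to_dict(orient="records"),
        "simple_slopes": slopes.to_dict(orient="records"),
    }
    return fit, slopes, report


def run_pipeline(config: PipelineConfig, output_dir: str | Path) -> dict:
    """Run every stage and write tables plus a single JSON report."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    schedule = build_run_schedule(
        config.design.fixation_len,
        config.design.n_pairs,
        config.design.fcnf_len,
        config.design.nonf_len,
        config.design.start_condition,
    )
    feedback = config.feedback.to_feedback_config()

    sim_seed = stage_seed(config.seed, "simulate")
    log.info("stage=simulate seed=%d n_subjects=%d", sim_seed, config.simulate.n_subjects)
    try:
        cohort = simulate_cohort(
            config.simulate.to_cohort_params(sim_seed),
            schedule,
            n_runs=config.design.n_runs,
            counterbalance=config.simulate.counterbalance,
        )
    except Exception as exc:
        raise PipelineError(f"stage 'simulate' failed: {exc}") from exc

    schedule.to_tsv(out / "schedule.tsv")
    (out / "schedule.json").write_text(schedule.to_json_blocks())
    write_table(cohort.timeseries, out / "timeseries.tsv")
    write_table(cohort.covariates, out / "covariates.tsv")
    log.info("stage=simulate wrote timeseries.tsv digest=%s", digest(out / "timeseries.tsv"))

    try:
        streams = compute_cohort_streams(cohort, feedback)
        stream_tables = []
        for subject, runs in streams.items():
            for run_idx, s in enumerate(runs, start=1):
                t = s.table.copy()
                t.insert(0, "run", run_idx)
                t.insert(0, "subject", subject)
                stream_tables.append(t)
        write_table(pd.concat(stream_tables, ignore_index=True), out / "streams.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'feedback' failed: {exc}") from exc
    log.info("stage=feedback wrote streams.tsv digest=%s", digest(out / "streams.tsv"))

    try:
        metrics, profiles = compute_cohort_metrics(streams, config.stats.slope_scope)
    except Exception as exc:
        raise PipelineError(f"stage 'metrics' failed: {exc}") from exc
    write_table(metrics, out / "metrics.tsv")
    write_table(profiles, out / "profiles.tsv")
    log.info("stage=metrics wrote metrics.tsv digest=%s", digest(out / "metrics.tsv"))

    group_seed = stage_seed(config.seed, "groupstats")
    log.info("stage=groupstats seed=%d", group_seed)
    gp, corr_table, group_report = _group_stage(
        metrics, cohort.covariates, profiles, config, group_seed
    )
    write_table(gp, out / "group_profile.tsv")
    write_table(corr_table, out / "correlations.tsv")

    mod_report = None
    if config.simulate.n_subjects >= 10:
        fit, slopes, mod_report = _moderation_stage(metrics, cohort.covariates)
        write_table(fit.coefficients, out / "moderation_coefficients.tsv")
        write_table(slopes, out / "simple_slopes.tsv")

    report = {
        "config": json.loads(config.model_dump_json()),
        "seeds": {
            "global": config.seed,
            "simulate": sim_seed,
            "groupstats": group_seed,
        },
        "n_volumes_per_run": schedule.n_volumes,
        "groupstats": group_report,
        "moderation": mod_report,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log.info("wrote report.json digest=%s", digest(out / "report.json"))
    return report
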