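"""Synthetic ROI time series and cohort covariates.

The generator emulates, at the level the analysis actually touches, the
statistical structure of a connectivity-neurofeedback session:

* PFC and amygdala innovations are bivariate Gaussian with an
  instantaneous correlation ``ρ(t)`` that is piecewise constant per
  block: ``ρ(t) = rho_base + delta_response·1[feedback block]
  + run_drift·(run − 1)``. A negative ``delta_response`` is a subject
  who successfully shifts connectivity toward negative values under
  feedback.
* Each channel is passed through an order-1 autoregression
  (``ar_coef``) to give BOLD-like temporal smoothness.
* A shared nuisance component loads on all three channels: the control
  (CST) channel *is* the nuisance process (loading 1), and it leaks
  into PFC and amygdala with loading ``gamma``. Because the task
  channels' nuisance share is an exact multiple of the control signal,
  regressing the control channel out removes it fully — the design
  property the control-region partialling relies on. (An additive
  confound with an extra independent control-channel noise term would
  leave residual confounding that no amount of partialling removes.)
* Apart from the leak, the control channel is independent noise.

At the cohort level, subject parameters are deterministic functions of
Gaussian covariates plus noise, with signs chosen to mirror the
brain–behaviour relationships the analysis is designed to detect:
trait anxiety raises baseline connectivity, thought-control ability
lowers it, state anxiety attenuates the feedback response, and the
PFC-GABA × ACC-GABA product moderates that attenuation. No hemodynamic
convolution is applied: the analysis operates on ROI signals directly
and the moving window itself smears block transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .schedule import FCNF, RunSchedule

__all__ = ["SubjectParams", "CohortParams", "CohortData",
           "simulate_subject_timeseries", "draw_cohort_params", "simulate_cohort"]


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters for one subject's ROI time series."""

    rho_base: float = 0.15
    delta_response: float = -0.15
    run_drift: float = 0.0
    gamma: float = 0.5
    ar_coef: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.rho_base < 1.0:
            raise ValueError("rho_base must lie in (-1, 1)")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValueError("ar_coef must lie in [0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def _rho_per_volume(params: SubjectParams, schedule: RunSchedule, run: int) -> np.ndarray:
    rho = np.full(schedule.n_volumes, params.rho_base, dtype=float)
    rho[schedule.labels == FCNF] += params.delta_response
    rho += params.run_drift * (run - 1)
    if np.any(np.abs(rho) >= 1.0):
        raise ValueError("invalid coupling: |rho(t)| >= 1 at some volume")
    return rho


def simulate_subject_timeseries(
    params: SubjectParams, schedule: RunSchedule, n_runs: int
) -> pd.DataFrame:
    """Generate a tidy per-volume table for one subject.

    Returns columns ``run, volume, condition, pfc, amy, cst``. The PFC
    and amygdala innovation correlation at volume ``t`` equals ``ρ(t)``
    exactly (correlated streams are produced by the mixing construction
    ``y = ρ·x + sqrt(1−ρ²)·e``); reproducible from ``params.seed``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(params.seed)
    n = schedule.n_volumes
    frames = []
    for run in range(1, n_runs + 1):
        rho = _rho_per_volume(params, schedule, run)
        x = rng.standard_normal(n)
        e = rng.standard_normal(n)
        w = rng.standard_normal(n)
        y = rho * x + np.sqrt(1.0 - rho**2) * e
        ar = [1.0, -params.ar_coef]
        cst = lfilter([1.0], ar, params.noise_sd * w)
        pfc = lfilter([1.0], ar, params.noise_sd * x) + params.gamma * cst
        amy = lfilter([1.0], ar, params.noise_sd * y) + params.gamma * cst
        frames.append(
            pd.DataFrame(
                {
                    "run": run,
                    "volume": np.arange(1, n + 1),
                    "condition": schedule.labels,
                    "pfc": pfc,
                    "amy": amy,
                    "cst": cst,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class CohortParams:
    """Cohort size, covariate distributions, and covariate→parameter links.

    Link coefficients are per standard deviation of the (population-
    standardized) covariate, on the correlation scale of the parameter
    they feed. Signs encode the relationships the group analysis is
    meant to recover; magnitudes are generator conventions chosen for
    adequate power at cohort sizes of a few hundred.
    """

    n_subjects: int = 20
    seed: int = 0
    # covariate distributions (questionnaire totals and GABA/Cr ratios)
    stai_s_mean: float = 38.0
    stai_s_sd: float = 9.0
    stai_t_mean: float = 40.0
    stai_t_sd: float = 9.0
    tcaq_pre_mean: float = 80.0
    tcaq_pre_sd: float = 12.0
    tcaq_change_mean: float = 4.0
    gaba_pfc_mean: float = 1.1
    gaba_pfc_sd: float = 0.12
    gaba_acc_mean: float = 1.2
    gaba_acc_sd: float = 0.12
    # baseline-connectivity links
    rho_base_mean: float = 0.15
    link_stait_rho: float = 0.08
    link_tcaq_rho: float = -0.08
    rho_noise_sd: float = 0.08
    # feedback-response links (X = state anxiety, W = PFC GABA, Z = ACC GABA)
    delta_mean: float = -0.15
    link_stais_delta: float = 0.04
    link_xw_delta: float = -0.035
    link_xwz_delta: float = 0.04
    delta_noise_sd: float = 0.04
    # practice drift and its reflection in thought-control change
    drift_mean: float = -0.01
    drift_sd: float = 0.015
    link_drift_tcaq: float = 2.5
    tcaq_change_noise_sd: float = 3.0
    # time-series nuisance structure shared by all subjects
    gamma: float = 0.5
    ar_coef: float = 0.3
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name in ("stai_s_sd", "stai_t_sd", "tcaq_pre_sd", "gaba_pfc_sd", "gaba_acc_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class CohortData:
    """Everything one simulated cohort produces."""

    timeseries: pd.DataFrame = field(repr=False)
    covariates: pd.DataFrame = field(repr=False)
    subject_params: list[SubjectParams] = field(repr=False)
    schedules: dict[str, RunSchedule] = field(repr=False)
    n_runs: int = 4


def draw_cohort_params(
    cohort: CohortParams,
) -> tuple[pd.DataFrame, list[SubjectParams]]:
    """Draw covariates and derive per-subject generative parameters.

    Covariates are Gaussian; subject parameters are the stated link
    functions of the *population*-standardized covariates plus Gaussian
    noise, so the generating coefficients are exact regardless of the
    sample draw. Reproducible from ``cohort.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cohort.seed, 0]))
    n = cohort.n_subjects
    stai_s = cohort.stai_s_mean + cohort.stai_s_sd * rng.standard_normal(n)
    stai_t = cohort.stai_t_mean + cohort.stai_t_sd * rng.standard_normal(n)
    tcaq_pre = cohort.tcaq_pre_mean + cohort.tcaq_pre_sd * rng.standard_normal(n)
    gaba_pfc = cohort.gaba_pfc_mean + cohort.gaba_pfc_sd * rng.standard_normal(n)
    gaba_acc = cohort.gaba_acc_mean + cohort.gaba_acc_sd * rng.standard_normal(n)

    zs = (stai_s - cohort.stai_s_mean) / cohort.stai_s_sd
    zt = (stai_t - cohort.stai_t_mean) / cohort.stai_t_sd
    zq = (tcaq_pre - cohort.tcaq_pre_mean) / cohort.tcaq_pre_sd
    zw = (gaba_pfc - cohort.gaba_pfc_mean) / cohort.gaba_pfc_sd
    zz = (gaba_acc - cohort.gaba_acc_mean) / cohort.gaba_acc_sd

    rho_base = (
        cohort.rho_base_mean
        + cohort.link_stait_rho * zt
        + cohort.link_tcaq_rho * zq
        + cohort.rho_noise_sd * rng.standard_normal(n)
    )
    delta = (
        cohort.delta_mean
        + cohort.link_stais_delta * zs
        + cohort.link_xw_delta * zs * zw
        + cohort.link_xwz_delta * zs * zw * zz
        + cohort.delta_noise_sd * rng.standard_normal(n)
    )
    drift = cohort.drift_mean + cohort.drift_sd * rng.standard_normal(n)
    z_drift = (drift - cohort.drift_mean) / cohort.drift_sd
    tcaq_change = (
        cohort.tcaq_change_mean
        - cohort.link_drift_tcaq * z_drift
        + cohort.tcaq_change_noise_sd * rng.standard_normal(n)
    )
    # keep every subject inside the admissible coupling range
    rho_base = np.clip(rho_base, -0.85, 0.85)
    delta = np.clip(delta, -0.95 - rho_base, 0.95 - rho_base)

    covariates = pd.DataFrame(
        {
            "subject": [f"sub{i + 1:03d}" for i in range(n)],
            "stai_s": stai_s,
            "stai_t": stai_t,
            "tcaq_pre": tcaq_pre,
            "tcaq_post": tcaq_pre + tcaq_change,
            "gaba_pfc": gaba_pfc,
            "gaba_acc": gaba_acc,
        }
    )
    subject_seeds = np.random.SeedSequence([cohort.seed, 1]).generate_state(n) % (2**31)
    params = [
        SubjectParams(
            rho_base=float(rho_base[i]),
            delta_response=float(delta[i]),
            run_drift=float(drift[i]),
            gamma=cohort.gamma,
            ar_coef=cohort.ar_coef,
            noise_sd=cohort.noise_sd,
            seed=int(subject_seeds[i]),
        )
        for i in range(n)
    ]
    return covariates, params


def simulate_cohort(
    cohort: CohortParams,
    schedule: RunSchedule,
    n_runs: int = 4,
    counterbalance: bool = True,
) -> CohortData:
    """Simulate time series and covariates for a whole cohort.

    When ``counterbalance`` is set, exactly half the subjects (seeded
    assignment) receive the supplied schedule with feedback and
    no-feedback mini-blocks exchanged, emulating start-condition
    counterbalancing.
    """
    covariates, params = draw_cohort_params(cohort)
    swapped = schedule.with_swapped_conditions()
    if counterbalance:
        from .schedule import counterbalanced_starts

        first = str(schedule.labels[schedule.labels != "fixation"][0])
        starts = counterbalanced_starts(
            cohort.n_subjects,
            int(np.random.SeedSequence([cohort.seed, 2]).generate_state(1)[0] % (2**31)),
        )
        schedules = {
            covariates["subject"][i]: schedule if starts[i] == first else swapped
            for i in range(cohort.n_subjects)
        }
    else:
        schedules = {s: schedule for s in covariates["subject"]}
    frames = []
    for i, subject in enumerate(covariates["subject"]):
        ts = simulate_subject_timeseries(params[i], schedules[subject], n_runs)
        ts.insert(0, "subject", subject)
        frames.append(ts)
    return CohortData(
        timeseries=pd.concat(frames, ignore_index=True),
        covariates=covariates,
        subject_params=params,
        schedules=schedules,
        n_runs=n_runs,
    )
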