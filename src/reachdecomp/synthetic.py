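"""Synthetic cohorts with the statistical structure of intensive reach training.

No trial-level data were deposited with the study this package analyses, so
every downstream stage (fitting, metrics, statistics) is exercised on
synthetic cohorts built here.  The generator emulates a study with 16
"stroke" and 10 "control" subjects, each performing a 600-movement session
(120 reaches to each of 5 targets in pseudo-random order), with

* subject-level heterogeneity: ``A`` and ``tau`` log-normal (positive,
  right-skewed) with medians at the published group medians and log-scale
  SDs calibrated so the quartiles match the published IQRs; ``C`` and the
  ``D_k`` normal around the published medians,
* additive homoscedastic Gaussian trial noise (76 ms stroke / 24 ms control,
  the residual scale a well-specified fit reports), and
* test-phase summaries (Pre1 and 1-month means) in which the long-term gain
  is driven by the learning amplitude through a single retention fraction —
  a deliberately simple, synthetic-only retention model.

The generating per-subject parameters are kept losslessly in the returned
cohort so that recovery of them by the fitter can be measured exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import N_TARGETS, SubjectParams, predict_mt

# log-scale SD that maps a log-normal's IQR [q25, q75] onto the normal
# quartile points: sd = ln(q75/q25) / (2 * 0.6745)
_Z75 = 0.6744897501960817


def lognormal_sd_from_iqr(q25: float, q75: float) -> float:
    """Log-scale SD of a log-normal whose quartiles are q25 and q75."""
    if not 0 < q25 < q75:
        raise ValueError("need 0 < q25 < q75")
    return float(np.log(q75 / q25) / (2 * _Z75))


def normal_sd_from_iqr(q25: float, q75: float) -> float:
    """SD of a normal whose quartiles are q25 and q75."""
    if q75 <= q25:
        raise ValueError("need q25 < q75")
    return float((q75 - q25) / (2 * _Z75))


@dataclass(frozen=True)
class CohortConfig:
    """Population recipe for one synthetic group.

    Medians anchor the subject-parameter distributions (log-normal for
    ``A``/``tau``, normal for ``C``/``D_k``).  ``d_medians`` must be the
    five per-target intercept medians in target order; the defaults
    interpolate linearly between the published first and last target since
    the intermediate medians increase monotonically but were not printed.
    """

    group: str
    n_subjects: int
    a_median: float          # ms
    tau_median: float        # trials
    c_median: float          # ms/trial
    d_medians: tuple[float, ...]  # ms, one per target
    a_log_sd: float = 0.0
    tau_log_sd: float = 0.0
    c_sd: float = 0.0
    d_sd: float = 0.0
    sigma_eps: float = 0.0   # trial-noise SD, ms
    retention_fraction: float = 0.8
    retention_noise_sd: float = 0.0  # ms, on the test-phase means
    n_targets: int = N_TARGETS
    trials_per_target: int = 120
    mt_floor: float = 50.0   # ms; guards against non-physical negatives
    no_immediate_repeat: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("stroke", "control"):
            raise ValueError(f"unknown group label {self.group!r}")
        if self.a_median <= 0 or self.tau_median <= 0:
            raise ValueError("log-normal medians (A, tau) must be positive")
        if any(d <= 0 for d in self.d_medians):
            raise ValueError("target-intercept medians must be positive")
        if len(self.d_medians) != self.n_targets:
            raise ValueError("one D median per target required")
        if min(self.a_log_sd, self.tau_log_sd, self.c_sd, self.d_sd,
               self.sigma_eps, self.retention_noise_sd) < 0:
            raise ValueError("dispersions must be non-negative")
        if not 0 <= self.retention_fraction <= 1:
            raise ValueError("retention fraction must lie in [0, 1]")

    @property
    def session_length(self) -> int:
        return self.n_targets * self.trials_per_target


def stroke_config(n_subjects: int = 16, seed: int = 0, **over) -> CohortConfig:
    """Stroke-group recipe at the published medians and IQR-calibrated SDs."""
    kw = dict(
        group="stroke", n_subjects=n_subjects,
        a_median=279.0, tau_median=64.0, c_median=1.11,
        d_medians=(328.0, 354.0, 380.0, 406.0, 432.0),
        a_log_sd=lognormal_sd_from_iqr(210.0, 455.0),
        tau_log_sd=lognormal_sd_from_iqr(44.0, 145.0),
        c_sd=normal_sd_from_iqr(0.57, 1.59),
        d_sd=normal_sd_from_iqr(392.0, 445.0),
        sigma_eps=76.0, retention_noise_sd=30.0, seed=seed,
    )
    kw.update(over)
    return CohortConfig(**kw)


def control_config(n_subjects: int = 10, seed: int = 0, **over) -> CohortConfig:
    """Control-group recipe at the published medians and IQR-calibrated SDs."""
    kw = dict(
        group="control", n_subjects=n_subjects,
        a_median=128.0, tau_median=36.0, c_median=0.12,
        d_medians=(227.0, 243.5, 260.0, 276.5, 293.0),
        a_log_sd=lognormal_sd_from_iqr(100.0, 151.0),
        tau_log_sd=lognormal_sd_from_iqr(24.0, 58.0),
        c_sd=normal_sd_from_iqr(0.07, 0.16),
        d_sd=normal_sd_from_iqr(266.0, 327.0),
        sigma_eps=24.0, retention_noise_sd=15.0, seed=seed,
    )
    kw.update(over)
    return CohortConfig(**kw)


def draw_subject_params(config: CohortConfig, rng: np.random.Generator,
                        subject_id: str = "S1") -> SubjectParams:
    """Draw one subject from the population recipe.

    ``A`` and ``tau`` are log-normal with median = the configured median
    (the location parameter of a log-normal is its log-median, so the
    sample median converges to the recipe value); ``C`` and the ``D_k``
    are normal around their medians.
    """
    a = config.a_median * np.exp(rng.normal(0.0, config.a_log_sd))
    tau = config.tau_median * np.exp(rng.normal(0.0, config.tau_log_sd))
    c = rng.normal(config.c_median, config.c_sd)
    d = tuple(rng.normal(m, config.d_sd) for m in config.d_medians)
    return SubjectParams(subject_id, float(a), float(tau), float(c), d)


def draw_cohort_params(config: CohortConfig,
                       rng: np.random.Generator) -> list[SubjectParams]:
    prefix = "S" if config.group == "stroke" else "C"
    return [draw_subject_params(config, rng, f"{prefix}{i + 1}")
            for i in range(config.n_subjects)]


def _target_sequence(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Pseudo-random target order with exact per-target counts.

    With ``no_immediate_repeat`` the next target is always one of the other
    four locations, as in the training protocol.  Sequential weighted draws
    restart on the (rare) dead end where only the previous target remains.
    """
    counts0 = np.full(config.n_targets, config.trials_per_target)
    if not config.no_immediate_repeat:
        seq = np.repeat(np.arange(1, config.n_targets + 1), config.trials_per_target)
        rng.shuffle(seq)
        return seq
    while True:
        counts = counts0.copy()
        seq = np.empty(config.session_length, dtype=int)
        prev = -1
        ok = True
        for i in range(config.session_length):
            w = counts.astype(float)
            if prev >= 0:
                w[prev] = 0.0
            tot = w.sum()
            if tot == 0:
                ok = False
                break
            tgt = rng.choice(config.n_targets, p=w / tot)
            seq[i] = tgt + 1
            counts[tgt] -= 1
            prev = tgt
        if ok:
            return seq


def generate_training_trials(subjects: list[SubjectParams], config: CohortConfig,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Trial table for a full training session per subject.

    Columns: subject, group, global_trial (1..600), t (per-target occurrence
    index, 1-based), target (1..5), mt_ms.  MT = structural prediction +
    N(0, sigma_eps), floored at ``mt_floor``.
    """
    frames = []
    for sp in subjects:
        targets = _target_sequence(config, rng)
        t_idx = np.empty_like(targets)
        seen = np.zeros(config.n_targets, dtype=int)
        for i, k in enumerate(targets):
            seen[k - 1] += 1
            t_idx[i] = seen[k - 1]
        mt = predict_mt(sp, t_idx, targets)
        if config.sigma_eps > 0:
            mt = mt + rng.normal(0.0, config.sigma_eps, size=mt.shape)
        mt = np.maximum(mt, config.mt_floor)
        frames.append(pd.DataFrame({
            "subject": sp.subject_id,
            "group": config.group,
            "global_trial": np.arange(1, config.session_length + 1),
            "t": t_idx,
            "target": targets,
            "mt_ms": mt,
        }))
    return pd.concat(frames, ignore_index=True)


def generate_test_phases(subjects: list[SubjectParams], config: CohortConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Pre1 and 1-month mean MTs per subject (rested: no fatigue term).

    Pre1 reflects naive performance, mean_k(A + D_k); at one month a
    fraction ``retention_fraction`` of the learning amplitude is retained,
    so the 1-month mean is mean_k(D_k) + (1 - retention) * A.  Gaussian
    noise of SD ``retention_noise_sd`` is added to each mean.  This
    generative link between training and retention is a synthetic-only
    construction: by design the long-term change is driven by the learning
    component, which is the structure the prediction analyses look for.
    """
    rows = []
    for sp in subjects:
        d_bar = float(np.mean(sp.D))
        pre1 = sp.A + d_bar
        one_month = (1.0 - config.retention_fraction) * sp.A + d_bar
        if config.retention_noise_sd > 0:
            pre1 += rng.normal(0.0, config.retention_noise_sd)
            one_month += rng.normal(0.0, config.retention_noise_sd)
        pre1 = max(pre1, config.mt_floor)
        one_month = max(one_month, config.mt_floor)
        rows.append({
            "subject": sp.subject_id,
            "group": config.group,
            "mt_pre1_ms": pre1,
            "mt_1month_ms": one_month,
            "long_term_change": (pre1 - one_month) / pre1,
        })
    return pd.DataFrame(rows)


@dataclass
class SyntheticCohort:
    """One generated group: parameters, trials, test phases, provenance."""

    config: CohortConfig
    subjects: list[SubjectParams]
    trials: pd.DataFrame
    test_phases: pd.DataFrame

    def provenance(self) -> dict:
        return {"config": asdict(self.config), "seed": self.config.seed}

    def params_frame(self) -> pd.DataFrame:
        rows = []
        for sp in self.subjects:
            row = {"subject": sp.subject_id, "group": self.config.group,
                   "A": sp.A, "tau": sp.tau, "C": sp.C}
            row.update({f"D{k + 1}": d for k, d in enumerate(sp.D)})
            rows.append(row)
        return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Full cohort draw from ``config.seed``: params, trials, test phases."""
    rng = np.random.default_rng(config.seed)
    subjects = draw_cohort_params(config, rng)
    trials = generate_training_trials(subjects, config, rng)
    phases = generate_test_phases(subjects, config, rng)
    return SyntheticCohort(config, subjects, trials, phases)


# ---------------------------------------------------------------------------
# Minimum-jerk trajectory fixture for the kinematics stage

#: Fraction of the minimum-jerk duration spanned by the 5%-of-peak-speed
#: crossings: 2*root of s^2 (1-s)^2 = 0.05 * 0.0625 solved for s < 1/2,
#: i.e. sqrt(1 - 4 sqrt(0.05)/ (2 ... )) — evaluated once, see tests.
MINJERK_SPAN_FRACTION = float(np.sqrt(1.0 - 4.0 * 0.25 * np.sqrt(0.05)))


def minimum_jerk_position(s: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk path coordinate: 10s^3 - 15s^4 + 6s^5."""
    s = np.clip(s, 0.0, 1.0)
    return 10 * s**3 - 15 * s**4 + 6 * s**5


@dataclass(frozen=True)
class TrajectorySample:
    """A simulated fingertip trace with its ground-truth movement time."""

    frame: pd.DataFrame          # columns t_s, x_cm, y_cm
    true_mt_ms: float            # continuous-time 5%-threshold span
    duration_ms: float
    distance_cm: float
    target_x_cm: float
    target_y_cm: float
    sample_rate_hz: float


def generate_trajectory(duration_ms: float, distance_cm: float,
                        sample_rate_hz: float,
                        rng: np.random.Generator | None = None,
                        *, angle_deg: float = 90.0, noise_sd_cm: float = 0.0,
                        pad_s: float = 0.3) -> TrajectorySample:
    """Planar minimum-jerk reach from the home position with stationary padding.

    ``duration_ms`` is the full minimum-jerk duration; the ground-truth
    movement time (onset/offset at 5% of peak speed) is
    ``MINJERK_SPAN_FRACTION * duration_ms`` and is returned alongside the
    sampled trace so extraction error can be measured exactly.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    if distance_cm <= 0:
        raise ValueError("distance must be positive (zero-extent reach is degenerate)")
    T = duration_ms / 1000.0
    if sample_rate_hz * T < 20:
        raise ValueError(
            f"sample rate {sample_rate_hz} Hz resolves only "
            f"{sample_rate_hz * T:.0f} samples within the movement (< 20)")
    n_pad = int(round(pad_s * sample_rate_hz))
    n_move = int(round(T * sample_rate_hz))
    n = n_pad + n_move + n_pad + 1
    t = np.arange(n) / sample_rate_hz
    s = (t - pad_s) / T
    theta = np.deg2rad(angle_deg)
    path = distance_cm * minimum_jerk_position(s)
    x = path * np.cos(theta)
    y = path * np.sin(theta)
    if noise_sd_cm > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd_cm > 0")
        x = x + rng.normal(0.0, noise_sd_cm, size=n)
        y = y + rng.normal(0.0, noise_sd_cm, size=n)
    frame = pd.DataFrame({"t_s": t, "x_cm": x, "y_cm": y})
    return TrajectorySample(
        frame=frame,
        true_mt_ms=MINJERK_SPAN_FRACTION * duration_ms,
        duration_ms=duration_ms,
        distance_cm=distance_cm,
        target_x_cm=float(distance_cm * np.cos(theta)),
        target_y_cm=float(distance_cm * np.sin(theta)),
        sample_rate_hz=sample_rate_hz,
    )
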