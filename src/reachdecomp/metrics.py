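"""Derived learning and performance quantities per subject.

From the fitted per-subject parameters the analysis derives, with
``model(t) = A e^(-t/tau) + C t + mean_k(D_k)`` and ``T`` the number of
trials per target:

* initial performance      — model(1), the modelled MT on the first trial;
* amount of learning       — A (e^(-1/tau) - e^(-T/tau)), the drop of the
  exponential component across training;
* normalized learning      — amount of learning / initial performance;
* final fatigue            — C T, the linear worsening accumulated by the
  last trial;
* normalized performance change — (model(1) - model(T)) / initial
  performance, the *net* modelled improvement, i.e. learning minus the
  fatigue accrued between first and last trial;
* half-life                — tau ln 2, trials for the learning component
  to halve.

The learning/performance distinction lives in the gap between normalized
learning and normalized performance change: they coincide exactly when
C = 0 and diverge by C (T-1) / initial performance otherwise.

Long-term performance change is a test-phase quantity, independent of the
model fit: (mean Pre1 MT - mean 1-month MT) / mean Pre1 MT, positive when
the subject improved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import SubjectParams


@dataclass(frozen=True)
class DerivedMetrics:
    subject_id: str
    initial_performance_ms: float
    amount_of_learning_ms: float
    normalized_learning: float
    final_fatigue_ms: float
    normalized_performance_change: float
    half_life_trials: float          # full precision; round only for reports


@dataclass(frozen=True)
class TestPhaseSummary:
    subject_id: str
    mt_pre1_ms: float
    mt_1month_ms: float

    def __post_init__(self) -> None:
        if self.mt_pre1_ms <= 0 or self.mt_1month_ms <= 0:
            raise ValueError("test-phase mean MTs must be positive")


def _model_mean_target(params: SubjectParams, t: float) -> float:
    d_bar = float(np.mean(params.D))
    return params.A * np.exp(-t / params.tau) + params.C * t + d_bar


def derive_metrics(params: SubjectParams, trials_per_target: int = 120) -> DerivedMetrics:
    """All per-subject derived quantities, targets aggregated by mean(D_k)."""
    T = trials_per_target
    if T < 2:
        raise ValueError("need at least 2 trials per target")
    initial = _model_mean_target(params, 1.0)
    if initial <= 0:
        raise ValueError(
            f"initial performance {initial:.1f} ms is non-positive; "
            f"normalized quantities undefined")
    learning = params.A * (np.exp(-1.0 / params.tau) - np.exp(-T / params.tau))
    final_model = _model_mean_target(params, float(T))
    return DerivedMetrics(
        subject_id=params.subject_id,
        initial_performance_ms=float(initial),
        amount_of_learning_ms=float(learning),
        normalized_learning=float(learning / initial),
        final_fatigue_ms=float(params.C * T),
        normalized_performance_change=float((initial - final_model) / initial),
        half_life_trials=float(half_life(params.tau, rounded=False)),
    )


def metrics_frame(subjects: list[SubjectParams], trials_per_target: int = 120,
                  groups: list[str] | None = None) -> pd.DataFrame:
    rows = []
    for i, sp in enumerate(subjects):
        m = derive_metrics(sp, trials_per_target)
        row = {
            "subject": m.subject_id,
            "initial_performance_ms": m.initial_performance_ms,
            "amount_of_learning_ms": m.amount_of_learning_ms,
            "normalized_learning": m.normalized_learning,
            "final_fatigue_ms": m.final_fatigue_ms,
            "normalized_performance_change": m.normalized_performance_change,
            "half_life_trials": m.half_life_trials,
        }
        if groups is not None:
            row["group"] = groups[i]
        rows.append(row)
    return pd.DataFrame(rows)


def long_term_change(summary: TestPhaseSummary) -> float:
    """(Pre1 - 1-month) / Pre1; positive values mean long-term improvement."""
    if summary.mt_pre1_ms <= 0:
        raise ValueError("Pre1 mean MT must be positive")
    return (summary.mt_pre1_ms - summary.mt_1month_ms) / summary.mt_pre1_ms


def half_life(tau: float, *, rounded: bool = True) -> float:
    """Trials for the exponential learning component to halve: tau ln 2.

    Reports round to the nearest integer trial; internal computations keep
    full precision.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    hl = tau * np.log(2.0)
    return float(round(hl)) if rounded else float(hl)
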