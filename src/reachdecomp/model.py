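"""Structural model of movement time during intensive reach training.

A subject's movement time (MT, in ms) on the ``t``-th reach to target ``k``
is decomposed into a decreasing exponential (motor learning), an increasing
linear term (activity-dependent fatigability and other learning-unrelated
worsening), and a target-specific asymptote::

    MT(t, k) = A * exp(-t / tau) + C * t + D_k + noise

with ``A`` (ms) the exponential amplitude, ``tau`` (trials) the decay
constant, ``C`` (ms/trial) the fatigue slope, and ``D_k`` (ms) the
per-target intercept.  ``t`` is the *per-target* occurrence index, starting
at 1: with five targets and 120 reaches to each, a 600-movement session maps
to t = 1..120 for each target.  This indexing sets the scale of ``tau`` —
a tau of 64 means the learning component halves every ~44 reaches *to the
same target*, not every 44 movements overall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_TARGETS = 5

#: Parameter order used everywhere a flat 8-vector appears.
PARAM_NAMES = ("A", "tau", "C", "D1", "D2", "D3", "D4", "D5")


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject model parameters.

    ``A`` and the ``D_k`` are in ms, ``tau`` in trials, ``C`` in ms/trial.
    ``C`` may be negative (a subject who speeds up linearly); ``tau`` must be
    strictly positive.
    """

    subject_id: str
    A: float
    tau: float
    C: float
    D: tuple[float, ...]  # D_1 .. D_5

    def __post_init__(self) -> None:
        if not np.isfinite(self.tau) or self.tau <= 0:
            raise ValueError(f"tau must be positive and finite, got {self.tau}")
        if len(self.D) != N_TARGETS:
            raise ValueError(f"expected {N_TARGETS} target intercepts, got {len(self.D)}")
        if not (np.isfinite(self.A) and all(np.isfinite(d) for d in self.D)):
            raise ValueError("A and D must be finite")

    def as_vector(self) -> np.ndarray:
        """Flat (A, tau, C, D1..D5) vector in :data:`PARAM_NAMES` order."""
        return np.array([self.A, self.tau, self.C, *self.D], dtype=float)

    @classmethod
    def from_vector(cls, subject_id: str, vec: np.ndarray) -> "SubjectParams":
        vec = np.asarray(vec, dtype=float)
        return cls(subject_id, float(vec[0]), float(vec[1]), float(vec[2]),
                   tuple(float(v) for v in vec[3:8]))


@dataclass(frozen=True)
class PopulationParams:
    """Population-level (mixed-effects) parameters.

    ``fixed`` holds the eight fixed effects on the *natural* scale
    (median A, median tau, mean C, mean D1..D5 — medians for the
    log-transformed parameters because the fixed effect lives on the log
    scale there).  ``omega2`` holds the diagonal random-effect variances on
    the transform scale (log for A and tau, identity for C and D), and
    ``sigma`` the residual SD in ms.
    """

    fixed: tuple[float, ...]
    omega2: tuple[float, ...]
    sigma: float

    def __post_init__(self) -> None:
        if len(self.fixed) != 8 or len(self.omega2) != 8:
            raise ValueError("exactly 8 fixed effects and 8 variances required")
        if any(v < 0 for v in self.omega2):
            raise ValueError("random-effect variances must be non-negative")
        if self.sigma <= 0:
            raise ValueError("residual SD must be positive")

    def mean_subject(self, subject_id: str = "population") -> SubjectParams:
        f = self.fixed
        return SubjectParams(subject_id, f[0], f[1], f[2], tuple(f[3:8]))


def predict_mt(params: SubjectParams, t, k) -> np.ndarray | float:
    """Deterministic MT prediction A·e^(−t/tau) + C·t + D_k.

    ``t`` is the per-target trial index (>= 1), ``k`` the target number in
    1..5.  Both may be scalars or equal-length arrays; the result matches
    their shape.
    """
    t_arr = np.asarray(t, dtype=float)
    k_arr = np.asarray(k, dtype=int)
    if np.any(t_arr < 1):
        raise ValueError("trial index t starts at 1")
    if np.any((k_arr < 1) | (k_arr > N_TARGETS)):
        raise ValueError(f"target k must be in 1..{N_TARGETS}")
    D = np.asarray(params.D, dtype=float)
    out = params.A * np.exp(-t_arr / params.tau) + params.C * t_arr + D[k_arr - 1]
    return float(out) if np.isscalar(t) and np.isscalar(k) else out


def simulate_trial(params: SubjectParams, t, k, sigma_eps: float,
                   rng: np.random.Generator) -> np.ndarray | float:
    """One (or many) noisy trial(s): structural prediction + N(0, sigma_eps)."""
    if sigma_eps < 0:
        raise ValueError("residual SD must be >= 0")
    pred = predict_mt(params, t, k)
    if sigma_eps == 0:
        return pred
    noise = rng.normal(0.0, sigma_eps, size=np.shape(pred))
    out = pred + noise
    return float(out) if np.isscalar(pred) else out
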