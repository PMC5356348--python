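"""Population fitting of the learning/fatigue model by SAEM.

The movement-time model ``MT = A e^(-t/tau) + C t + D_k + eps`` is treated
as a nonlinear mixed-effects model: each subject's parameter vector is a
random draw from a population distribution with eight fixed effects (one
mean per parameter) and a diagonal random-effect covariance, plus a common
residual SD.  Estimation follows stochastic-approximation EM (SAEM):

* E-step: per subject, an MCMC chain samples the individual parameters
  from their conditional posterior given the data and the current
  population distribution.  The sampler exploits conditional linearity:
  given (A, tau) the model is linear in (C, D_1..D_5), so that block is
  integrated out analytically and (log A, log tau) is updated by
  Metropolis against the *collapsed* likelihood (one independence kernel
  drawing from the population distribution plus adaptive random-walk
  kernels), after which (C, D) is drawn exactly from its Gaussian
  conditional.  Collapsing removes the long A/tau/C/D trade-off ridge
  that makes naive componentwise walks mix impractically slowly on this
  model;
* SA step: the complete-data sufficient statistics (sum and sum of squares
  of the individual parameters, residual sum of squares) are updated with
  step size 1 during burn-in and 1/iter^0.7 afterwards, with simulated
  annealing keeping the variances generous early in burn-in;
* M-step: population means, variances and the residual variance(s) are
  the closed-form maximizers given the smoothed statistics.  The residual
  variance is estimated per group by default (the two groups' trial noise
  differs threefold; a pooled variance misweights whichever group it does
  not match) or pooled on request.

Individual parameters live on a transform scale: log for ``A`` and ``tau``
(positivity; their fixed effects back-transform to population *medians*)
and identity for ``C`` (whose sign must stay free) and the ``D_k``.
``tau`` is box-bounded during estimation to stop exponential/linear
aliasing on flat learners.  After the schedule finishes, per-subject
empirical-Bayes estimates are the posterior modes under the fitted
population distribution.

Two-stage initialization (independent per-subject nonlinear least squares,
then cross-subject medians/dispersions) both seeds SAEM and doubles as a
deterministic reference fitter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .model import PARAM_NAMES, PopulationParams, SubjectParams

_LOG_COMPONENTS = (0, 1)  # log A, log tau


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class FitConfig:
    """Estimation settings; defaults follow standard SAEM practice."""

    n_burn: int = 300            # exploration iterations, step size 1
    n_iter: int = 200            # convergence iterations, step 1/m^exponent
    step_exponent: float = 0.7
    n_mh: int = 2                # Metropolis sweeps per SAEM iteration
    anneal_decay: float = 0.97   # burn-in lower bound on sigma2/omega2 decays by this
    anneal_inflate: float = 2.0  # annealing starts from inflated initial variances
    seed: int = 0
    tau_lower: float = 0.5
    tau_upper: float | None = None   # None -> 10 * trials_per_target
    drop_fatigue: bool = False       # ablation: C frozen at 0
    single_intercept: bool = False   # ablation: one shared D for all targets
    error_model: str = "by_group"    # residual variance per group, or "pooled"
    omega2_floor: float = 1e-8
    sigma2_floor: float = 1e-6
    adapt_rate: float = 0.25
    target_acceptance: float = 0.30
    compute_loglik: bool = False     # Laplace marginal log-likelihood

    def __post_init__(self) -> None:
        if self.n_burn < 1 or self.n_iter < 1:
            raise ValueError("n_burn and n_iter must each be >= 1")
        if not 0.5 < self.step_exponent <= 1.0:
            raise ValueError("step exponent must lie in (0.5, 1]")
        if self.tau_lower <= 0:
            raise ValueError("tau lower bound must be positive")
        if self.error_model not in ("by_group", "pooled"):
            raise ValueError("error_model must be 'by_group' or 'pooled'")


@dataclass
class FitResult:
    population: PopulationParams
    subjects: list[SubjectParams]
    phi: np.ndarray                   # (N, 8) empirical-Bayes transform-scale
    rmse: dict[str, float]            # per group + "overall", ms
    trace: pd.DataFrame               # per-iteration natural fixed effects + sigma
    config: FitConfig
    sigma_by_group: dict[str, float] | None = None  # ms, when error_model="by_group"
    loglik: float | None = None       # Laplace approx marginal log-likelihood
    loglik_init: float | None = None
    improved_over_init: bool | None = None
    warnings: list[str] = field(default_factory=list)

    def params_frame(self) -> pd.DataFrame:
        rows = []
        for sp, g in zip(self.subjects, self._groups):
            row = {"subject": sp.subject_id, "group": g,
                   "A": sp.A, "tau": sp.tau, "C": sp.C}
            row.update({f"D{k + 1}": d for k, d in enumerate(sp.D)})
            rows.append(row)
        return pd.DataFrame(rows)

    _groups: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Data marshalling

@dataclass
class _Stacked:
    """Per-subject trial arrays padded to a common length."""

    subjects: list[str]
    groups: list[str]
    t: np.ndarray      # (N, n_max) float
    kidx: np.ndarray   # (N, n_max) int, 0-based
    y: np.ndarray      # (N, n_max)
    mask: np.ndarray   # (N, n_max) bool, True where real data
    n_obs: np.ndarray  # (N,)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_total(self) -> int:
        return int(self.n_obs.sum())

    @property
    def t_max(self) -> float:
        return float(self.t[self.mask].max())


def _stack(trials: pd.DataFrame) -> _Stacked:
    required = {"subject", "t", "target", "mt_ms"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    subjects, groups, ts, ks, ys = [], [], [], [], []
    for sid, sub in trials.groupby("subject", sort=True):
        y = sub["mt_ms"].to_numpy(float)
        if not np.all(np.isfinite(y)):
            bad = sub.index[~np.isfinite(y)][0]
            raise FitError(f"non-finite MT for subject {sid!r} at row {bad}")
        subjects.append(str(sid))
        groups.append(str(sub["group"].iloc[0]) if "group" in sub else "all")
        ts.append(sub["t"].to_numpy(float))
        ks.append(sub["target"].to_numpy(int) - 1)
        ys.append(y)
    n_obs = np.array([len(v) for v in ys])
    n_max = int(n_obs.max())
    N = len(subjects)
    t = np.ones((N, n_max))
    kidx = np.zeros((N, n_max), dtype=int)
    y = np.zeros((N, n_max))
    mask = np.zeros((N, n_max), dtype=bool)
    for i in range(N):
        n = n_obs[i]
        t[i, :n], kidx[i, :n], y[i, :n] = ts[i], ks[i], ys[i]
        mask[i, :n] = True
    return _Stacked(subjects, groups, t, kidx, y, mask, n_obs)


# ---------------------------------------------------------------------------
# Model on the transform scale

def _predict_phi(phi: np.ndarray, data: _Stacked, single_intercept: bool,
                 drop_fatigue: bool) -> np.ndarray:
    """(N, n_max) structural predictions from transform-scale parameters."""
    A = np.exp(phi[:, 0])[:, None]
    tau = np.exp(phi[:, 1])[:, None]
    C = 0.0 if drop_fatigue else phi[:, 2][:, None]
    D = phi[:, 3:8]
    kidx = np.zeros_like(data.kidx) if single_intercept else data.kidx
    Dsel = np.take_along_axis(D, kidx, axis=1)
    return A * np.exp(-data.t / tau) + C * data.t + Dsel


def _ss(phi: np.ndarray, data: _Stacked, single_intercept: bool,
        drop_fatigue: bool) -> np.ndarray:
    pred = _predict_phi(phi, data, single_intercept, drop_fatigue)
    r = (data.y - pred) * data.mask
    return np.einsum("ij,ij->i", r, r)


def _phi_to_subject(sid: str, phi_row: np.ndarray) -> SubjectParams:
    return SubjectParams(sid, float(np.exp(phi_row[0])), float(np.exp(phi_row[1])),
                         float(phi_row[2]), tuple(float(v) for v in phi_row[3:8]))


def _natural_fixed(mu: np.ndarray) -> tuple[float, ...]:
    out = mu.copy()
    out[list(_LOG_COMPONENTS)] = np.exp(out[list(_LOG_COMPONENTS)])
    return tuple(float(v) for v in out)


# ---------------------------------------------------------------------------
# Two-stage initialization (per-subject NLS, then cross-subject summaries)

def fit_subject_nls(t: np.ndarray, k: np.ndarray, y: np.ndarray,
                    tau_bounds: tuple[float, float]) -> tuple[np.ndarray, float]:
    """Bounded nonlinear least squares for one subject.

    Returns the transform-scale parameter vector and the residual sum of
    squares.  Multi-start over tau to dodge the exponential/linear
    aliasing valley on near-flat learners.
    """
    t = np.asarray(t, float)
    kidx = np.asarray(k, int) - 1
    y = np.asarray(y, float)
    T = float(t.max())

    # crude moment-style start values
    d0 = np.empty(5)
    late = t > 0.75 * T
    for j in range(5):
        sel = (kidx == j) & late
        d0[j] = y[sel].mean() if sel.any() else y.mean()
    half = t > 0.5 * T
    if half.sum() >= 3 and np.ptp(t[half]) > 0:
        c0 = float(np.polyfit(t[half], y[half] - d0[kidx[half]], 1)[0])
    else:
        c0 = 0.0
    c0 = float(np.clip(c0, -10, 10))
    early = t <= max(3.0, 0.03 * T)
    a0 = max(float(np.mean(y[early] - d0[kidx[early]] - c0 * t[early])), 1.0)

    # D >= 0: an asymptotic MT cannot be negative.  Without this bound the
    # exponential/linear aliasing valley (tau -> huge, A e^(-t/tau) ~ A - At/tau)
    # admits degenerate solutions with A ~ +3000 / D ~ -3000 at near-equal SS.
    lo = np.array([np.log(1e-2), np.log(tau_bounds[0]), -50.0, *[0.0] * 5])
    hi = np.array([np.log(5e3), np.log(tau_bounds[1]), 50.0, *[5e3] * 5])

    def resid(theta: np.ndarray) -> np.ndarray:
        A, tau = np.exp(theta[0]), np.exp(theta[1])
        return A * np.exp(-t / tau) + theta[2] * t + theta[3 + kidx] - y

    best = None
    for tau0 in (T / 8.0, T / 2.0, 2.0 * T):
        theta0 = np.clip(
            np.array([np.log(a0), np.log(tau0), c0, *d0]), lo, hi)
        try:
            sol = least_squares(resid, theta0, bounds=(lo, hi), method="trf",
                                xtol=1e-10, ftol=1e-10)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("per-subject least squares failed from every start")
    return best.x, float(2 * best.cost)


@dataclass
class TwoStageInit:
    population: PopulationParams
    phi: np.ndarray              # (N, 8)
    subjects: list[SubjectParams]
    excluded: list[str]


def initialize_two_stage(trials: pd.DataFrame,
                         config: FitConfig | None = None) -> TwoStageInit:
    """Independent per-subject NLS fits summarized into a population start.

    Fixed effects are cross-subject medians on the transform scale (robust
    to the odd wild individual fit), random-effect variances the
    cross-subject variances, and the residual SD the pooled residual SD.
    Order of subjects does not affect the summaries.
    """
    config = config or FitConfig()
    data = _stack(trials)
    tau_hi = config.tau_upper or 10.0 * data.t_max
    phi_rows, ss_list, kept, excluded = [], [], [], []
    for i, sid in enumerate(data.subjects):
        n = data.n_obs[i]
        try:
            row, ss = fit_subject_nls(data.t[i, :n], data.kidx[i, :n] + 1,
                                      data.y[i, :n], (config.tau_lower, tau_hi))
        except FitError:
            warnings.warn(f"initialization NLS failed for subject {sid}; excluded")
            excluded.append(sid)
            continue
        phi_rows.append(row)
        ss_list.append(ss)
        kept.append(i)
    if len(phi_rows) < 2:
        raise FitError("fewer than 2 subjects with a usable initialization fit")
    phi_fit = np.vstack(phi_rows)
    mu = np.median(phi_fit, axis=0)
    # robust dispersion: a few subjects sit on weakly identified ridges and
    # would blow up a plain variance, leaving the population prior useless
    iqr = np.subtract(*np.percentile(phi_fit, [75, 25], axis=0))
    omega2 = np.maximum((iqr / 1.349) ** 2, config.omega2_floor)
    n_used = data.n_obs[kept].sum()
    sigma = float(np.sqrt(max(np.sum(ss_list) / n_used, config.sigma2_floor)))
    pop = PopulationParams(_natural_fixed(mu), tuple(omega2), sigma)
    # excluded subjects start from the population medians
    phi_all = np.tile(mu, (data.n_subjects, 1))
    phi_all[kept] = phi_fit
    subjects = [_phi_to_subject(s, phi_all[i]) for i, s in enumerate(data.subjects)]
    return TwoStageInit(pop, phi_all, subjects, excluded)


# ---------------------------------------------------------------------------
# SAEM

def _pop_to_mu(pop: PopulationParams) -> np.ndarray:
    mu = np.array(pop.fixed, dtype=float)
    mu[list(_LOG_COMPONENTS)] = np.log(mu[list(_LOG_COMPONENTS)])
    return mu


def fit_nlme(trials: pd.DataFrame, config: FitConfig | None = None,
             init: TwoStageInit | None = None) -> FitResult:
    """SAEM fit of the population model to a trial table.

    Deterministic given ``config.seed`` and the data.  The convergence
    trace records the natural-scale fixed effects and residual SD at every
    iteration.
    """
    config = config or FitConfig()
    data = _stack(trials)
    if data.n_subjects < 2:
        raise FitError("population fit requires at least 2 subjects")
    rng = np.random.default_rng(config.seed)
    tau_hi = config.tau_upper or 10.0 * data.t_max
    log_tau_lo, log_tau_hi = np.log(config.tau_lower), np.log(tau_hi)

    if init is None:
        init = initialize_two_stage(trials, config)
    mu = _pop_to_mu(init.population)
    omega2 = np.maximum(np.array(init.population.omega2), config.omega2_floor)
    phi = init.phi.copy()
    phi[:, 1] = np.clip(phi[:, 1], log_tau_lo, log_tau_hi)

    # residual-variance blocks: one per group, or a single pooled block
    groups_arr = np.array(data.groups)
    if config.error_model == "by_group":
        block_names = sorted(set(data.groups))
    else:
        block_names = ["all"]
    blk = (np.array([block_names.index(g) for g in data.groups])
           if config.error_model == "by_group"
           else np.zeros(data.n_subjects, dtype=int))
    n_blocks = len(block_names)
    n_obs_blk = np.array([data.n_obs[blk == b].sum() for b in range(n_blocks)])
    ss_init = _ss(phi, data, config.single_intercept, config.drop_fatigue)
    sigma2_blk = np.array([
        max(ss_init[blk == b].sum() / n_obs_blk[b], config.sigma2_floor)
        for b in range(n_blocks)])

    free = np.ones(8, dtype=bool)
    if config.drop_fatigue:
        free[2] = False
        phi[:, 2] = 0.0
        mu[2] = 0.0
        omega2[2] = config.omega2_floor
    if config.single_intercept:
        free[4:8] = False

    N, n_total = data.n_subjects, data.n_total

    # Conditional-linearity setup.  Given (A, tau) the model is linear in
    # beta = (C, D_1..D_5): y = A e(tau) + X beta + eps with X = [t | target
    # dummies].  The E-step therefore samples (log A, log tau) by Metropolis
    # against the *marginal* likelihood with beta integrated out (a smooth
    # 2-D target — the A/tau/C/D trade-off ridge that defeats plain
    # componentwise walks disappears), then draws beta exactly from its
    # Gaussian conditional.
    beta_idx = ([] if config.drop_fatigue else [2]) + \
        ([3] if config.single_intercept else [3, 4, 5, 6, 7])
    p = len(beta_idx)
    X = np.zeros((N, data.t.shape[1], p))
    col = 0
    if not config.drop_fatigue:
        X[:, :, 0] = data.t * data.mask
        col = 1
    if config.single_intercept:
        X[:, :, col] = 1.0 * data.mask
    else:
        for j in range(5):
            X[:, :, col + j] = (data.kidx == j) * data.mask
    XtX = np.einsum("nij,nik->njk", X, X)
    Xty = np.einsum("nij,ni->nj", X, data.y * data.mask)
    tmask = data.t * data.mask

    a_cur = np.exp(phi[:, 0])
    tau_cur = np.exp(phi[:, 1])
    prop_sd = np.array([0.3, 0.3])   # RW scales for (log A, log tau)

    def e_scalars(tau: np.ndarray, w: np.ndarray, wtw: np.ndarray):
        """tau-dependent pieces of the collapsed likelihood."""
        e = np.exp(-tmask / tau[:, None]) * data.mask
        return {
            "e": e,
            "ete": np.einsum("ni,ni->n", e, e),
            "wte": np.einsum("ni,ni->n", w, e),
            "Xte": np.einsum("nij,ni->nj", X, e),
            "wtw": wtw,
        }

    def marg_loglik(a: np.ndarray, sc: dict, Minv: np.ndarray,
                    Xtw: np.ndarray, sig2: np.ndarray) -> np.ndarray:
        """Collapsed log-likelihood up to within-iteration constants."""
        rtr = sc["wtw"] - 2 * a * sc["wte"] + a ** 2 * sc["ete"]
        v = Xtw - a[:, None] * sc["Xte"]
        q = rtr - np.einsum("ni,nij,nj->n", v, Minv, v)
        return -0.5 * q / sig2

    s1 = phi.sum(axis=0)
    s2 = (phi ** 2).sum(axis=0)
    s3 = np.zeros(n_blocks)   # overwritten on the first iteration, where gamma = 1
    n_total_iter = config.n_burn + config.n_iter
    trace_rows = np.empty((n_total_iter, 9))

    # simulated-annealing floors: keep the variances generous during burn-in
    # so the chains can still move; the floors decay geometrically to nothing
    anneal_omega2 = config.anneal_inflate * omega2.copy()
    anneal_sigma2 = config.anneal_inflate * sigma2_blk.copy()

    for m in range(1, n_total_iter + 1):
        gamma = 1.0 if m <= config.n_burn else (m - config.n_burn) ** (-config.step_exponent)

        # iteration-constant matrices for the collapsed likelihood
        lam = omega2[beta_idx]
        mu_b = mu[beta_idx]
        sig2 = sigma2_blk[blk]
        M = XtX + sig2[:, None, None] * np.diag(1.0 / lam)[None, :, :]
        Minv = np.linalg.inv(M)
        w = (data.y - np.einsum("nij,j->ni", X, mu_b)) * data.mask
        wtw = np.einsum("ni,ni->n", w, w)
        Xtw = Xty - XtX @ mu_b
        sc_cur = e_scalars(tau_cur, w, wtw)
        f_cur = marg_loglik(a_cur, sc_cur, Minv, Xtw, sig2)

        for _ in range(config.n_mh):
            # kernel 1: independence proposal from N(mu, Omega) on (logA, logtau);
            # the prior terms cancel, leaving the collapsed likelihood ratio
            la_p = mu[0] + np.sqrt(omega2[0]) * rng.standard_normal(N)
            lt_p = mu[1] + np.sqrt(omega2[1]) * rng.standard_normal(N)
            ok = (lt_p >= log_tau_lo) & (lt_p <= log_tau_hi)
            sc_p = e_scalars(np.exp(lt_p), w, wtw)
            f_p = marg_loglik(np.exp(la_p), sc_p, Minv, Xtw, sig2)
            acc = ok & (np.log(rng.random(N)) < f_p - f_cur)
            if np.any(acc):
                phi[acc, 0], phi[acc, 1] = la_p[acc], lt_p[acc]
                a_cur, tau_cur = np.exp(phi[:, 0]), np.exp(phi[:, 1])
                f_cur = np.where(acc, f_p, f_cur)
                for key in ("e", "ete", "wte"):
                    sc_cur[key][acc] = sc_p[key][acc]
                sc_cur["Xte"][acc] = sc_p["Xte"][acc]
            # kernel 2a: random walk on log A (tau unchanged: reuse scalars)
            la_p = phi[:, 0] + prop_sd[0] * rng.standard_normal(N)
            f_p = marg_loglik(np.exp(la_p), sc_cur, Minv, Xtw, sig2)
            dprior = ((la_p - mu[0]) ** 2 - (phi[:, 0] - mu[0]) ** 2) / omega2[0]
            acc = np.log(rng.random(N)) < f_p - f_cur - 0.5 * dprior
            phi[acc, 0] = la_p[acc]
            a_cur = np.exp(phi[:, 0])
            f_cur = np.where(acc, f_p, f_cur)
            if m <= config.n_burn:
                prop_sd[0] = np.clip(prop_sd[0] * np.exp(
                    config.adapt_rate * (acc.mean() - config.target_acceptance)),
                    1e-4, 5.0)
            # kernel 2b: random walk on log tau
            lt_p = phi[:, 1] + prop_sd[1] * rng.standard_normal(N)
            ok = (lt_p >= log_tau_lo) & (lt_p <= log_tau_hi)
            sc_p = e_scalars(np.exp(lt_p), w, wtw)
            f_p = marg_loglik(a_cur, sc_p, Minv, Xtw, sig2)
            dprior = ((lt_p - mu[1]) ** 2 - (phi[:, 1] - mu[1]) ** 2) / omega2[1]
            acc = ok & (np.log(rng.random(N)) < f_p - f_cur - 0.5 * dprior)
            if np.any(acc):
                phi[acc, 1] = lt_p[acc]
                tau_cur = np.exp(phi[:, 1])
                f_cur = np.where(acc, f_p, f_cur)
                for key in ("e", "ete", "wte"):
                    sc_cur[key][acc] = sc_p[key][acc]
                sc_cur["Xte"][acc] = sc_p["Xte"][acc]
            if m <= config.n_burn:
                prop_sd[1] = np.clip(prop_sd[1] * np.exp(
                    config.adapt_rate * (acc.mean() - config.target_acceptance)),
                    1e-4, 5.0)

        # exact Gibbs draw of beta | A, tau (posterior precision M / sigma2)
        rhs = sig2[:, None] * (mu_b / lam) + Xty - a_cur[:, None] * sc_cur["Xte"]
        beta_mean = np.einsum("nij,nj->ni", Minv, rhs)
        cov = sig2[:, None, None] * Minv
        cov = 0.5 * (cov + np.transpose(cov, (0, 2, 1)))
        L = np.linalg.cholesky(cov)
        beta = beta_mean + np.einsum("nij,nj->ni", L, rng.standard_normal((N, p)))
        phi[:, beta_idx] = beta
        if config.single_intercept:
            phi[:, 4:8] = phi[:, 3:4]
        if config.drop_fatigue:
            phi[:, 2] = 0.0

        pred = (a_cur[:, None] * sc_cur["e"] +
                np.einsum("nij,nj->ni", X, beta)) * data.mask
        ss_cur = np.einsum("ni,ni->n", data.y * data.mask - pred,
                           data.y * data.mask - pred)

        s1 = s1 + gamma * (phi.sum(axis=0) - s1)
        s2 = s2 + gamma * ((phi ** 2).sum(axis=0) - s2)
        ss_blk = np.array([ss_cur[blk == b].sum() for b in range(n_blocks)])
        s3 = s3 + gamma * (ss_blk - s3)
        mu[free] = (s1 / N)[free]
        omega2[free] = np.maximum((s2 / N - (s1 / N) ** 2)[free], config.omega2_floor)
        sigma2_blk = np.maximum(s3 / n_obs_blk, config.sigma2_floor)
        if m <= config.n_burn:
            anneal_omega2 *= config.anneal_decay
            anneal_sigma2 *= config.anneal_decay
            omega2[free] = np.maximum(omega2, anneal_omega2)[free]
            sigma2_blk = np.maximum(sigma2_blk, anneal_sigma2)
        if config.single_intercept:
            mu[4:8] = mu[3]
            omega2[4:8] = omega2[3]
        trace_rows[m - 1, :8] = _natural_fixed(mu)
        trace_rows[m - 1, 8] = np.sqrt(float((sigma2_blk * n_obs_blk).sum() / n_total))

    sigma_pooled = float(np.sqrt((sigma2_blk * n_obs_blk).sum() / n_total))
    pop = PopulationParams(_natural_fixed(mu), tuple(omega2), sigma_pooled)

    # empirical-Bayes posterior modes, started from the final chain state
    warn_list: list[str] = []
    phi_eb = np.empty_like(phi)
    for i in range(N):
        phi_eb[i], ok = _eb_mode(data, i, mu, omega2, float(sigma2_blk[blk[i]]),
                                 config, start=phi[i],
                                 tau_log_bounds=(log_tau_lo, log_tau_hi))
        if not ok:
            warn_list.append(f"empirical-Bayes optimizer did not converge for "
                             f"subject {data.subjects[i]}; population means used")
    subjects = [_phi_to_subject(s, phi_eb[i]) for i, s in enumerate(data.subjects)]
    rmse = _rmse_from_phi(phi_eb, data, config)
    trace = pd.DataFrame(trace_rows, columns=[*PARAM_NAMES, "sigma"])
    trace.insert(0, "iteration", np.arange(1, n_total_iter + 1))

    result = FitResult(pop, subjects, phi_eb, rmse, trace, config,
                       sigma_by_group={block_names[b]: float(np.sqrt(sigma2_blk[b]))
                                       for b in range(n_blocks)},
                       warnings=warn_list, _groups=data.groups)
    if config.compute_loglik:
        result.loglik = marginal_loglik(trials, pop, config)
        result.loglik_init = marginal_loglik(trials, init.population, config)
        result.improved_over_init = bool(result.loglik >= result.loglik_init)
        if not result.improved_over_init:
            result.warnings.append("SAEM estimate did not improve the approximate "
                                   "marginal log-likelihood over initialization")
    return result


def _neg_log_post(phi_row: np.ndarray, data: _Stacked, i: int, mu: np.ndarray,
                  omega2: np.ndarray, sigma2: float, config: FitConfig) -> float:
    ss = _ss(phi_row[None, :], _subject_view(data, i),
             config.single_intercept, config.drop_fatigue)[0]
    prior = np.sum((phi_row - mu) ** 2 / omega2)
    return 0.5 * ss / sigma2 + 0.5 * prior


def _subject_view(data: _Stacked, i: int) -> _Stacked:
    sl = slice(i, i + 1)
    return _Stacked([data.subjects[i]], [data.groups[i]], data.t[sl],
                    data.kidx[sl], data.y[sl], data.mask[sl], data.n_obs[sl])


def _eb_mode(data: _Stacked, i: int, mu: np.ndarray, omega2: np.ndarray,
             sigma2: float, config: FitConfig, start: np.ndarray,
             tau_log_bounds: tuple[float, float]) -> tuple[np.ndarray, bool]:
    """Posterior mode for one subject by profiling out the linear block.

    Given (log A, log tau) the optimal (C, D) is the closed-form ridge
    solution, so the mode search is a well-conditioned 2-D minimization
    instead of a badly scaled 8-D one.
    """
    n = data.n_obs[i]
    t = data.t[i, :n]
    kidx = data.kidx[i, :n]
    y = data.y[i, :n]
    beta_idx = ([] if config.drop_fatigue else [2]) + \
        ([3] if config.single_intercept else [3, 4, 5, 6, 7])
    p = len(beta_idx)
    X = np.zeros((n, p))
    col = 0
    if not config.drop_fatigue:
        X[:, 0] = t
        col = 1
    if config.single_intercept:
        X[:, col] = 1.0
    else:
        for j in range(5):
            X[:, col + j] = kidx == j
    XtX = X.T @ X
    lam = omega2[beta_idx]
    mu_b = mu[beta_idx]
    M = XtX + sigma2 * np.diag(1.0 / lam)
    Minv = np.linalg.inv(M)
    w = y - X @ mu_b

    def profiled(z: np.ndarray) -> float:
        a, tau = np.exp(z[0]), np.exp(z[1])
        r = w - a * np.exp(-t / tau)
        v = X.T @ r
        q = r @ r - v @ Minv @ v
        prior = (z[0] - mu[0]) ** 2 / omega2[0] + (z[1] - mu[1]) ** 2 / omega2[1]
        return 0.5 * q / sigma2 + 0.5 * prior

    bounds = [(None, None), tau_log_bounds]
    best = None
    starts = [start[:2], mu[:2]]
    for z0 in starts:
        z0 = np.array([z0[0], np.clip(z0[1], *tau_log_bounds)])
        res = minimize(profiled, z0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        res.x[1] = np.clip(res.x[1], *tau_log_bounds)
        res_fun = profiled(res.x)
        if best is None or res_fun < best[1]:
            best = (res.x, res_fun)
    z, f = best
    ok = f <= profiled(np.array([start[0], np.clip(start[1], *tau_log_bounds)])) + 1e-9
    a = np.exp(z[0])
    r = w - a * np.exp(-t / np.exp(z[1]))
    beta = mu_b + Minv @ (X.T @ r)
    phi_row = mu.copy()
    phi_row[0], phi_row[1] = z
    phi_row[beta_idx] = beta
    if config.drop_fatigue:
        phi_row[2] = 0.0
    if config.single_intercept:
        phi_row[4:8] = phi_row[3]
    return (phi_row, True) if ok else (mu.copy(), False)


def empirical_bayes(trials: pd.DataFrame, pop: PopulationParams,
                    config: FitConfig | None = None) -> list[SubjectParams]:
    """Posterior-mode subject parameters under a given population model.

    With vanishing random-effect variance or an uninformative likelihood
    the mode collapses to the population means, as it should.
    """
    config = config or FitConfig()
    data = _stack(trials)
    mu = _pop_to_mu(pop)
    omega2 = np.maximum(np.array(pop.omega2), config.omega2_floor)
    sigma2 = max(pop.sigma ** 2, config.sigma2_floor)
    tau_hi = config.tau_upper or 10.0 * data.t_max
    lb = (np.log(config.tau_lower), np.log(tau_hi))
    out = []
    for i, sid in enumerate(data.subjects):
        row, ok = _eb_mode(data, i, mu, omega2, sigma2, config,
                           start=mu.copy(), tau_log_bounds=lb)
        if not ok:
            warnings.warn(f"empirical-Bayes optimizer flagged subject {sid}; "
                          f"population means returned")
        out.append(_phi_to_subject(sid, np.clip(row, -1e6, 1e6)))
    return out


# ---------------------------------------------------------------------------
# Goodness of fit and likelihood

def _rmse_from_phi(phi: np.ndarray, data: _Stacked,
                   config: FitConfig) -> dict[str, float]:
    pred = _predict_phi(phi, data, config.single_intercept, config.drop_fatigue)
    sq = ((data.y - pred) ** 2) * data.mask
    out: dict[str, float] = {}
    groups = np.array(data.groups)
    for g in sorted(set(data.groups)):
        sel = groups == g
        out[g] = float(np.sqrt(sq[sel].sum() / data.n_obs[sel].sum()))
    out["overall"] = float(np.sqrt(sq.sum() / data.n_total))
    return out


def compute_rmse(trials: pd.DataFrame,
                 subjects: list[SubjectParams]) -> dict[str, float]:
    """Root-mean-square residual in ms, per group and overall."""
    data = _stack(trials)
    by_id = {sp.subject_id: sp for sp in subjects}
    missing = [s for s in data.subjects if s not in by_id]
    if missing:
        raise ValueError(f"no parameters for subjects: {missing}")
    phi = np.vstack([
        np.array([np.log(max(by_id[s].A, 1e-300)), np.log(by_id[s].tau),
                  by_id[s].C, *by_id[s].D]) for s in data.subjects])
    if not all(g for g in data.groups):
        raise ValueError("empty group label")
    return _rmse_from_phi(phi, data, FitConfig())


def marginal_loglik(trials: pd.DataFrame, pop: PopulationParams,
                    config: FitConfig | None = None) -> float:
    """Laplace approximation to the marginal log-likelihood.

    Per subject: log p(y, phi*) at the posterior mode plus the Gaussian
    volume correction from the numeric Hessian of the negative log joint.
    Used for sanity comparisons between fits, not for inference.
    """
    config = config or FitConfig()
    data = _stack(trials)
    mu = _pop_to_mu(pop)
    omega2 = np.maximum(np.array(pop.omega2), config.omega2_floor)
    sigma2 = max(pop.sigma ** 2, config.sigma2_floor)
    tau_hi = config.tau_upper or 10.0 * data.t_max
    lb = (np.log(config.tau_lower), np.log(tau_hi))
    total = 0.0
    d = 8
    for i in range(data.n_subjects):
        mode, _ = _eb_mode(data, i, mu, omega2, sigma2, config,
                           start=mu.copy(), tau_log_bounds=lb)
        f0 = _neg_log_post(mode, data, i, mu, omega2, sigma2, config)
        n_i = data.n_obs[i]
        # constants of the joint density
        log_joint = (-f0
                     - 0.5 * n_i * np.log(2 * np.pi * sigma2)
                     - 0.5 * np.sum(np.log(2 * np.pi * omega2)))
        H = _numeric_hessian(
            lambda p: _neg_log_post(p, data, i, mu, omega2, sigma2, config), mode)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:  # mode on a bound or flat direction: fall back to prior curvature
            logdet = float(np.sum(np.log(1.0 / omega2)))
        total += log_joint + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet
    return float(total)


def _numeric_hessian(f, x0: np.ndarray, h: float = 1e-4) -> np.ndarray:
    d = len(x0)
    H = np.empty((d, d))
    f0 = f(x0)
    steps = h * np.maximum(1.0, np.abs(x0))
    for a in range(d):
        ea = np.zeros(d); ea[a] = steps[a]
        fpp = f(x0 + ea); fmm = f(x0 - ea)
        H[a, a] = (fpp - 2 * f0 + fmm) / steps[a] ** 2
        for b in range(a + 1, d):
            eb = np.zeros(d); eb[b] = steps[b]
            fab = f(x0 + ea + eb); fa_b = f(x0 + ea - eb)
            f_ab = f(x0 - ea + eb); f_a_b = f(x0 - ea - eb)
            H[a, b] = H[b, a] = (fab - fa_b - f_ab + f_a_b) / (4 * steps[a] * steps[b])
    return H
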