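"""Bayesian calibration machinery.

The evidence is a table of biweekly ovitrap means; the simulated counterpart
y(r, w, theta) is the windowed sum of eggs laid.  The likelihood has two
Gaussian parts: the observed means themselves (sd = reported SEM) and, within
each surveillance year, the differences of consecutive observations (sd = the
pooled SEM of the two windows); the first window of each year carries no
difference term.  The objective is half the squared Mahalanobis distance of
the stacked prior and data residuals — i.e. the negative log posterior up to
an additive constant.

Optimisation/sampling is an annealed basin-hopping MCMC: several adaptive
Metropolis chains cycle a geometric annealing-temperature ladder (hops across
basins at high temperature, refinement at low temperature, acceptance
min{1, exp[(f - f')/T_ann]}), after which each surviving mode centre is
sampled at a fixed temperature to approximate the local posterior.  Mode
masses are importance-sampled with a tolerance factor T_tol; at T_tol = 1
mass ratios are Bayes factors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from . import life_history as lh
from .environment import SurveillanceTable
from .population import MU_MAX

__all__ = [
    "ObjectiveValue",
    "ModelObjective",
    "BasinHoppingConfig",
    "ModeCandidate",
    "ModeSamples",
    "PosteriorModeSet",
    "SensitivityMatrix",
    "pooled_sem",
    "data_loglik",
    "acceptance_probability",
    "basin_hopping_mcmc",
    "sample_mode",
    "mode_posterior_mass",
    "expected_output",
    "sensitivity",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Likelihood pieces
# ---------------------------------------------------------------------------

def pooled_sem(n1: int, n2: int, s1: float, s2: float) -> float:
    """Pooled standard error of the mean of two trap collections."""
    if n1 <= 1 or n2 <= 1:
        raise ValueError("pooled SEM requires n1, n2 >= 2")
    within = (n1 * (n1 - 1) * s1**2 + n2 * (n2 - 1) * s2**2) / (n1 + n2 - 2)
    return math.sqrt((1.0 / n1 + 1.0 / n2) * within)


def _residual_rows(obs: SurveillanceTable, sim: dict):
    """Standardized level and consecutive-difference residuals.

    ``sim`` maps (province, window_end) to the simulated observable.  Returns
    (z_levels, z_diffs, log_norm) where log_norm is the sum of Gaussian
    normalization constants.
    """
    z_levels, z_diffs = [], []
    log_norm = 0.0
    df = obs.data
    for province, grp in df.groupby("province", sort=False):
        grp = grp.sort_values("window_end")
        prev = None
        for _, row in grp.iterrows():
            key = (province, pd.Timestamp(row["window_end"]))
            if key not in sim:
                raise KeyError(f"no simulated value for {key}")
            y = sim[key]
            sigma = float(row["sem"])
            if sigma <= 0:
                raise ValueError("sem must be > 0")
            z_levels.append((row["mean_eggs"] - y) / sigma)
            log_norm -= math.log(sigma * math.sqrt(2.0 * math.pi))
            if prev is not None and not bool(row["first_of_year"]):
                sp = pooled_sem(int(prev["n_traps"]), int(row["n_traps"]),
                                float(prev["sem"]), float(row["sem"]))
                y_prev = sim[(province, pd.Timestamp(prev["window_end"]))]
                d_obs = row["mean_eggs"] - prev["mean_eggs"]
                d_sim = y - y_prev
                z_diffs.append((d_obs - d_sim) / sp)
                log_norm -= math.log(sp * math.sqrt(2.0 * math.pi))
            prev = row
    return np.array(z_levels), np.array(z_diffs), log_norm


def data_loglik(obs: SurveillanceTable, sim: dict) -> float:
    """Gaussian log-likelihood of the surveillance table given simulations."""
    z_lv, z_df, log_norm = _residual_rows(obs, sim)
    return float(log_norm - 0.5 * (np.sum(z_lv**2) + np.sum(z_df**2)))


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

@dataclass
class ObjectiveValue:
    """Half squared Mahalanobis distance with its prior/data breakdown."""

    f: float
    prior_term: float
    data_term: float


class ModelObjective:
    """Posterior objective f(theta) for the population model.

    Holds the surveillance table, the per-province environments (each a single
    series or a list of grid-cell series to be averaged), the prior, and an
    optional set of *free* parameter names — the others stay pinned at the
    prior mean, and the chains run in the reduced space.
    """

    def __init__(self, obs: SurveillanceTable, envs: dict, prior: lh.PriorSpec,
                 free: Optional[Sequence[str]] = None,
                 count_diapause_conversions: bool = False):
        self.obs = obs
        self.envs = envs
        self.prior = prior
        self.count_diapause_conversions = count_diapause_conversions
        self.free_names = list(free) if free is not None else list(lh.PARAM_NAMES)
        unknown = set(self.free_names) - set(lh.PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown free parameters: {sorted(unknown)}")
        self._free_idx = np.array([lh.PARAM_NAMES.index(n) for n in self.free_names])
        self._chol = cho_factor(prior.cov + 1e-12 * np.eye(48))
        self._windows = [
            (row["province"], pd.Timestamp(row["window_end"]))
            for _, row in obs.data.iterrows()]
        self.n_evals = 0
        # precomputed day-index ranges of each window within its province series
        self._env_lists = {p: list(e) if isinstance(e, (list, tuple)) else [e]
                           for p, e in envs.items()}
        self._win_idx = {}
        for prov, end in self._windows:
            series = self._env_lists[prov][0]
            i_end = int((end - series.dates[0]).days)
            i_start = i_end - 13
            if i_start < 0 or i_end >= len(series):
                raise ValueError(f"window ending {end.date()} outside environment span")
            self._win_idx[(prov, end)] = (i_start, i_end)

    # -- free-space packing --------------------------------------------------
    @property
    def ndim(self) -> int:
        return len(self.free_names)

    def pack(self, theta_full: np.ndarray) -> np.ndarray:
        return np.asarray(theta_full, dtype=float)[self._free_idx]

    def unpack(self, x: np.ndarray) -> np.ndarray:
        theta = self.prior.mean.copy()
        theta[self._free_idx] = x
        return theta

    @property
    def bounds(self) -> np.ndarray:
        return np.array([self.prior.bounds[n] for n in self.free_names])

    def x0(self) -> np.ndarray:
        return self.pack(self.prior.mean)

    # -- evaluation ----------------------------------------------------------
    def simulate_windows(self, theta_full: np.ndarray) -> dict:
        """Simulate every province and collect the windowed observables.

        Calls the compiled kernel directly and sums precomputed window slices
        of the oviposition inflows (plus tagged-to-diapausing conversions if
        configured), averaging over a province's grid cells.
        """
        from ._kernel import simulate_kernel

        theta = np.asarray(theta_full, dtype=float)
        sim = {}
        for province, env_list in self._env_lists.items():
            laid = []
            for e in env_list:
                raw = simulate_kernel(e.T_a, e.precip, e.photoperiod,
                                      float(e.p_dens), theta, MU_MAX,
                                      lh.DURATION_FLOOR, False)
                col = raw[:, 7] + raw[:, 8]
                if self.count_diapause_conversions:
                    col = col + raw[:, 9]
                if not np.all(np.isfinite(col)):
                    raise RuntimeError(f"invalid population state in {province}")
                laid.append(np.concatenate(([0.0], np.cumsum(col))))
            for (prov, end), (i0, i1) in self._win_idx.items():
                if prov == province:
                    sim[(prov, end)] = float(np.mean(
                        [c[i1 + 1] - c[i0] for c in laid]))
        return sim

    def value(self, x: np.ndarray) -> ObjectiveValue:
        theta = self.unpack(np.asarray(x, dtype=float))
        if not self.prior.within_bounds(theta):
            return ObjectiveValue(np.inf, np.inf, np.inf)
        self.n_evals += 1
        resid = theta - self.prior.mean
        prior_term = 0.5 * float(resid @ cho_solve(self._chol, resid))
        try:
            sim = self.simulate_windows(theta)
        except RuntimeError:
            return ObjectiveValue(np.inf, prior_term, np.inf)
        z_lv, z_df, _ = _residual_rows(self.obs, sim)
        data_term = 0.5 * float(np.sum(z_lv**2) + np.sum(z_df**2))
        return ObjectiveValue(prior_term + data_term, prior_term, data_term)

    def __call__(self, x: np.ndarray) -> float:
        return self.value(x).f


# ---------------------------------------------------------------------------
# Annealed basin-hopping MCMC
# ---------------------------------------------------------------------------

def acceptance_probability(f_current: float, f_proposed: float, T_ann: float) -> float:
    """min{1, exp[(f(theta) - f(theta'))/T_ann]}; Metropolis-Hastings at T_ann = 1."""
    if T_ann <= 0:
        raise ValueError("annealing temperature must be > 0")
    if not np.isfinite(f_proposed):
        return 0.0
    if f_proposed <= f_current:
        return 1.0
    return math.exp((f_current - f_proposed) / T_ann)


@dataclass
class BasinHoppingConfig:
    """Tunables of the annealed basin-hopping search."""

    n_chains: int = 8
    n_phases: int = 3
    iters_per_phase: int = 300
    T_high: float = 50.0
    T_low: float = 1.0
    target_accept: float = 0.3
    adapt_rate: float = 0.05
    init_scale_frac: float = 0.1    # initial proposal sd as fraction of prior sd / range
    cov_adapt_min: int = 50          # accepted points before covariance adaptation
    dedupe_dist: float = 1.0         # normalized distance separating modes
    polish: bool = True              # descend each candidate to its local minimizer
    polish_maxfev: int = 300         # budget per candidate for the polish


@dataclass
class ModeCandidate:
    theta: np.ndarray
    f: float


def _proposal_scales(bounds: np.ndarray, scales: Optional[np.ndarray],
                     frac: float) -> np.ndarray:
    if scales is not None:
        return np.asarray(scales, dtype=float) * frac
    span = bounds[:, 1] - bounds[:, 0]
    span = np.where(np.isfinite(span), span, 10.0)
    return frac * span


def basin_hopping_mcmc(objective: Callable, bounds: np.ndarray,
                       config: BasinHoppingConfig = None, seed: int = 0,
                       x0: Optional[np.ndarray] = None,
                       scales: Optional[np.ndarray] = None) -> List[ModeCandidate]:
    """Search for posterior mode centres with annealed adaptive chains.

    Each chain runs ``n_phases`` cycles of a geometric temperature ladder from
    ``T_high`` down to ``T_low``; proposals are Gaussian with per-dimension
    scales adapted toward the target acceptance rate, switching to the
    empirical covariance of accepted history once enough points accumulate.
    Chain bests are deduplicated by a normalized distance threshold.
    """
    cfg = config or BasinHoppingConfig()
    bounds = np.asarray(bounds, dtype=float)
    d = bounds.shape[0]
    rng = np.random.default_rng(seed)
    base_scale = _proposal_scales(bounds, scales, cfg.init_scale_frac)
    norm = np.where(base_scale > 0, base_scale, 1.0)

    start_spread = _proposal_scales(bounds, scales, 1.0)
    candidates: List[ModeCandidate] = []
    any_finite = False
    for chain in range(cfg.n_chains):
        if x0 is not None:
            x = np.asarray(x0, dtype=float).copy()
            if chain > 0:
                # alternate narrow and wide starts: odd chains spread over the
                # full prior scale so separated basins are reachable, even
                # chains stay near the supplied centre
                spread = start_spread if chain % 2 else base_scale
                x = x + spread * rng.standard_normal(d)
        else:
            lo = np.where(np.isfinite(bounds[:, 0]), bounds[:, 0], -10.0)
            hi = np.where(np.isfinite(bounds[:, 1]), bounds[:, 1], 10.0)
            x = rng.uniform(lo, hi)
        x = np.clip(x, bounds[:, 0], bounds[:, 1])
        f = float(objective(x))
        best_x, best_f = x.copy(), f
        scale_mult = 1.0
        accepted_hist = [x.copy()]
        for phase in range(cfg.n_phases):
            ladder = np.geomspace(cfg.T_high, cfg.T_low, cfg.iters_per_phase)
            for it, T in enumerate(ladder):
                if len(accepted_hist) >= cfg.cov_adapt_min:
                    hist = np.array(accepted_hist[-500:])
                    cov = np.cov(hist.T) + 1e-10 * np.diag(norm**2)
                    try:
                        L = np.linalg.cholesky((2.38**2 / d) * cov)
                        stp = scale_mult * (L @ rng.standard_normal(d))
                    except np.linalg.LinAlgError:
                        stp = scale_mult * base_scale * rng.standard_normal(d)
                else:
                    stp = scale_mult * base_scale * rng.standard_normal(d)
                x_new = x + stp
                if np.any(x_new < bounds[:, 0]) or np.any(x_new > bounds[:, 1]):
                    f_new = np.inf
                else:
                    f_new = float(objective(x_new))
                if rng.random() < acceptance_probability(f, f_new, T):
                    x, f = x_new, f_new
                    accepted_hist.append(x.copy())
                    scale_mult *= 1.0 + cfg.adapt_rate * (1.0 - cfg.target_accept)
                else:
                    scale_mult *= 1.0 - cfg.adapt_rate * cfg.target_accept
                scale_mult = float(np.clip(scale_mult, 1e-3, 1e3))
                if f < best_f:
                    best_x, best_f = x.copy(), f
            # restart next phase from the chain's best (the hop refinement)
            x, f = best_x.copy(), best_f
        if np.isfinite(best_f):
            any_finite = True
            candidates.append(ModeCandidate(best_x, best_f))
    if not any_finite:
        raise RuntimeError("basin hopping found no finite objective value")

    # descend each chain best to its local minimizer so that modes are
    # compared at their floors, not at wherever the chains stopped
    if cfg.polish:
        from scipy.optimize import minimize

        for c in candidates:
            res = minimize(
                lambda x: float(objective(x)), c.theta, method="Nelder-Mead",
                options={"maxfev": cfg.polish_maxfev,
                         "xatol": 1e-4, "fatol": 1e-8})
            x_pol = np.asarray(res.x, dtype=float)
            inside = bool(np.all(x_pol >= bounds[:, 0]) and np.all(x_pol <= bounds[:, 1]))
            if inside and np.isfinite(res.fun) and res.fun < c.f:
                c.theta, c.f = x_pol, float(res.fun)

    # dedupe by normalized distance, best first
    candidates.sort(key=lambda c: c.f)
    modes: List[ModeCandidate] = []
    for c in candidates:
        if all(np.linalg.norm((c.theta - m.theta) / norm) > cfg.dedupe_dist
               for m in modes):
            modes.append(c)
    return modes


def sample_mode(objective: Callable, theta0: np.ndarray, bounds: np.ndarray,
                T_ann: float = 10.0, n_samples: int = 100, seed: int = 0,
                thin: int = 5, burn: int = 100,
                scales: Optional[np.ndarray] = None,
                scale_frac: float = 0.02) -> tuple:
    """Sample a posterior mode with a fixed-temperature Metropolis chain.

    Returns ``(samples, f_values)`` of ``n_samples`` thinned draws.  The
    proposal stays local (no tempered hops) so the chain explores a single
    basin; the stationary law is the posterior tempered by ``T_ann``.
    """
    bounds = np.asarray(bounds, dtype=float)
    d = bounds.shape[0]
    rng = np.random.default_rng(seed)
    scale = _proposal_scales(bounds, scales, scale_frac)
    x = np.asarray(theta0, dtype=float).copy()
    f = float(objective(x))
    if not np.isfinite(f):
        raise ValueError("mode centre has non-finite objective")
    samples = np.empty((n_samples, d))
    fvals = np.empty(n_samples)
    kept = 0
    it = 0
    scale_mult = 1.0
    while kept < n_samples:
        x_new = x + scale_mult * scale * rng.standard_normal(d)
        if np.any(x_new < bounds[:, 0]) or np.any(x_new > bounds[:, 1]):
            f_new = np.inf
        else:
            f_new = float(objective(x_new))
        if rng.random() < acceptance_probability(f, f_new, T_ann):
            x, f = x_new, f_new
            scale_mult *= 1.0 + 0.05 * 0.7
        else:
            scale_mult *= 1.0 - 0.05 * 0.3
        scale_mult = float(np.clip(scale_mult, 1e-3, 1e3))
        it += 1
        if it > burn and it % thin == 0:
            samples[kept] = x
            fvals[kept] = f
            kept += 1
    return samples, fvals


# ---------------------------------------------------------------------------
# Posterior-mode comparison
# ---------------------------------------------------------------------------

@dataclass
class ModeSamples:
    """Samples of one posterior mode with their objective values."""

    label: str
    samples: np.ndarray          # (N, d)
    f_values: np.ndarray         # (N,)
    center: Optional[np.ndarray] = None

    def gaussian_approx(self, ridge: float = 1e-10):
        mean = self.samples.mean(axis=0)
        cov = np.cov(self.samples.T, ddof=0)
        cov = np.atleast_2d(cov)
        cov = cov + ridge * np.eye(cov.shape[0]) * max(1.0, np.trace(cov))
        return mean, cov


@dataclass
class PosteriorModeSet:
    """Labelled posterior modes and their importance-sampled masses."""

    modes: List[ModeSamples]

    def __post_init__(self):
        if not self.modes:
            raise ValueError("at least one mode required")

    def sampling_logpdf(self, points: np.ndarray) -> np.ndarray:
        """log Pr(theta | S): equal-weight mixture of per-mode Gaussians."""
        points = np.atleast_2d(points)
        logps = []
        for m in self.modes:
            mean, cov = m.gaussian_approx()
            logps.append(multivariate_normal(mean, cov, allow_singular=True).logpdf(points))
        logps = np.atleast_2d(np.array(logps))
        return logsumexp(logps, axis=0) - math.log(len(self.modes))


def mode_posterior_mass(mode_set: PosteriorModeSet, T_tol: float = 1.0) -> np.ndarray:
    """Normalized posterior masses of the modes at tolerance T_tol.

    mass(Theta) ~ (1/N) sum_i exp(-f(theta_i)/T_tol) / Pr(theta_i | S),
    importance-corrected by the sampling mixture and normalized over the set.
    At T_tol = 1 mass ratios equal Bayes factors.
    """
    if T_tol <= 0:
        raise ValueError("T_tol must be > 0")
    log_masses = []
    for m in mode_set.modes:
        logq = mode_set.sampling_logpdf(m.samples)
        if np.any(~np.isfinite(logq)):
            raise ValueError(f"zero sampling density for a sample of mode {m.label}")
        terms = -m.f_values / T_tol - logq
        log_masses.append(logsumexp(terms) - math.log(len(m.f_values)))
    log_masses = np.array(log_masses)
    return np.exp(log_masses - logsumexp(log_masses))


def expected_output(samples: np.ndarray, objective: ModelObjective) -> pd.DataFrame:
    """Posterior-expected windowed observable with a 95% band.

    Simulates every sampled parameter vector and averages the per-window
    observables; the band is the 2.5/97.5 percentile across samples.
    """
    per_sample = []
    for th in np.atleast_2d(samples):
        theta = objective.unpack(th) if th.shape[0] == objective.ndim else th
        sim = objective.simulate_windows(theta)
        per_sample.append([sim[k] for k in objective._windows])
    arr = np.array(per_sample)
    return pd.DataFrame({
        "province": [k[0] for k in objective._windows],
        "window_end": [k[1] for k in objective._windows],
        "y_mean": arr.mean(axis=0),
        "y_lo": np.percentile(arr, 2.5, axis=0),
        "y_hi": np.percentile(arr, 97.5, axis=0),
    })


# ---------------------------------------------------------------------------
# Sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivityMatrix:
    """H = diag(theta_hat)^T Sigma^-1 diag(theta_hat) with named diagonal."""

    H: np.ndarray
    names: Optional[List[str]] = None

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.H)

    def per_parameter(self) -> pd.Series:
        idx = self.names if self.names is not None else range(self.H.shape[0])
        return pd.Series(self.diagonal, index=idx, name="sensitivity")


def sensitivity(theta_hat: np.ndarray, Sigma: np.ndarray,
                names: Optional[List[str]] = None,
                ridge: float = 0.0) -> SensitivityMatrix:
    """Sensitivity of the posterior to relative parameter perturbations.

    Large H_ii means the posterior degrades quickly when parameter i moves a
    given *fraction* of its value.  ``Sigma`` is the mode's sample covariance;
    a ridge is added (and logged) if it is numerically singular.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    d = Sigma.shape[0]
    if ridge > 0:
        Sigma = Sigma + ridge * np.eye(d)
    try:
        Sinv = np.linalg.inv(Sigma)
    except np.linalg.LinAlgError:
        logger.info("singular mode covariance; applying ridge")
        scale = max(np.trace(Sigma) / d, 1e-12)
        Sigma = Sigma + 1e-8 * scale * np.eye(d)
        try:
            Sinv = np.linalg.inv(Sigma)
        except np.linalg.LinAlgError as exc:
            raise ValueError("mode covariance singular even after ridge") from exc
    D = np.diag(theta_hat)
    return SensitivityMatrix(D.T @ Sinv @ D, names)
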