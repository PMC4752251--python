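"""Daily stage- and age-structured projection of the mosquito life cycle.

State vector (7 compartments): non-diapausing eggs (Egg), tagged eggs (Egg*),
diapausing eggs (Egg deg), larvae, pupae, naive (nulliparous) females and
parous adult females.  One step advances a day:

    n[t+1] = G(n, t) + M(n, t) . n[t]

where M carries survival, oviposition and diapause switching, and G moves
cohorts that completed development between stages.  Development is delayed and
age-structured: a batch laid on one day accumulates daily fractions 1/d_t and
progresses on the first day the accumulated fraction reaches 1 (the infimum
rule), with survival applied each day in between.  Pupae split 1:1 by sex and
only females are followed.

Two equivalent execution routes exist: the explicit :class:`PopulationState` /
:func:`step` objects below (the reference and the contract surface), and a
compiled kernel (:mod:`tigerpop._kernel`) used by :func:`simulate` for
calibration-scale work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from . import life_history as lh
from .breeding_site import CapacityState
from .diapause import SeasonState, season_indicators
from .environment import EnvironmentSeries, water_temperature

__all__ = [
    "CohortQueue",
    "PopulationState",
    "SimulationOutput",
    "DailyRates",
    "advance_cohorts",
    "development_total_days",
    "daily_rates",
    "step",
    "simulate",
    "windowed_egg_observable",
]

#: Cap on the immature density index when capacity collapses to ~0.
MU_MAX = 1e3

#: Batches smaller than this are dropped during queue compaction.
SIZE_EPS = 1e-30

#: Tolerance on the development-completion threshold: a batch whose
#: accumulated fraction reaches 1 within this slack progresses, so that d days
#: at a constant rate 1/d complete on day d despite rounding.
DEV_EPS = 1e-9

COMPARTMENTS = ("egg", "egg_tagged", "egg_diap", "larva", "pupa", "naive", "adult")


# ---------------------------------------------------------------------------
# Cohort queues and the delayed-development rule
# ---------------------------------------------------------------------------

@dataclass
class CohortQueue:
    """Ordered batches of (size, accumulated development fraction)."""

    batches: List[list] = field(default_factory=list)

    @property
    def total(self) -> float:
        return float(sum(b[0] for b in self.batches))

    def push(self, size: float):
        if size > 0.0:
            self.batches.append([float(size), 0.0])

    def advance(self, rate: float, survival: float) -> float:
        """Apply one day of survival and development; flush completed batches.

        Every batch is scaled by ``survival`` and gains ``rate`` development;
        batches whose accumulated fraction reaches 1 are removed and their
        summed size returned.
        """
        if rate < 0:
            raise ValueError("development rate must be >= 0")
        if not 0.0 <= survival <= 1.0:
            raise ValueError("survival must be in [0, 1]")
        developed = 0.0
        kept = []
        for size, dev in self.batches:
            size *= survival
            dev += rate
            if dev >= 1.0 - DEV_EPS:
                developed += size
            elif size > SIZE_EPS:
                kept.append([size, dev])
        self.batches = kept
        return developed

    def copy(self) -> "CohortQueue":
        return CohortQueue([list(b) for b in self.batches])


def advance_cohorts(queue: CohortQueue, rate: float, survival: float):
    """Functional form of :meth:`CohortQueue.advance`: returns (queue', developed)."""
    out = queue.copy()
    developed = out.advance(rate, survival)
    return out, developed


def development_total_days(rates) -> int:
    """Realized development duration: the smallest n with sum(rates[:n]) >= 1."""
    acc = 0.0
    for n, r in enumerate(rates, start=1):
        if r < 0:
            raise ValueError("development rates must be >= 0")
        acc += r
        if acc >= 1.0 - DEV_EPS:
            return n
    raise ValueError("development never completes within the given rate series")


# ---------------------------------------------------------------------------
# Daily rates from the life-history functions
# ---------------------------------------------------------------------------

@dataclass
class DailyRates:
    """All projection-matrix entries for one day, given temperature and density."""

    d1: float
    d2: float
    d3: float
    t_bm: float
    F4: float
    p0: float
    p1: float
    p2: float
    p3: float
    p4: float
    p_LD: float
    d23: float


def daily_rates(params: lh.ParameterVector, T_a: float, mu: float,
                floor: float = lh.DURATION_FLOOR) -> DailyRates:
    """Evaluate development times, survivals and fecundity for one day.

    Immature development and survival respond to water temperature
    (T_w = T_a - delta_T); adult survival, fecundity and blood-meal timing to
    air temperature.  Density inflates larval/pupal development times (d23
    factor) and depresses their survival (p_LD).
    """
    T_w = water_temperature(T_a, params["delta_T"])
    d23 = lh.density_dev_factor(
        mu, T_w, params["alpha_a"], params["alpha_b"], params["alpha_c"],
        params["alpha_d"], params["alpha_e"])
    p_LD = lh.density_survival(mu, params["alpha_LD"]) if mu > 0 else 1.0
    return DailyRates(
        d1=lh.eval_development(params.poly("d1"), T_w, floor),
        d2=lh.eval_development(params.poly("d2"), T_w, floor) * d23,
        d3=lh.eval_development(params.poly("d3"), T_w, floor) * d23,
        t_bm=lh.eval_development(params.poly("tbm"), T_a, floor),
        F4=max(0.0, params.poly("F4")(T_a)),
        p0=float(np.clip(params["p0_b0"] + params["p0_b1"] * T_a, 0.0, 1.0)),
        p1=lh.eval_two_sided_sigmoid(params.sigmoid("p1"), T_w),
        p2=lh.eval_two_sided_sigmoid(params.sigmoid("p2"), T_w) * p_LD,
        p3=lh.eval_two_sided_sigmoid(params.sigmoid("p3"), T_w) * p_LD,
        p4=lh.eval_two_sided_sigmoid(params.sigmoid("p4"), T_a),
        p_LD=p_LD,
        d23=d23,
    )


# ---------------------------------------------------------------------------
# Population state and the daily step
# ---------------------------------------------------------------------------

@dataclass
class PopulationState:
    """The 7 compartments with their cohort queues and auxiliary state."""

    capacity: CapacityState
    season: SeasonState
    egg_q: CohortQueue = field(default_factory=CohortQueue)
    egg_tagged_q: CohortQueue = field(default_factory=CohortQueue)
    larva_q: CohortQueue = field(default_factory=CohortQueue)
    pupa_q: CohortQueue = field(default_factory=CohortQueue)
    naive_q: CohortQueue = field(default_factory=CohortQueue)
    egg_diap: float = 0.0
    adult: float = 0.0
    day: int = 0

    @classmethod
    def initial(cls, params: lh.ParameterVector, p_dens: float,
                ramp_counts_unfav_only: bool = False) -> "PopulationState":
        """Winter-introduction state: E0_init diapausing eggs, all else zero."""
        cap = CapacityState(params["alpha_pdens"], params["alpha_dprec"],
                            params["alpha_evap"], p_dens)
        season = SeasonState(params["p_s"], ramp_counts_unfav_only)
        return cls(cap, season, egg_diap=params["E0_init"])

    @property
    def egg(self) -> float:
        return self.egg_q.total

    @property
    def egg_tagged(self) -> float:
        return self.egg_tagged_q.total

    @property
    def larva(self) -> float:
        return self.larva_q.total

    @property
    def pupa(self) -> float:
        return self.pupa_q.total

    @property
    def naive(self) -> float:
        return self.naive_q.total

    def vector(self) -> np.ndarray:
        """The 7-compartment state vector n_t."""
        return np.array([self.egg, self.egg_tagged, self.egg_diap,
                         self.larva, self.pupa, self.naive, self.adult])


def immature_density(larva: float, pupa: float, K: float, mu_max: float = MU_MAX) -> float:
    """Density index mu = (Larva + Pupa) / K, with the 0/0 and K=0 conventions."""
    lp = larva + pupa
    if K <= 0.0:
        return 0.0 if lp == 0.0 else mu_max
    return min(lp / K, mu_max)


def step(state: PopulationState, env_day, params: lh.ParameterVector,
         mu_max: float = MU_MAX) -> dict:
    """Advance the population by one day in place; returns the day's record.

    ``env_day`` needs attributes/items ``T_a``, ``precip`` and ``photoperiod``.
    Order within the day: capacity -> density -> rates -> season indicators ->
    cohort development -> stock survival -> oviposition.  All flows are
    evaluated from the start-of-day state, matching the projection form
    n[t+1] = G + M . n[t].
    """
    T_a = float(env_day["T_a"] if isinstance(env_day, (dict, pd.Series)) else env_day.T_a)
    precip = float(env_day["precip"] if isinstance(env_day, (dict, pd.Series)) else env_day.precip)
    pp = float(env_day["photoperiod"] if isinstance(env_day, (dict, pd.Series))
               else env_day.photoperiod)

    adult_t = state.adult
    K = state.capacity.step(precip)
    mu = immature_density(state.larva, state.pupa, K, mu_max)
    r = daily_rates(params, T_a, mu)
    I_fav, I_unfav = season_indicators(T_a, pp, params["T_crt"], params["CPP"])
    p_dp = state.season.update(state.day, I_fav, I_unfav)

    egg_dev = state.egg_q.advance(1.0 / r.d1, r.p1)
    eggstar_dev = state.egg_tagged_q.advance(1.0 / r.d1, r.p1)
    larva_dev = state.larva_q.advance(1.0 / r.d2, r.p2)
    pupa_dev = state.pupa_q.advance(1.0 / r.d3, r.p3)
    naive_dev = state.naive_q.advance(1.0 / r.t_bm, r.p4)

    hatched = I_fav * r.p0 * params["p_n"] * state.egg_diap
    state.egg_diap = r.p0 * (1.0 - I_fav * params["p_n"]) * state.egg_diap + eggstar_dev
    state.adult = r.p4 * adult_t + naive_dev

    laid = r.F4 * adult_t
    laid_tagged = I_unfav * p_dp * laid
    laid_normal = laid - laid_tagged
    state.egg_q.push(laid_normal)
    state.egg_tagged_q.push(laid_tagged)
    state.larva_q.push(egg_dev + hatched)
    state.pupa_q.push(larva_dev)
    state.naive_q.push(0.5 * pupa_dev)
    state.day += 1

    vec = state.vector()
    if not np.all(np.isfinite(vec)) or np.any(vec < 0):
        raise RuntimeError(f"invalid population state on day {state.day}: {vec}")

    return {
        "egg": vec[0], "egg_tagged": vec[1], "egg_diap": vec[2], "larva": vec[3],
        "pupa": vec[4], "naive": vec[5], "adult": vec[6],
        "laid_normal": laid_normal, "laid_tagged": laid_tagged,
        "diap_conversions": eggstar_dev, "K": K,
        "I_fav": I_fav, "I_unfav": I_unfav, "mu": mu,
    }


# ---------------------------------------------------------------------------
# Full simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationOutput:
    """Per-day trajectory: the 7 compartments, oviposition inflows, K, season
    indicators and the density index.  Row t is the state after day t."""

    data: pd.DataFrame
    env: EnvironmentSeries

    def __len__(self):
        return len(self.data)

    def to_csv(self, path):
        self.data.to_csv(path, index=False)


def simulate(env: EnvironmentSeries, params, engine: str = "numba",
             mu_max: float = MU_MAX,
             ramp_counts_unfav_only: bool = False) -> SimulationOutput:
    """Run the daily projection over a full driver series.

    The initial state holds ``E0_init`` diapausing eggs at the first day of
    the series (a winter introduction) and nothing else; the run is
    deterministic.  ``engine`` selects the compiled kernel (default) or the
    pure-Python reference (``"python"``); both produce the same trajectory.
    """
    if isinstance(params, lh.ParameterVector):
        theta = params.values
    else:
        theta = np.asarray(params, dtype=float)
        params = lh.ParameterVector(theta)
    if engine == "numba":
        try:
            from ._kernel import simulate_kernel
        except ImportError:  # pragma: no cover - numba is a hard dependency
            engine = "python"
    if engine == "numba":
        raw = simulate_kernel(env.T_a, env.precip, env.photoperiod,
                              float(env.p_dens), theta, mu_max,
                              lh.DURATION_FLOOR, bool(ramp_counts_unfav_only))
        if not np.all(np.isfinite(raw)):
            bad = int(np.argwhere(~np.isfinite(raw).all(axis=1))[0, 0])
            raise RuntimeError(f"invalid population state on day {bad + 1}")
        df = pd.DataFrame(raw, columns=[
            "egg", "egg_tagged", "egg_diap", "larva", "pupa", "naive", "adult",
            "laid_normal", "laid_tagged", "diap_conversions", "K",
            "I_fav", "I_unfav", "mu"])
    elif engine == "python":
        state = PopulationState.initial(params, env.p_dens, ramp_counts_unfav_only)
        rows = []
        for i in range(len(env)):
            rows.append(step(state, {"T_a": env.T_a[i], "precip": env.precip[i],
                                     "photoperiod": env.photoperiod[i]}, params, mu_max))
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    df.insert(0, "date", env.dates)
    return SimulationOutput(df, env)


def windowed_egg_observable(output, window_end, days: int = 14,
                            count_diapause_conversions: bool = False) -> float:
    """Mean eggs per trap over the 14 days up to ``window_end`` (inclusive).

    Sums the daily oviposition inflows (normal + tagged); with
    ``count_diapause_conversions`` the tagged-to-diapausing conversions are
    added as well (a sensitivity variant — conversions re-count eggs already
    counted when laid).  ``output`` may be a single :class:`SimulationOutput`
    or a list of them (grid cells of one province), in which case the per-cell
    sums are averaged.
    """
    if isinstance(output, (list, tuple)):
        return float(np.mean([
            windowed_egg_observable(o, window_end, days, count_diapause_conversions)
            for o in output]))
    end = pd.Timestamp(window_end)
    start = end - pd.Timedelta(days=days - 1)
    dates = output.data["date"]
    if start < dates.iloc[0] or end > dates.iloc[-1]:
        raise ValueError(f"window ending {end.date()} not fully inside the simulation span")
    sel = (dates >= start) & (dates <= end)
    if int(sel.sum()) != days:
        raise ValueError("window does not cover the expected number of days")
    sub = output.data.loc[sel]
    total = float(sub["laid_normal"].sum() + sub["laid_tagged"].sum())
    if count_diapause_conversions:
        total += float(sub["diap_conversions"].sum())
    return total
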