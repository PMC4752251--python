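"""Top-level Model / Results interface over the calibration machinery.

:class:`VectorPopulationModel` binds surveillance evidence, per-province
driver series and a prior; :meth:`fit` runs the annealed basin-hopping search
plus fixed-temperature mode sampling and returns a
:class:`CalibrationResults` carrying the posterior modes, their masses,
parameter estimates with spreads, sensitivities and plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import life_history as lh
from .environment import SurveillanceTable
from .inference import (
    BasinHoppingConfig,
    ModelObjective,
    ModeSamples,
    PosteriorModeSet,
    basin_hopping_mcmc,
    expected_output,
    mode_posterior_mass,
    sample_mode,
    sensitivity,
)

__all__ = ["VectorPopulationModel", "CalibrationResults"]


class VectorPopulationModel:
    """Environmentally-driven mosquito population model bound to evidence.

    Parameters
    ----------
    surveillance : SurveillanceTable
        Biweekly ovitrap means per province.
    environments : dict
        Province name -> EnvironmentSeries (or list of them for several grid
        cells per province).
    prior : PriorSpec, optional
        Defaults to the package's literature-style prior.
    free : sequence of str, optional
        Parameter names allowed to move during calibration; the rest stay at
        the prior mean.
    """

    def __init__(self, surveillance: SurveillanceTable, environments: dict,
                 prior: Optional[lh.PriorSpec] = None,
                 free: Optional[Sequence[str]] = None):
        self.prior = prior or lh.default_prior()
        self.objective = ModelObjective(surveillance, environments, self.prior, free)
        self.surveillance = surveillance
        self.environments = environments

    @classmethod
    def from_files(cls, surveillance_csv, environments: dict, prior_yaml=None,
                   free=None) -> "VectorPopulationModel":
        prior = lh.PriorSpec.from_yaml(prior_yaml) if prior_yaml else None
        return cls(SurveillanceTable.from_csv(surveillance_csv), environments,
                   prior, free)

    def loglike_objective(self, theta) -> float:
        """f(theta) of a full 48-vector (lower is better)."""
        th = theta.values if isinstance(theta, lh.ParameterVector) else np.asarray(theta)
        return float(self.objective(self.objective.pack(th)))

    def fit(self, config: Optional[BasinHoppingConfig] = None, seed: int = 0,
            n_mode_samples: int = 100, T_sample: float = 10.0,
            start_from_prior_mean: bool = True) -> "CalibrationResults":
        """Run the annealed basin-hopping search and sample each mode.

        The search phase locates candidate mode centres; each centre is then
        sampled with a fixed-temperature chain (default T_ann = 10, 100 draws)
        to approximate the local posterior.
        """
        obj = self.objective
        sds = np.array([np.sqrt(self.prior.cov[i, i])
                        for i in obj._free_idx])
        candidates = basin_hopping_mcmc(
            obj, obj.bounds, config, seed=seed,
            x0=obj.x0() if start_from_prior_mean else None, scales=sds)
        modes = []
        for k, cand in enumerate(candidates):
            samples, fvals = sample_mode(
                obj, cand.theta, obj.bounds, T_ann=T_sample,
                n_samples=n_mode_samples, seed=seed + 1000 + k, scales=sds)
            modes.append(ModeSamples(f"Theta{k + 1}", samples, fvals, cand.theta))
        return CalibrationResults(self, PosteriorModeSet(modes))


@dataclass
class CalibrationResults:
    """Posterior modes of a fitted :class:`VectorPopulationModel`."""

    model: VectorPopulationModel
    mode_set: PosteriorModeSet

    @property
    def modes(self) -> List[ModeSamples]:
        return self.mode_set.modes

    @property
    def best_mode(self) -> ModeSamples:
        return min(self.modes, key=lambda m: float(np.min(m.f_values)))

    @property
    def params(self) -> lh.ParameterVector:
        """Best mode centre as a full ParameterVector."""
        best = self.best_mode
        theta = best.center if best.center is not None else best.samples.mean(axis=0)
        return lh.ParameterVector(self.model.objective.unpack(theta))

    def mode_masses(self, T_tol: float = 1.0) -> pd.Series:
        masses = mode_posterior_mass(self.mode_set, T_tol)
        return pd.Series(masses, index=[m.label for m in self.modes], name="mass")

    def sensitivity(self, mode: Optional[ModeSamples] = None):
        m = mode or self.best_mode
        mean, cov = m.gaussian_approx()
        center = m.center if m.center is not None else mean
        return sensitivity(center, cov, names=self.model.objective.free_names)

    def expected_output(self, mode: Optional[ModeSamples] = None) -> pd.DataFrame:
        m = mode or self.best_mode
        return expected_output(m.samples, self.model.objective)

    def summary(self) -> str:
        """Human-readable calibration summary."""
        obj = self.model.objective
        lines = ["Vector population model calibration",
                 "=" * 51,
                 f"observations: {len(self.model.surveillance)}  "
                 f"provinces: {len(self.model.surveillance.provinces)}",
                 f"free parameters: {obj.ndim} / 48",
                 f"posterior modes: {len(self.modes)}"]
        masses = self.mode_masses(T_tol=10.0)
        for m in self.modes:
            lines.append(f"  {m.label}: min f = {float(np.min(m.f_values)):.3f}, "
                         f"mass(T_tol=10) = {masses[m.label]:.3f}")
        lines.append("-" * 51)
        lines.append(f"{'parameter':<14}{'estimate':>12}{'post sd':>12}{'prior mean':>13}")
        best = self.best_mode
        est = best.center if best.center is not None else best.samples.mean(axis=0)
        sds = best.samples.std(axis=0)
        prior_mean = obj.pack(self.model.prior.mean)
        for name, e, s, pm in zip(obj.free_names, est, sds, prior_mean):
            lines.append(f"{name:<14}{e:>12.4f}{s:>12.4f}{pm:>13.4f}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed vs posterior-expected windowed egg counts per province."""
        import matplotlib.pyplot as plt

        exp = self.expected_output()
        obs = self.model.surveillance.data
        provinces = list(obs["province"].unique())
        if ax is None:
            _, axes = plt.subplots(len(provinces), 1, sharex=True,
                                   figsize=(8, 2.5 * len(provinces)), squeeze=False)
            axes = axes[:, 0]
        else:
            axes = [ax] * len(provinces)
        for p, a in zip(provinces, axes):
            o = obs[obs["province"] == p]
            e = exp[exp["province"] == p]
            a.errorbar(o["window_end"], o["mean_eggs"], yerr=o["sem"], fmt="d",
                       label="observed")
            a.plot(e["window_end"], e["y_mean"], "k-", label="model")
            a.fill_between(e["window_end"], e["y_lo"], e["y_hi"], color="r", alpha=0.2)
            a.set_ylabel(f"{p}\neggs/trap")
        axes[0].legend()
        return axes
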