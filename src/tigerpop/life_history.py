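"""Temperature-dependent life-history traits and the canonical parameter vector.

Development times (egg, larva, pupa) and the time from adult emergence to the
first blood meal are second-degree polynomials of temperature; fecundity is a
polynomial of air temperature; daily survival of non-diapausing eggs, larvae,
pupae and adults follows two-sided sigmoids of temperature; diapausing-egg
survival is linear in air temperature.  Density dependence enters through a
multiplicative inflation of larval/pupal development times and an exponential
depression of their survival.

The model is parameterised by a flat 48-entry vector (:class:`ParameterVector`)
with named entries, grouped by role, each with hard bounds.  Priors are
multivariate Gaussians, block-diagonal by fitted curve (:class:`PriorSpec`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import curve_fit
from scipy.special import expit

__all__ = [
    "PolyCoeffs",
    "TwoSidedSigmoidCoeffs",
    "LinearCoeffs",
    "ParameterVector",
    "PriorSpec",
    "PARAM_NAMES",
    "PARAM_GROUPS",
    "PARAM_BOUNDS",
    "eval_development",
    "eval_poly",
    "eval_two_sided_sigmoid",
    "eval_linear_survival",
    "daily_survival_from_total",
    "daily_fecundity",
    "density_dev_factor",
    "density_survival",
    "fit_prior",
    "default_parameters",
    "default_prior",
]

#: Minimum admissible stage duration in days (guards 1/d rates).
DURATION_FLOOR = 1.0


# ---------------------------------------------------------------------------
# Functional forms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolyCoeffs:
    """Quadratic a0 + a1*T + a2*T**2 (days when used as a duration)."""

    a0: float
    a1: float
    a2: float

    def __call__(self, T):
        return self.a0 + self.a1 * T + self.a2 * T * T


@dataclass(frozen=True)
class TwoSidedSigmoidCoeffs:
    """Product of a rising and a falling logistic, scaled by ``p_max``.

    value(T) = p_max * logistic(s_low*(T - T_low)) * logistic(-s_high*(T - T_high))
    """

    p_max: float
    T_low: float
    T_high: float
    s_low: float
    s_high: float

    def __post_init__(self):
        if not self.T_low < self.T_high:
            raise ValueError(
                f"two-sided sigmoid requires T_low < T_high, got "
                f"({self.T_low}, {self.T_high})"
            )

    def __call__(self, T):
        return (
            self.p_max
            * expit(self.s_low * (np.asarray(T, dtype=float) - self.T_low))
            * expit(-self.s_high * (np.asarray(T, dtype=float) - self.T_high))
        )


@dataclass(frozen=True)
class LinearCoeffs:
    """Linear probability b0 + b1*T, clamped to [0, 1]."""

    b0: float
    b1: float

    def __call__(self, T):
        return np.clip(self.b0 + self.b1 * np.asarray(T, dtype=float), 0.0, 1.0)


def eval_poly(a0: float, a1: float, a2: float, T: float) -> float:
    return a0 + a1 * T + a2 * T * T


def eval_development(coeffs: PolyCoeffs, T: float, floor: float = DURATION_FLOOR) -> float:
    """Stage duration in days at temperature ``T``, clamped below by ``floor``."""
    return max(float(floor), float(coeffs(T)))


def eval_two_sided_sigmoid(coeffs: TwoSidedSigmoidCoeffs, T: float) -> float:
    return float(coeffs(T))


def eval_linear_survival(coeffs: LinearCoeffs, T: float) -> float:
    return float(coeffs(T))


def daily_survival_from_total(S_total: float, duration: float) -> float:
    """Daily survival from a stage-total survival under fixed daily mortality.

    Solves p**duration = S_total.
    """
    if not 0.0 <= S_total <= 1.0:
        raise ValueError("total survival must be in [0, 1]")
    if duration < 1:
        raise ValueError("duration must be >= 1 day")
    if S_total == 0.0:
        import warnings

        warnings.warn("total survival of 0 gives daily survival 0", stacklevel=2)
        return 0.0
    return S_total ** (1.0 / duration)


def daily_fecundity(F_total: float, p4: float) -> float:
    """Eggs laid per day from lifetime fecundity under fixed daily mortality.

    Expected adult lifespan under daily survival ``p4`` is the geometric mean
    1/(1 - p4); daily fecundity is lifetime fecundity divided by it.
    """
    if not 0.0 <= p4 < 1.0:
        raise ValueError("daily survival must be in [0, 1); p4 = 1 gives infinite lifespan")
    lifespan = 1.0 / (1.0 - p4)
    return F_total / lifespan


def mean_lifespan(p4: float, convention: str = "geometric") -> float:
    """Expected adult lifespan in days under fixed daily survival ``p4``.

    ``geometric`` uses 1/(1-p4); ``continuous`` uses the exponential-hazard
    analogue -1/ln(p4).
    """
    if convention == "geometric":
        return 1.0 / (1.0 - p4)
    if convention == "continuous":
        return -1.0 / math.log(p4)
    raise ValueError(f"unknown lifespan convention {convention!r}")


def density_dev_factor(
    mu: float, T_w: float, alpha_a: float, alpha_b: float, alpha_c: float,
    alpha_d: float, alpha_e: float,
) -> float:
    """Multiplicative inflation of larval/pupal development times.

    d23(mu, T_w) = alpha_d * mu**alpha_e * tau(T_w) with
    tau(T_w) = alpha_a + alpha_b*T_w + alpha_c*T_w**2, floored at 1 so that at
    negligible density development times are set by temperature alone.
    """
    if mu < 0:
        raise ValueError("density mu must be >= 0")
    if mu == 0.0:
        return 1.0
    tau = alpha_a + alpha_b * T_w + alpha_c * T_w * T_w
    return max(1.0, alpha_d * mu ** alpha_e * tau)


def density_survival(mu: float, alpha_LD: float) -> float:
    """Density-dependent survival factor exp(-alpha_LD * mu) for immatures."""
    if mu < 0:
        raise ValueError("density mu must be >= 0")
    if alpha_LD <= 0:
        raise ValueError("alpha_LD must be > 0")
    return math.exp(-alpha_LD * mu)


# ---------------------------------------------------------------------------
# The canonical 48-entry parameter vector
# ---------------------------------------------------------------------------

def _poly_names(stem):
    return [f"{stem}_a0", f"{stem}_a1", f"{stem}_a2"]


def _sig_names(stem):
    return [f"{stem}_max", f"{stem}_Tlow", f"{stem}_Thigh", f"{stem}_slope"]


#: Ordered names of the 48 parameters.  Each two-sided sigmoid contributes four
#: entries (p_max, T_low, T_high, one shared slope).
PARAM_NAMES: tuple = tuple(
    _poly_names("d1") + _poly_names("d2") + _poly_names("d3") + _poly_names("tbm")
    + _poly_names("F4")
    + ["p0_b0", "p0_b1"]
    + _sig_names("p1") + _sig_names("p2") + _sig_names("p3") + _sig_names("p4")
    + ["alpha_a", "alpha_b", "alpha_c", "alpha_d", "alpha_e", "alpha_LD"]
    + ["alpha_pdens", "alpha_dprec", "alpha_evap"]
    + ["T_crt", "CPP", "p_s", "p_n"]
    + ["delta_T", "E0_init"]
)
assert len(PARAM_NAMES) == 48

#: Parameter groups (prior covariance blocks follow these).
PARAM_GROUPS: dict = {
    "dev_egg": _poly_names("d1"),
    "dev_larva": _poly_names("d2"),
    "dev_pupa": _poly_names("d3"),
    "dev_bloodmeal": _poly_names("tbm"),
    "fecundity": _poly_names("F4"),
    "surv_diapause_egg": ["p0_b0", "p0_b1"],
    "surv_egg": _sig_names("p1"),
    "surv_larva": _sig_names("p2"),
    "surv_pupa": _sig_names("p3"),
    "surv_adult": _sig_names("p4"),
    "density": ["alpha_a", "alpha_b", "alpha_c", "alpha_d", "alpha_e", "alpha_LD"],
    "breeding_site": ["alpha_pdens", "alpha_dprec", "alpha_evap"],
    "diapause": ["T_crt", "CPP", "p_s", "p_n"],
    "water_offset": ["delta_T"],
    "introduction": ["E0_init"],
}

_BIG = 1e6

#: Hard bounds per entry (lower, upper); proposals outside are rejected.
PARAM_BOUNDS: dict = {}
for _n in PARAM_NAMES:
    PARAM_BOUNDS[_n] = (-_BIG, _BIG)
for _n in ("p1_max", "p2_max", "p3_max", "p4_max"):
    PARAM_BOUNDS[_n] = (0.0, 1.0)
for _n in ("p1_slope", "p2_slope", "p3_slope", "p4_slope"):
    PARAM_BOUNDS[_n] = (1e-3, 100.0)
PARAM_BOUNDS.update({
    "p0_b0": (0.0, 1.5),
    "p0_b1": (-0.5, 0.5),
    "alpha_d": (0.0, _BIG),
    "alpha_e": (0.0, 10.0),
    "alpha_LD": (1e-9, 100.0),
    "alpha_pdens": (0.0, _BIG),
    "alpha_dprec": (0.0, _BIG),
    "alpha_evap": (1e-9, 1.0 - 1e-9),
    "T_crt": (-20.0, 40.0),
    "CPP": (1e-6, 24.0 - 1e-6),
    "p_s": (1e-9, 1.0),
    "p_n": (1e-9, 1.0),
    "E0_init": (0.0, _BIG),
})

_INDEX = {n: i for i, n in enumerate(PARAM_NAMES)}


class ParameterVector:
    """The 48-entry model parameter set with named access and group views.

    Backed by a flat float64 array in the canonical order (``PARAM_NAMES``).
    """

    names = PARAM_NAMES
    groups = PARAM_GROUPS

    def __init__(self, values):
        arr = np.asarray(values, dtype=float).copy()
        if arr.shape != (48,):
            raise ValueError(f"expected 48 entries, got shape {arr.shape}")
        self.values = arr

    @classmethod
    def from_dict(cls, mapping: dict) -> "ParameterVector":
        missing = set(PARAM_NAMES) - set(mapping)
        extra = set(mapping) - set(PARAM_NAMES)
        if missing or extra:
            raise ValueError(f"bad parameter mapping: missing={sorted(missing)}, "
                             f"unknown={sorted(extra)}")
        return cls([mapping[n] for n in PARAM_NAMES])

    def to_dict(self) -> dict:
        return {n: float(v) for n, v in zip(PARAM_NAMES, self.values)}

    def group(self, name: str) -> dict:
        return {n: self[n] for n in PARAM_GROUPS[name]}

    def __getitem__(self, name: str) -> float:
        return float(self.values[_INDEX[name]])

    def __setitem__(self, name: str, value: float):
        self.values[_INDEX[name]] = value

    def __len__(self):
        return 48

    def replace(self, **kwargs) -> "ParameterVector":
        out = ParameterVector(self.values)
        for k, v in kwargs.items():
            out[k] = v
        return out

    def within_bounds(self) -> bool:
        return all(
            PARAM_BOUNDS[n][0] <= v <= PARAM_BOUNDS[n][1]
            for n, v in zip(PARAM_NAMES, self.values)
        )

    # -- typed views used by the dynamics ------------------------------------
    def poly(self, stem: str) -> PolyCoeffs:
        return PolyCoeffs(self[f"{stem}_a0"], self[f"{stem}_a1"], self[f"{stem}_a2"])

    def sigmoid(self, stem: str) -> TwoSidedSigmoidCoeffs:
        return TwoSidedSigmoidCoeffs(
            self[f"{stem}_max"], self[f"{stem}_Tlow"], self[f"{stem}_Thigh"],
            self[f"{stem}_slope"], self[f"{stem}_slope"],
        )

    def linear(self, stem: str) -> LinearCoeffs:
        return LinearCoeffs(self[f"{stem}_b0"], self[f"{stem}_b1"])

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterVector":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def __repr__(self):
        return f"ParameterVector({self.to_dict()!r})"


#: Reference parameter values: plausible temperate-strain life history at the
#: per-ovitrap habitat scale.  Development minima of a few days near 25-30 C,
#: adult thermal survival window anchored at (-3, 37.5) C, diapause thresholds
#: in the range reported for southern-European populations.
_DEFAULTS = {
    # development-time polynomials, days vs water temperature
    "d1_a0": 30.0, "d1_a1": -1.8, "d1_a2": 0.03,
    "d2_a0": 35.0, "d2_a1": -2.0, "d2_a2": 0.034,
    "d3_a0": 12.0, "d3_a1": -0.7, "d3_a2": 0.012,
    # emergence to first blood meal, days vs air temperature
    "tbm_a0": 6.0, "tbm_a1": -0.25, "tbm_a2": 0.004,
    # daily fecundity, eggs/female/day vs air temperature (clamped >= 0;
    # positive down to ~11 C so laying continues into the diapause window)
    "F4_a0": -25.0, "F4_a1": 2.8, "F4_a2": -0.055,
    # diapausing-egg daily survival, linear in air temperature
    "p0_b0": 0.98, "p0_b1": 0.002,
    # daily survival sigmoids
    "p1_max": 0.99, "p1_Tlow": 0.0, "p1_Thigh": 40.0, "p1_slope": 0.5,
    "p2_max": 0.98, "p2_Tlow": 2.0, "p2_Thigh": 38.0, "p2_slope": 0.5,
    "p3_max": 0.98, "p3_Tlow": 2.0, "p3_Thigh": 38.0, "p3_slope": 0.5,
    "p4_max": 0.96, "p4_Tlow": -3.0, "p4_Thigh": 37.5, "p4_slope": 0.5,
    # density dependence
    "alpha_a": 1.0, "alpha_b": 0.0, "alpha_c": 0.0,
    "alpha_d": 1.5, "alpha_e": 1.0, "alpha_LD": 0.1,
    # breeding site
    "alpha_pdens": 0.02, "alpha_dprec": 5.0, "alpha_evap": 0.9,
    # diapause switching: entry while autumn laying is still active
    "T_crt": 16.0, "CPP": 12.5, "p_s": 0.2, "p_n": 0.1,
    # water-air temperature offset and introduction size
    "delta_T": 0.0, "E0_init": 100.0,
}


def default_parameters() -> ParameterVector:
    """Reference ParameterVector (also the default prior mean)."""
    return ParameterVector.from_dict(_DEFAULTS)


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Multivariate Gaussian prior over the 48 parameters.

    Covariance is block-diagonal by fitted curve; hard bounds truncate it.
    """

    mean: np.ndarray
    cov: np.ndarray
    bounds: dict = field(default_factory=lambda: dict(PARAM_BOUNDS))

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean.shape != (48,) or self.cov.shape != (48, 48):
            raise ValueError("prior must cover all 48 parameters")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("prior covariance must be symmetric")
        mv = ParameterVector(self.mean)
        if not mv.within_bounds():
            raise ValueError("prior mean violates hard bounds")

    def set_block(self, names, mean, cov):
        """Insert a fitted block (means + covariance) for the named entries."""
        idx = np.array([_INDEX[n] for n in names])
        mean = np.asarray(mean, dtype=float)
        cov = np.atleast_2d(np.asarray(cov, dtype=float))
        self.mean[idx] = mean
        self.cov[np.ix_(idx, idx)] = cov

    def sds(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def within_bounds(self, theta: np.ndarray) -> bool:
        lo = np.array([self.bounds[n][0] for n in PARAM_NAMES])
        hi = np.array([self.bounds[n][1] for n in PARAM_NAMES])
        th = np.asarray(theta, dtype=float)
        return bool(np.all(th >= lo) and np.all(th <= hi))

    def to_yaml(self, path):
        payload = {
            "mean": {n: float(v) for n, v in zip(PARAM_NAMES, self.mean)},
            "sd": {n: float(v) for n, v in zip(PARAM_NAMES, self.sds())},
            "bounds": {n: [float(b) for b in self.bounds[n]] for n in PARAM_NAMES},
            "blocks": {g: list(ns) for g, ns in PARAM_GROUPS.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PriorSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        mean = np.array([payload["mean"][n] for n in PARAM_NAMES])
        sd = np.array([payload["sd"][n] for n in PARAM_NAMES])
        bounds = {n: tuple(payload["bounds"][n]) for n in PARAM_NAMES}
        return cls(mean, np.diag(sd**2), bounds)


_FORM_FUNCS = {
    "poly": (lambda T, a0, a1, a2: a0 + a1 * T + a2 * T**2, 3),
    "linear": (lambda T, b0, b1: b0 + b1 * T, 2),
    "sigmoid": (
        lambda T, pmax, Tlow, Thigh, s: pmax * expit(s * (T - Tlow)) * expit(-s * (T - Thigh)),
        4,
    ),
}


def fit_prior(x, y, form: str, trait: str = "", p0=None):
    """Least-squares fit of a functional form to trait observations.

    Returns ``(estimate, covariance)`` from :func:`scipy.optimize.curve_fit`
    (Jacobian-based covariance), ready for :meth:`PriorSpec.set_block`.
    Raises a ``ValueError`` naming the trait on a singular/failed fit.
    """
    if form not in _FORM_FUNCS:
        raise ValueError(f"unknown functional form {form!r}")
    func, nparam = _FORM_FUNCS[form]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < nparam:
        raise ValueError(f"trait {trait or '?'}: need >= {nparam} points, got {len(x)}")
    try:
        popt, pcov = curve_fit(func, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise ValueError(f"trait {trait or '?'}: fit failed ({exc})") from exc
    if not np.all(np.isfinite(popt)):
        raise ValueError(f"trait {trait or '?'}: singular fit")
    return popt, pcov


def load_trait_table(path):
    """Read a delimited literature table ``trait,temperature,value,source``."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"trait", "temperature", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"trait table must have columns {sorted(required)}")
    return df


#: Default prior standard deviations.  Curve parameters get moderate spread;
#: the adult thermal limits are anchored at sd 1 C, the water-temperature
#: offset at sd 3 C, and the diapause thresholds are broad (inference targets).
_DEFAULT_SDS = {}
for _n in PARAM_NAMES:
    _DEFAULT_SDS[_n] = max(0.1, 0.1 * abs(_DEFAULTS[_n]))
_DEFAULT_SDS.update({
    "p4_Tlow": 1.0, "p4_Thigh": 1.0,       # literature thermal anchors for adults
    "delta_T": 3.0,                          # water-air offset
    "T_crt": 3.0, "CPP": 1.5,               # diapause thresholds: weakly informed
    "p_s": 0.1, "p_n": 0.05,
    "p1_max": 0.02, "p2_max": 0.02, "p3_max": 0.02, "p4_max": 0.02,
    "alpha_evap": 0.05,
    "E0_init": 50.0,
})


def default_prior() -> PriorSpec:
    """Diagonal default prior centred on :func:`default_parameters`."""
    mean = default_parameters().values
    sd = np.array([_DEFAULT_SDS[n] for n in PARAM_NAMES])
    return PriorSpec(mean, np.diag(sd**2))
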