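"""Daily carrying-capacity dynamics of a breeding site.

Capacity accumulates contributions from human population density and daily
precipitation, and decays by evaporation/absorption:

    B[t+1] = alpha_pdens * p_dens + alpha_dprec * precip[t] + alpha_evap * B[t]

The scaled carrying capacity

    K[t] = (1 - alpha_evap) / (1 - alpha_evap**t) * B[t]

is an exponentially-weighted *average* (mean retention time
-1/ln(alpha_evap) days) of recent daily inputs rather than their aggregate,
so K can never exceed the largest daily input sum seen in the history.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CapacityState", "update_B", "capacity"]


def _check_alpha_evap(alpha_evap: float):
    if not 0.0 < alpha_evap < 1.0:
        raise ValueError(f"alpha_evap must be in (0, 1), got {alpha_evap}")


def update_B(B_t: float, precip_t: float, p_dens: float,
             alpha_pdens: float, alpha_dprec: float, alpha_evap: float) -> float:
    """One-day update of the unnormalized capacity accumulator."""
    _check_alpha_evap(alpha_evap)
    return alpha_pdens * p_dens + alpha_dprec * precip_t + alpha_evap * B_t


def capacity(B_t: float, t: int, alpha_evap: float) -> float:
    """Scaled carrying capacity K_t from the accumulator B_t at day index t >= 1."""
    _check_alpha_evap(alpha_evap)
    if t < 1:
        raise ValueError("day index t must be >= 1")
    return (1.0 - alpha_evap) / (1.0 - alpha_evap ** t) * B_t


@dataclass
class CapacityState:
    """Running capacity state: accumulator B, day counter t, scaled capacity K.

    Starts from B = 0 before the first day; the first :meth:`step` brings it to
    t = 1 where the normalizer is exactly 1.
    """

    alpha_pdens: float
    alpha_dprec: float
    alpha_evap: float
    p_dens: float
    B: float = 0.0
    t: int = 0
    K: float = 0.0

    def __post_init__(self):
        _check_alpha_evap(self.alpha_evap)

    def step(self, precip_t: float) -> float:
        """Advance one day with today's precipitation; returns the new K."""
        self.B = update_B(self.B, precip_t, self.p_dens,
                          self.alpha_pdens, self.alpha_dprec, self.alpha_evap)
        self.t += 1
        self.K = capacity(self.B, self.t, self.alpha_evap)
        return self.K
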