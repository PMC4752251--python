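"""Season indicators and gradual diapause entry/exit rules.

Two mutually exclusive daily indicators delineate the seasons:

* favourable   (I_fav = 1):   T_a >= T_crt  and  photoperiod >= CPP
* unfavourable (I_unfav = 1): T_a <  T_crt  and  photoperiod <  CPP

Neither factor alone triggers a switch: on mixed days both indicators are 0,
normal eggs are laid and no diapausing eggs hatch.  During an unfavourable
season a growing fraction p_dp of eggs is "tagged" to become diapausing at the
end of embryonic development; once conditions turn favourable a fixed daily
fraction p_n of diapausing eggs re-enters the developmental cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = ["SeasonState", "season_indicators", "tagged_fraction"]


def season_indicators(T_a: float, photoperiod: float,
                      T_crt: float, CPP: float) -> tuple:
    """Daily (I_fav, I_unfav) from air temperature and photoperiod."""
    fav = int(T_a >= T_crt and photoperiod >= CPP)
    unfav = int(T_a < T_crt and photoperiod < CPP)
    return fav, unfav


def tagged_fraction(t: int, t_dp: int, p_s: float) -> float:
    """Fraction of eggs tagged for diapause on day ``t`` of a season begun on
    ``t_dp``: starts at p_s and grows by p_s per day, capped at 1."""
    if t < t_dp:
        raise ValueError("t must be >= season onset t_dp")
    if not 0.0 < p_s <= 1.0:
        raise ValueError("p_s must be in (0, 1]")
    return min(1.0, (1 + t - t_dp) * p_s)


@dataclass
class SeasonState:
    """Minimal season memory across days.

    A season begins on the first unfavourable day when none is active, and
    ends only on a favourable day.  On mixed days inside a season tagging
    pauses (I_unfav = 0 removes the tagged-egg split) but the season — and the
    ramp origin t_dp — persists.  With ``ramp_counts_unfav_only`` the p_dp ramp
    advances only on unfavourable days instead of with the calendar.
    """

    p_s: float
    ramp_counts_unfav_only: bool = False
    t_dp: Optional[int] = None
    _unfav_days: int = 0

    def update(self, t: int, I_fav: int, I_unfav: int) -> float:
        """Advance one day; returns today's tagged fraction p_dp."""
        if I_fav and I_unfav:
            raise ValueError("indicators are mutually exclusive")
        if I_fav:
            self.t_dp = None
            self._unfav_days = 0
            return 0.0
        if I_unfav:
            if self.t_dp is None:
                self.t_dp = t
                self._unfav_days = 0
            self._unfav_days += 1
            if self.ramp_counts_unfav_only:
                return min(1.0, self._unfav_days * self.p_s)
            return tagged_fraction(t, self.t_dp, self.p_s)
        return 0.0  # mixed day: no tagging today, season persists

    @property
    def active(self) -> bool:
        return self.t_dp is not None
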