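"""Bimonthly survey time grid.

The study year is divided into four two-month survey periods (May-Jun,
Jul-Aug, Sep-Oct, Nov-Dec); January-April is snowbound and unobserved, so
the step from a Nov-Dec period into the following May-Jun period spans the
whole snow season.  Period indices ``t`` are 1-based and run ``1..4*n_years``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Season(str, Enum):
    MAY_JUN = "MAY_JUN"
    JUL_AUG = "JUL_AUG"
    SEP_OCT = "SEP_OCT"
    NOV_DEC = "NOV_DEC"


SEASON_ORDER: tuple[Season, ...] = (
    Season.MAY_JUN,
    Season.JUL_AUG,
    Season.SEP_OCT,
    Season.NOV_DEC,
)


@dataclass(frozen=True)
class TimeIndex:
    """Grid of bimonthly periods starting in May-Jun of ``start_year``.

    ``t = 1`` is (start_year, MAY_JUN); consecutive ``t`` advance through the
    fixed season cycle, rolling to the next calendar year after NOV_DEC.
    """

    start_year: int
    n_years: int

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")

    def __len__(self) -> int:
        return 4 * self.n_years

    @property
    def T(self) -> int:
        return len(self)

    def year(self, t: int) -> int:
        self._check(t)
        return self.start_year + (t - 1) // 4

    def season(self, t: int) -> Season:
        self._check(t)
        return SEASON_ORDER[(t - 1) % 4]

    def period(self, t: int) -> tuple[int, Season]:
        return self.year(t), self.season(t)

    def t_of(self, year: int, season: Season | str) -> int:
        season = Season(season)
        t = 4 * (year - self.start_year) + SEASON_ORDER.index(season) + 1
        self._check(t)
        return t

    def is_winter_transition(self, t: int) -> bool:
        """True if period ``t`` is entered from Nov-Dec across the Jan-Apr gap.

        These are the May-Jun periods from the second year on: the transition
        into them spans four months, applies growth twice on the log scale and
        is the step at which winter mortality acts.
        """
        self._check(t)
        return t > 1 and (t - 1) % 4 == 0

    @property
    def winter_transitions(self) -> tuple[int, ...]:
        return tuple(range(5, self.T + 1, 4))

    @property
    def n_winters(self) -> int:
        return len(self.winter_transitions)

    def _check(self, t: int) -> None:
        if not 1 <= t <= self.T:
            raise IndexError(f"period index t={t} outside 1..{self.T}")
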