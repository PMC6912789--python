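"""Dyadic dominance indices from decisive agonistic interactions.

Two indices rank the animals of a pen from dominant (+1) to subordinate (-1):

* ``DI1 = (wins - defeats) / (wins + defeats)`` -- win/defeat counts only.
* ``DI2 = (wins * Pwon - defeats * Plost) / ((wins + defeats) * (n - 1))`` --
  additionally weights by the number of distinct pen mates beaten (``Pwon``)
  or lost to (``Plost``) and the group size ``n``.

Both indices are undefined (missing, *not* zero) for animals with no decisive
interaction; the distinction from a zero centrality matters downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .events import InteractionEvent, PenRoster, ValidationError

__all__ = ["FightTally", "tally_fights", "di1", "di2", "dominance_table"]


@dataclass(frozen=True)
class FightTally:
    """Per-animal win/defeat counts and distinct-opponent counts."""

    animal: str
    wins: int = 0
    defeats: int = 0
    p_won: int = 0
    p_lost: int = 0

    def __post_init__(self) -> None:
        if min(self.wins, self.defeats, self.p_won, self.p_lost) < 0:
            raise ValueError("tally counts must be non-negative")
        if self.p_won > self.wins or self.p_lost > self.defeats:
            raise ValueError("distinct-opponent counts cannot exceed fight counts")

    @property
    def total(self) -> int:
        return self.wins + self.defeats


def tally_fights(
    events: Iterable[InteractionEvent], roster: PenRoster
) -> dict[str, FightTally]:
    """Count wins, defeats and distinct opponents for every rostered animal.

    ``events`` must all be decisive and belong to the roster's pen; animals
    with no events get the all-zero tally.
    """
    wins: dict[str, int] = {a: 0 for a in roster.animals}
    defeats: dict[str, int] = {a: 0 for a in roster.animals}
    beaten: dict[str, set[str]] = {a: set() for a in roster.animals}
    lost_to: dict[str, set[str]] = {a: set() for a in roster.animals}
    for e in events:
        if not e.decisive:
            raise ValidationError("tally_fights expects decisive events only")
        if e.winner not in wins or e.loser not in wins:
            raise ValidationError(
                f"participant {e.winner!r}/{e.loser!r} not in roster "
                f"of pen {roster.pen_id!r}"
            )
        wins[e.winner] += 1
        defeats[e.loser] += 1
        beaten[e.winner].add(e.loser)
        lost_to[e.loser].add(e.winner)
    return {
        a: FightTally(a, wins[a], defeats[a], len(beaten[a]), len(lost_to[a]))
        for a in roster.animals
    }


def di1(tally: FightTally) -> float:
    """Bowen-Brooks dominance index; NaN for animals with no fights."""
    if tally.total == 0:
        return math.nan
    return (tally.wins - tally.defeats) / tally.total


def di2(tally: FightTally, n: int) -> float:
    """Opponent-weighted dominance index for a pen of ``n``; NaN if no fights."""
    if n < 2:
        raise ValueError(f"group size must be at least 2, got {n}")
    if tally.total == 0:
        return math.nan
    return (tally.wins * tally.p_won - tally.defeats * tally.p_lost) / (
        tally.total * (n - 1)
    )


def dominance_table(
    events: Iterable[InteractionEvent], roster: PenRoster
) -> pd.DataFrame:
    """Per-animal tally and indices for one pen, as a tidy frame.

    Columns: pen_id, animal, wins, defeats, p_won, p_lost, di1, di2.
    Missing indices appear as NaN.
    """
    tallies = tally_fights(events, roster)
    rows = [
        {
            "pen_id": roster.pen_id,
            "animal": a,
            "wins": t.wins,
            "defeats": t.defeats,
            "p_won": t.p_won,
            "p_lost": t.p_lost,
            "di1": di1(t),
            "di2": di2(t, roster.n),
        }
        for a, t in sorted(tallies.items())
    ]
    return pd.DataFrame(rows)
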