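"""Event/roster data model, observation-schedule clock, and delimited-text I/O.

An agonistic interaction is a fight or physical displacement between two pigs
with identifiable roles: every event has an initiator and a receiver, and a
*decisive* event additionally has a winner and a loser (one of the two
participants).  Time is stored as cumulative *observed* hours since mixing
start -- the pen is only videotaped during daytime blocks, and all downstream
analyses are indexed by observed hours, so the unobserved gaps are removed
from the clock.  Wall-clock positions are derived on demand.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "InteractionEvent",
    "PenRoster",
    "ObservationSchedule",
    "ValidationError",
    "SCHEDULE_PRESETS",
    "schedule_preset",
    "obs_hour_to_wall_clock",
    "read_events",
    "write_events",
    "read_rosters",
    "write_rosters",
    "filter_decisive",
]

EVENT_COLUMNS = ("pen_id", "t_obs", "initiator", "receiver", "winner", "loser", "decisive")
ROSTER_COLUMNS = ("pen_id", "animal_id", "profile")


class ValidationError(ValueError):
    """An input record violates the event/roster data model."""


@dataclass(frozen=True)
class InteractionEvent:
    """One agonistic interaction between two pen mates.

    Parameters
    ----------
    pen_id : str
        Pen the interaction took place in.
    t_obs : float
        Cumulative observed hours since mixing start (gaps removed).
    initiator, receiver : str
        The attacking and the attacked animal; must differ.
    winner, loser : str or None
        Outcome roles; both present iff the event is decisive, in which
        case ``{winner, loser} == {initiator, receiver}``.
    decisive : bool
        Whether clear submissive behavior identified a winner and loser.
    """

    pen_id: str
    t_obs: float
    initiator: str
    receiver: str
    winner: str | None
    loser: str | None
    decisive: bool

    def __post_init__(self) -> None:
        if self.initiator == self.receiver:
            raise ValidationError(
                f"self-interaction: initiator == receiver == {self.initiator!r}"
            )
        if self.t_obs < 0:
            raise ValidationError(f"negative observed time {self.t_obs}")
        if self.decisive:
            if self.winner is None or self.loser is None:
                raise ValidationError("decisive event must carry winner and loser")
            if {self.winner, self.loser} != {self.initiator, self.receiver}:
                raise ValidationError(
                    f"winner/loser {{{self.winner!r}, {self.loser!r}}} must equal "
                    f"the participants {{{self.initiator!r}, {self.receiver!r}}}"
                )
        else:
            if self.winner is not None or self.loser is not None:
                raise ValidationError("indecisive event cannot carry winner/loser")


@dataclass(frozen=True)
class PenRoster:
    """Full roster of one pen: every animal, including ones that never fight."""

    pen_id: str
    animals: tuple[str, ...]
    profile: str = "custom"

    def __post_init__(self) -> None:
        if len(set(self.animals)) != len(self.animals):
            raise ValidationError(f"duplicate animal ids in pen {self.pen_id!r}")
        if len(self.animals) < 2:
            raise ValidationError(f"pen {self.pen_id!r} needs at least 2 animals")

    @property
    def n(self) -> int:
        """Group size."""
        return len(self.animals)

    def __contains__(self, animal: str) -> bool:
        return animal in set(self.animals)


@dataclass(frozen=True)
class ObservationSchedule:
    """Ordered daytime video-observation blocks.

    ``blocks`` is a list of ``(day, start_hour, end_hour)`` in wall-clock
    hours; blocks must be ordered and non-overlapping.  ``total_hours`` is
    the cumulative observed time, i.e. the length of the observed-hours axis.
    """

    blocks: tuple[tuple[int, float, float], ...]

    def __post_init__(self) -> None:
        prev = None
        for day, start, end in self.blocks:
            if end <= start:
                raise ValidationError(f"empty/reversed block {(day, start, end)}")
            if prev is not None:
                pday, pend = prev
                if day < pday or (day == pday and start < pend):
                    raise ValidationError("observation blocks overlap or are unordered")
            prev = (day, end)

    @property
    def total_hours(self) -> float:
        return sum(end - start for _, start, end in self.blocks)


# Presets: mixing happens at 12:00 on day 1; piglets are observed for 2.5
# daytime days (28 h), fatteners and gilts for 1.5 days (17 h).
SCHEDULE_PRESETS: dict[str, ObservationSchedule] = {
    "piglet": ObservationSchedule(((1, 12.0, 18.0), (2, 7.0, 18.0), (3, 7.0, 18.0))),
    "fattener": ObservationSchedule(((1, 12.0, 18.0), (2, 7.0, 18.0))),
    "gilt": ObservationSchedule(((1, 12.0, 18.0), (2, 7.0, 18.0))),
}


def schedule_preset(profile: str) -> ObservationSchedule:
    """Return the observation schedule for an age-group profile.

    ``piglet`` totals 28 observed hours, ``fattener`` and ``gilt`` 17.
    """
    try:
        return SCHEDULE_PRESETS[profile]
    except KeyError:
        raise ValidationError(
            f"unknown profile {profile!r}; known: {sorted(SCHEDULE_PRESETS)}"
        ) from None


def obs_hour_to_wall_clock(
    schedule: ObservationSchedule, t_obs: float
) -> tuple[int, float]:
    """Map cumulative observed hours to a ``(day, clock_hour)`` position.

    The mapping skips unobserved gaps: observed hour 0 is the start of the
    first block, and each block's interior maps linearly.  A time landing
    exactly on a block boundary maps to the *end* of the earlier block.
    """
    if t_obs < 0 or t_obs > schedule.total_hours:
        raise ValidationError(
            f"t_obs {t_obs} outside [0, {schedule.total_hours}]"
        )
    elapsed = 0.0
    for day, start, end in schedule.blocks:
        length = end - start
        if t_obs <= elapsed + length:
            return day, start + (t_obs - elapsed)
        elapsed += length
    # numerically t_obs == total_hours
    day, _, end = schedule.blocks[-1]
    return day, end


def filter_decisive(events: Iterable[InteractionEvent]) -> list[InteractionEvent]:
    """Keep only events with a clear winner and loser, preserving order.

    Indecisive interactions carry no outcome and enter no index or network.
    """
    return [e for e in events if e.decisive]


# ---------------------------------------------------------------------------
# Delimited-text I/O.  Dialect: comma-separated, UTF-8, one header line,
# empty winner/loser cells iff decisive is false; decisive written as 1/0.
# ---------------------------------------------------------------------------

_TRUE = {"1", "true", "True", "TRUE"}
_FALSE = {"0", "false", "False", "FALSE"}


def _parse_decisive(cell: str, where: str) -> bool:
    if cell in _TRUE:
        return True
    if cell in _FALSE:
        return False
    raise ValidationError(f"{where}: cannot parse decisive flag {cell!r}")


def read_events(
    path: str | Path,
    roster: PenRoster | dict[str, PenRoster] | None = None,
    schedule: ObservationSchedule | None = None,
) -> list[InteractionEvent]:
    """Read an events CSV, validating every record.

    ``roster`` may be a single :class:`PenRoster`, a ``{pen_id: roster}``
    mapping, or ``None`` (no membership validation).  If ``schedule`` is
    given, event times must lie within the observed period.
    """
    rosters: dict[str, PenRoster] | None
    if roster is None:
        rosters = None
    elif isinstance(roster, PenRoster):
        rosters = {roster.pen_id: roster}
    else:
        rosters = roster

    events: list[InteractionEvent] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(h.strip() for h in header) != EVENT_COLUMNS:
            raise ValidationError(
                f"{path}: header {header!r} does not match {EVENT_COLUMNS}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            where = f"{path}:{lineno}"
            if len(row) != len(EVENT_COLUMNS):
                raise ValidationError(f"{where}: expected {len(EVENT_COLUMNS)} cells")
            pen_id, t_cell, init, recv, win, lose, dec_cell = (c.strip() for c in row)
            try:
                t_obs = float(t_cell)
            except ValueError:
                raise ValidationError(f"{where}: bad t_obs {t_cell!r}") from None
            decisive = _parse_decisive(dec_cell, where)
            try:
                ev = InteractionEvent(
                    pen_id=pen_id,
                    t_obs=t_obs,
                    initiator=init,
                    receiver=recv,
                    winner=win or None,
                    loser=lose or None,
                    decisive=decisive,
                )
            except ValidationError as exc:
                raise ValidationError(f"{where}: {exc}") from None
            if rosters is not None:
                pen = rosters.get(pen_id)
                if pen is None:
                    raise ValidationError(f"{where}: unknown pen {pen_id!r}")
                for a in (ev.initiator, ev.receiver):
                    if a not in pen:
                        raise ValidationError(
                            f"{where}: animal {a!r} not in roster of pen {pen_id!r}"
                        )
            if schedule is not None and ev.t_obs > schedule.total_hours:
                raise ValidationError(
                    f"{where}: t_obs {ev.t_obs} beyond the {schedule.total_hours} h "
                    "observation period"
                )
            events.append(ev)
    return events


def write_events(events: Sequence[InteractionEvent], path: str | Path) -> None:
    """Write events to CSV in the canonical column order."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        for e in events:
            writer.writerow(
                [
                    e.pen_id,
                    repr(e.t_obs),  # shortest exact round-trip form
                    e.initiator,
                    e.receiver,
                    e.winner or "",
                    e.loser or "",
                    int(e.decisive),
                ]
            )


def read_rosters(path: str | Path) -> dict[str, PenRoster]:
    """Read a roster CSV (pen_id, animal_id, profile) into per-pen rosters."""
    pens: dict[str, list[str]] = {}
    profiles: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(h.strip() for h in header) != ROSTER_COLUMNS:
            raise ValidationError(
                f"{path}: header {header!r} does not match {ROSTER_COLUMNS}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 3:
                raise ValidationError(f"{path}:{lineno}: expected 3 cells")
            pen_id, animal, profile = (c.strip() for c in row)
            pens.setdefault(pen_id, []).append(animal)
            prev = profiles.setdefault(pen_id, profile)
            if prev != profile:
                raise ValidationError(
                    f"{path}:{lineno}: conflicting profiles for pen {pen_id!r}"
                )
    return {
        pen_id: PenRoster(pen_id, tuple(animals), profiles[pen_id])
        for pen_id, animals in pens.items()
    }


def write_rosters(rosters: Iterable[PenRoster], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ROSTER_COLUMNS)
        for roster in rosters:
            for animal in roster.animals:
                writer.writerow([roster.pen_id, animal, roster.profile])
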