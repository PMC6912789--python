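"""Rising cumulative time windows, per-window parameter panels and Spearman series.

After mixing, hierarchies form quickly: most information about the final rank
order is contained in the first observed hours.  To trace this, every
parameter (the two dominance indices and the five centralities for both
network flavors) is recomputed on cumulative windows of 1, 2, ..., T observed
hours, and per window the Spearman rank correlation between each dominance
index and each centrality is taken.  Rank correlation is the right yardstick
because the question is whether two parameters order the animals the same
way, not whether their values agree.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dominance import dominance_table
from .events import InteractionEvent, ObservationSchedule, PenRoster, filter_decisive
from .networks import build_network, centrality_table, isolated_fraction

__all__ = [
    "PARAMETERS",
    "DEFAULT_PAIRS",
    "rising_windows",
    "compute_panel",
    "compute_panels",
    "spearman",
    "correlation_series",
    "descriptive_trajectories",
]

# Analysis parameters of a panel: dominance indices plus the five
# centralities per network flavor (standardized degrees).
PARAMETERS = (
    "di1",
    "di2",
    "ir_in_degree",
    "ir_out_degree",
    "ir_closeness_in",
    "ir_closeness_out",
    "ir_betweenness",
    "wl_in_degree",
    "wl_out_degree",
    "wl_closeness_in",
    "wl_closeness_out",
    "wl_betweenness",
)

# Default correlation pairs: each dominance index against each centrality,
# plus the two indices against each other.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (di, c) for di in ("di1", "di2") for c in PARAMETERS[2:]
) + (("di1", "di2"),)


def rising_windows(
    events: Sequence[InteractionEvent], schedule: ObservationSchedule
) -> dict[int, list[InteractionEvent]]:
    """Nested cumulative event subsets for windows of 1..total observed hours.

    Window ``k`` holds exactly the events with ``t_obs <= k`` (boundary events
    belong to the earlier window).
    """
    total = int(round(schedule.total_hours))
    return {k: [e for e in events if e.t_obs <= k] for k in range(1, total + 1)}


def compute_panel(
    events: Iterable[InteractionEvent],
    rosters: PenRoster | Sequence[PenRoster],
    window_hours: int | None = None,
) -> pd.DataFrame:
    """Per-animal parameter panel on one event subset.

    Indecisive events are dropped first; isolated animals get zero
    centralities and missing (NaN) dominance indices.  Returns one row per
    rostered animal with the :data:`PARAMETERS` columns plus identifiers.
    """
    if isinstance(rosters, PenRoster):
        rosters = [rosters]
    events = list(events)
    frames = []
    for roster in rosters:
        pen_events = filter_decisive(e for e in events if e.pen_id == roster.pen_id)
        dom = dominance_table(pen_events, roster).set_index("animal")
        block = {"pen_id": roster.pen_id, "di1": dom["di1"], "di2": dom["di2"]}
        for flavor in ("IR", "WL"):
            cent = centrality_table(build_network(pen_events, roster, flavor))
            key = flavor.lower()
            block[f"{key}_in_degree"] = cent["in_degree_std"]
            block[f"{key}_out_degree"] = cent["out_degree_std"]
            block[f"{key}_closeness_in"] = cent["closeness_in"]
            block[f"{key}_closeness_out"] = cent["closeness_out"]
            block[f"{key}_betweenness"] = cent["betweenness"]
        frames.append(pd.DataFrame(block))
    panel = pd.concat(frames).rename_axis("animal").reset_index()
    if window_hours is not None:
        panel.insert(0, "window_hours", window_hours)
    return panel[
        (["window_hours"] if window_hours is not None else [])
        + ["pen_id", "animal"]
        + list(PARAMETERS)
    ]


def compute_panels(
    events: Sequence[InteractionEvent],
    rosters: Sequence[PenRoster],
    schedule: ObservationSchedule,
) -> pd.DataFrame:
    """Panels for every rising window, stacked into one long frame."""
    windows = rising_windows(events, schedule)
    return pd.concat(
        [compute_panel(sub, rosters, window_hours=k) for k, sub in windows.items()],
        ignore_index=True,
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Pairs with a missing value are removed first.  The p-value uses the
    t approximation with ``len - 2`` degrees of freedom.  Returns
    ``(nan, nan)`` when fewer than 3 complete pairs remain or either
    variable is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_series(
    panels: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    per_pen: bool = False,
) -> pd.DataFrame:
    """Spearman rs and p per parameter pair per rising window.

    By default animals are pooled across pens within a window (one rs per
    window per pair); with ``per_pen=True`` each pen contributes its own
    series.  Animals missing either value of a pair (isolated animals'
    dominance indices) are excluded pairwise.  Windows with fewer than 3
    usable pairs, or with a constant variable, carry NaN rs/p and are
    flagged undefined.
    """
    group_cols = ["window_hours", "pen_id"] if per_pen else ["window_hours"]
    rows = []
    for keys, group in panels.groupby(group_cols, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for a, b in pairs:
            sub = group[[a, b]].dropna()
            rs, p = spearman(sub[a].to_numpy(), sub[b].to_numpy())
            rows.append(
                dict(zip(group_cols, keys))
                | {
                    "x": a,
                    "y": b,
                    "rs": rs,
                    "p_value": p,
                    "n_animals": len(sub),
                    "defined": not math.isnan(rs),
                    "significant": (not math.isnan(p)) and p < 0.05,
                }
            )
    return pd.DataFrame(rows)


def descriptive_trajectories(
    events: Sequence[InteractionEvent],
    rosters: Sequence[PenRoster],
    schedule: ObservationSchedule,
) -> pd.DataFrame:
    """Isolated-animal fraction and initiator-win proportion per rising window.

    The isolated fraction is averaged over pens (animals with no decisive
    interaction yet); the initiator-win proportion pools decisive events
    across pens.  Both trace how fast the hierarchy information accumulates.
    """
    rows = []
    for k, window in rising_windows(events, schedule).items():
        iso = []
        decisive = 0
        init_wins = 0
        for roster in rosters:
            pen_events = filter_decisive(
                e for e in window if e.pen_id == roster.pen_id
            )
            decisive += len(pen_events)
            init_wins += sum(e.winner == e.initiator for e in pen_events)
            iso.append(isolated_fraction(build_network(pen_events, roster, "WL")))
        rows.append(
            {
                "window_hours": k,
                "isolated_fraction": float(np.mean(iso)) if iso else math.nan,
                "initiator_win_prop": init_wins / decisive if decisive else math.nan,
                "n_decisive_events": decisive,
            }
        )
    return pd.DataFrame(rows)
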