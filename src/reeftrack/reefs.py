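"""Reef association metrics: nearest reef, visits, switching, height above bottom.

A fix is *visiting* its nearest reef when the 2-D (x, y) Euclidean
distance to that reef is at most the visit radius (20 m by default — a
conservative cut-off given a minimum reef spacing near 90 m, so a fix
can never plausibly belong to two reefs).  Maximal runs of consecutive
fixes visiting the same reef collapse to one visit event.  A *switch* is
a transition between successive visit events with different reef ids;
leaving and returning to the same reef is, by default, not a switch.
Average time per reef is days tracked divided by the number of reef
visits (switches + 1), and fish averaging under 2 days per reef are
flagged as "super-switchers".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BathymetryGrid

#: Default visit radius (m) around a reef.
VISIT_RADIUS_M = 20.0

#: Mean days-per-reef below which a fish is classed as a super-switcher.
SUPER_SWITCHER_DAYS = 2.0


def _reef_arrays(reefs: pd.DataFrame):
    """Reef ids/coords sorted by id so argmin tie-breaks lexicographically."""
    if len(reefs) == 0:
        raise ValueError("empty reef set")
    r = reefs.sort_values("station_id", kind="mergesort")
    return (
        r["station_id"].to_numpy(),
        r["x"].to_numpy(dtype=float),
        r["y"].to_numpy(dtype=float),
    )


def nearest_reef(x, y, reefs: pd.DataFrame):
    """Nearest reef to one point: ``(reef_id, distance_m)``.

    Distance is 2-D (x, y only).  Ties break to the lexicographically
    smallest reef id.
    """
    ids, rx, ry = _reef_arrays(reefs)
    d = np.hypot(rx - x, ry - y)
    i = int(np.argmin(d))  # first minimum == smallest id after sort
    return ids[i], float(d[i])


def nearest_reefs(track: pd.DataFrame, reefs: pd.DataFrame):
    """Vectorised nearest reef per fix: ``(ids, distances)`` arrays."""
    ids, rx, ry = _reef_arrays(reefs)
    dx = track["x"].to_numpy(dtype=float)[:, None] - rx[None, :]
    dy = track["y"].to_numpy(dtype=float)[:, None] - ry[None, :]
    d = np.hypot(dx, dy)
    i = np.argmin(d, axis=1)
    return ids[i], d[np.arange(len(i)), i]


def distance_to_reef_series(track: pd.DataFrame, reefs: pd.DataFrame) -> pd.DataFrame:
    """Per-fix distance to the nearest reef (for the 5-m-filtered track)."""
    ids, dist = nearest_reefs(track, reefs)
    out = pd.DataFrame(
        {
            "fish_id": track["fish_id"].to_numpy()
            if "fish_id" in track.columns
            else None,
            "t": track["t"].to_numpy(),
            "reef_id": ids,
            "distance_m": dist,
        }
    )
    return out


def detect_visits(
    track: pd.DataFrame,
    reefs: pd.DataFrame,
    visit_radius: float = VISIT_RADIUS_M,
) -> pd.DataFrame:
    """Collapse a time-sorted, error-filtered track into reef visit events.

    Returns a frame with ``fish_id, reef_id, t_start, t_end, n_fixes``,
    one row per maximal run of fixes visiting the same reef.  Off-reef
    fixes belong to no event.  Handles multi-fish tracks (grouped by
    ``fish_id``).
    """
    if "fish_id" not in track.columns:
        track = track.assign(fish_id="_")
    events = []
    for fish_id, grp in track.groupby("fish_id", sort=False):
        grp = grp.sort_values("t")
        ids, dist = nearest_reefs(grp, reefs)
        visiting = dist <= visit_radius
        t = grp["t"].to_numpy()
        run_reef = None
        run_start = run_end = None
        n = 0
        for j in range(len(grp)):
            if visiting[j] and ids[j] == run_reef:
                run_end = t[j]
                n += 1
                continue
            if run_reef is not None:
                events.append((fish_id, run_reef, run_start, run_end, n))
                run_reef = None
            if visiting[j]:
                run_reef, run_start, run_end, n = ids[j], t[j], t[j], 1
        if run_reef is not None:
            events.append((fish_id, run_reef, run_start, run_end, n))
    return pd.DataFrame(
        events, columns=["fish_id", "reef_id", "t_start", "t_end", "n_fixes"]
    )


@dataclass
class SwitchSummary:
    """Per-fish reef-switching summary."""

    fish_id: str
    n_reefs_visited: int
    n_switches: int
    days_tracked: float
    super_switcher: bool

    @property
    def avg_days_per_reef(self) -> float:
        # days tracked divided by number of reef visits (N switches + 1)
        return self.days_tracked / (self.n_switches + 1)


def summarize_switching(
    visits: pd.DataFrame,
    days_tracked: float,
    fish_id: str | None = None,
    count_same_reef_returns: bool = False,
) -> SwitchSummary:
    """Count reef switches from a time-sorted visit-event list.

    A switch is a transition between successive visit events with
    different reef ids.  With ``count_same_reef_returns=True`` every new
    visit event after the first counts instead (departure/return to the
    same reef increments the count).
    """
    if not days_tracked > 0:
        raise ValueError(f"days_tracked must be > 0, got {days_tracked}")
    visits = visits.sort_values("t_start")
    if fish_id is None:
        uniq = visits["fish_id"].unique()
        fish_id = str(uniq[0]) if len(uniq) == 1 else "?"
    reefs_seq = visits["reef_id"].to_numpy()
    if count_same_reef_returns:
        n_switches = max(len(reefs_seq) - 1, 0)
    else:
        n_switches = int(np.sum(reefs_seq[1:] != reefs_seq[:-1])) if len(reefs_seq) else 0
    summary = SwitchSummary(
        fish_id=fish_id,
        n_reefs_visited=int(pd.unique(reefs_seq).size),
        n_switches=n_switches,
        days_tracked=float(days_tracked),
        super_switcher=False,
    )
    summary.super_switcher = summary.avg_days_per_reef < SUPER_SWITCHER_DAYS
    return summary


def summarize_switching_all(
    visits: pd.DataFrame, days_tracked: dict | pd.Series, **kwargs
) -> pd.DataFrame:
    """Switch summaries for every fish with at least one visit."""
    rows = []
    for fish_id, grp in visits.groupby("fish_id"):
        s = summarize_switching(
            grp, float(days_tracked[fish_id]), fish_id=str(fish_id), **kwargs
        )
        rows.append(
            {
                "fish_id": s.fish_id,
                "n_reefs_visited": s.n_reefs_visited,
                "n_switches": s.n_switches,
                "days_tracked": s.days_tracked,
                "avg_days_per_reef": s.avg_days_per_reef,
                "super_switcher": s.super_switcher,
            }
        )
    return pd.DataFrame(rows)


def height_above_bottom(track: pd.DataFrame, bathymetry: BathymetryGrid) -> pd.Series:
    """Height above the seabed (m) per fix: seabed depth minus sensor depth.

    Negative values (sensor below the charted seabed) are retained —
    they flag either bathymetry error or position error, and callers may
    want to inspect them.  Fixes outside the grid or over NODATA cells
    yield NaN.
    """
    seabed = bathymetry.depth_at(
        track["x"].to_numpy(dtype=float), track["y"].to_numpy(dtype=float)
    )
    hab = seabed - track["depth"].to_numpy(dtype=float)
    return pd.Series(hab, index=track.index, name="height_above_bottom")
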