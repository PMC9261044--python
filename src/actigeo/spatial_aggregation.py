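"""Assign located minutes to dissemination areas and build person-day-DA totals.

The analysis unit downstream is the participant x date x DA row: total worn
minutes and minutes in each intensity class, with PA = light+moderate+vigorous
and MVPA = moderate+vigorous, plus covariate flags (home DA, weekend) and
city-wide daily weather.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point, Polygon

__all__ = [
    "DAIndex",
    "assign_da",
    "aggregate",
    "filter_min_dwell",
    "home_share",
    "AggregationResult",
]

_CLASS_COLS = ["sedentary", "light", "moderate", "vigorous"]


class DAIndex:
    """Spatial index over DA polygons with a deterministic boundary rule.

    Points on a shared boundary are assigned to the lexicographically smallest
    matching DA id; points outside every polygon get None.
    """

    def __init__(self, polygons: dict[str, Polygon]):
        for da_id, poly in polygons.items():
            if not poly.is_valid:
                raise ValueError(f"invalid geometry for DA {da_id}")
        # sort ids so the first hit in a stable scan is the smallest id
        self.ids = np.array(sorted(polygons), dtype=object)
        self.geoms = np.array([polygons[i] for i in self.ids], dtype=object)
        self._tree = STRtree(list(self.geoms))

    def assign(self, lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
        """Vectorised containment query; returns object array of DA ids / None."""
        pts = [Point(x, y) for x, y in zip(lons, lats)]
        # predicate applies as point.covered_by(tree polygon): boundary-inclusive
        hit_pt, hit_geom = self._tree.query(pts, predicate="covered_by")
        out = np.full(len(pts), None, dtype=object)
        if len(hit_pt):
            df = pd.DataFrame({"pt": hit_pt, "da": self.ids[hit_geom]})
            best = df.groupby("pt")["da"].min()
            out[best.index.to_numpy()] = best.to_numpy()
        return out


def assign_da(location: tuple[float, float] | None, polygons: dict[str, Polygon]) -> str | None:
    """Assign a single (lon, lat) location to a DA id, or None if outside all."""
    if location is None:
        return None
    idx = DAIndex(polygons)
    return idx.assign(np.array([location[0]]), np.array([location[1]]))[0]


@dataclass
class AggregationResult:
    """Person-day-DA table plus data-cleaning accounting."""

    table: pd.DataFrame
    n_dropped_missing_location: int
    n_dropped_outside_das: int

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_missing_location + self.n_dropped_outside_das


def aggregate(
    minute_records: pd.DataFrame,
    roster: pd.DataFrame,
    weather: pd.DataFrame,
    da_index: DAIndex,
) -> AggregationResult:
    """Aggregate fused minute records to person-day-DA rows.

    ``minute_records``: participant_id, minute_start, intensity, lon, lat
    (NaN location allowed — those records are dropped and counted).
    ``roster``: participant_id, home_da (+ demographics, carried through).
    ``weather``: date, precipitation_mm, temperature_c (city-wide by day).

    Rows carry minutes_total and the four class totals, pa/mvpa sums,
    is_home_da, is_weekend, and the day's weather.  Dropped-record counts are
    reported, mirroring explicit data-cleaning accounting.
    """
    rec = minute_records.copy()
    unknown = set(rec["participant_id"].unique()) - set(roster["participant_id"])
    if unknown:
        raise ValueError(f"participants absent from roster: {sorted(unknown)[:5]}")

    missing_loc = rec["lon"].isna() | rec["lat"].isna()
    n_missing = int(missing_loc.sum())
    rec = rec[~missing_loc].copy()

    if len(rec):
        rec["da_id"] = da_index.assign(rec["lon"].to_numpy(), rec["lat"].to_numpy())
    else:
        rec["da_id"] = pd.Series(dtype=object)
    outside = rec["da_id"].isna()
    n_outside = int(outside.sum())
    rec = rec[~outside].copy()

    rec["date"] = pd.to_datetime(rec["minute_start"]).dt.normalize()
    onehot = pd.get_dummies(rec["intensity"]).reindex(columns=_CLASS_COLS, fill_value=0)
    rec = pd.concat([rec[["participant_id", "date", "da_id"]], onehot.astype(int)], axis=1)

    g = rec.groupby(["participant_id", "date", "da_id"], sort=True, as_index=False)[_CLASS_COLS].sum()
    g = g.rename(columns={c: f"minutes_{c}" for c in _CLASS_COLS})
    g["minutes_total"] = sum(g[f"minutes_{c}"] for c in _CLASS_COLS)
    g["pa_minutes"] = g["minutes_light"] + g["minutes_moderate"] + g["minutes_vigorous"]
    g["mvpa_minutes"] = g["minutes_moderate"] + g["minutes_vigorous"]

    g = g.merge(roster, on="participant_id", how="left")
    g["is_home_da"] = (g["da_id"] == g["home_da"]).astype(int)
    g["is_weekend"] = (g["date"].dt.dayofweek >= 5).astype(int)

    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"]).dt.normalize()
    g = g.merge(w[["date", "precipitation_mm", "temperature_c"]], on="date", how="left")
    return AggregationResult(g, n_missing, n_outside)


def filter_min_dwell(rows: pd.DataFrame, threshold_min: int = 5) -> pd.DataFrame:
    """Keep person-day-DA rows where at least ``threshold_min`` minutes were spent."""
    return rows[rows["minutes_total"] >= threshold_min].reset_index(drop=True)


def home_share(rows: pd.DataFrame, outcome: str = "pa") -> float:
    """Share of activity minutes spent in the participant's home DA.

    ``outcome`` is "pa" or "mvpa".  Raises on an all-zero denominator.
    """
    col = {"pa": "pa_minutes", "mvpa": "mvpa_minutes"}[outcome]
    total = rows[col].sum()
    if total == 0:
        raise ZeroDivisionError("no activity minutes: home share undefined")
    return float(rows.loc[rows["is_home_da"] == 1, col].sum() / total)
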