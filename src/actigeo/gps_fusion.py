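"""Reduce 1 Hz GPS fixes to one location per minute and join to intensity minutes.

The minute location is the component-wise median of that minute's fixes
(mean of the two middle order statistics at even cardinality), mirroring the
standard epoch-median reduction used when fusing GPS with accelerometry.
Minutes with a worn intensity class but no fix are kept with an absent
location so that downstream aggregation can account for dropped records
explicitly rather than silently discarding them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["epoch_median_location", "minute_median_locations", "fuse"]


def epoch_median_location(fixes) -> tuple[float, float] | None:
    """Component-wise median (lon, lat) of fixes within one clock minute.

    ``fixes`` is a sequence of (lon, lat) pairs; empty input returns None.
    """
    arr = np.asarray(list(fixes), dtype=float)
    if arr.size == 0:
        return None
    lon = float(np.median(arr[:, 0]))
    lat = float(np.median(arr[:, 1]))
    return lon, lat


def minute_median_locations(fixes: pd.DataFrame) -> pd.DataFrame:
    """Median location per (participant_id, minute_start) from 1 Hz fixes.

    ``fixes`` needs columns participant_id, timestamp, lon, lat.  Timestamps
    are floored to the clock minute; medians are taken per component.
    """
    required = {"participant_id", "timestamp", "lon", "lat"}
    if missing := required - set(fixes.columns):
        raise ValueError(f"fixes missing columns: {sorted(missing)}")
    lat = fixes["lat"].to_numpy(dtype=float)
    lon = fixes["lon"].to_numpy(dtype=float)
    if ((lat < -90) | (lat > 90)).any() or ((lon < -180) | (lon > 180)).any():
        raise ValueError("coordinates outside WGS84 bounds")
    g = fixes.assign(minute_start=pd.to_datetime(fixes["timestamp"]).dt.floor("min"))
    out = (
        g.groupby(["participant_id", "minute_start"], sort=True)[["lon", "lat"]]
        .median()
        .reset_index()
    )
    return out


def fuse(minute_classes: pd.DataFrame, minute_locations: pd.DataFrame) -> pd.DataFrame:
    """Join per-minute intensity classes with per-minute median locations.

    Both inputs are keyed by (participant_id, minute_start).  ``minute_classes``
    needs an ``intensity`` column; non-wear minutes are dropped.  Minutes with
    a worn class but no location are emitted with NaN lon/lat (they are later
    dropped — and counted — at aggregation); located minutes without a worn
    class are dropped.  Duplicate keys in either input are a data error.

    Returns minute records sorted by key: participant_id, minute_start,
    intensity, lon, lat.
    """
    key = ["participant_id", "minute_start"]
    for name, df in (("classes", minute_classes), ("locations", minute_locations)):
        if df.duplicated(subset=key).any():
            raise ValueError(f"duplicate (participant, minute) keys in {name}")
    worn = minute_classes[minute_classes["intensity"] != "nonwear"]
    out = worn.merge(minute_locations[key + ["lon", "lat"]], on=key, how="left")
    out = out.sort_values(key, kind="mergesort").reset_index(drop=True)
    return out[key + ["intensity", "lon", "lat"]]
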