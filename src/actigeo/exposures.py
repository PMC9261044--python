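"""DA-level exposure construction: active-living composite, proximity quintiles,
gentrification classes, and the join onto the analysis table.

Three families of measures:

* **Active-living composite** (Can-ALE style): counts of intersections,
  dwellings, points of interest and transit stops within a circular 1-km
  buffer of each DA centroid, z-scored across DAs, summed into a composite,
  and cut into quintiles 1 (very low) to 5 (very high).
* **Proximity quintiles**: block-level 0-1 proximity scores for ten amenity
  types are summarised as the median over each DA's blocks, then cut into
  quintiles pooled across all cities.
* **Gentrification** (Ding-style tract rule): a tract is eligible when its
  baseline median household income is strictly below the metro median;
  an eligible tract is *gentrified* when (a) median gross rent OR median home
  value grew more than citywide AND (b) the college-educated share grew more
  than citywide; otherwise it is *low SES, not gentrified*.  Non-eligible
  tracts are *high SES*.  Tract classes broadcast to member DAs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "PROXIMITY_AMENITIES",
    "ALE_LAYERS",
    "GENTRIFICATION_CLASSES",
    "quintiles",
    "compute_can_ale",
    "summarize_proximity",
    "classify_gentrification",
    "attach_exposures",
    "exposure_correlations",
]

#: the four point layers of the active-living composite
ALE_LAYERS = ("intersections", "dwellings", "points_of_interest", "transit_stops")

#: amenity classes of the proximity database
PROXIMITY_AMENITIES = (
    "employment",
    "pharmacy",
    "childcare",
    "health",
    "grocery",
    "primary_education",
    "secondary_education",
    "library",
    "transit",
    "parks",
)

GENTRIFICATION_CLASSES = ("high_ses", "low_ses_not_gentrified", "gentrified")


def quintiles(values) -> np.ndarray:
    """Quintile labels 1..5 of a value vector.

    Ties get average ranks; cut points are the empirical 20/40/60/80
    percentiles of the ranks, with left-closed intervals (a value equal to a
    cut point falls in the upper bin).  With n distinct values divisible by 5
    this yields exactly n/5 per quintile.
    """
    v = np.asarray(values, dtype=float)
    r = rankdata(v, method="average")
    cuts = np.quantile(r, [0.2, 0.4, 0.6, 0.8])
    return (1 + (r[:, None] >= cuts[None, :]).sum(axis=1)).astype(int)


def compute_can_ale(city, buffer_m: float = 1000.0) -> pd.DataFrame:
    """Active-living composite quintile per DA.

    ``city`` is a :class:`~actigeo.synthetic_city.CityLayout` (or anything
    exposing ``da_ids``, ``da_centroids()`` planar metres, and
    ``amenity_layers`` with planar point arrays).  For each DA centroid the
    four layer counts within ``buffer_m`` are z-scored across DAs and summed;
    a zero-variance layer contributes 0 with a warning.

    Returns columns: da_id, the four counts, can_ale_composite, can_ale_q.
    """
    for layer in ALE_LAYERS:
        if layer not in city.amenity_layers:
            raise ValueError(f"missing amenity layer {layer!r}")
    cent = city.da_centroids()  # (n, 2) planar
    out = pd.DataFrame({"da_id": list(city.da_ids)})
    composite = np.zeros(len(cent))
    for layer in ALE_LAYERS:
        pts = np.asarray(city.amenity_layers[layer], dtype=float).reshape(-1, 2)
        if len(pts):
            d2 = ((cent[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            counts = (d2 <= buffer_m**2).sum(axis=1)
        else:
            counts = np.zeros(len(cent), dtype=int)
        out[f"n_{layer}"] = counts
        sd = counts.std()
        if sd == 0:
            warnings.warn(f"zero variance in layer {layer!r}; z-score set to 0", stacklevel=2)
            z = np.zeros(len(cent))
        else:
            z = (counts - counts.mean()) / sd
        composite += z
    out["can_ale_composite"] = composite
    out["can_ale_q"] = quintiles(composite)
    return out


def summarize_proximity(blocks: pd.DataFrame) -> pd.DataFrame:
    """Per-DA medians of block proximity scores, then pooled quintiles.

    ``blocks`` needs ``block_id``, ``da_id`` and one column per amenity in
    :data:`PROXIMITY_AMENITIES`, each on [0, 1].  Returns one row per DA with
    ``<amenity>_q`` quintile columns (pooled across all DAs, i.e. across
    cities when several are concatenated).
    """
    cols = [c for c in PROXIMITY_AMENITIES if c in blocks.columns]
    if not cols:
        raise ValueError("no proximity amenity columns found")
    vals = blocks[cols].to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("proximity scores must lie in [0, 1]")
    med = blocks.groupby("da_id", sort=True)[cols].median().reset_index()
    out = med[["da_id"]].copy()
    for c in cols:
        out[f"{c}_q"] = quintiles(med[c].to_numpy())
    return out


def classify_gentrification(
    panel: pd.DataFrame,
    metro: dict | pd.Series,
    mode: str = "relative",
) -> pd.Series:
    """Three-class tract gentrification labels from a two-wave census panel.

    ``panel`` needs per-tract columns: tract_id, median_income_t0,
    median_rent_t0/t1, median_home_value_t0/t1, college_share_t0/t1.
    ``metro`` provides the same aggregates for the metropolitan area.
    ``mode`` is "relative" (growth compared as relative change, default) or
    "absolute" (compared as absolute change).

    Eligibility: baseline income strictly below the metro median.  Gentrified:
    eligible AND (rent growth OR home-value growth exceeds citywide) AND
    (college-share growth exceeds citywide).  Tracts with missing wave values
    are labelled ``unclassifiable``.
    """
    if mode not in {"relative", "absolute"}:
        raise ValueError("mode must be 'relative' or 'absolute'")
    m = pd.Series(metro)

    def growth(t0, t1):
        if mode == "relative":
            return (t1 - t0) / t0
        return t1 - t0

    needed = [
        "median_income_t0",
        "median_rent_t0",
        "median_rent_t1",
        "median_home_value_t0",
        "median_home_value_t1",
        "college_share_t0",
        "college_share_t1",
    ]
    city_rent = growth(m["median_rent_t0"], m["median_rent_t1"])
    city_value = growth(m["median_home_value_t0"], m["median_home_value_t1"])
    city_college = growth(m["college_share_t0"], m["college_share_t1"])

    labels = []
    for _, row in panel.iterrows():
        if row[needed].isna().any():
            labels.append("unclassifiable")
            continue
        if row["median_income_t0"] >= m["median_income_t0"]:
            labels.append("high_ses")
            continue
        cond_a = (
            growth(row["median_rent_t0"], row["median_rent_t1"]) > city_rent
            or growth(row["median_home_value_t0"], row["median_home_value_t1"]) > city_value
        )
        cond_b = growth(row["college_share_t0"], row["college_share_t1"]) > city_college
        labels.append("gentrified" if (cond_a and cond_b) else "low_ses_not_gentrified")
    return pd.Series(labels, index=panel["tract_id"].to_numpy(), name="gentrification_class")


def attach_exposures(
    rows: pd.DataFrame,
    exposure: pd.DataFrame,
    tract_membership: dict[str, str] | None = None,
    tract_measures: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Left-join DA exposures (and tract measures broadcast to DAs) onto rows.

    ``rows`` is the person-day-DA table keyed by ``da_id``; ``exposure`` is
    keyed by ``da_id``.  ``tract_measures`` (keyed by ``tract_id``, e.g.
    urban compactness and gentrification class) is broadcast through
    ``tract_membership`` (DA id -> tract id).  Row count is preserved; a DA
    in ``rows`` missing from the exposure table is an error naming the ids.
    """
    missing = set(rows["da_id"].unique()) - set(exposure["da_id"])
    if missing:
        raise ValueError(f"DAs without exposures: {sorted(missing)[:10]}")
    exp = exposure.copy()
    if tract_measures is not None:
        if tract_membership is None:
            raise ValueError("tract_membership required to broadcast tract measures")
        exp["tract_id"] = exp["da_id"].map(tract_membership)
        if exp["tract_id"].isna().any():
            bad = exp.loc[exp["tract_id"].isna(), "da_id"].tolist()
            raise ValueError(f"DAs without tract membership: {bad[:10]}")
        exp = exp.merge(tract_measures, on="tract_id", how="left")
    out = rows.merge(exp, on="da_id", how="left")
    assert len(out) == len(rows)
    return out


def exposure_correlations(exposure: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Correlation matrix over the numeric exposure columns (report convenience)."""
    num = exposure.select_dtypes(include=[np.number]).drop(columns=["tract_id"], errors="ignore")
    return num.corr(method=method)
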