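"""Synthetic city, cohort, sensor streams, census tables and weather.

Everything downstream of the sensors is tested against this generator's
planted ground truth:

* a rectangular grid of dissemination areas (DAs) nested in census tracts,
  with homogeneous-Poisson amenity point layers, in a local planar metre
  frame mapped to WGS84 by a fixed affine;
* a cohort with configurable categorical demographics and home DAs;
* wear days built from dwell episodes (home, then exposure-weighted
  destination DAs).  Within each visited DA the day's physical-activity
  minutes are drawn from a negative-binomial law whose log-mean is a linear
  function of planted exposure coefficients plus per-person random effects —
  exactly the model the analysis stage fits;
* per-minute streams at two fidelity levels: ``"counts"`` emits counts/min
  directly inside the intended cut-point band, ``"signal"`` synthesizes a
  50 Hz tri-axial stream whose derived counts land in that band;
* two-wave census tract panels constructed so the gentrification classifier
  reproduces configured class proportions, and daily weather series.

Random-number discipline: all draws derive from ``numpy`` ``SeedSequence``
spawns of a single seed, so identical configuration + seed gives identical
output; the day *plan* (who went where, and how many minutes of each class)
uses a stream separate from the *materialization* (which minute, which GPS
fix), so the count-level and table-level paths share identical row truth.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .exposures import GENTRIFICATION_CLASSES, PROXIMITY_AMENITIES
from .geometry import PlanarCRS, feature_collection, rect_polygon
from .sensor_processing import CountCascadeParams, CutPoints, RawAccelSignal, compute_counts

__all__ = [
    "CityLayout",
    "SyntheticTruth",
    "MobilityConfig",
    "DEFAULT_DEMOGRAPHICS",
    "generate_city",
    "generate_cohort",
    "generate_exposure_table",
    "generate_census_panel",
    "generate_proximity_blocks",
    "generate_weather",
    "plan_day",
    "materialize_counts_day",
    "materialize_signal_day",
    "simulate_cohort_table",
    "class_amplitudes",
]


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# city layout
# ---------------------------------------------------------------------------


@dataclass
class CityLayout:
    """Rectangular DA grid nested in tracts, with amenity point layers.

    DAs are ``cell_size_m`` squares laid out row-major on an ``nx`` x ``ny``
    grid (the last row may be partial); they tile the city extent without
    overlap.  ``tract_membership`` maps every DA id to exactly one tract id.
    Amenity layers are (n, 2) planar point arrays.
    """

    nx: int
    ny: int
    cell_size_m: float
    da_ids: list[str]
    tract_membership: dict[str, str]
    amenity_layers: dict[str, np.ndarray]
    crs: PlanarCRS = field(default_factory=PlanarCRS)
    city_id: str = "synthcity"

    @property
    def n_da(self) -> int:
        return len(self.da_ids)

    def da_bounds(self, da_id: str) -> tuple[float, float, float, float]:
        i = self.da_ids.index(da_id) if not da_id.startswith("DA") else int(da_id[2:])
        r, c = divmod(i, self.nx)
        s = self.cell_size_m
        return (c * s, r * s, (c + 1) * s, (r + 1) * s)

    def da_polygon(self, da_id: str, wgs84: bool = False) -> Polygon:
        x0, y0, x1, y1 = self.da_bounds(da_id)
        poly = rect_polygon(x0, y0, x1, y1)
        return self.crs.polygon_to_wgs84(poly) if wgs84 else poly

    def da_polygons(self, wgs84: bool = False) -> dict[str, Polygon]:
        return {d: self.da_polygon(d, wgs84=wgs84) for d in self.da_ids}

    def da_centroids(self) -> np.ndarray:
        idx = np.arange(self.n_da)
        r, c = np.divmod(idx, self.nx)
        s = self.cell_size_m
        return np.column_stack([(c + 0.5) * s, (r + 0.5) * s])

    @property
    def extent_area_km2(self) -> float:
        return self.n_da * (self.cell_size_m / 1000.0) ** 2

    def to_geojson(self, metadata: dict | None = None) -> dict:
        feats = []
        for d in self.da_ids:
            poly = self.da_polygon(d, wgs84=True)
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"da_id": d, "tract_id": self.tract_membership[d]},
                    "geometry": {"type": "Polygon", "coordinates": [list(map(list, poly.exterior.coords))]},
                }
            )
        return feature_collection(feats, metadata)


#: default amenity intensities, points per km^2
DEFAULT_AMENITY_DENSITY = {
    "intersections": 60.0,
    "dwellings": 400.0,
    "points_of_interest": 30.0,
    "transit_stops": 20.0,
    **{a: 5.0 for a in PROXIMITY_AMENITIES},
}


def generate_city(
    n_da: int,
    das_per_tract: int,
    amenity_density: dict[str, float] | None = None,
    seed: int = 0,
    cell_size_m: float = 500.0,
    crs: PlanarCRS | None = None,
    city_id: str = "synthcity",
) -> CityLayout:
    """Grid city with homogeneous-Poisson amenity layers.

    DA cells are squares; tracts are consecutive runs of ``das_per_tract``
    DAs.  Layer point counts are Poisson(density x extent area) placed
    uniformly over the extent.
    """
    if n_da < 4 or das_per_tract < 1 or cell_size_m <= 0:
        raise ConfigurationError("need n_da >= 4, das_per_tract >= 1, positive cell size")
    density = dict(DEFAULT_AMENITY_DENSITY)
    if amenity_density is not None:
        density.update(amenity_density)
    if any(v < 0 for v in density.values()):
        raise ConfigurationError("amenity densities must be non-negative")

    nx = int(np.ceil(np.sqrt(n_da)))
    ny = int(np.ceil(n_da / nx))
    da_ids = [f"DA{i:04d}" for i in range(n_da)]
    membership = {d: f"CT{i // das_per_tract:03d}" for i, d in enumerate(da_ids)}

    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    # sample points uniformly over the union of cells (row-major, last row partial)
    area_km2 = n_da * (cell_size_m / 1000.0) ** 2
    layers: dict[str, np.ndarray] = {}
    for name in sorted(density):
        lam = density[name] * area_km2
        k = int(rng.poisson(lam)) if lam > 0 else 0
        if k == 0:
            layers[name] = np.empty((0, 2))
            continue
        cell = rng.integers(0, n_da, size=k)
        r, c = np.divmod(cell, nx)
        u = rng.random((k, 2))
        layers[name] = np.column_stack(
            [(c + u[:, 0]) * cell_size_m, (r + u[:, 1]) * cell_size_m]
        )
    return CityLayout(nx, ny, cell_size_m, da_ids, membership, layers, crs or PlanarCRS(), city_id)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "age_group": {"18-24": 0.07, "25-44": 0.45, "45-64": 0.33, "65+": 0.15},
    "gender_group": {"woman": 0.60, "man": 0.38, "nonbinary": 0.02},
    "income_group": {"<50k": 0.25, "50-100k": 0.30, "100k+": 0.45},
    "race_group": {"white": 0.87, "minority_indigenous": 0.13},
}


def generate_cohort(
    n_participants: int,
    city: CityLayout,
    demographics: dict[str, dict[str, float]] | None = None,
    home_da_weights: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Roster with home DA and categorical demographics.

    Each demographic is an independent categorical draw; home DAs are uniform
    over the city unless ``home_da_weights`` is given.  Probabilities must sum
    to 1 within 1e-6.
    """
    demo = demographics or DEFAULT_DEMOGRAPHICS
    for name, dist in demo.items():
        if abs(sum(dist.values()) - 1.0) > 1e-6:
            raise ConfigurationError(f"{name} probabilities sum to {sum(dist.values())}, not 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 22]))
    out = {"participant_id": [f"P{i:04d}" for i in range(n_participants)]}
    if home_da_weights is None:
        homes = rng.choice(city.da_ids, size=n_participants)
    else:
        ids = list(home_da_weights)
        p = np.array([home_da_weights[d] for d in ids], dtype=float)
        if abs(p.sum() - 1.0) > 1e-6:
            raise ConfigurationError("home DA weights must sum to 1")
        homes = rng.choice(ids, size=n_participants, p=p)
    out["home_da"] = homes
    for name, dist in demo.items():
        cats = list(dist)
        p = np.array([dist[c] for c in cats], dtype=float)
        out[name] = rng.choice(cats, size=n_participants, p=p / p.sum())
    df = pd.DataFrame(out)
    df["device_error"] = False
    return df


# ---------------------------------------------------------------------------
# planted truth and exposures
# ---------------------------------------------------------------------------


def _default_beta() -> dict[str, float]:
    return {
        "intercept": float(np.log(3.0)),
        "can_ale_q": float(np.log(1.3)),
        "parks_q": float(np.log(1.1)),
        "urban_compactness": float(np.log(0.6)),
        "is_home_da": float(np.log(30.0)),
        "is_weekend": float(np.log(0.95)),
        "precipitation_mm": float(np.log(0.998)),
        "temperature_c": float(np.log(0.99)),
    }


@dataclass
class SyntheticTruth:
    """Planted parameters of the activity-generating process.

    ``beta`` maps covariate names to log-rate coefficients (``exp(beta)`` are
    the planted incidence rate ratios).  Quintile covariates enter centred at
    3 so the intercept is the log of expected activity minutes in a median DA
    per visit.  If ``home_dwell_share`` is set, the home-DA mean is rescaled
    each person-day so the expected share of activity minutes in the home DA
    equals it (and ``beta['is_home_da']`` is ignored); when None, the planted
    home coefficient governs.
    """

    beta: dict[str, float] = field(default_factory=_default_beta)
    re_sd_intercept: float = 0.35
    re_sd_slope: float = 0.03
    re_corr: float = 0.2
    dispersion: float = 4.0
    home_dwell_share: float | None = None
    pa_split: tuple[float, float, float] = (0.70, 0.25, 0.05)  # light/moderate/vigorous

    def __post_init__(self) -> None:
        if self.dispersion <= 0 or self.re_sd_intercept < 0 or self.re_sd_slope < 0:
            raise ConfigurationError("dispersion must be > 0, random-effect sds >= 0")
        if not -1 <= self.re_corr <= 1:
            raise ConfigurationError("re_corr must lie in [-1, 1]")
        if self.home_dwell_share is not None and not 0 < self.home_dwell_share <= 1:
            raise ConfigurationError("home_dwell_share must lie in (0, 1]")

    @property
    def re_cov(self) -> np.ndarray:
        c = self.re_corr * self.re_sd_intercept * self.re_sd_slope
        return np.array([[self.re_sd_intercept**2, c], [c, self.re_sd_slope**2]])


def generate_exposure_table(
    city: CityLayout, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant DA- and tract-level exposures directly (the external-database analogue).

    Returns ``(exposure_da, tract_measures)``: per-DA quintiles (active-living
    composite and the ten proximity amenities, uniform over 1..5) and per-tract
    urban compactness (standard normal score) plus a gentrification class
    drawn with probabilities (0.40 high SES, 0.35 low SES, 0.25 gentrified).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 33]))
    exposure = pd.DataFrame({"da_id": city.da_ids})
    exposure["can_ale_q"] = rng.integers(1, 6, size=city.n_da)
    for a in PROXIMITY_AMENITIES:
        exposure[f"{a}_q"] = rng.integers(1, 6, size=city.n_da)
    tracts = sorted(set(city.tract_membership.values()))
    tract_measures = pd.DataFrame(
        {
            "tract_id": tracts,
            "urban_compactness": rng.normal(0.0, 1.0, size=len(tracts)),
            "gentrification_class": rng.choice(
                GENTRIFICATION_CLASSES, size=len(tracts), p=[0.40, 0.35, 0.25]
            ),
        }
    )
    return exposure, tract_measures


def _da_covariate_frame(city: CityLayout, exposure_da: pd.DataFrame, tract_measures: pd.DataFrame) -> pd.DataFrame:
    df = exposure_da.copy()
    df["tract_id"] = df["da_id"].map(city.tract_membership)
    df = df.merge(tract_measures, on="tract_id", how="left")
    return df.set_index("da_id")


# ---------------------------------------------------------------------------
# day planning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MobilityConfig:
    """Dwell-episode mobility and device configuration for one wear day.

    The day is home -> destination(s) -> home.  ``travel_speed_m_s=None``
    snaps transitions to minute boundaries (every minute lies wholly in one
    DA); a float enables constant-speed GPS travel segments between DA
    centroids for realism-oriented runs.
    """

    wear_start_hour: int = 9
    wear_minutes: int = 480
    n_destinations: int = 2
    dest_dwell_min: int = 45
    destination_weight_temp: float = 0.15  # softmax weight on active-living quintile
    travel_speed_m_s: float | None = None
    gps_hz: int = 1
    gps_noise_m: float = 3.0
    nonwear_gap_min: int = 0  # planted device-off gap prepended to the day
    gps_dropout_minutes: int = 0  # planted minutes with no GPS fix


@dataclass
class DayPlan:
    """Ground truth for one participant wear day."""

    participant_id: str
    date: pd.Timestamp
    day_index: int  # 1-based observation day
    episodes: list[tuple[str, int]]  # (da_id, minutes), in temporal order
    da_class_minutes: dict[str, dict[str, int]]  # da -> class -> minutes
    mu: dict[str, float]  # planted NB mean per visited DA
    n_truncated: int
    nonwear_gap_min: int

    def rows(self) -> pd.DataFrame:
        recs = []
        for da, cm in self.da_class_minutes.items():
            total = sum(cm.values())
            recs.append(
                {
                    "participant_id": self.participant_id,
                    "date": self.date,
                    "da_id": da,
                    "minutes_sedentary": cm["sedentary"],
                    "minutes_light": cm["light"],
                    "minutes_moderate": cm["moderate"],
                    "minutes_vigorous": cm["vigorous"],
                    "minutes_total": total,
                    "pa_minutes": cm["light"] + cm["moderate"] + cm["vigorous"],
                    "mvpa_minutes": cm["moderate"] + cm["vigorous"],
                }
            )
        return pd.DataFrame(recs)


def participant_random_effects(truth: SyntheticTruth, n: int, seed: int) -> np.ndarray:
    """(n, 2) per-person (intercept, slope) effects, drawn once per cohort."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 44]))
    L = np.linalg.cholesky(truth.re_cov + 1e-12 * np.eye(2))
    return rng.standard_normal((n, 2)) @ L.T


def plan_day(
    participant: pd.Series,
    date: pd.Timestamp,
    day_index: int,
    n_days: int,
    city: CityLayout,
    truth: SyntheticTruth,
    da_cov: pd.DataFrame,
    weather_row: pd.Series,
    re_effects: np.ndarray,
    config: MobilityConfig,
    rng: np.random.Generator,
) -> DayPlan:
    """Draw one wear day's visited DAs, dwell minutes and intensity classes.

    Activity: for each visited DA d with T_d worn minutes, PA minutes are
    ``min(T_d, NB(mu_d, theta))`` with
    ``log mu_d = beta.x_d + b0 + b1 * centred day index`` (quintiles centred
    at 3), then split light/moderate/vigorous multinomially; the rest of T_d
    is sedentary.  Capping at T_d is recorded in ``n_truncated``.
    """
    home = participant["home_da"]
    if home not in city.tract_membership:
        raise ConfigurationError(f"home DA {home} not in city")
    date = pd.Timestamp(date)
    day_c = day_index - (n_days + 1) / 2.0

    # destinations, exposure-weighted; a planted home share of 1 means the
    # whole wear day is spent at home
    others = [d for d in city.da_ids if d != home]
    k = min(config.n_destinations, len(others))
    if truth.home_dwell_share is not None and truth.home_dwell_share >= 1.0:
        k = 0
    w = np.exp(config.destination_weight_temp * da_cov.loc[others, "can_ale_q"].to_numpy(float))
    dests = list(rng.choice(others, size=k, replace=False, p=w / w.sum())) if k else []

    dest_minutes = config.dest_dwell_min
    home_minutes = config.wear_minutes - dest_minutes * len(dests)
    if home_minutes < 2:
        raise ConfigurationError("wear day too short for the configured destinations")
    home_am = home_minutes // 2
    episodes = [(home, home_am)]
    episodes += [(d, dest_minutes) for d in dests]
    episodes.append((home, home_minutes - home_am))

    visited: dict[str, int] = {}
    for d, m in episodes:
        visited[d] = visited.get(d, 0) + m

    is_weekend = 1.0 if date.dayofweek >= 5 else 0.0
    b0, b1 = re_effects
    base = truth.beta.get("intercept", 0.0) + b0 + b1 * day_c
    base += truth.beta.get("is_weekend", 0.0) * is_weekend
    base += truth.beta.get("precipitation_mm", 0.0) * float(weather_row["precipitation_mm"])
    base += truth.beta.get("temperature_c", 0.0) * float(weather_row["temperature_c"])

    def lin_exposure(da: str) -> float:
        v = 0.0
        for name, b in truth.beta.items():
            if name in ("intercept", "is_home_da", "is_weekend", "precipitation_mm", "temperature_c"):
                continue
            if name == "gentrification_class":
                continue
            if name in ("gentrification_low_ses", "gentrification_gentrified"):
                cls = da_cov.loc[da, "gentrification_class"]
                if name.endswith("low_ses") and cls == "low_ses_not_gentrified":
                    v += b
                if name.endswith("gentrified") and cls == "gentrified":
                    v += b
                continue
            x = float(da_cov.loc[da, name])
            if name.endswith("_q"):
                x -= 3.0  # centre quintiles
            v += b * x
        return v

    mu = {d: float(np.exp(base + lin_exposure(d))) for d in visited}
    if truth.home_dwell_share is not None:
        s = truth.home_dwell_share
        mu_away = sum(m for d, m in mu.items() if d != home)
        mu[home] = s / (1.0 - s) * mu_away if mu_away > 0 else mu[home]
    else:
        mu[home] *= float(np.exp(truth.beta.get("is_home_da", 0.0)))

    theta = truth.dispersion
    split = np.asarray(truth.pa_split, dtype=float)
    da_class_minutes: dict[str, dict[str, int]] = {}
    n_trunc = 0
    for d in visited:
        T = visited[d]
        y = int(rng.negative_binomial(theta, theta / (theta + mu[d])))
        if y > T:
            y = T
            n_trunc += 1
        lmv = rng.multinomial(y, split / split.sum())
        da_class_minutes[d] = {
            "sedentary": T - y,
            "light": int(lmv[0]),
            "moderate": int(lmv[1]),
            "vigorous": int(lmv[2]),
        }
    return DayPlan(
        participant_id=participant["participant_id"],
        date=date,
        day_index=day_index,
        episodes=episodes,
        da_class_minutes=da_class_minutes,
        mu=mu,
        n_truncated=n_trunc,
        nonwear_gap_min=config.nonwear_gap_min,
    )


# ---------------------------------------------------------------------------
# materialization: minute classes, counts, GPS, raw signal
# ---------------------------------------------------------------------------

_COUNT_BANDS = {
    "sedentary": (5, 99),
    "light": (100, 2019),
    "moderate": (2020, 5998),
    "vigorous": (5999, 11998),
}


def _minute_sequences(plan: DayPlan, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute (da_id, class) arrays over the wear day, episodes in order.

    Class minutes for each DA are permuted randomly over that DA's minutes.
    """
    n_min = sum(m for _, m in plan.episodes)
    da_seq = np.empty(n_min, dtype=object)
    pos = 0
    per_da_slots: dict[str, list[int]] = {}
    for d, m in plan.episodes:
        da_seq[pos : pos + m] = d
        per_da_slots.setdefault(d, []).extend(range(pos, pos + m))
        pos += m
    cls_seq = np.empty(n_min, dtype=object)
    for d, slots in per_da_slots.items():
        labels: list[str] = []
        for cls in ("light", "moderate", "vigorous", "sedentary"):
            labels += [cls] * plan.da_class_minutes[d][cls]
        order = rng.permutation(len(slots))
        for slot, lab in zip(np.asarray(slots)[order], labels):
            cls_seq[slot] = lab
    return da_seq, cls_seq


def materialize_counts_day(
    plan: DayPlan,
    city: CityLayout,
    config: MobilityConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[pd.Timestamp, pd.Timestamp]]]:
    """Emit minute-count and 1 Hz GPS frames for a planned day.

    Returns ``(minute_counts, gps_fixes, nonwear_truth)``.  Minute counts are
    drawn uniformly inside the planted class band (sedentary minutes get small
    nonzero counts, so only device-off gaps produce zero runs).  A planted
    non-wear gap of ``config.nonwear_gap_min`` zero-count minutes (device at
    home, gravity only) is prepended.  ``config.gps_dropout_minutes`` worn
    minutes lose all fixes (planted missing-location records).
    """
    da_seq, cls_seq = _minute_sequences(plan, rng)
    gap = plan.nonwear_gap_min
    start = plan.date + pd.Timedelta(hours=config.wear_start_hour) - pd.Timedelta(minutes=gap)
    n_min = gap + len(da_seq)
    minutes = start + pd.to_timedelta(np.arange(n_min), unit="min")

    counts = np.zeros(n_min, dtype=np.int64)
    for i, cls in enumerate(cls_seq):
        lo, hi = _COUNT_BANDS[cls]
        counts[gap + i] = rng.integers(lo, hi + 1)
    nonwear_truth = []
    if gap:
        nonwear_truth.append((minutes[0], minutes[gap - 1]))

    minute_counts = pd.DataFrame(
        {"participant_id": plan.participant_id, "minute_start": minutes, "counts": counts}
    )

    # GPS: anchor per minute inside the minute's DA cell, jittered fixes
    full_da_seq = np.concatenate([np.array([plan.episodes[0][0]] * gap, dtype=object), da_seq])
    bounds = {d: city.da_bounds(d) for d in set(full_da_seq)}
    b = np.array([bounds[d] for d in full_da_seq], dtype=float)  # (n_min, 4)
    margin = min(3 * config.gps_noise_m, city.cell_size_m / 4)
    ax = b[:, 0] + margin + rng.random(n_min) * (b[:, 2] - b[:, 0] - 2 * margin)
    ay = b[:, 1] + margin + rng.random(n_min) * (b[:, 3] - b[:, 1] - 2 * margin)
    n_fix = 60 * config.gps_hz
    fx = np.repeat(ax, n_fix) + rng.normal(0, config.gps_noise_m, n_min * n_fix)
    fy = np.repeat(ay, n_fix) + rng.normal(0, config.gps_noise_m, n_min * n_fix)
    np.clip(fx, np.repeat(b[:, 0], n_fix), np.repeat(b[:, 2], n_fix), out=fx)
    np.clip(fy, np.repeat(b[:, 1], n_fix), np.repeat(b[:, 3], n_fix), out=fy)
    if config.travel_speed_m_s:
        # constant-speed straight-line travel into each new episode: the first
        # seconds of the episode trace the line from the previous minute's
        # anchor, so minute medians can land in traversed (pass-through) DAs
        ep_start = gap + np.cumsum([0] + [m for _, m in plan.episodes[:-1]])
        for e, m0 in enumerate(ep_start[1:], start=1):
            x0, y0 = ax[m0 - 1], ay[m0 - 1]
            x1, y1 = ax[m0], ay[m0]
            dist = float(np.hypot(x1 - x0, y1 - y0))
            cap = min(3, plan.episodes[e][1]) * n_fix
            n_travel = min(int(np.ceil(dist / config.travel_speed_m_s * config.gps_hz)), cap)
            if n_travel == 0:
                continue
            frac = (np.arange(n_travel) + 1) / n_travel
            s0 = m0 * n_fix
            fx[s0 : s0 + n_travel] = x0 + frac * (x1 - x0)
            fy[s0 : s0 + n_travel] = y0 + frac * (y1 - y0)
    ts = np.repeat(minutes.values, n_fix) + np.tile(
        pd.to_timedelta(np.arange(n_fix) / config.gps_hz, unit="s").values, n_min
    )
    lon, lat = city.crs.to_wgs84(fx, fy)
    gps = pd.DataFrame(
        {"participant_id": plan.participant_id, "timestamp": ts, "lon": lon, "lat": lat}
    )
    if config.gps_dropout_minutes:
        worn_idx = np.arange(gap, n_min)
        drop = rng.choice(worn_idx, size=min(config.gps_dropout_minutes, len(worn_idx)), replace=False)
        drop_minutes = set(minutes[drop])
        gps = gps[~pd.to_datetime(gps["timestamp"]).dt.floor("min").isin(drop_minutes)]
        gps = gps.reset_index(drop=True)
    return minute_counts, gps, nonwear_truth


@functools.lru_cache(maxsize=8)
def class_amplitudes(
    cuts: CutPoints = CutPoints(),
    cascade: CountCascadeParams = CountCascadeParams(),
    freq_hz: float = 1.5,
    rate_hz: float = 50.0,
) -> dict[str, float]:
    """Calibrate sinusoid amplitudes (g) that land counts mid-band per class.

    Uses bisection on the (monotone below saturation) amplitude -> counts/min
    map of the count cascade, probing with a 3-minute constant-amplitude tone
    and reading the middle minute.
    """

    def counts_at(a: float) -> int:
        t = np.arange(int(3 * 60 * rate_hz)) / rate_hz
        y = 1.0 + a * np.sin(2 * np.pi * freq_hz * t)
        sig = RawAccelSignal(pd.Timestamp("2000-01-01 12:00"), rate_hz, np.column_stack([0 * t, y, 0 * t]))
        df = compute_counts(sig, params=cascade)
        return int(df[cascade.vertical_axis].iloc[1])

    targets = {
        "sedentary": (cuts.sedentary_max + 1) // 2,
        "light": (cuts.sedentary_max + 1 + cuts.light_max) // 2,
        "moderate": (cuts.light_max + 1 + cuts.moderate_max) // 2,
        "vigorous": int(cuts.moderate_max * 1.5),
    }
    out: dict[str, float] = {}
    for cls, target in targets.items():
        lo, hi = 0.0, cascade.saturation_g
        for _ in range(40):
            mid = (lo + hi) / 2
            if counts_at(mid) < target:
                lo = mid
            else:
                hi = mid
        out[cls] = (lo + hi) / 2
    return out


def materialize_signal_day(
    plan: DayPlan,
    city: CityLayout,
    config: MobilityConfig,
    rng: np.random.Generator,
    cuts: CutPoints = CutPoints(),
    cascade: CountCascadeParams = CountCascadeParams(),
    rate_hz: float = 50.0,
) -> tuple[RawAccelSignal, pd.DataFrame, list]:
    """Emit a 50 Hz tri-axial stream (plus GPS) for a planned day.

    Each worn minute carries a vertical-axis tone at the class-calibrated
    amplitude (with per-minute phase), superposed on 1 g static gravity;
    planted non-wear gap minutes carry gravity only, so the derived counts are
    zero there.  Intended for short unit-test spans — a full cohort at 50 Hz
    is deliberately out of the count-mode path.
    """
    minute_counts, gps, nonwear_truth = materialize_counts_day(plan, city, config, rng)
    amps = class_amplitudes(cuts, cascade, rate_hz=rate_hz)
    # classes re-derived from band membership of the planted counts
    bands_sorted = sorted(_COUNT_BANDS.items(), key=lambda kv: kv[1][0])

    def band_of(c: int) -> str | None:
        if c == 0:
            return None
        for cls, (lo, hi) in bands_sorted:
            if lo <= c <= hi:
                return cls
        return "vigorous"

    n_min = len(minute_counts)
    spm = int(60 * rate_hz)
    y = np.ones(n_min * spm)
    t = np.arange(spm) / rate_hz
    for i, c in enumerate(minute_counts["counts"].to_numpy()):
        cls = band_of(int(c))
        if cls is None:
            continue
        phase = rng.random() * 2 * np.pi
        y[i * spm : (i + 1) * spm] += amps[cls] * np.sin(2 * np.pi * 1.5 * t + phase)
    samples = np.column_stack([np.zeros_like(y), y, np.zeros_like(y)])
    sig = RawAccelSignal(minute_counts["minute_start"].iloc[0], rate_hz, samples)
    return sig, gps, nonwear_truth


# ---------------------------------------------------------------------------
# census panel, proximity blocks, weather
# ---------------------------------------------------------------------------


def generate_census_panel(
    city: CityLayout,
    gentrify_fraction: float = 0.25,
    high_ses_fraction: float = 0.40,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict, pd.Series]:
    """Two-wave tract panel constructed so the Ding-style classifier recovers
    configured class proportions.

    Returns ``(panel, metro, truth_labels)``.  ``gentrify_fraction`` is the
    share of *eligible* (below-metro-income) tracts that gentrify.  Citywide
    (metro) growth is 10% rent, 15% home value, 20% college share; gentrified
    tracts exceed the rent and college growth, others stay below the college
    growth (failing condition (b)).
    """
    if not 0 <= gentrify_fraction <= 1 or not 0 <= high_ses_fraction <= 1:
        raise ConfigurationError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 55]))
    tracts = sorted(set(city.tract_membership.values()))
    n = len(tracts)
    metro = {
        "median_income_t0": 70_000.0,
        "median_rent_t0": 1000.0,
        "median_rent_t1": 1100.0,
        "median_home_value_t0": 300_000.0,
        "median_home_value_t1": 345_000.0,
        "college_share_t0": 0.30,
        "college_share_t1": 0.36,
    }
    n_high = int(round(high_ses_fraction * n))
    eligible = n - n_high
    n_gent = int(round(gentrify_fraction * eligible))
    labels = (
        ["high_ses"] * n_high + ["gentrified"] * n_gent + ["low_ses_not_gentrified"] * (eligible - n_gent)
    )
    rng.shuffle(labels)

    rows = []
    for tract, lab in zip(tracts, labels):
        if lab == "high_ses":
            income = metro["median_income_t0"] * rng.uniform(1.0, 1.6)
        else:
            income = metro["median_income_t0"] * rng.uniform(0.5, 0.95)
        rent0 = rng.uniform(700, 1300)
        value0 = rng.uniform(200_000, 450_000)
        college0 = rng.uniform(0.10, 0.45)
        if lab == "gentrified":
            rent_g = 0.10 + rng.uniform(0.05, 0.25)  # exceeds citywide 10%
            value_g = 0.15 + rng.uniform(-0.10, 0.20)
            college_g = 0.20 + rng.uniform(0.05, 0.30)  # exceeds citywide 20%
        else:
            rent_g = rng.uniform(-0.05, 0.30)
            value_g = rng.uniform(-0.05, 0.30)
            college_g = 0.20 - rng.uniform(0.02, 0.15)  # below citywide: fails (b)
        rows.append(
            {
                "tract_id": tract,
                "median_income_t0": income,
                "median_rent_t0": rent0,
                "median_rent_t1": rent0 * (1 + rent_g),
                "median_home_value_t0": value0,
                "median_home_value_t1": value0 * (1 + value_g),
                "college_share_t0": college0,
                "college_share_t1": min(1.0, college0 * (1 + college_g)),
            }
        )
    panel = pd.DataFrame(rows)
    truth = pd.Series(labels, index=tracts, name="gentrification_class")
    return panel, metro, truth


def generate_proximity_blocks(
    city: CityLayout, blocks_per_da: int = 4, seed: int = 0
) -> pd.DataFrame:
    """Block-level 0-1 proximity scores: a DA-level latent score plus block noise."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 66]))
    rows = []
    for d in city.da_ids:
        latent = rng.random(len(PROXIMITY_AMENITIES))
        for b in range(blocks_per_da):
            scores = np.clip(latent + rng.normal(0, 0.08, len(PROXIMITY_AMENITIES)), 0, 1)
            rows.append(
                {"block_id": f"{d}-B{b}", "da_id": d, **dict(zip(PROXIMITY_AMENITIES, scores))}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WeatherConfig:
    p_wet: float = 0.35
    gamma_shape: float = 1.2
    gamma_scale_mm: float = 4.0
    temp_mean_c: float = 10.0
    temp_seasonal_amp_c: float = 12.0
    temp_noise_sd_c: float = 3.0


def generate_weather(dates, seed: int = 0, config: WeatherConfig | None = None) -> pd.DataFrame:
    """Daily precipitation (zero-inflated gamma, mm) and mean temperature (C).

    Temperature follows a sinusoidal annual cycle plus Gaussian noise.
    Deterministic for a fixed seed; zero-variance configs give constant series.
    """
    cfg = config or WeatherConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    dates = pd.DatetimeIndex(pd.to_datetime(list(dates))).normalize()
    wet = rng.random(len(dates)) < cfg.p_wet
    amount = (
        rng.gamma(cfg.gamma_shape, cfg.gamma_scale_mm, len(dates))
        if cfg.gamma_scale_mm > 0
        else np.zeros(len(dates))
    )
    precip = np.where(wet, amount, 0.0)
    doy = dates.dayofyear.to_numpy()
    temp = (
        cfg.temp_mean_c
        - cfg.temp_seasonal_amp_c * np.cos(2 * np.pi * (doy - 15) / 365.25)
        + (rng.normal(0, cfg.temp_noise_sd_c, len(dates)) if cfg.temp_noise_sd_c > 0 else 0.0)
    )
    return pd.DataFrame({"date": dates, "precipitation_mm": precip, "temperature_c": temp})


# ---------------------------------------------------------------------------
# cohort-scale direct table path
# ---------------------------------------------------------------------------


def simulate_cohort_table(
    city: CityLayout,
    roster: pd.DataFrame,
    truth: SyntheticTruth,
    exposure_da: pd.DataFrame,
    tract_measures: pd.DataFrame,
    weather: pd.DataFrame,
    n_days: int,
    start_date: str | pd.Timestamp = "2018-06-04",
    config: MobilityConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Person-day-DA analysis table drawn directly from the planted process.

    This is the cohort-scale fidelity level: it shares the day-planning draws
    with the count-level path (same row truth) but skips minute and GPS
    materialization.  Covariates and exposures are already joined; the result
    matches the schema produced by the aggregation + exposure-attachment
    pipeline stages.
    """
    config = config or MobilityConfig()
    da_cov = _da_covariate_frame(city, exposure_da, tract_measures)
    re = participant_random_effects(truth, len(roster), seed)
    start = pd.Timestamp(start_date)
    dates = [start + pd.Timedelta(days=k) for k in range(n_days)]
    wx = weather.set_index(pd.to_datetime(weather["date"]).dt.normalize())

    ss = np.random.SeedSequence([seed, 88])
    child = ss.spawn(len(roster))
    frames = []
    for i, (_, person) in enumerate(roster.iterrows()):
        rng = np.random.default_rng(child[i])
        for k, date in enumerate(dates, start=1):
            plan = plan_day(
                person, date, k, n_days, city, truth, da_cov, wx.loc[date.normalize()], re[i], config, rng
            )
            rows = plan.rows()
            rows["day_index"] = k
            frames.append(rows)
    table = pd.concat(frames, ignore_index=True)
    table = table.merge(roster, on="participant_id", how="left")
    table["is_home_da"] = (table["da_id"] == table["home_da"]).astype(int)
    table["is_weekend"] = (pd.to_datetime(table["date"]).dt.dayofweek >= 5).astype(int)
    table = table.merge(
        weather.assign(date=pd.to_datetime(weather["date"]).dt.normalize()),
        on="date",
        how="left",
    )
    from .exposures import attach_exposures

    return attach_exposures(table, exposure_da, city.tract_membership, tract_measures)
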