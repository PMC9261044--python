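"""End-to-end pipeline orchestration with plain-text stage artifacts.

Every stage reads and writes CSV/GeoJSON/JSON so each can be run and tested
in isolation.  All CSV outputs start with a ``# actigeo ...`` metadata line
carrying the config hash and seed (read back with ``comment='#'``); JSON
outputs carry a ``_meta`` object.  A cleaning ledger accounts for records
dropped for missing location or falling outside the DA layer and for
participants dropped for device error, and the run is idempotent for a fixed
config + seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic_city as sc
from .exposures import attach_exposures, classify_gentrification, compute_can_ale, summarize_proximity
from .geometry import read_geojson_polygons, write_geojson
from .gps_fusion import fuse, minute_median_locations
from .model import FitControl, ModelSpec, run_study
from .sensor_processing import ChoiParams, CutPoints, compute_counts, process_minutes
from .spatial_aggregation import DAIndex, aggregate
from .validation import RECOVERY_FIXED

__all__ = ["PipelineConfig", "run_pipeline", "write_csv", "read_csv"]


@dataclass
class PipelineConfig:
    """Everything one simulated-city run needs; loadable from YAML."""

    seed: int = 0
    # city & cohort
    n_da: int = 64
    das_per_tract: int = 4
    cell_size_m: float = 500.0
    n_participants: int = 10
    n_days: int = 3
    start_date: str = "2018-06-04"
    mode: str = "counts"  # "counts" or "signal"
    gentrify_fraction: float = 0.25
    # mobility / device
    wear_minutes: int = 480
    n_destinations: int = 2
    dest_dwell_min: int = 45
    nonwear_gap_min: int = 0
    gps_dropout_minutes: int = 0
    # processing
    choi: tuple[int, int, int] = (90, 2, 30)
    cuts: tuple[int, int, int] = (99, 2019, 5998)
    buffer_m: float = 1000.0
    # exposures fed to the model: "planted" uses the generator's exposure
    # tables (known truth); "constructed" rebuilds them from amenity layers,
    # blocks and the census panel
    exposure_source: str = "planted"
    # modelling
    outcomes: tuple[str, ...] = ("pa_minutes", "mvpa_minutes")
    fixed: tuple[str, ...] = RECOVERY_FIXED
    dwell_threshold: int = 5
    nagq: int = 3
    run_fit: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        if unknown := set(raw) - known:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("choi", "cuts", "outcomes", "fixed"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def mobility(self) -> sc.MobilityConfig:
        return sc.MobilityConfig(
            wear_minutes=self.wear_minutes,
            n_destinations=self.n_destinations,
            dest_dwell_min=self.dest_dwell_min,
            nonwear_gap_min=self.nonwear_gap_min,
            gps_dropout_minutes=self.gps_dropout_minutes,
        )


def _meta_line(cfg_hash: str, seed: int) -> str:
    return f"# actigeo config_hash={cfg_hash} seed={seed}\n"


def write_csv(df: pd.DataFrame, path, cfg_hash: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_line(cfg_hash, seed))
        df.to_csv(fh, index=False)


def read_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def _write_json(obj: dict, path, cfg_hash: str, seed: int) -> None:
    obj = {"_meta": {"config_hash": cfg_hash, "seed": seed}, **obj}
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Simulate -> process -> fuse -> aggregate -> exposures -> fit.

    Writes every intermediate artifact under ``out_dir`` and returns it.
    Stage failures raise with the stage name in the message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h, seed = config.config_hash, config.seed
    ledger: dict = {"seed": seed, "config_hash": h}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
                return False

        return _Ctx()

    with stage("simulate"):
        city = sc.generate_city(
            config.n_da, config.das_per_tract, seed=seed, cell_size_m=config.cell_size_m
        )
        roster = sc.generate_cohort(config.n_participants, city, seed=seed)
        exposure_da, tract_measures = sc.generate_exposure_table(city, seed=seed)
        panel, metro, gent_truth = sc.generate_census_panel(
            city, gentrify_fraction=config.gentrify_fraction, seed=seed
        )
        blocks = sc.generate_proximity_blocks(city, seed=seed)
        dates = pd.date_range(config.start_date, periods=config.n_days)
        weather = sc.generate_weather(dates, seed=seed)
        truth = sc.SyntheticTruth()
        mobility = config.mobility()

        write_geojson(out / "das.geojson", city.to_geojson({"config_hash": h, "seed": seed}))
        write_csv(roster, out / "roster.csv", h, seed)
        write_csv(exposure_da, out / "exposure_planted_da.csv", h, seed)
        write_csv(tract_measures, out / "exposure_planted_tract.csv", h, seed)
        write_csv(panel, out / "census_panel.csv", h, seed)
        write_csv(blocks, out / "proximity_blocks.csv", h, seed)
        write_csv(weather, out / "weather.csv", h, seed)
        _write_json({"metro": metro, "beta": truth.beta}, out / "truth.json", h, seed)

        da_cov = sc._da_covariate_frame(city, exposure_da, tract_measures)
        re = sc.participant_random_effects(truth, len(roster), seed)
        wx = weather.set_index(pd.to_datetime(weather["date"]).dt.normalize())
        plan_streams = np.random.SeedSequence([seed, 88]).spawn(len(roster))
        mat_streams = np.random.SeedSequence([seed, 99]).spawn(len(roster))
        gps_frames, count_frames, signal_frames = [], [], []
        for i, (_, person) in enumerate(roster.iterrows()):
            rng_plan = np.random.default_rng(plan_streams[i])
            rng_mat = np.random.default_rng(mat_streams[i])
            for k, date in enumerate(dates, start=1):
                plan = sc.plan_day(
                    person, date, k, config.n_days, city, truth, da_cov,
                    wx.loc[date.normalize()], re[i], mobility, rng_plan,
                )
                if config.mode == "signal":
                    sig, gps, _ = sc.materialize_signal_day(plan, city, mobility, rng_mat)
                    ts = sig.start_time + pd.to_timedelta(
                        np.arange(sig.n_samples) / sig.rate_hz, unit="s"
                    )
                    signal_frames.append(
                        pd.DataFrame(
                            {
                                "participant_id": person["participant_id"],
                                "timestamp": ts,
                                "x_g": sig.samples[:, 0].round(5),
                                "y_g": sig.samples[:, 1].round(5),
                                "z_g": sig.samples[:, 2].round(5),
                            }
                        )
                    )
                elif config.mode == "counts":
                    mc, gps, _ = sc.materialize_counts_day(plan, city, mobility, rng_mat)
                    count_frames.append(mc)
                else:
                    raise ValueError(f"unknown mode {config.mode!r}")
                gps_frames.append(gps)
        write_csv(pd.concat(gps_frames, ignore_index=True), out / "gps.csv", h, seed)
        if config.mode == "signal":
            write_csv(pd.concat(signal_frames, ignore_index=True), out / "accel_raw.csv", h, seed)
        else:
            write_csv(pd.concat(count_frames, ignore_index=True), out / "accel_minutes.csv", h, seed)

    with stage("process-accel"):
        choi = ChoiParams(*config.choi)
        cuts = CutPoints(*config.cuts)
        if config.mode == "signal":
            raw = read_csv(out / "accel_raw.csv", parse_dates=["timestamp"])
            per = []
            for pid, g in raw.groupby("participant_id", sort=True):
                g = g.sort_values("timestamp")
                # split into contiguous 50 Hz segments (one per wear day)
                gaps = g["timestamp"].diff().dt.total_seconds().fillna(0.02) > 1.0
                for _, seg in g.groupby(gaps.cumsum()):
                    sig = sc.RawAccelSignal(
                        seg["timestamp"].iloc[0], 50.0, seg[["x_g", "y_g", "z_g"]].to_numpy()
                    )
                    cdf = compute_counts(sig)
                    cdf = cdf.reset_index().rename(columns={"y": "counts"})
                    cdf["participant_id"] = pid
                    per.append(cdf[["participant_id", "epoch_start", "counts"]])
            counts = pd.concat(per, ignore_index=True).rename(columns={"epoch_start": "minute_start"})
        else:
            counts = read_csv(out / "accel_minutes.csv", parse_dates=["minute_start"])
        minute_frames = []
        for pid, g in counts.groupby("participant_id", sort=True):
            res = process_minutes(g.set_index("minute_start")["counts"], choi, cuts).reset_index()
            res["participant_id"] = pid
            minute_frames.append(res)
        minutes = pd.concat(minute_frames, ignore_index=True)
        write_csv(minutes, out / "minutes.csv", h, seed)

    with stage("fuse"):
        gps_df = read_csv(out / "gps.csv", parse_dates=["timestamp"])
        locations = minute_median_locations(gps_df)
        records = fuse(minutes[["participant_id", "minute_start", "intensity"]], locations)
        write_csv(records, out / "minute_records.csv", h, seed)

    with stage("aggregate"):
        polygons = read_geojson_polygons(out / "das.geojson")
        idx = DAIndex(polygons)
        agg = aggregate(records, roster, weather, idx)
        ledger["records_dropped_missing_location"] = agg.n_dropped_missing_location
        ledger["records_dropped_outside_das"] = agg.n_dropped_outside_das
        dropped_participants = roster.loc[roster["device_error"], "participant_id"].tolist()
        ledger["participants_dropped_device_error"] = len(dropped_participants)
        table = agg.table[~agg.table["participant_id"].isin(dropped_participants)]

    with stage("exposures"):
        if config.exposure_source == "constructed":
            ale = compute_can_ale(city, buffer_m=config.buffer_m)
            prox = summarize_proximity(blocks)
            exp_da = ale[["da_id", "can_ale_q"]].merge(prox, on="da_id")
            gent = classify_gentrification(panel, metro)
            tm = tract_measures[["tract_id", "urban_compactness"]].merge(
                gent.rename_axis("tract_id").reset_index(), on="tract_id"
            )
        else:
            exp_da, tm = exposure_da, tract_measures
        write_csv(exp_da, out / "exposures_da.csv", h, seed)
        write_csv(tm, out / "exposures_tract.csv", h, seed)
        analysis = attach_exposures(table, exp_da, city.tract_membership, tm)
        # observation-day index per participant for the random slope
        analysis = analysis.sort_values(["participant_id", "date", "da_id"]).reset_index(drop=True)
        day_rank = analysis.groupby("participant_id")["date"].rank(method="dense")
        analysis["day_index"] = day_rank.astype(int)
        write_csv(analysis, out / "analysis_table.csv", h, seed)

    _write_json(ledger, out / "cleaning_ledger.json", h, seed)

    if config.run_fit:
        with stage("fit"):
            spec = ModelSpec(fixed=config.fixed)
            report = run_study(
                {city.city_id: analysis},
                outcomes=config.outcomes,
                dwell_threshold=config.dwell_threshold,
                spec=spec,
                control=FitControl(nagq=config.nagq),
            )
            for (city_id, outcome, arm), irr in report.irr.items():
                write_csv(irr, out / f"irr_{city_id}_{outcome}_{arm}.csv", h, seed)
            meta = {
                f"{k[0]}|{k[1]}|{k[2]}": {
                    "loglik": f.loglik,
                    "converged": f.converged,
                    "dispersion": f.dispersion,
                    "n_obs": f.n_obs,
                    "n_groups": f.n_groups,
                }
                for k, f in report.fits.items()
            }
            meta["errors"] = {"|".join(k): v for k, v in report.errors.items()}
            _write_json(meta, out / "fit_metadata.json", h, seed)
    return out
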