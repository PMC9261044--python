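"""Simulation-based validation studies on the synthetic city.

Two study designs used to check the full chain against planted truth:

* :func:`recovery_study` — repeated cohort simulations with known incidence
  rate ratios, refit with the multilevel NB model; summarised as relative
  bias of the mean recovered IRR and Wald 95% CI coverage per coefficient.
* :func:`home_share_study` — a cohort generated with a planted expected share
  of activity minutes in the home DA, pushed through the full count/GPS
  pipeline (wear detection, minute fusion, DA aggregation), returning the
  pipeline-computed home share and its Monte-Carlo standard error.  Because
  person-day activity totals are overdispersed and clustered, the MC error is
  the ratio-estimator standard error over person-day clusters (floored at the
  minute-level binomial SE).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthetic_city as sc
from .gps_fusion import fuse, minute_median_locations
from .model import FitControl, ModelSpec, fit_nb_glmm, irr_table
from .sensor_processing import ChoiParams, CutPoints, process_minutes
from .spatial_aggregation import DAIndex, aggregate, home_share

__all__ = [
    "RECOVERY_FIXED",
    "RECOVERY_TARGET_IRRS",
    "recovery_study",
    "summarize_recovery",
    "cohort_minutes_pipeline",
    "home_share_study",
]

#: covariates of the recovery design (all with planted coefficients)
RECOVERY_FIXED = (
    "can_ale_q",
    "parks_q",
    "urban_compactness",
    "is_home_da",
    "is_weekend",
    "precipitation_mm",
    "temperature_c",
)

#: the planted IRRs whose recovery is tracked
RECOVERY_TARGET_IRRS = {
    "can_ale_q": 1.3,
    "parks_q": 1.1,
    "urban_compactness": 0.6,
    "is_home_da": 30.0,
}


def _study_inputs(n_da: int, n_participants: int, n_days: int, seed: int):
    city = sc.generate_city(n_da, das_per_tract=4, seed=seed)
    roster = sc.generate_cohort(n_participants, city, seed=seed)
    exposure_da, tract_measures = sc.generate_exposure_table(city, seed=seed)
    weather = sc.generate_weather(pd.date_range("2018-06-04", periods=n_days), seed=seed)
    return city, roster, exposure_da, tract_measures, weather


def recovery_study(
    n_replicates: int = 80,
    n_participants: int = 120,
    n_days: int = 8,
    n_da: int = 100,
    seed: int = 0,
    nagq: int = 3,
    truth: sc.SyntheticTruth | None = None,
) -> pd.DataFrame:
    """Replicate planted-IRR recovery: one row per replicate x tracked term.

    Each replicate regenerates the cohort, exposures, weather and activity
    draws under a fresh seed, fits the PA model with the correct random-effect
    structure, and records the recovered IRR, its Wald 95% CI and whether the
    CI covers the planted value.  City geometry and planted exposures are
    redrawn per replicate as well, so the summary averages over designs.
    """
    truth = truth or sc.SyntheticTruth()
    control = FitControl(nagq=nagq)
    rows = []
    warm = None
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n_replicates)]
    for rep, rseed in enumerate(rep_seeds):
        city, roster, exposure_da, tract_measures, weather = _study_inputs(
            n_da, n_participants, n_days, rseed
        )
        table = sc.simulate_cohort_table(
            city, roster, truth, exposure_da, tract_measures, weather, n_days=n_days, seed=rseed
        )
        # a replicate can draw a covariate with no variation (e.g. an all-dry
        # week): drop such columns, as an analyst would — the design is
        # otherwise rank-deficient
        fixed = tuple(c for c in RECOVERY_FIXED if table[c].nunique() > 1)
        spec = ModelSpec(outcome="pa_minutes", fixed=fixed)
        if warm is not None and len(warm) != len(fixed) + 5:
            warm = None
        fit = fit_nb_glmm(table, spec, control, start_params=warm)
        warm = fit.params_packed  # a start point cannot move the (unique) optimum
        irr = irr_table(fit).set_index("term")
        for term, planted in RECOVERY_TARGET_IRRS.items():
            r = irr.loc[term]
            rows.append(
                {
                    "replicate": rep,
                    "term": term,
                    "planted_irr": planted,
                    "irr": r["irr"],
                    "ci_lo": r["ci_lo"],
                    "ci_hi": r["ci_hi"],
                    "covered": bool(r["ci_lo"] <= planted <= r["ci_hi"]),
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


def summarize_recovery(replicates: pd.DataFrame) -> pd.DataFrame:
    """Per-term mean IRR, relative bias of the mean, and CI coverage."""
    out = []
    for term, g in replicates.groupby("term"):
        mean_irr = g["irr"].mean()
        planted = g["planted_irr"].iloc[0]
        out.append(
            {
                "term": term,
                "planted_irr": planted,
                "mean_irr": mean_irr,
                "rel_bias": abs(mean_irr - planted) / planted,
                "coverage": g["covered"].mean(),
                "n_replicates": len(g),
            }
        )
    return pd.DataFrame(out).set_index("term")


def cohort_minutes_pipeline(
    city: sc.CityLayout,
    roster: pd.DataFrame,
    truth: sc.SyntheticTruth,
    exposure_da: pd.DataFrame,
    tract_measures: pd.DataFrame,
    weather: pd.DataFrame,
    n_days: int,
    config: sc.MobilityConfig,
    seed: int,
    choi: ChoiParams | None = None,
    cuts: CutPoints | None = None,
):
    """Run a counts-mode cohort through the sensor/fusion/aggregation stages.

    Materializes minute counts and 1 Hz GPS day by day, applies wear
    detection and intensity classification per participant, reduces GPS to
    minute medians, fuses, and aggregates to person-day-DA rows.  Returns the
    aggregation result together with the planted row truth (concatenated day
    plans) for conservation checks.
    """
    da_cov = sc._da_covariate_frame(city, exposure_da, tract_measures)
    re = sc.participant_random_effects(truth, len(roster), seed)
    start = pd.Timestamp("2018-06-04")
    dates = [start + pd.Timedelta(days=k) for k in range(n_days)]
    wx = weather.set_index(pd.to_datetime(weather["date"]).dt.normalize())

    plan_streams = np.random.SeedSequence([seed, 88]).spawn(len(roster))
    mat_streams = np.random.SeedSequence([seed, 99]).spawn(len(roster))
    count_frames, gps_frames, truth_frames = [], [], []
    for i, (_, person) in enumerate(roster.iterrows()):
        rng_plan = np.random.default_rng(plan_streams[i])
        rng_mat = np.random.default_rng(mat_streams[i])
        for k, date in enumerate(dates, start=1):
            plan = sc.plan_day(
                person, date, k, n_days, city, truth, da_cov,
                wx.loc[date.normalize()], re[i], config, rng_plan,
            )
            mc, gps, _ = sc.materialize_counts_day(plan, city, config, rng_mat)
            count_frames.append(mc)
            gps_frames.append(gps)
            truth_frames.append(plan.rows())
    counts = pd.concat(count_frames, ignore_index=True)
    gps = pd.concat(gps_frames, ignore_index=True)
    row_truth = pd.concat(truth_frames, ignore_index=True)

    processed = []
    for pid, g in counts.groupby("participant_id", sort=True):
        res = process_minutes(g.set_index("minute_start")["counts"], choi, cuts)
        res = res.reset_index()
        res["participant_id"] = pid
        processed.append(res)
    minutes = pd.concat(processed, ignore_index=True)

    locations = minute_median_locations(gps)
    records = fuse(minutes[["participant_id", "minute_start", "intensity"]], locations)
    idx = DAIndex(city.da_polygons(wgs84=True))
    agg = aggregate(records, roster, weather, idx)
    return agg, row_truth


def home_share_study(
    n_participants: int = 100,
    n_days: int = 4,
    planted_share: float = 0.45,
    n_da: int = 64,
    seed: int = 0,
) -> dict:
    """Pipeline-computed PA home share for a cohort with a planted share.

    Returns the estimate, the planted value, the total PA minutes, and a
    Monte-Carlo standard error: the ratio-estimator SE over person-day
    clusters, floored at the minute-level binomial SE.
    """
    city, roster, exposure_da, tract_measures, weather = _study_inputs(
        n_da, n_participants, n_days, seed
    )
    truth = sc.SyntheticTruth(home_dwell_share=planted_share)
    config = sc.MobilityConfig()
    agg, _ = cohort_minutes_pipeline(
        city, roster, truth, exposure_da, tract_measures, weather, n_days, config, seed
    )
    tab = agg.table
    est = home_share(tab, "pa")

    per_day = (
        tab.assign(home_pa=tab["pa_minutes"] * tab["is_home_da"])
        .groupby(["participant_id", "date"])[["pa_minutes", "home_pa"]]
        .sum()
    )
    n_minutes = float(per_day["pa_minutes"].sum())
    # ratio-estimator SE: var of per-cluster (h_d - p * t_d) residuals
    resid = per_day["home_pa"] - est * per_day["pa_minutes"]
    se_ratio = float(np.sqrt((resid**2).sum()) / n_minutes)
    se_binom = float(np.sqrt(est * (1 - est) / n_minutes))
    return {
        "estimate": est,
        "planted": planted_share,
        "mc_se": max(se_ratio, se_binom),
        "n_pa_minutes": n_minutes,
        "n_rows": len(tab),
    }
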