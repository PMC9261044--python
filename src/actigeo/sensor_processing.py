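"""Raw acceleration -> activity counts, non-wear detection, intensity classes.

Implements the device-style processing chain used in wearable physical-activity
research:

1. :func:`compute_counts` converts a tri-axial acceleration stream (g units,
   >= 30 Hz) into integer "activity counts" per epoch through a
   frequency-filtering cascade: resample to 30 Hz, band-pass to the human
   movement band, rectify, dead-band, saturate, quantize to 8-bit resolution,
   integrate per second, and sum seconds into clock-aligned epochs.
2. :func:`detect_nonwear` applies the Choi algorithm to vertical-axis
   counts/min: a minute is non-wear when it belongs to a run of >= 90 zero
   minutes, allowing artifactual interruptions of <= 2 consecutive nonzero
   minutes whose 30-minute flanks on both sides are all zero.
3. :func:`classify_intensity` buckets worn minutes into
   sedentary / light / moderate / vigorous using counts-per-minute cut points
   (Troiano 2008 thresholds by default).

The cascade follows the published frequency-filtering approach for deriving
counts from raw accelerometry; the band edges, dead-band, saturation, and
quantization step are configuration constants with documented defaults, not a
claim of brand-exact firmware replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "RawAccelSignal",
    "CountCascadeParams",
    "ChoiParams",
    "CutPoints",
    "INTENSITY_LABELS",
    "compute_counts",
    "detect_nonwear",
    "classify_intensity",
    "fill_count_gaps",
]

INTENSITY_LABELS = ("sedentary", "light", "moderate", "vigorous", "nonwear")


class UnsupportedRateError(ValueError):
    """Sampling rate too low to derive counts."""


@dataclass
class RawAccelSignal:
    """A contiguous tri-axial acceleration recording in g units."""

    start_time: pd.Timestamp
    rate_hz: float
    samples: np.ndarray  # (n, 3) float array, axes x/y/z

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class CountCascadeParams:
    """Constants of the raw-signal -> counts cascade.

    target_rate_hz : internal processing rate, Hz.
    band_hz        : pass band of the Butterworth band-pass (order ``filter_order``);
                     rejects the static gravity component and high-frequency noise.
    deadband_g     : rectified values below this are zeroed (sensor noise floor).
    saturation_g   : rectified values are clipped here before quantization.
    adc_bits       : quantization resolution over [0, saturation_g].
    vertical_axis  : axis used for wear detection and intensity classification.
    """

    target_rate_hz: float = 30.0
    band_hz: tuple[float, float] = (0.25, 2.5)
    filter_order: int = 3
    deadband_g: float = 0.05
    saturation_g: float = 2.0
    adc_bits: int = 8
    vertical_axis: str = "y"

    @property
    def quantum_g(self) -> float:
        # half the ADC range is used for magnitude after rectification
        return self.saturation_g / (2 ** (self.adc_bits - 1))


@dataclass(frozen=True)
class ChoiParams:
    """Choi non-wear parameters (minutes)."""

    window_min: int = 90
    spike_tolerance_min: int = 2
    flank_min: int = 30

    def __post_init__(self) -> None:
        if min(self.window_min, self.spike_tolerance_min, self.flank_min) <= 0:
            raise ValueError("Choi parameters must be positive")
        if self.spike_tolerance_min >= self.window_min:
            raise ValueError("spike tolerance must be smaller than the window")


@dataclass(frozen=True)
class CutPoints:
    """Counts/min thresholds: sedentary <= sedentary_max < light <= light_max < ..."""

    sedentary_max: int = 99
    light_max: int = 2019
    moderate_max: int = 5998

    def __post_init__(self) -> None:
        if not 0 <= self.sedentary_max < self.light_max < self.moderate_max:
            raise ValueError("cut points must be strictly increasing and non-negative")


def _resample_to(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    if rate_in == rate_out:
        return x
    n_out = int(round(len(x) * rate_out / rate_in))
    t_in = np.arange(len(x)) / rate_in
    t_out = np.arange(n_out) / rate_out
    return np.interp(t_out, t_in, x)


def compute_counts(
    sig: RawAccelSignal,
    epoch_s: int = 60,
    params: CountCascadeParams | None = None,
) -> pd.DataFrame:
    """Convert a raw signal to per-epoch counts for each axis.

    Returns a DataFrame indexed by ``epoch_start`` (clock-aligned to
    ``epoch_s`` boundaries in the device's local time) with integer columns
    ``x``, ``y``, ``z``.  A constant (gravity) input produces zero counts:
    the band-pass has zero DC gain and the residue falls below the dead band.
    """
    params = params or CountCascadeParams()
    if sig.rate_hz < 30.0:
        raise UnsupportedRateError(f"rate {sig.rate_hz} Hz < 30 Hz minimum")
    if 60 % epoch_s != 0:
        raise ValueError("epoch_s must divide 60")
    if sig.n_samples == 0:
        return pd.DataFrame(columns=["x", "y", "z"], dtype=int).rename_axis("epoch_start")

    fs = params.target_rate_hz
    sos = sps.butter(params.filter_order, params.band_hz, btype="bandpass", fs=fs, output="sos")
    per_axis = []
    for ax in range(3):
        v = _resample_to(sig.samples[:, ax], sig.rate_hz, fs)
        v = sps.sosfiltfilt(sos, v)
        v = np.abs(v)
        v[v < params.deadband_g] = 0.0
        np.clip(v, 0.0, params.saturation_g, out=v)
        q = np.round(v / params.quantum_g)  # integer quanta per sample
        # integrate per second
        n_sec = int(len(q) // fs)
        sec = q[: int(n_sec * fs)].reshape(n_sec, int(fs)).sum(axis=1)
        per_axis.append(sec.astype(np.int64))

    n_sec = min(map(len, per_axis))
    if n_sec == 0:
        return pd.DataFrame(columns=["x", "y", "z"], dtype=int).rename_axis("epoch_start")
    sec_counts = np.column_stack([a[:n_sec] for a in per_axis])

    sec_times = sig.start_time + pd.to_timedelta(np.arange(n_sec), unit="s")
    epoch_start = sec_times.floor(f"{epoch_s}s")
    df = pd.DataFrame(sec_counts, columns=["x", "y", "z"])
    df["epoch_start"] = epoch_start
    out = df.groupby("epoch_start", sort=True).sum()
    return out.astype(np.int64)


def fill_count_gaps(minute_counts: pd.Series) -> tuple[pd.Series, int]:
    """Fill missing minutes with zero counts before wear detection.

    Returns the gap-filled series (complete minute grid between the first and
    last observed minute) and the number of filled minutes.  Devices drop
    epochs occasionally; the wear detector requires a gapless grid.
    """
    idx = pd.DatetimeIndex(minute_counts.index)
    full = pd.date_range(idx.min(), idx.max(), freq="1min")
    filled = minute_counts.reindex(full)
    n_gap = int(filled.isna().sum())
    return filled.fillna(0).astype(np.int64), n_gap


def detect_nonwear(vertical_minute_counts, params: ChoiParams | None = None) -> np.ndarray:
    """Choi non-wear detection on 1-min vertical-axis counts.

    Returns a boolean wear mask (True = worn).  A minute is non-wear iff it is
    part of an interval of at least ``window_min`` minutes of zero counts,
    where interruptions of at most ``spike_tolerance_min`` consecutive nonzero
    minutes are tolerated when the ``flank_min`` minutes immediately before
    and after the interruption are all zero.  Tolerated interruptions count
    toward the interval length.  Interruptions at the series edge (with no
    full flank on one side) are genuine wear.
    """
    params = params or ChoiParams()
    c = np.asarray(vertical_minute_counts)
    if isinstance(vertical_minute_counts, pd.Series):
        c = vertical_minute_counts.to_numpy()
    if np.isnan(np.asarray(c, dtype=float)).any():
        raise ValueError("missing minutes must be gap-filled before wear detection")
    c = np.asarray(c, dtype=np.int64)
    n = len(c)
    wear = np.ones(n, dtype=bool)
    if n == 0:
        return wear

    nz = c != 0
    # run-length encode
    change = np.flatnonzero(np.diff(nz))
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [n]])
    run_nz = nz[starts]

    # a nonzero run is an 'artifactual spike' if short enough and flanked by
    # all-zero windows of flank_min on both sides
    def _is_spike(i: int) -> bool:
        if not run_nz[i]:
            return False
        if ends[i] - starts[i] > params.spike_tolerance_min:
            return False
        lo, hi = starts[i] - params.flank_min, ends[i] + params.flank_min
        if lo < 0 or hi > n:
            return False
        return not nz[lo : starts[i]].any() and not nz[ends[i] : hi].any()

    spike = np.array([_is_spike(i) for i in range(len(starts))])

    # merge zero runs across spikes into candidate intervals
    i = 0
    while i < len(starts):
        if run_nz[i]:
            i += 1
            continue
        j = i
        # extend: zero run, then (spike, zero run)* chains
        while j + 2 < len(starts) and spike[j + 1] and not run_nz[j + 2]:
            j += 2
        total = ends[j] - starts[i]
        if total >= params.window_min:
            wear[starts[i] : ends[j]] = False
        i = j + 1
    return wear


def classify_intensity(
    vertical_minute_counts,
    wear_mask,
    cuts: CutPoints | None = None,
) -> np.ndarray:
    """Label each minute sedentary/light/moderate/vigorous/nonwear.

    Worn minutes fall into exactly one closed band of the cut points; non-worn
    minutes are labelled ``nonwear`` and are excluded downstream.
    """
    cuts = cuts or CutPoints()
    c = np.asarray(vertical_minute_counts, dtype=np.int64)
    wear = np.asarray(wear_mask, dtype=bool)
    if c.shape != wear.shape:
        raise ValueError("counts and wear mask must align minute-for-minute")
    if (c < 0).any():
        raise ValueError("negative counts")
    labels = np.where(
        c <= cuts.sedentary_max,
        "sedentary",
        np.where(c <= cuts.light_max, "light", np.where(c <= cuts.moderate_max, "moderate", "vigorous")),
    )
    labels = labels.astype(object)
    labels[~wear] = "nonwear"
    return np.asarray(labels, dtype=object)


def process_minutes(
    minute_counts: pd.Series,
    choi: ChoiParams | None = None,
    cuts: CutPoints | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: gap-fill, wear-detect, classify one participant-stream.

    ``minute_counts`` is vertical-axis counts indexed by minute start.  Returns
    a frame with columns ``counts``, ``wear``, ``intensity`` indexed by minute.
    """
    filled, _ = fill_count_gaps(minute_counts)
    wear = detect_nonwear(filled, choi)
    labels = classify_intensity(filled.to_numpy(), wear, cuts)
    return pd.DataFrame(
        {"counts": filled.to_numpy(), "wear": wear, "intensity": labels},
        index=filled.index.rename("minute_start"),
    )
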