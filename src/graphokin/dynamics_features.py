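"""Kinematic, pressure, and tilt features, and full feature-vector assembly.

All dynamic features share one smoothed-derivative engine: within each stroke
the raw channels are passed through a moving-average filter (n = 10 by
default) to suppress sensor noise, every 10th point is retained, and the
derivative between consecutive retained points is formed from actual
timestamps. A measurement is kept only if the pen stayed on the surface for
the whole underlying span, so derivatives never straddle pen lifts.

From the derived series come the summary statistics (mean, max, population
std), the least-squares slope over time ("evolution"), the Gaussian-smoothed
extrema rate ("peaks per second"), and — through the packet-spectrum engine —
the bandwidth / median / distance-to-cohort frequency features.

The assembled descriptor of one recording holds 52 named scalars in a fixed
order (8 static, 12 kinematic, 10 pressure, 22 tilt); features that a
recording is too short to support are NaN, never silently imputed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import static_features as sf
from .spectral import (DegenerateSignalError, InsufficientDataError,
                       SpectralConfig, Spectrum, adaptive_packet_size,
                       cohort_mean_spectrum, mean_power_spectrum,
                       spectral_bandwidth, spectral_distance, spectral_median)
from .static_features import StaticConfig, tremor_signal
from .trace_model import Recording, segment_strokes

__all__ = [
    "DynamicsConfig",
    "DerivedSeries",
    "FeatureVector",
    "CohortReference",
    "CohortFeatures",
    "FEATURE_NAMES",
    "SPECTRAL_FAMILIES",
    "derived_speed",
    "channel_change_speed",
    "series_stats",
    "slope_over_time",
    "peaks_per_second",
    "series_spectral_features",
    "acceleration_stats",
    "in_air_time_ratio",
    "extract_features",
    "extract_cohort",
]


@dataclasses.dataclass(frozen=True)
class DynamicsConfig:
    """Parameters of the smoothed-derivative engine.

    smooth_n   : moving-average window, in raw samples.
    subsample  : keep every k-th smoothed point.
    peak_sigma : Gaussian smoothing width for extrema counting, in seconds
        (specified in time, not samples, so it survives resampling).
    spectral   : packet-spectrum configuration for the derived-series spectra.
    """

    smooth_n: int = 10
    subsample: int = 10
    peak_sigma: float = 0.25
    spectral: SpectralConfig = dataclasses.field(default_factory=SpectralConfig)

    def __post_init__(self) -> None:
        if self.smooth_n < 1 or self.subsample < 1:
            raise ValueError("smooth_n and subsample must be >= 1")
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be > 0")


@dataclasses.dataclass(frozen=True)
class DerivedSeries:
    """A derivative series on retained points.

    v holds speeds (units/s), pressure-change rates (1/s) or tilt-change
    rates (deg/s); seg labels the stroke each point came from so later
    differencing never crosses a pen lift; effective_rate = raw rate /
    subsample; on_surface_duration is the recording's total writing time in
    seconds (the denominator of the extrema-rate feature).
    """

    t: np.ndarray
    v: np.ndarray
    seg: np.ndarray
    effective_rate: float
    on_surface_duration: float

    def __len__(self) -> int:
        return len(self.v)


def _smoothed_retained(arr: np.ndarray, t: np.ndarray, cfg: DynamicsConfig):
    """Moving average (window smooth_n) then every subsample-th point."""
    n = cfg.smooth_n
    if len(arr) < n + 1:
        return None
    kernel = np.full(n, 1.0 / n)
    sm = np.convolve(arr, kernel, mode="valid")
    st = np.convolve(t, kernel, mode="valid")
    return sm[:: cfg.subsample], st[:: cfg.subsample]


def _derive(rec: Recording, channels: Sequence[str], cfg: DynamicsConfig,
            combine) -> DerivedSeries:
    ts, vs, segs = [], [], []
    for stroke in segment_strokes(rec):
        t_raw = stroke.t
        retained = [_smoothed_retained(stroke.channel(ch), t_raw, cfg) for ch in channels]
        if any(r is None for r in retained):
            continue
        t_ret = retained[0][1]
        if len(t_ret) < 2:
            continue
        dt = np.diff(t_ret)
        deltas = [np.diff(r[0]) for r in retained]
        v = combine(deltas, dt)
        ts.append(0.5 * (t_ret[1:] + t_ret[:-1]))
        vs.append(v)
        segs.append(np.full(len(v), stroke.index))
    if not vs:
        raise InsufficientDataError(
            f"no stroke long enough for the smoothing window (smooth_n={cfg.smooth_n})")
    return DerivedSeries(
        t=np.concatenate(ts), v=np.concatenate(vs), seg=np.concatenate(segs),
        effective_rate=rec.sampling_rate / cfg.subsample,
        on_surface_duration=_on_surface_duration(rec))


def derived_speed(rec: Recording, cfg: DynamicsConfig | None = None) -> DerivedSeries:
    """Pen speed: Euclidean displacement over elapsed time between retained
    points (units/s), on-surface spans only."""
    cfg = cfg or DynamicsConfig()
    return _derive(rec, ("x", "y"), cfg,
                   lambda d, dt: np.hypot(d[0], d[1]) / dt)


def channel_change_speed(rec: Recording, channel: str,
                         cfg: DynamicsConfig | None = None) -> DerivedSeries:
    """|Δ smoothed channel| / Δt for pressure (1/s) or tilt_x / tilt_y (deg/s)."""
    if channel not in ("pressure", "tilt_x", "tilt_y"):
        raise ValueError(f"unknown channel {channel!r}")
    cfg = cfg or DynamicsConfig()
    return _derive(rec, (channel,), cfg, lambda d, dt: np.abs(d[0]) / dt)


def series_stats(values: np.ndarray | DerivedSeries) -> dict[str, float]:
    """Mean, maximum, and population standard deviation."""
    v = values.v if isinstance(values, DerivedSeries) else np.asarray(values, dtype=float)
    if v.size == 0:
        return {"mean": math.nan, "max": math.nan, "std": math.nan}
    return {"mean": float(v.mean()), "max": float(v.max()), "std": float(v.std())}


def slope_over_time(s: DerivedSeries) -> float:
    """Ordinary least-squares slope of the series against time (per second)."""
    if len(s) < 2 or float(np.ptp(s.t)) == 0.0:
        return math.nan
    return float(np.polyfit(s.t, s.v, 1)[0])


def _on_surface_duration(rec: Recording) -> float:
    dt = np.diff(rec.t)
    return float(dt[rec.on_surface[:-1]].sum())


def peaks_per_second(s: DerivedSeries, cfg: DynamicsConfig | None = None) -> float:
    """Strict local extrema of the Gaussian-smoothed series per second of
    on-surface writing time."""
    cfg = cfg or DynamicsConfig()
    if len(s) < 3:
        return math.nan
    sigma_samples = cfg.peak_sigma * s.effective_rate
    smoothed = gaussian_filter1d(s.v, sigma=sigma_samples, mode="nearest")
    d = np.diff(smoothed)
    sign = np.sign(d)
    sign = sign[sign != 0]
    n_extrema = int(np.sum(sign[1:] != sign[:-1])) if sign.size > 1 else 0
    duration = s.on_surface_duration
    return n_extrema / duration if duration > 0 else math.nan


def acceleration_series(s: DerivedSeries) -> np.ndarray:
    """Finite-difference |Δv|/Δt of a speed series, within strokes only."""
    out = []
    for seg in np.unique(s.seg):
        m = s.seg == seg
        if m.sum() < 2:
            continue
        out.append(np.abs(np.diff(s.v[m])) / np.diff(s.t[m]))
    return np.concatenate(out) if out else np.array([])


def acceleration_stats(s: DerivedSeries) -> dict[str, float]:
    """Mean, max, std of the magnitude of speed change (units/s²)."""
    return series_stats(acceleration_series(s))


def in_air_time_ratio(rec: Recording) -> float:
    """Fraction of the recording's span spent with the pen off the surface.

    Each inter-sample interval is attributed to the state of its left sample.
    Sums are exact (fsum), so the ratio is independent of accumulation order.
    """
    dt = np.diff(rec.t)
    total = math.fsum(dt)
    off = math.fsum(dt[~rec.on_surface[:-1]])
    return off / total if total > 0 else math.nan


def _series_spectrum(s: DerivedSeries, cfg: SpectralConfig,
                     packet_size: int | None = None) -> Spectrum:
    if packet_size is None:
        packet_size = adaptive_packet_size(len(s), cfg)
        if packet_size is None:
            raise InsufficientDataError(
                f"series of {len(s)} points is below the minimum packet ({cfg.min_packet})")
    return mean_power_spectrum(s.v, s.effective_rate,
                               dataclasses.replace(cfg, packet_size=packet_size))


def series_spectral_features(s: DerivedSeries, ref: Spectrum | None = None,
                             cfg: SpectralConfig | None = None) -> dict[str, float]:
    """Bandwidth, median, distance-to-reference of a derived series' spectrum.

    With a reference, the spectrum is computed at the reference's packet size
    so the distance is well-defined; too-short series yield NaNs.
    """
    cfg = cfg or SpectralConfig()
    packet = len(ref.freqs) * 2 - 2 if ref is not None else None
    try:
        spec = _series_spectrum(s, cfg, packet_size=packet)
    except (InsufficientDataError, DegenerateSignalError):
        return {"bandwidth": math.nan, "median": math.nan, "distance": math.nan}
    dist = spectral_distance(spec, ref) if ref is not None else math.nan
    return {"bandwidth": spectral_bandwidth(spec, cfg.coverage),
            "median": spectral_median(spec), "distance": dist}


# ---------------------------------------------------------------------------
# Feature vector assembly

SPECTRAL_FAMILIES = ("tremor", "speed", "dpressure", "dtilt_x", "dtilt_y")

_FAMILY_COLUMN = {
    "tremor": "tremor",
    "speed": "speed_freq",
    "dpressure": "dpressure_freq",
    "dtilt_x": "dtilt_x_freq",
    "dtilt_y": "dtilt_y_freq",
}

FEATURE_NAMES: tuple[str, ...] = (
    # static (8)
    "space_between_words", "word_spacing_std", "handwriting_density",
    "handwriting_moment", "handwriting_size",
    "tremor_bandwidth", "tremor_median", "tremor_distance",
    # kinematic (12)
    "speed_mean", "speed_max", "speed_std", "speed_slope", "speed_peaks_per_s",
    "speed_freq_bandwidth", "speed_freq_median", "speed_freq_distance",
    "accel_mean", "accel_max", "accel_std", "in_air_ratio",
    # pressure (10)
    "pressure_mean", "pressure_max", "pressure_std",
    "dpressure_mean", "dpressure_max", "dpressure_std", "dpressure_peaks_per_s",
    "dpressure_freq_bandwidth", "dpressure_freq_median", "dpressure_freq_distance",
    # tilt (22)
    "tilt_x_mean", "tilt_x_max", "tilt_x_std",
    "tilt_y_mean", "tilt_y_max", "tilt_y_std",
    "dtilt_x_mean", "dtilt_x_max", "dtilt_x_std", "dtilt_x_peaks_per_s", "dtilt_x_slope",
    "dtilt_y_mean", "dtilt_y_max", "dtilt_y_std", "dtilt_y_peaks_per_s", "dtilt_y_slope",
    "dtilt_x_freq_bandwidth", "dtilt_x_freq_median", "dtilt_x_freq_distance",
    "dtilt_y_freq_bandwidth", "dtilt_y_freq_median", "dtilt_y_freq_distance",
)

DISTANCE_COLUMNS = {fam: _FAMILY_COLUMN[fam] + "_distance" for fam in SPECTRAL_FAMILIES}


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """Named scalar descriptor of one recording (fixed name set and order)."""

    values: dict[str, float]
    writer_id: str = ""
    label: str = "unknown"

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        extra = set(self.values) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValueError(f"feature set mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        object.__setattr__(self, "values",
                           {name: float(self.values[name]) for name in FEATURE_NAMES})

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.writer_id or None)

    def missing(self) -> list[str]:
        return [k for k, v in self.values.items() if math.isnan(v)]


@dataclasses.dataclass(frozen=True)
class CohortReference:
    """Training-cohort mean spectra, one per spectral family.

    Distances of a writer's spectra to these means are the "distance to mean"
    features; the reference is built from training recordings only and stored
    inside the model so test data never leak into it.
    """

    spectra: dict[str, Spectrum]
    training_ids: tuple[str, ...] = ()
    config_hash: str = ""

    def packet_size(self, family: str) -> int:
        return len(self.spectra[family].freqs) * 2 - 2


def _family_spectrum(rec: Recording, family: str, static_cfg: StaticConfig,
                     dyn_cfg: DynamicsConfig, packet_size: int | None):
    """Spectrum of one signal family for one recording, or None if too short."""
    try:
        if family == "tremor":
            return sf.tremor_spectrum(rec, static_cfg, packet_size=packet_size)
        if family == "speed":
            s = derived_speed(rec, dyn_cfg)
        else:
            s = channel_change_speed(rec, family[1:], dyn_cfg)  # dpressure -> pressure
        return _series_spectrum(s, dyn_cfg.spectral, packet_size=packet_size)
    except (InsufficientDataError, DegenerateSignalError):
        return None


def _family_series_length(rec: Recording, family: str, static_cfg: StaticConfig,
                          dyn_cfg: DynamicsConfig) -> int:
    try:
        if family == "tremor":
            return tremor_signal(rec, static_cfg).size
        if family == "speed":
            return len(derived_speed(rec, dyn_cfg))
        return len(channel_change_speed(rec, family[1:], dyn_cfg))
    except InsufficientDataError:
        return 0


def _base_features(rec: Recording, static_cfg: StaticConfig,
                   dyn_cfg: DynamicsConfig) -> dict[str, float]:
    """All features except the five distance-to-cohort ones."""
    f: dict[str, float] = dict.fromkeys(FEATURE_NAMES, math.nan)
    on = rec.on_surface

    spacing = sf.space_between_words(rec, static_cfg)
    f["space_between_words"] = spacing["mean_log_gap"]
    f["word_spacing_std"] = spacing["gap_std"]
    f["handwriting_density"] = sf.handwriting_density(rec, static_cfg)
    f["handwriting_moment"] = sf.handwriting_moment(rec, static_cfg)
    f["handwriting_size"] = sf.handwriting_size(rec, static_cfg)

    f["in_air_ratio"] = in_air_time_ratio(rec)
    if on.any():
        for ch, prefix in (("pressure", "pressure"), ("tilt_x", "tilt_x"), ("tilt_y", "tilt_y")):
            stats = series_stats(getattr(rec, ch)[on])
            for k, v in stats.items():
                f[f"{prefix}_{k}"] = v

    try:
        speed = derived_speed(rec, dyn_cfg)
    except InsufficientDataError:
        speed = None
    if speed is not None:
        for k, v in series_stats(speed).items():
            f[f"speed_{k}"] = v
        f["speed_slope"] = slope_over_time(speed)
        f["speed_peaks_per_s"] = peaks_per_second(speed, dyn_cfg)
        for k, v in acceleration_stats(speed).items():
            f[f"accel_{k}"] = v

    for channel, prefix in (("pressure", "dpressure"), ("tilt_x", "dtilt_x"),
                            ("tilt_y", "dtilt_y")):
        try:
            s = channel_change_speed(rec, channel, dyn_cfg)
        except InsufficientDataError:
            continue
        for k, v in series_stats(s).items():
            f[f"{prefix}_{k}"] = v
        f[f"{prefix}_peaks_per_s"] = peaks_per_second(s, dyn_cfg)
        if prefix != "dpressure":
            f[f"{prefix}_slope"] = slope_over_time(s)
    return f


def extract_features(rec: Recording, ref: CohortReference | None = None,
                     static_cfg: StaticConfig | None = None,
                     dyn_cfg: DynamicsConfig | None = None) -> FeatureVector:
    """Assemble the full 52-feature descriptor of one recording.

    With a :class:`CohortReference`, each spectral family is computed at the
    reference's packet size and the distance features are filled; without one
    the packet adapts to the recording and distances stay NaN. Deterministic
    given inputs and configuration. Features the recording cannot support are
    NaN; a recording supporting none raises.
    """
    static_cfg = static_cfg or StaticConfig()
    dyn_cfg = dyn_cfg or DynamicsConfig()
    f = _base_features(rec, static_cfg, dyn_cfg)
    for family in SPECTRAL_FAMILIES:
        col = _FAMILY_COLUMN[family]
        packet = ref.packet_size(family) if ref is not None and family in ref.spectra else None
        spec = _family_spectrum(rec, family, static_cfg, dyn_cfg, packet)
        if spec is None:
            continue
        cov = (SpectralConfig().coverage if family == "tremor"
               else dyn_cfg.spectral.coverage)
        f[f"{col}_bandwidth"] = spectral_bandwidth(spec, cov)
        f[f"{col}_median"] = spectral_median(spec)
        if ref is not None and family in ref.spectra:
            f[f"{col}_distance"] = spectral_distance(spec, ref.spectra[family])
    if all(math.isnan(v) for v in f.values()):
        raise InsufficientDataError("recording supports no feature at all")
    return FeatureVector(values=f, writer_id=rec.meta.id, label=rec.meta.label)


@dataclasses.dataclass
class CohortFeatures:
    """Feature table plus per-recording family spectra for a whole cohort.

    Keeping the spectra alongside the table lets an evaluation protocol
    rebuild the cohort reference — and hence the distance features — from each
    training split alone, without re-extracting anything.
    """

    features: pd.DataFrame           # rows = recordings, columns = FEATURE_NAMES
    labels: pd.Series                # "TD" / "D"
    spectra: list[dict[str, Spectrum]]   # per recording; families may be absent
    packets: dict[str, int]

    def reference(self, rows: Sequence[int] | None = None) -> CohortReference:
        """Cohort-mean reference from the given row subset (default: all)."""
        rows = range(len(self.spectra)) if rows is None else rows
        spectra = {}
        for family in SPECTRAL_FAMILIES:
            pool = [self.spectra[i][family] for i in rows if family in self.spectra[i]]
            if pool:
                spectra[family] = cohort_mean_spectrum(pool)
        return CohortReference(spectra=spectra,
                               training_ids=tuple(self.features.index[list(rows)]))

    def with_distances(self, ref: CohortReference,
                       rows: Sequence[int] | None = None) -> pd.DataFrame:
        """Copy of the feature table with distance columns recomputed
        against ``ref`` (for the given rows; default all)."""
        rows = list(range(len(self.spectra))) if rows is None else list(rows)
        table = self.features.iloc[rows].copy()
        for family, col in DISTANCE_COLUMNS.items():
            if family not in ref.spectra:
                continue
            vals = []
            for i in rows:
                spec = self.spectra[i].get(family)
                vals.append(spectral_distance(spec, ref.spectra[family])
                            if spec is not None else math.nan)
            table[col] = vals
        return table


def extract_cohort(recordings: Sequence[Recording],
                   static_cfg: StaticConfig | None = None,
                   dyn_cfg: DynamicsConfig | None = None) -> CohortFeatures:
    """Extract features for a cohort on shared spectral axes.

    Per family, the packet size is the smallest adaptive packet any recording
    in the cohort supports (capped at the configured packet), so every
    writer's spectrum lives on one axis and cohort means and distances are
    well-defined. The returned table's distance columns are filled against
    the full-cohort mean; evaluation protocols recompute them per training
    split via :meth:`CohortFeatures.with_distances`.
    """
    static_cfg = static_cfg or StaticConfig()
    dyn_cfg = dyn_cfg or DynamicsConfig()
    scfg_for = {"tremor": SpectralConfig(packet_size=static_cfg.tremor_packet,
                                         window_size=static_cfg.tremor_window)}
    packets: dict[str, int] = {}
    for family in SPECTRAL_FAMILIES:
        cfg = scfg_for.get(family, dyn_cfg.spectral)
        sizes = [adaptive_packet_size(_family_series_length(r, family, static_cfg, dyn_cfg), cfg)
                 for r in recordings]
        sizes = [s for s in sizes if s is not None]
        if sizes:
            packets[family] = min(sizes)

    spectra: list[dict[str, Spectrum]] = []
    rows, ids, labels = [], [], []
    for i, rec in enumerate(recordings):
        per_rec: dict[str, Spectrum] = {}
        for family, packet in packets.items():
            spec = _family_spectrum(rec, family, static_cfg, dyn_cfg, packet)
            if spec is not None:
                per_rec[family] = spec
        spectra.append(per_rec)
        f = _base_features(rec, static_cfg, dyn_cfg)
        for family, spec in per_rec.items():
            col = _FAMILY_COLUMN[family]
            cov = scfg_for.get(family, dyn_cfg.spectral).coverage
            f[f"{col}_bandwidth"] = spectral_bandwidth(spec, cov)
            f[f"{col}_median"] = spectral_median(spec)
        rows.append(f)
        ids.append(rec.meta.id or f"rec{i:04d}")
        labels.append(rec.meta.label)

    table = pd.DataFrame(rows, index=ids, columns=list(FEATURE_NAMES))
    cohort = CohortFeatures(features=table, labels=pd.Series(labels, index=ids),
                            spectra=spectra, packets=packets)
    cohort.features = cohort.with_distances(cohort.reference())
    return cohort
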