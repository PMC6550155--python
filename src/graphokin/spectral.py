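"""Packet-averaged normalized power spectra and their scalar summaries.

This is the frequency-domain engine shared by the tremor, speed,
pressure-change, and tilt-change features. A 1-D signal is cut into
consecutive non-overlapping packets (600 samples by default), each packet is
mean-removed, the squared magnitude of its DFT at non-negative frequencies is
taken, the per-packet powers are averaged, and the averaged power vector is
normalized to unit sum. Normalizing makes writers with different writing
amplitudes comparable: only the *shape* of the spectrum is kept.

Three scalar summaries are derived from such a spectrum:

* the **bandwidth** — width of the central frequency interval holding a given
  fraction (90% by default) of the total power, tails split symmetrically;
* the **median** — the frequency at which cumulative power first reaches 1/2;
* the **distance to a reference** — the Euclidean distance between the
  normalized power vector and a cohort-mean spectrum on the same axis.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "Spectrum",
    "SpectralConfig",
    "InsufficientDataError",
    "DegenerateSignalError",
    "mean_power_spectrum",
    "spectral_bandwidth",
    "spectral_median",
    "spectral_distance",
    "cohort_mean_spectrum",
    "adaptive_packet_size",
]

_NORM_TOL = 1e-9


class InsufficientDataError(ValueError):
    """Signal too short for the requested packet size."""


class DegenerateSignalError(ValueError):
    """Signal carries no power after mean removal (e.g. a constant)."""


@dataclasses.dataclass(frozen=True)
class SpectralConfig:
    """Parameters of the packet-spectrum pipeline.

    packet_size : samples per packet (and DFT length).
    coverage    : power fraction captured by the bandwidth summary.
    window      : taper applied per packet; "rect" (none) or "hann".
    min_packet  : floor for adaptive packet shrinking on short series.
    """

    packet_size: int = 600
    coverage: float = 0.90
    window_size: int = 10
    window: str = "rect"
    min_packet: int = 128

    def __post_init__(self) -> None:
        if self.packet_size < 2 * self.window_size:
            raise ValueError("packet_size must be >= 2 * window_size")
        if not 0.0 < self.coverage < 1.0:
            raise ValueError("coverage must be in (0, 1)")
        if self.window not in ("rect", "hann"):
            raise ValueError(f"unknown window {self.window!r}")


@dataclasses.dataclass(frozen=True)
class Spectrum:
    """A discrete normalized power spectrum with its frequency axis."""

    freqs: np.ndarray  # Hz, ascending, uniform spacing rate/packet_size
    power: np.ndarray  # non-negative, sums to 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "power", np.asarray(self.power, dtype=float))
        if self.freqs.shape != self.power.shape or self.freqs.ndim != 1:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        if np.any(self.power < -_NORM_TOL):
            raise ValueError("power must be non-negative")

    @property
    def df(self) -> float:
        """Frequency bin spacing in Hz."""
        return float(self.freqs[1] - self.freqs[0])

    def is_normalized(self) -> bool:
        return abs(float(self.power.sum()) - 1.0) <= _NORM_TOL


def _check_normalized(s: Spectrum, op: str) -> None:
    if not s.is_normalized():
        raise ValueError(f"{op} requires a unit-sum spectrum (sum={s.power.sum():g})")


def mean_power_spectrum(signal: np.ndarray, rate: float,
                        cfg: SpectralConfig | None = None) -> Spectrum:
    """Packet-averaged, unit-sum normalized power spectrum of a signal.

    The signal is split into consecutive non-overlapping packets of
    ``cfg.packet_size`` samples (trailing remainder discarded), each packet is
    mean-removed (so the zero-frequency bin carries no DC power) and optionally
    Hann-tapered, per-packet power = |rFFT|^2, powers are averaged across
    packets and normalized to unit sum.

    Raises
    ------
    InsufficientDataError : fewer samples than one packet.
    DegenerateSignalError : total power is zero (constant signal).
    """
    cfg = cfg or SpectralConfig()
    signal = np.asarray(signal, dtype=float)
    n = cfg.packet_size
    if signal.size < n:
        raise InsufficientDataError(
            f"need at least {n} samples for one packet, got {signal.size}")
    n_packets = signal.size // n
    packets = signal[: n_packets * n].reshape(n_packets, n)
    packets = packets - packets.mean(axis=1, keepdims=True)
    if cfg.window == "hann":
        packets = packets * np.hanning(n)
    power = np.abs(np.fft.rfft(packets, axis=1)) ** 2
    mean_power = power.mean(axis=0)
    total = mean_power.sum()
    if total <= 0.0:
        raise DegenerateSignalError("signal has no spectral power after mean removal")
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    return Spectrum(freqs=freqs, power=mean_power / total)


def _quantile_freq(s: Spectrum, q: float) -> float:
    """Smallest frequency whose cumulative power reaches q (left-continuous
    discrete quantile over bins)."""
    cum = np.cumsum(s.power)
    idx = int(np.searchsorted(cum, q - _NORM_TOL))
    idx = min(idx, len(s.freqs) - 1)
    return float(s.freqs[idx])


def spectral_bandwidth(s: Spectrum, coverage: float = 0.90) -> float:
    """Width (Hz) of the central interval holding ``coverage`` of the power.

    Tails are symmetric: the interval runs from the (1-c)/2 to the 1-(1-c)/2
    discrete quantile of the power-weighted frequency distribution. A
    single-bin spectrum has bandwidth 0.
    """
    _check_normalized(s, "spectral_bandwidth")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    alpha = (1.0 - coverage) / 2.0
    return _quantile_freq(s, 1.0 - alpha) - _quantile_freq(s, alpha)


def spectral_median(s: Spectrum) -> float:
    """Frequency (Hz) at which cumulative power first reaches one half."""
    _check_normalized(s, "spectral_median")
    return _quantile_freq(s, 0.5)


def spectral_distance(s: Spectrum, ref: Spectrum) -> float:
    """Euclidean distance between two unit-sum power vectors on one axis."""
    _check_normalized(s, "spectral_distance")
    _check_normalized(ref, "spectral_distance")
    if s.freqs.shape != ref.freqs.shape or not np.allclose(s.freqs, ref.freqs):
        raise ValueError("spectra live on different frequency axes; no resampling is done")
    return float(np.linalg.norm(s.power - ref.power))


def cohort_mean_spectrum(spectra: list[Spectrum]) -> Spectrum:
    """Element-wise mean of unit-sum spectra, re-normalized to unit sum.

    This is the cohort reference object the "distance to mean" features are
    measured against.
    """
    if not spectra:
        raise ValueError("cohort_mean_spectrum needs at least one spectrum")
    axis = spectra[0].freqs
    for s in spectra[1:]:
        if s.freqs.shape != axis.shape or not np.allclose(s.freqs, axis):
            raise ValueError("all spectra must share one frequency axis")
    mean = np.mean([s.power for s in spectra], axis=0)
    return Spectrum(freqs=axis.copy(), power=mean / mean.sum())


def adaptive_packet_size(series_len: int, cfg: SpectralConfig) -> int | None:
    """Packet size usable for a series of the given length.

    The configured packet when the series is long enough, else the largest
    power of two that fits, but never below ``cfg.min_packet`` — shorter
    series get ``None`` (spectral features are then reported missing).
    """
    if series_len >= cfg.packet_size:
        return cfg.packet_size
    if series_len < cfg.min_packet:
        return None
    return 1 << (series_len.bit_length() - 1)
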