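"""Pen-trace data types, file I/O, validation, stroke segmentation, truncation.

A recording is the multichannel time series a digitizer tablet produces while a
child writes: per sample the timestamp, pen position, normalized tip pressure,
the two pen inclination angles, and whether the pen touched the surface.
Hover (in-air) samples are kept in the stream — the in-air-time ratio needs
them — and are excluded from geometry downstream via the ``on_surface`` flag.

Conventions: x increases along the writing direction (left to right), y
increases downward (screen convention). Positions are in device units
(0.25 mm/unit on the reference hardware). Pressure is already normalized to
[0, 1]; calibrating raw force between tablet models is the acquisition step's
job, the loader only enforces the range. Tilt angles live in [-60, 60] degrees.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "PenSample",
    "Recording",
    "Stroke",
    "TraceFormatError",
    "TraceValidationError",
    "DegenerateRecordingError",
    "load_recording",
    "write_recording",
    "segment_strokes",
    "truncate",
]

TRACE_COLUMNS = ("t_s", "x", "y", "pressure", "tilt_x_deg", "tilt_y_deg", "on_surface")

TILT_RANGE = (-60.0, 60.0)


class TraceFormatError(ValueError):
    """A trace or sidecar file could not be parsed."""


class TraceValidationError(ValueError):
    """Parsed data violates a recording invariant (range, monotonicity...)."""


class DegenerateRecordingError(ValueError):
    """An operation would leave fewer than two samples."""


class PenSample(NamedTuple):
    """One digitizer sample."""

    t: float
    x: float
    y: float
    pressure: float
    tilt_x: float
    tilt_y: float
    on_surface: bool


@dataclasses.dataclass(frozen=True)
class WriterMeta:
    """Sidecar metadata describing the writer of a recording."""

    id: str = ""
    age: float | None = None
    gender: str = ""
    laterality: str = ""
    label: str = "unknown"  # TD | D | unknown


@dataclasses.dataclass(frozen=True)
class Recording:
    """A validated pen-trace recording.

    Channels are stored as parallel float arrays (``on_surface`` as bool).
    ``sampling_rate`` is the nominal acquisition rate in Hz; it is used only
    to build spectral frequency axes — all time computations use the actual
    timestamps, so irregular sampling (dropped frames) is tolerated.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pressure: np.ndarray
    tilt_x: np.ndarray
    tilt_y: np.ndarray
    on_surface: np.ndarray
    sampling_rate: float = 200.0
    meta: WriterMeta = dataclasses.field(default_factory=WriterMeta)

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("t", "x", "y", "pressure", "tilt_x", "tilt_y"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
        arrays["on_surface"] = np.asarray(self.on_surface, dtype=bool)
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)
        _validate_channels(arrays, self.sampling_rate)

    def __len__(self) -> int:
        return len(self.t)

    def __getitem__(self, i: int) -> PenSample:
        return PenSample(
            float(self.t[i]), float(self.x[i]), float(self.y[i]),
            float(self.pressure[i]), float(self.tilt_x[i]), float(self.tilt_y[i]),
            bool(self.on_surface[i]),
        )

    def samples(self) -> Iterator[PenSample]:
        """Iterate over the recording as :class:`PenSample` tuples."""
        for i in range(len(self)):
            yield self[i]

    @classmethod
    def from_samples(
        cls,
        samples: Sequence[PenSample],
        sampling_rate: float = 200.0,
        meta: WriterMeta | None = None,
    ) -> "Recording":
        cols = list(zip(*samples)) if samples else [[]] * 7
        return cls(
            t=np.array(cols[0], dtype=float),
            x=np.array(cols[1], dtype=float),
            y=np.array(cols[2], dtype=float),
            pressure=np.array(cols[3], dtype=float),
            tilt_x=np.array(cols[4], dtype=float),
            tilt_y=np.array(cols[5], dtype=float),
            on_surface=np.array(cols[6], dtype=bool),
            sampling_rate=sampling_rate,
            meta=meta or WriterMeta(),
        )

    @property
    def duration(self) -> float:
        """Total recorded time span, in seconds."""
        return float(self.t[-1] - self.t[0])

    def replace(self, **kwargs) -> "Recording":
        return dataclasses.replace(self, **kwargs)


def _validate_channels(arrays: dict, sampling_rate: float) -> None:
    n = len(arrays["t"])
    problems: list[str] = []
    if sampling_rate <= 0:
        problems.append(f"sampling_rate must be > 0, got {sampling_rate}")
    if n < 2:
        problems.append(f"a recording needs at least 2 samples, got {n}")
    for name, arr in arrays.items():
        if len(arr) != n:
            problems.append(f"channel {name!r} has length {len(arr)}, expected {n}")
    if problems:
        raise TraceValidationError("; ".join(problems))
    t = arrays["t"]
    if t[0] < 0:
        problems.append(f"timestamps must be >= 0 (first is {t[0]:g})")
    if not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        problems.append(f"timestamps not strictly increasing at sample {bad}")
    p = arrays["pressure"]
    if np.any((p < 0) | (p > 1)):
        problems.append("pressure outside [0, 1]")
    lo, hi = TILT_RANGE
    for name in ("tilt_x", "tilt_y"):
        v = arrays[name]
        if np.any((v < lo) | (v > hi)):
            problems.append(f"{name} outside [{lo:g}, {hi:g}]")
    for name in ("t", "x", "y", "pressure", "tilt_x", "tilt_y"):
        if not np.all(np.isfinite(arrays[name])):
            problems.append(f"channel {name!r} contains non-finite values")
    if problems:
        raise TraceValidationError("; ".join(problems))


@dataclasses.dataclass(frozen=True)
class Stroke:
    """A maximal contiguous run of on-surface samples.

    ``start``/``stop`` index the parent recording (half-open)."""

    recording: Recording
    start: int
    stop: int
    index: int

    def __len__(self) -> int:
        return self.stop - self.start

    @property
    def t(self) -> np.ndarray:
        return self.recording.t[self.start:self.stop]

    @property
    def x(self) -> np.ndarray:
        return self.recording.x[self.start:self.stop]

    @property
    def y(self) -> np.ndarray:
        return self.recording.y[self.start:self.stop]

    def channel(self, name: str) -> np.ndarray:
        return getattr(self.recording, name)[self.start:self.stop]


def segment_strokes(rec: Recording) -> list[Stroke]:
    """Split a recording into strokes (maximal on-surface runs), in time order.

    A recording with no on-surface samples yields an empty list.
    """
    mask = rec.on_surface
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    return [Stroke(rec, int(a), int(b), i) for i, (a, b) in enumerate(zip(starts, stops))]


def truncate(rec: Recording, duration: float) -> Recording:
    """Keep only the samples with ``t < rec.t[0] + duration``.

    Mirrors restricting the analysis to the first seconds of the copy test.
    Metadata and sampling rate are preserved. Idempotent.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    keep = rec.t < rec.t[0] + duration
    n = int(keep.sum())
    if n == len(rec):
        return rec
    if n < 2:
        raise DegenerateRecordingError(
            f"truncation to {duration:g} s leaves {n} sample(s)")
    return rec.replace(
        t=rec.t[:n], x=rec.x[:n], y=rec.y[:n], pressure=rec.pressure[:n],
        tilt_x=rec.tilt_x[:n], tilt_y=rec.tilt_y[:n], on_surface=rec.on_surface[:n],
    )


# ---------------------------------------------------------------------------
# File format: UTF-8 TSV with a fixed header, one row per sample, plus an
# optional flat key-value sidecar "<trace>.meta" holding writer metadata.

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta") if path.suffix != ".meta" else path


def load_recording(path: str | Path, flip_y: bool = False) -> Recording:
    """Load a trace file (and its metadata sidecar, when present).

    Parameters
    ----------
    path : trace file in the tab-separated format written by
        :func:`write_recording`.
    flip_y : negate the y axis at load, for sources whose y grows upward.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if tuple(header) != TRACE_COLUMNS:
            raise TraceFormatError(
                f"{path}: expected header {' '.join(TRACE_COLUMNS)!r}, got {' '.join(header)!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise TraceFormatError(
                    f"{path}:{lineno}: expected 7 tab-separated fields, got {len(parts)}")
            try:
                vals = tuple(float(v) for v in parts[:6])
                flag = parts[6].strip()
                if flag not in ("0", "1"):
                    raise ValueError
            except ValueError:
                raise TraceFormatError(f"{path}:{lineno}: malformed row {line.strip()!r}") from None
            rows.append(vals + (flag == "1",))
    if not rows:
        raise TraceFormatError(f"{path}: no data rows")
    cols = list(zip(*rows))
    meta, rate = _load_sidecar(_sidecar_path(path))
    y = np.array(cols[2], dtype=float)
    if flip_y:
        y = -y
    return Recording(
        t=np.array(cols[0]), x=np.array(cols[1]), y=y,
        pressure=np.array(cols[3]), tilt_x=np.array(cols[4]), tilt_y=np.array(cols[5]),
        on_surface=np.array(cols[6], dtype=bool),
        sampling_rate=rate, meta=meta,
    )


def _load_sidecar(path: Path) -> tuple[WriterMeta, float]:
    if not path.exists():
        return WriterMeta(), 200.0
    kv: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise TraceFormatError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
    age = float(kv["age"]) if kv.get("age") else None
    meta = WriterMeta(
        id=kv.get("id", ""), age=age, gender=kv.get("gender", ""),
        laterality=kv.get("laterality", ""), label=kv.get("label", "unknown"),
    )
    return meta, float(kv.get("sampling_rate_hz", 200.0))


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a trace TSV plus its metadata sidecar."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TRACE_COLUMNS) + "\n")
        for i in range(len(rec)):
            fh.write(
                f"{rec.t[i]:.6f}\t{rec.x[i]:.6f}\t{rec.y[i]:.6f}\t"
                f"{rec.pressure[i]:.6f}\t{rec.tilt_x[i]:.6f}\t{rec.tilt_y[i]:.6f}\t"
                f"{1 if rec.on_surface[i] else 0}\n")
    m = rec.meta
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        fh.write(f"id={m.id}\n")
        fh.write(f"age={'' if m.age is None else m.age:g}\n" if m.age is not None else "age=\n")
        fh.write(f"gender={m.gender}\n")
        fh.write(f"laterality={m.laterality}\n")
        fh.write(f"label={m.label}\n")
        fh.write(f"sampling_rate_hz={rec.sampling_rate:g}\n")


def validation_report(path: str | Path) -> tuple[bool, str]:
    """Validate a trace file; returns (ok, human-readable report)."""
    try:
        rec = load_recording(path)
    except (TraceFormatError, TraceValidationError, FileNotFoundError) as exc:
        return False, f"INVALID: {exc}"
    n_on = int(rec.on_surface.sum())
    return True, (
        f"OK: {len(rec)} samples, {rec.duration:.2f} s at nominal {rec.sampling_rate:g} Hz; "
        f"{n_on} on-surface ({100 * n_on / len(rec):.1f}%), "
        f"{len(segment_strokes(rec))} strokes; writer id={rec.meta.id!r} label={rec.meta.label}"
    )
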