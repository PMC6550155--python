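"""Geometry-only features of the written product.

These features look only at where ink was deposited, not at when: word
spacing, ink density on a grid, the drift of the text line, the size of
writing, and the tremor-frequency features built from the cross-product
deviance of the pen path.

The tremor construction: within consecutive windows of 10 on-surface points,
the 9 inter-point difference vectors are the "local" vectors and their mean is
the "global" direction of the movement in that window. The magnitude of the
z-component of the cross product between each local vector and the global one
measures how far the pen deviated sideways from its own short-term direction —
shaky writing produces local vectors rarely aligned with the global direction,
hence large cross products. Concatenated over the recording, these values form
a 1-D signal whose packet-averaged spectrum yields the tremor bandwidth,
median, and distance-to-cohort features.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .spectral import (InsufficientDataError, SpectralConfig, Spectrum,
                       adaptive_packet_size, mean_power_spectrum,
                       spectral_bandwidth, spectral_distance, spectral_median)
from .trace_model import Recording, Stroke, segment_strokes

__all__ = [
    "StaticConfig",
    "WordBox",
    "segment_lines",
    "segment_words",
    "space_between_words",
    "handwriting_density",
    "handwriting_moment",
    "handwriting_size",
    "tremor_signal",
    "tremor_spectrum",
    "tremor_spectral_features",
]


@dataclasses.dataclass(frozen=True)
class StaticConfig:
    """Knobs of the static features.

    word_gap_time : pen-up seconds below which neighbouring strokes are the
        same word.
    word_gap_x : horizontal bounding-box gap (device units) below which
        neighbouring strokes are the same word; both thresholds must be
        exceeded for a word break.
    density_cell_side : side of the square density-grid cells (device units).
    moment_bin / size_bin : on-surface points per bin for the line-drift and
        writing-size features.
    tremor_packet / tremor_window : spectral packet and direction-window sizes
        (in emitted values and raw points respectively).
    log_spacing : report ln(mean word gap) instead of the raw mean.
    """

    word_gap_time: float = 0.15
    word_gap_x: float = 40.0
    density_cell_side: float = 300.0
    moment_bin: int = 300
    size_bin: int = 300
    tremor_packet: int = 600
    tremor_window: int = 10
    log_spacing: bool = True

    def __post_init__(self) -> None:
        for name in ("word_gap_time", "word_gap_x", "density_cell_side",
                     "moment_bin", "size_bin", "tremor_packet", "tremor_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclasses.dataclass(frozen=True)
class WordBox:
    """Axis-aligned bounding box of one word (a run of merged strokes)."""

    line_index: int
    left: float
    right: float
    top: float
    bottom: float
    strokes: tuple[Stroke, ...]


def segment_lines(strokes: list[Stroke], cfg: StaticConfig | None = None) -> list[list[Stroke]]:
    """Group time-ordered strokes into text lines.

    A new line starts when a stroke's x-start retreats leftward by more than
    half the running line's width while its y-centroid drops by more than the
    running median stroke height. A single line is a valid outcome.
    """
    if not strokes:
        return []
    lines: list[list[Stroke]] = [[strokes[0]]]
    heights = [float(strokes[0].y.max() - strokes[0].y.min())]
    line_left = float(strokes[0].x.min())
    line_right = float(strokes[0].x.max())
    prev_ycent = float(strokes[0].y.mean())
    for s in strokes[1:]:
        x0 = float(s.x.min())
        ycent = float(s.y.mean())
        width = max(line_right - line_left, 1e-9)
        med_h = max(float(np.median(heights)), 1e-9)
        retreat = (line_right - x0) > 0.5 * width
        descent = (ycent - prev_ycent) > med_h
        if retreat and descent:
            lines.append([s])
            line_left, line_right = x0, float(s.x.max())
        else:
            lines[-1].append(s)
            line_left = min(line_left, x0)
            line_right = max(line_right, float(s.x.max()))
        heights.append(float(s.y.max() - s.y.min()))
        prev_ycent = ycent
    return lines


def segment_words(line: list[Stroke], cfg: StaticConfig | None = None,
                  line_index: int = 0) -> list[WordBox]:
    """Merge a line's strokes into words.

    Consecutive strokes stay in one word unless separated by a pen-up interval
    longer than ``word_gap_time`` AND a horizontal bounding-box gap larger
    than ``word_gap_x`` (letter spacing fails at least one threshold).
    """
    cfg = cfg or StaticConfig()
    if not line:
        return []
    groups: list[list[Stroke]] = [[line[0]]]
    for prev, cur in zip(line, line[1:]):
        pen_up = float(cur.t[0] - prev.t[-1])
        gap_x = float(cur.x.min()) - max(float(s.x.max()) for s in groups[-1])
        if pen_up > cfg.word_gap_time and gap_x > cfg.word_gap_x:
            groups.append([cur])
        else:
            groups[-1].append(cur)
    boxes = []
    for g in groups:
        xs = np.concatenate([s.x for s in g])
        ys = np.concatenate([s.y for s in g])
        boxes.append(WordBox(line_index, float(xs.min()), float(xs.max()),
                             float(ys.min()), float(ys.max()), tuple(g)))
    return boxes


def _word_gaps(rec: Recording, cfg: StaticConfig) -> np.ndarray:
    strokes = segment_strokes(rec)
    gaps: list[float] = []
    for i, line in enumerate(segment_lines(strokes, cfg)):
        words = segment_words(line, cfg, line_index=i)
        for a, b in zip(words, words[1:]):
            gaps.append(b.left - a.right)
    return np.asarray(gaps, dtype=float)


def space_between_words(rec: Recording, cfg: StaticConfig | None = None) -> dict[str, float]:
    """Mean gap between consecutive words on a line (log-transformed by
    default) and the raw standard deviation of the gaps.

    Gaps are right-edge-to-left-edge distances in device units. With fewer
    than two words anywhere both values are NaN (missing, not fatal) —
    irregular word spacing is reported via the std, a marker of poorly
    automatized writing.
    """
    cfg = cfg or StaticConfig()
    gaps = _word_gaps(rec, cfg)
    gaps = gaps[gaps > 0]
    if gaps.size == 0:
        return {"mean_log_gap": math.nan, "gap_std": math.nan}
    mean_gap = float(gaps.mean())
    feature = math.log(mean_gap) if cfg.log_spacing else mean_gap
    return {"mean_log_gap": feature, "gap_std": float(gaps.std())}


def handwriting_density(rec: Recording, cfg: StaticConfig | None = None) -> float:
    """Mean number of on-surface samples per occupied grid cell.

    A square grid (cell side ``density_cell_side``) is anchored at the trace's
    bounding-box corner; only non-empty cells enter the mean.
    """
    cfg = cfg or StaticConfig()
    on = rec.on_surface
    if not on.any():
        return math.nan
    x, y = rec.x[on], rec.y[on]
    side = cfg.density_cell_side
    ix = np.floor((x - x.min()) / side).astype(np.int64)
    iy = np.floor((y - y.min()) / side).astype(np.int64)
    _, counts = np.unique(ix * (iy.max() + 1) + iy, return_counts=True)
    return float(counts.mean())


def _line_point_bins(line: list[Stroke], bin_size: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Consecutive bins of ``bin_size`` on-surface points along one line."""
    xs = np.concatenate([s.x for s in line])
    ys = np.concatenate([s.y for s in line])
    n_bins = len(xs) // bin_size
    return [(xs[i * bin_size:(i + 1) * bin_size], ys[i * bin_size:(i + 1) * bin_size])
            for i in range(n_bins)]


def handwriting_moment(rec: Recording, cfg: StaticConfig | None = None) -> float:
    """Average |Δy| between barycenters of consecutive 300-point bins.

    A proxy for how straight the written line is: per text line, consecutive
    bins of ``moment_bin`` points are reduced to their barycenter, and the
    mean absolute vertical jump between consecutive barycenters is taken,
    averaged over lines weighted by their number of bin pairs. NaN when no
    line holds two full bins.
    """
    cfg = cfg or StaticConfig()
    deltas: list[float] = []
    for line in segment_lines(segment_strokes(rec), cfg):
        bins = _line_point_bins(line, cfg.moment_bin)
        bary_y = [float(ys.mean()) for _, ys in bins]
        deltas.extend(abs(b - a) for a, b in zip(bary_y, bary_y[1:]))
    return float(np.mean(deltas)) if deltas else math.nan


def handwriting_size(rec: Recording, cfg: StaticConfig | None = None) -> float:
    """Mean bounding-box area of consecutive 300-point bins (device units²)."""
    cfg = cfg or StaticConfig()
    areas: list[float] = []
    for line in segment_lines(segment_strokes(rec), cfg):
        for xs, ys in _line_point_bins(line, cfg.size_bin):
            areas.append(float((xs.max() - xs.min()) * (ys.max() - ys.min())))
    return float(np.mean(areas)) if areas else math.nan


def tremor_signal(rec: Recording, cfg: StaticConfig | None = None) -> np.ndarray:
    """Cross-product deviance signal of the pen path.

    Per consecutive window of ``tremor_window`` on-surface points (windows
    never straddle stroke boundaries; remainder points at stroke ends are
    skipped), the window's 9 local difference vectors are compared with their
    mean ("global") vector; each emitted value is |local × global| (z-component
    magnitude). Collinear motion emits zeros; sideways jitter emits values
    growing with its amplitude. Values are concatenated in time order.
    """
    cfg = cfg or StaticConfig()
    w = cfg.tremor_window
    out: list[np.ndarray] = []
    for stroke in segment_strokes(rec):
        n_win = len(stroke) // w
        if n_win == 0:
            continue
        pts = np.stack([stroke.x[: n_win * w], stroke.y[: n_win * w]], axis=1)
        wins = pts.reshape(n_win, w, 2)
        local = np.diff(wins, axis=1)              # (n_win, w-1, 2)
        global_vec = local.mean(axis=1, keepdims=True)
        cross = local[..., 0] * global_vec[..., 1] - local[..., 1] * global_vec[..., 0]
        out.append(np.abs(cross).ravel())
    if not out:
        raise InsufficientDataError("no complete tremor window in any stroke")
    return np.concatenate(out)


def tremor_spectrum(rec: Recording, cfg: StaticConfig | None = None,
                    packet_size: int | None = None) -> Spectrum:
    """Packet-averaged normalized power spectrum of the tremor signal.

    The signal is sampled at (approximately) the recording's nominal rate, so
    that rate defines the frequency axis. ``packet_size`` overrides the
    configured packet (used to match a cohort reference axis); otherwise the
    packet shrinks adaptively on short recordings.
    """
    cfg = cfg or StaticConfig()
    sig = tremor_signal(rec, cfg)
    scfg = SpectralConfig(packet_size=cfg.tremor_packet, window_size=cfg.tremor_window)
    if packet_size is None:
        packet_size = adaptive_packet_size(sig.size, scfg)
        if packet_size is None:
            raise InsufficientDataError(
                f"tremor series of {sig.size} values is below the minimum packet "
                f"({scfg.min_packet})")
    scfg = dataclasses.replace(scfg, packet_size=packet_size)
    return mean_power_spectrum(sig, rec.sampling_rate, scfg)


def tremor_spectral_features(rec: Recording, ref: Spectrum | None = None,
                             cfg: StaticConfig | None = None,
                             coverage: float = 0.90) -> dict[str, float]:
    """Bandwidth, median, and distance-to-reference of the tremor spectrum."""
    packet = len(ref.freqs) * 2 - 2 if ref is not None else None
    try:
        s = tremor_spectrum(rec, cfg, packet_size=packet)
    except InsufficientDataError:
        return {"bandwidth": math.nan, "median": math.nan, "distance": math.nan}
    dist = spectral_distance(s, ref) if ref is not None else math.nan
    return {
        "bandwidth": spectral_bandwidth(s, coverage),
        "median": spectral_median(s),
        "distance": dist,
    }
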