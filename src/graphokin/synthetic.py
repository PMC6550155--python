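"""Seeded generator of handwriting-like pen traces with group structure.

The generator is a test harness, not a model of children's handwriting: it
produces multi-line, multi-word traces whose low-level structure (loopy
letter oscillations, speed saccades, narrowband tremor, drifting pressure,
oscillating tilt, word gaps, in-air hops) exercises every feature extractor,
with knobs that move each feature family in a known direction.

Trajectory model: within a word the pen advances along an arc-length
parameterized chain of oscillatory letter loops at an instantaneous nominal
speed ``base_speed * exp(saccade(t))``, where the saccade process is a
piecewise-constant log-factor jumping at a Poisson rate (abrupt multiplicative
speed changes). Narrowband tremor (a phase-diffused sinusoid around
``tremor_freq``) is added to both coordinates. Between words the pen lifts
for an in-air hop sized to realize the profile's target in-air time fraction;
lines break after a fixed number of words. Pressure follows a clipped
mean-reverting (AR(1)) process; each tilt angle is a base value plus a
phase-diffused sinusoid plus optional broadband jitter.

Determinism: a (profile, seed) pair always yields byte-identical recordings;
cohort generation spawns one independent stream per writer from the cohort
seed, so adding writers never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .trace_model import Recording, WriterMeta

# Relative amplitude of the secondary x oscillation shaping the letter loops.
# Kept small so the loop's radius of curvature stays above the arc the pen
# covers during the extractor's smoothing window; tighter loops would alias
# letter geometry into the speed spectrum as deep chord-shortening dips.
_LOOP_WIGGLE = 0.02

__all__ = [
    "WriterProfile",
    "CohortSpec",
    "generate_trace",
    "generate_cohort",
    "default_profiles",
]


@dataclasses.dataclass(frozen=True)
class WriterProfile:
    """All knobs of one synthetic writer.

    Geometry is in device units (0.25 mm/unit nominal), times in seconds,
    angles in degrees. Each knob maps to a feature family: tremor_amplitude →
    the tremor signal and its spectrum; speed_saccade_rate/magnitude → the
    speed spectrum; word_gap_mean/std → word spacing; in_air_fraction → the
    in-air time ratio; tilt_*_change_freq → the tilt-change spectral median;
    tilt_x_jitter → the tilt-x change spectral bandwidth.
    """

    base_speed: float = 320.0            # units/s along the pen path
    speed_saccade_rate: float = 1.5      # jumps per second
    saccade_magnitude: float = 0.20      # std of the log speed factor
    tremor_amplitude: float = 0.4        # units, added to x and y
    tremor_freq: float = 8.0             # Hz (physiological-tremor band)
    pressure_mean: float = 0.55
    pressure_change_rate: float = 0.30   # diffusion of the pressure process, 1/sqrt(s)
    tilt_x_base: float = 20.0
    tilt_y_base: float = -30.0
    tilt_x_change_freq: float = 1.5      # Hz
    tilt_x_change_amp: float = 4.0       # deg
    tilt_x_jitter: float = 0.5           # deg, broadband component
    tilt_y_change_freq: float = 3.0
    tilt_y_change_amp: float = 4.0
    tilt_y_jitter: float = 0.5
    word_gap_mean: float = 140.0         # units between word boxes
    word_gap_std: float = 25.0
    in_air_fraction: float = 0.18        # target fraction of time off-surface
    letters_per_word: int = 5
    words_per_line: int = 6
    n_lines: int = 10                    # lines per page (extra gap after)
    duration: float = 300.0              # s (a 5-minute copy test)
    rate: float = 200.0                  # Hz
    letter_width: float = 110.0
    letter_height: float = 44.0
    line_height: float = 400.0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.rate <= 0:
            raise ValueError("duration and rate must be positive")
        if not 0.0 <= self.in_air_fraction < 1.0:
            raise ValueError("in_air_fraction must be in [0, 1)")
        for name in ("base_speed", "speed_saccade_rate", "saccade_magnitude",
                     "tremor_amplitude", "tremor_freq", "pressure_change_rate",
                     "tilt_x_change_amp", "tilt_y_change_amp", "tilt_x_jitter",
                     "tilt_y_jitter", "word_gap_mean", "word_gap_std"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kwargs) -> "WriterProfile":
        return dataclasses.replace(self, **kwargs)


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """A two-group synthetic cohort.

    Per-writer profiles are drawn around the group profiles with a small
    multiplicative jitter so writers are not clones. Cohort sizes default to
    the 242 typically-developing / 56 dysgraphic imbalance of the reference
    clinical study design.
    """

    n_td: int = 242
    n_d: int = 56
    td_profile: WriterProfile | None = None
    d_profile: WriterProfile | None = None
    seed: int = 0
    jitter: float = 0.07     # relative spread of per-writer parameters

    def __post_init__(self) -> None:
        if self.n_td < 0 or self.n_d < 0:
            raise ValueError("cohort sizes must be >= 0")


def default_profiles(separation: str = "standard") -> dict[str, WriterProfile]:
    """Group profiles realizing the documented group contrasts.

    The dysgraphic (D) profile differs from the typically-developing (TD) one
    in the directions reported for real cohorts: more tremor, more and larger
    speed saccades, slower writing, smaller and more variable word gaps, more
    in-air time, slower tilt-y modulation, broader-band tilt-x jitter, and
    livelier pressure dynamics. Effect sizes are chosen clearly separable
    (≈2 pooled SD per manipulated knob); ``separation="hard"`` shrinks every
    manipulated difference to a quarter (≈0.5 SD) for power-style experiments.
    """
    td = WriterProfile()
    d_changes = dict(
        tremor_amplitude=2.0,       # ↑ tremor bandwidth in D
        speed_saccade_rate=4.0,     # ↑ speed-frequency median in D
        saccade_magnitude=0.50,
        base_speed=240.0,           # D writes slower
        word_gap_mean=80.0,         # ↓ space between words in D
        word_gap_std=40.0,          # more irregular spacing in D
        in_air_fraction=0.28,       # ↑ in-air ratio in D
        tilt_y_change_freq=1.2,     # ↓ tilt-y change-frequency median in D
        tilt_x_jitter=3.0,          # ↑ tilt-x change-frequency bandwidth in D
        pressure_change_rate=0.45,
    )
    if separation == "hard":
        d_changes = {k: getattr(td, k) + 0.25 * (v - getattr(td, k))
                     for k, v in d_changes.items()}
    elif separation != "standard":
        raise ValueError(f"unknown separation preset {separation!r}")
    return {"td": td, "d": td.replace(**d_changes)}


def _narrowband(rng: np.random.Generator, freq: float, t: np.ndarray,
                dt: float, phase_diffusion: float = 1.5) -> np.ndarray:
    """Unit-amplitude sinusoid at ``freq`` with a diffusing phase (narrow
    spectral line of width set by ``phase_diffusion``, rad/sqrt(s))."""
    walk = np.cumsum(rng.normal(0.0, phase_diffusion * np.sqrt(dt), t.size))
    phase0 = rng.uniform(0, 2 * np.pi)
    return np.sin(2 * np.pi * freq * t + phase0 + walk)


def _ar1(rng: np.random.Generator, n: int, dt: float, tau: float,
         sigma: float) -> np.ndarray:
    """Zero-mean mean-reverting (OU-like) process, relaxation time ``tau`` s,
    diffusion ``sigma`` per sqrt(s)."""
    a = np.exp(-dt / tau)
    noise = rng.normal(0.0, sigma * np.sqrt(dt), n)
    return lfilter([1.0], [1.0, -a], noise)


def _saccade_log_factor(rng: np.random.Generator, t: np.ndarray,
                        profile: WriterProfile) -> np.ndarray:
    """Piecewise-constant log speed factor jumping at a Poisson rate."""
    out = np.zeros(t.size)
    if profile.speed_saccade_rate <= 0 or profile.saccade_magnitude <= 0:
        return out
    total = t[-1] if t.size else 0.0
    n_events = max(16, int(2 * profile.speed_saccade_rate * total) + 8)
    gaps = rng.exponential(1.0 / profile.speed_saccade_rate, n_events)
    while gaps.sum() < total:
        gaps = np.concatenate([gaps, rng.exponential(1.0 / profile.speed_saccade_rate, n_events)])
    times = np.cumsum(gaps)
    times = times[times < total]
    levels = rng.normal(0.0, profile.saccade_magnitude, times.size + 1)
    return levels[np.searchsorted(times, t, side="right")]


def _letter_arclength_table(profile: WriterProfile) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative arc length along one letter loop, for inverse arc-length
    parameterization: advancing the pen by true arc length makes its measured
    speed equal the nominal (saccade-modulated) speed, independent of where
    on the loop it is."""
    phi = np.linspace(0.0, 1.0, 2001)
    x = profile.letter_width * phi + _LOOP_WIGGLE * profile.letter_width * np.sin(4 * np.pi * phi)
    y = 0.5 * profile.letter_height * np.sin(2 * np.pi * phi)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
    return phi, s


def generate_trace(profile: WriterProfile, seed: int,
                   meta: WriterMeta | None = None) -> Recording:
    """Generate one recording of exactly ``round(duration * rate)`` samples."""
    rng = np.random.default_rng(seed)
    n = int(round(profile.duration * profile.rate))
    if n < 2:
        raise ValueError("profile duration too short for a recording")
    dt = 1.0 / profile.rate
    t = np.arange(n) * dt

    v_nom = profile.base_speed * np.exp(_saccade_log_factor(rng, t, profile))
    arc = np.cumsum(v_nom * dt)
    trem_x = profile.tremor_amplitude * _narrowband(rng, profile.tremor_freq, t, dt)
    trem_y = profile.tremor_amplitude * _narrowband(rng, profile.tremor_freq, t, dt)

    pressure = np.clip(
        profile.pressure_mean + _ar1(rng, n, dt, tau=1.5, sigma=profile.pressure_change_rate),
        0.02, 1.0)
    tilt = {}
    for axis, base, freq, amp, jitter in (
            ("x", profile.tilt_x_base, profile.tilt_x_change_freq,
             profile.tilt_x_change_amp, profile.tilt_x_jitter),
            ("y", profile.tilt_y_base, profile.tilt_y_change_freq,
             profile.tilt_y_change_amp, profile.tilt_y_jitter)):
        sig = base + amp * _narrowband(rng, freq, t, dt, phase_diffusion=0.8)
        if jitter > 0:
            jit = _ar1(rng, n, dt, tau=0.08, sigma=jitter * 3.0)
            sig = sig + jit
        tilt[axis] = np.clip(sig, -59.9, 59.9)

    phi_grid, s_grid = _letter_arclength_table(profile)
    p_len = float(s_grid[-1])
    word_arc = profile.letters_per_word * p_len
    air_ratio = profile.in_air_fraction / (1.0 - profile.in_air_fraction)
    margin = 100.0
    hover_lift = 40.0

    x = np.empty(n)
    y = np.empty(n)
    on = np.ones(n, dtype=bool)

    i = 0
    x_cursor, line_y = margin, 200.0
    word_in_line = 0
    lines_done = 0
    pen_end = (x_cursor, line_y)
    while i < n:
        # --- write one word ---
        rel = arc - arc[i] + v_nom[i] * dt
        j = int(np.searchsorted(rel, rel[i] - v_nom[i] * dt + word_arc))
        j = min(max(j, i + 1), n)
        s_rel = rel[i:j] - (rel[i] - v_nom[i] * dt)
        letter_idx = np.floor(s_rel / p_len)
        frac = np.interp(s_rel - letter_idx * p_len, s_grid, phi_grid)
        phi = letter_idx + frac
        x[i:j] = (x_cursor + profile.letter_width * phi
                  + _LOOP_WIGGLE * profile.letter_width * np.sin(4 * np.pi * phi)
                  + trem_x[i:j])
        y[i:j] = (line_y + 0.5 * profile.letter_height * np.sin(2 * np.pi * phi)
                  + trem_y[i:j])
        word_time = (j - i) * dt
        word_right = x_cursor + profile.letter_width * float(phi[-1])
        pen_end = (float(x[j - 1]), float(y[j - 1]))
        i = j
        if i >= n:
            break

        # --- lift the pen: word gap, line break, or page break ---
        word_in_line += 1
        if word_in_line >= profile.words_per_line:
            word_in_line = 0
            lines_done += 1
            x_next = margin
            line_y += profile.line_height
            if lines_done % profile.n_lines == 0:
                line_y += 2.0 * profile.line_height  # page break
        else:
            gap = max(rng.normal(profile.word_gap_mean, profile.word_gap_std), 5.0)
            x_next = word_right + gap
        air_t = air_ratio * word_time
        m = max(1, int(round(air_t * profile.rate)))
        m = min(m, n - i)
        u = (np.arange(m) + 1.0) / (m + 1.0)
        x[i:i + m] = pen_end[0] + (x_next - pen_end[0]) * u
        y[i:i + m] = pen_end[1] + (line_y - pen_end[1]) * u - hover_lift * np.sin(np.pi * u)
        on[i:i + m] = False
        i += m
        x_cursor = x_next

    pressure = np.where(on, pressure, 0.0)
    return Recording(t=t, x=x, y=y, pressure=pressure,
                     tilt_x=tilt["x"], tilt_y=tilt["y"], on_surface=on,
                     sampling_rate=profile.rate, meta=meta or WriterMeta())


_JITTERED = (
    "base_speed", "speed_saccade_rate", "saccade_magnitude", "tremor_amplitude",
    "tremor_freq", "pressure_mean", "pressure_change_rate", "tilt_x_change_freq",
    "tilt_x_change_amp", "tilt_x_jitter", "tilt_y_change_freq", "tilt_y_change_amp",
    "tilt_y_jitter", "word_gap_mean", "word_gap_std",
)


def _draw_profile(rng: np.random.Generator, base: WriterProfile,
                  jitter: float) -> WriterProfile:
    changes = {name: getattr(base, name) * float(np.exp(rng.normal(0.0, jitter)))
               for name in _JITTERED}
    changes["in_air_fraction"] = float(np.clip(
        base.in_air_fraction + rng.normal(0.0, 0.02), 0.02, 0.6))
    changes["tilt_x_base"] = base.tilt_x_base + float(rng.normal(0.0, 3.0))
    changes["tilt_y_base"] = base.tilt_y_base + float(rng.normal(0.0, 3.0))
    return base.replace(**changes)


def generate_cohort(spec: CohortSpec) -> tuple[list[Recording], pd.DataFrame]:
    """Generate a labeled cohort.

    Returns the recordings (TD first, then D, writer ids ``td0000``/``d0000``)
    and a ground-truth table of every drawn per-writer parameter, for
    parameter-recovery tests.
    """
    profiles = default_profiles()
    td_base = spec.td_profile or profiles["td"]
    d_base = spec.d_profile or profiles["d"]
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(spec.n_td + spec.n_d)

    recordings: list[Recording] = []
    rows = []
    for k, stream in enumerate(streams):
        label = "TD" if k < spec.n_td else "D"
        base = td_base if label == "TD" else d_base
        wid = f"td{k:04d}" if label == "TD" else f"d{k - spec.n_td:04d}"
        rng = np.random.default_rng(stream)
        profile = _draw_profile(rng, base, spec.jitter)
        trace_seed = int(rng.integers(0, 2**31 - 1))
        meta = WriterMeta(id=wid, age=float(rng.integers(6, 13)),
                          gender=rng.choice(["f", "m"]), laterality="R", label=label)
        recordings.append(generate_trace(profile, trace_seed, meta=meta))
        row = {"id": wid, "label": label, "trace_seed": trace_seed}
        row.update(dataclasses.asdict(profile))
        rows.append(row)
    truth = pd.DataFrame(rows).set_index("id")
    return recordings, truth
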