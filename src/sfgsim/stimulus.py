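"""Stochastic figure-ground ("tone cloud") stimulus generation.

A stimulus is a sequence of brief chords, each a set of concurrent pure
tones drawn from a fixed log-spaced frequency grid.  In figure stimuli a
subset of the tones (the "figure") moves coherently upward in frequency
across consecutive chords; the remaining tones are background drawn i.i.d.
uniformly from the grid.  Stimuli exist both symbolically (a
:class:`ToneMatrix` of grid indices with figure/background role labels) and
as rendered 16-bit PCM audio with ISO 226 equal-loudness weighting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .errors import InfeasibleSpecError, InvalidParameterError, NormalizationError
from .iso226 import EqualLoudnessTable

__all__ = [
    "FrequencyGrid",
    "ToneCloudSpec",
    "ToneMatrix",
    "AudioWaveform",
    "build_frequency_grid",
    "default_grid",
    "sample_tone_cloud",
    "synthesize_audio",
    "write_wav",
    "matched_nofigure",
]

#: Study design constants: 40 chords x 50 ms = 2000 ms, grid of 129
#: log-spaced frequencies spanning 179-7246 Hz, 10-chord (500 ms) figures,
#: figure onset drawn from chord positions 7-31 (1-based) so the figure
#: always fits, 20 tones per chord in the low-noise condition.
N_CHORDS = 40
CHORD_DUR_MS = 50.0
GRID_FMIN = 179.0
GRID_FMAX = 7246.0
GRID_N = 129
FIGURE_LEN = 10
FIGURE_ONSET_RANGE = (7, 31)  # 1-based, inclusive
#: One semitone per chord transition = 2 steps on the half-semitone grid.
FIGURE_STEP = 2
TONES_PER_CHORD = 20
SAMPLE_RATE = 44100


@dataclass(frozen=True)
class FrequencyGrid:
    f_min: float
    f_max: float
    n_values: int
    values: np.ndarray

    @property
    def ratio(self) -> float:
        """Constant ratio between adjacent grid frequencies."""
        return (self.f_max / self.f_min) ** (1.0 / (self.n_values - 1))


def build_frequency_grid(f_min: float = GRID_FMIN, f_max: float = GRID_FMAX,
                         n: int = GRID_N) -> FrequencyGrid:
    """Log-equally spaced frequency grid spanning [f_min, f_max]."""
    if f_min <= 0 or f_max <= f_min:
        raise InvalidParameterError(
            f"need 0 < f_min < f_max, got ({f_min}, {f_max})")
    if n < 2:
        raise InvalidParameterError(f"grid needs at least 2 values, got {n}")
    values = np.geomspace(f_min, f_max, n)
    # pin the endpoints exactly
    values[0], values[-1] = f_min, f_max
    return FrequencyGrid(f_min=f_min, f_max=f_max, n_values=n, values=values)


def default_grid() -> FrequencyGrid:
    return build_frequency_grid()


@dataclass(frozen=True)
class ToneCloudSpec:
    """Parametric description of one stimulus.

    ``coherence`` is the number of figure tones per figure chord;
    ``n_background`` the number of background tones per chord *within* the
    figure span.  Every chord of the stimulus carries
    ``coherence + n_background`` tones in total, so figure and no-figure
    chords are indistinguishable by tone count.
    """

    has_figure: bool
    coherence: int = 0
    n_background: int = TONES_PER_CHORD
    n_chords: int = N_CHORDS
    chord_dur_ms: float = CHORD_DUR_MS
    figure_len: int = FIGURE_LEN
    figure_onset_chord: int | None = None  # 1-based; None -> drawn at sampling
    figure_step: int = FIGURE_STEP
    seed: int | None = None

    def __post_init__(self):
        if self.coherence < 0 or self.n_background < 0:
            raise InvalidParameterError("tone counts must be non-negative")
        if self.coherence + self.n_background < 1:
            raise InvalidParameterError("a chord needs at least one tone")
        if self.has_figure:
            if self.coherence < 1:
                raise InvalidParameterError("figure stimuli need coherence >= 1")
            if (self.figure_onset_chord is not None
                    and self.figure_onset_chord + self.figure_len - 1 > self.n_chords):
                raise InvalidParameterError("figure does not fit in the stimulus")

    @property
    def tones_per_chord(self) -> int:
        return self.coherence + self.n_background

    @property
    def duration_ms(self) -> float:
        return self.n_chords * self.chord_dur_ms


def matched_nofigure(spec: ToneCloudSpec) -> ToneCloudSpec:
    """No-figure counterpart with the same total tone count per chord."""
    return ToneCloudSpec(has_figure=False, coherence=0,
                         n_background=spec.tones_per_chord,
                         n_chords=spec.n_chords, chord_dur_ms=spec.chord_dur_ms,
                         figure_len=spec.figure_len, figure_step=spec.figure_step)


@dataclass
class ToneMatrix:
    """Realized stimulus: per-chord grid indices and role labels."""

    indices: list  # list of int arrays, one per chord
    is_figure: list  # parallel list of bool arrays
    spec: ToneCloudSpec
    figure_onset_chord: int | None  # 1-based, None for no-figure stimuli

    def tone_counts(self) -> np.ndarray:
        return np.array([len(ix) for ix in self.indices])

    def figure_counts(self) -> np.ndarray:
        return np.array([int(np.sum(f)) for f in self.is_figure])

    def to_json_dict(self) -> dict:
        d = asdict(self.spec)
        return {
            "spec": d,
            "figure_onset_chord": self.figure_onset_chord,
            "indices": [ix.tolist() for ix in self.indices],
            "is_figure": [f.tolist() for f in self.is_figure],
        }


def sample_tone_cloud(spec: ToneCloudSpec, grid: FrequencyGrid,
                      rng: np.random.Generator | None = None) -> ToneMatrix:
    """Draw one stimulus realization.

    Background tone indices are i.i.d. uniform over the grid (duplicates
    within a chord allowed).  Figure tones start at distinct grid indices
    (sampled without replacement) and each advances ``figure_step`` indices
    per chord for ``figure_len`` consecutive chords.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = grid.n_values
    total = spec.tones_per_chord

    onset = None
    traj_starts = None
    if spec.has_figure:
        span = spec.figure_step * (spec.figure_len - 1)
        n_valid_starts = n - span
        if n_valid_starts < spec.coherence:
            raise InfeasibleSpecError(
                f"coherence {spec.coherence} exceeds the {n_valid_starts} "
                f"valid figure start indices on this grid")
        if spec.figure_onset_chord is not None:
            onset = spec.figure_onset_chord
        else:
            lo, hi = FIGURE_ONSET_RANGE
            hi = min(hi, spec.n_chords - spec.figure_len + 1)
            onset = int(rng.integers(lo, hi + 1))
        if onset + spec.figure_len - 1 > spec.n_chords:
            raise InfeasibleSpecError("figure onset leaves no room for the figure")
        traj_starts = rng.choice(n_valid_starts, size=spec.coherence,
                                 replace=False)

    indices, roles = [], []
    for chord in range(1, spec.n_chords + 1):
        in_figure = (spec.has_figure
                     and onset <= chord < onset + spec.figure_len)
        if in_figure:
            k = chord - onset
            fig_idx = traj_starts + k * spec.figure_step
            bg_idx = rng.integers(0, n, size=spec.n_background)
            idx = np.concatenate([fig_idx, bg_idx])
            role = np.zeros(len(idx), dtype=bool)
            role[: spec.coherence] = True
        else:
            idx = rng.integers(0, n, size=total)
            role = np.zeros(total, dtype=bool)
        indices.append(idx.astype(int))
        roles.append(role)
    return ToneMatrix(indices=indices, is_figure=roles, spec=spec,
                      figure_onset_chord=onset)


@dataclass
class AudioWaveform:
    sample_rate: int
    samples: np.ndarray
    bit_depth: int = 16

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.sample_rate


def _chord_envelope(n_samples: int, ramp_samples: int) -> np.ndarray:
    """Raised-cosine (cos^2) on/off ramps within one chord slot."""
    env = np.ones(n_samples)
    t = np.arange(ramp_samples) / ramp_samples
    ramp = np.sin(0.5 * np.pi * t) ** 2
    env[:ramp_samples] = ramp
    env[-ramp_samples:] = ramp[::-1]
    return env


def synthesize_audio(matrix: ToneMatrix, grid: FrequencyGrid,
                     loudness: EqualLoudnessTable | None = None,
                     sample_rate: int = SAMPLE_RATE,
                     ramp_ms: float = 10.0,
                     target_rms: float = 0.05) -> AudioWaveform:
    """Render a tone matrix to audio.

    Each tone is a sine at its grid frequency scaled by its 60-phon
    equal-loudness gain, shaped by 10 ms raised-cosine ramps inside its
    chord slot; chords abut with zero inter-chord interval.  The summed
    waveform is RMS-normalized to ``target_rms`` (skipped for silence) and
    must not clip afterwards.
    """
    if loudness is None:
        loudness = EqualLoudnessTable.for_grid(grid.values)
    spec = matrix.spec
    chord_samples = int(round(spec.chord_dur_ms / 1000.0 * sample_rate))
    n_total = spec.n_chords * chord_samples
    ramp_samples = int(round(ramp_ms / 1000.0 * sample_rate))
    env = _chord_envelope(chord_samples, ramp_samples)
    t = np.arange(chord_samples) / sample_rate

    wave = np.zeros(n_total)
    for c, idx in enumerate(matrix.indices):
        if len(idx) == 0:
            continue
        freqs = grid.values[idx]
        gains = loudness.gains[idx]
        chord = (gains[:, None] * np.sin(2 * np.pi * freqs[:, None] * t)).sum(axis=0)
        wave[c * chord_samples:(c + 1) * chord_samples] = chord * env

    rms = float(np.sqrt(np.mean(wave ** 2)))
    if rms > 0:
        wave = wave * (target_rms / rms)
        peak = float(np.max(np.abs(wave)))
        if peak > 1.0:
            raise NormalizationError(
                f"normalized waveform clips (peak {peak:.3f} > 1); "
                f"lower target_rms")
    return AudioWaveform(sample_rate=sample_rate, samples=wave)


def write_wav(wave: AudioWaveform, path) -> None:
    """Write 16-bit PCM mono RIFF/WAVE."""
    samples = np.clip(wave.samples, -1.0, 1.0)
    pcm = np.round(samples * 32767.0).astype(np.int16)
    wavfile.write(str(path), wave.sample_rate, pcm)


def read_wav(path) -> AudioWaveform:
    sr, pcm = wavfile.read(str(path))
    return AudioWaveform(sample_rate=int(sr),
                         samples=pcm.astype(float) / 32767.0)


def write_sidecar(matrix: ToneMatrix, path) -> None:
    """JSON sidecar recording the full spec and realized tone matrix."""
    Path(path).write_text(json.dumps(matrix.to_json_dict(), indent=1))
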