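"""Synthetic listeners, audiograms, and EEG for simulated experiments.

Everything the real experiment measures from humans is emulated here:

* :class:`ObserverModel` — a simulated listener whose probability of
  reporting a figure is a Weibull function of the figure:background SNR
  (parametric kind) or who applies a noisy decision rule to the longest
  temporally coherent run in the symbolic stimulus (stimulus-domain kind).
* Audiogram profiles and the hearing-group classification rule (elderly
  with any hearing threshold above 45 dB count as mildly hearing impaired).
* Continuous multichannel EEG containing ORN- and P400-like deflections
  time-locked to figure onsets, 1/f noise, and occasional large artifacts.

Group-level defaults encode the reference cohort structure: 20 young, 13
normal-hearing elderly, and 16 hearing-impaired elderly listeners, with
hearing-impaired listeners requiring higher figure coherence, and ORN
latency delayed in the elderly groups (280 ms young vs. 421 ms elderly).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import IncompleteAudiogramError, InvalidParameterError
from .quest import PsychometricParams, weibull_p_yes
from .stimulus import ToneCloudSpec, ToneMatrix, FrequencyGrid, default_grid, \
    sample_tone_cloud, TONES_PER_CHORD

__all__ = [
    "ObserverModel",
    "ParticipantProfile",
    "ErpTemplate",
    "CohortConfig",
    "AUDIOMETRY_FREQS",
    "EEG_CHANNELS",
    "EEG_SFREQ",
    "classify_hearing_group",
    "generate_cohort",
    "coherence_statistic",
    "SessionTrial",
    "build_session_schedule",
    "generate_session_eeg",
    "save_session",
    "load_session",
    "young_template",
    "elderly_template",
]

AUDIOMETRY_FREQS = (250, 500, 1000, 2000, 4000, 6000, 8000)
EEG_CHANNELS = ("C3", "Cz", "C4", "P3", "Pz", "P4")
EEG_SFREQ = 1000.0


# ---------------------------------------------------------------------------
# Observers

@dataclass
class ObserverModel:
    """Simulated yes/no listener.

    ``kind='parametric'``: p(yes | figure stimulus) is a Weibull function of
    the stimulus SNR (figure:background tone ratio).  The ``threshold``
    of ``psychometric`` is expressed as a coherence level under 20-tone
    chords and converted to an SNR threshold internally, which makes the
    same observer consistent across the coherence staircase (total tones
    fixed) and the background staircase (background added at fixed
    coherence).  On no-figure stimuli the yes rate is ``false_alarm_rate``.

    ``kind='stimulus'``: responds to the realized tone matrix — yes iff the
    longest coherent run statistic plus Gaussian internal noise exceeds
    ``criterion``.

    Reaction times are drawn from a shifted lognormal.
    """

    kind: str = "parametric"
    psychometric: PsychometricParams = field(
        default_factory=lambda: PsychometricParams(threshold=10.0))
    false_alarm_rate: float = 0.2
    total_tones: int = TONES_PER_CHORD
    internal_noise_sd: float = 1.0
    criterion: float = 5.0
    rt_shift_ms: float = 150.0
    rt_mu: float = math.log(150.0)
    rt_sigma: float = 0.4
    grid: FrequencyGrid | None = None

    def __post_init__(self):
        if not 0 <= self.false_alarm_rate <= 1:
            raise InvalidParameterError("false_alarm_rate must be in [0,1]")
        if self.rt_shift_ms < 0:
            raise InvalidParameterError("RT shift must be non-negative")

    @property
    def _snr_threshold(self) -> float:
        c = self.psychometric.threshold
        b = self.total_tones - c
        if b <= 0:
            raise InvalidParameterError(
                "coherence threshold must leave background tones in the chord")
        return c / b

    def p_yes(self, spec: ToneCloudSpec) -> float:
        """Long-run yes probability for a parametric observer."""
        if self.kind != "parametric":
            raise InvalidParameterError("p_yes is defined for parametric observers")
        if not spec.has_figure:
            return self.false_alarm_rate
        if spec.n_background == 0:
            return 1.0 - self.psychometric.lapse
        snr = spec.coherence / spec.n_background
        return float(weibull_p_yes(snr, self.psychometric,
                                   threshold=self._snr_threshold))

    def p_yes_at(self, coherence: int, n_background: int) -> float:
        return self.p_yes(ToneCloudSpec(has_figure=True, coherence=coherence,
                                        n_background=n_background))

    def respond(self, spec: ToneCloudSpec,
                rng: np.random.Generator) -> tuple[bool, float]:
        """One trial: (yes/no response, reaction time in ms)."""
        if self.kind == "parametric":
            p = self.p_yes(spec)
        elif self.kind == "stimulus":
            grid = self.grid if self.grid is not None else default_grid()
            matrix = sample_tone_cloud(spec, grid, rng)
            return self.respond_matrix(matrix, rng)
        else:
            raise InvalidParameterError(f"unknown observer kind {self.kind!r}")
        yes = bool(rng.random() < p)
        rt = self.rt_shift_ms + float(rng.lognormal(self.rt_mu, self.rt_sigma))
        return yes, rt

    def respond_matrix(self, matrix: ToneMatrix,
                       rng: np.random.Generator) -> tuple[bool, float]:
        stat = coherence_statistic(matrix)
        noisy = stat + float(rng.normal(0.0, self.internal_noise_sd))
        yes = bool(noisy > self.criterion)
        rt = self.rt_shift_ms + float(rng.lognormal(self.rt_mu, self.rt_sigma))
        return yes, rt


def coherence_statistic(matrix: ToneMatrix) -> int:
    """Longest run of tones advancing exactly ``figure_step`` grid indices
    across consecutive chords (the temporal-coherence cue a figure creates).

    A full figure of length L yields L; no-figure clouds concentrate at
    small values because chance alignments are short.
    """
    step = matrix.spec.figure_step
    best = 1 if matrix.indices else 0
    prev: dict[int, int] = {}
    for idx in matrix.indices:
        cur: dict[int, int] = {}
        for i in set(int(v) for v in idx):
            run = prev.get(i - step, 0) + 1
            if run > cur.get(i, 0):
                cur[i] = run
        if cur:
            best = max(best, max(cur.values()))
        prev = cur
    return best


# ---------------------------------------------------------------------------
# ERP templates

@dataclass
class ErpTemplate:
    """Gaussian-bump ERP components injected at figure onset.

    Latencies are template centers in ms from figure onset; widths are
    Gaussian FWHM in ms.  Channel weights encode the components' scalp
    geometry: the ORN is fronto-central with left dominance
    (C3 > Cz >= C4), the P400 parietal with a midline maximum
    (Pz > P3/P4).
    """

    orn_amplitude_uv: float = -3.0
    orn_latency_ms: float = 280.0
    orn_width_ms: float = 80.0
    orn_weights: dict = field(default_factory=lambda: {
        "C3": 1.0, "Cz": 0.8, "C4": 0.7})
    p400_amplitude_uv: float = 4.0
    p400_latency_ms: float = 750.0
    p400_width_ms: float = 150.0
    p400_weights: dict = field(default_factory=lambda: {
        "Pz": 1.0, "P3": 0.75, "P4": 0.75})
    noise_sd_uv: float = 8.0
    artifact_rate_per_min: float = 2.0
    artifact_amplitude_uv: float = 150.0

    def __post_init__(self):
        if self.orn_amplitude_uv >= 0:
            raise InvalidParameterError("ORN amplitude must be negative")
        if self.p400_amplitude_uv <= 0:
            raise InvalidParameterError("P400 amplitude must be positive")


def young_template(**overrides) -> ErpTemplate:
    """Young-adult defaults: ORN at 280 ms, full-amplitude P400."""
    return ErpTemplate(**overrides)


def elderly_template(hearing_impaired: bool = False, **overrides) -> ErpTemplate:
    """Elderly defaults: ORN delayed to 421 ms, P400 scaled to 0.7x young."""
    kw = dict(orn_latency_ms=421.0, p400_amplitude_uv=4.0 * 0.7)
    kw.update(overrides)
    return ErpTemplate(**kw)


# ---------------------------------------------------------------------------
# Participants and cohorts

@dataclass
class ParticipantProfile:
    id: str
    age_group: str  # "young" | "elderly"
    audiogram: dict  # {"left": {freq: dB}, "right": {freq: dB}}
    digit_span_forward: int
    digit_span_backward: int
    observer: ObserverModel
    erp_template: ErpTemplate

    def mean_ht(self) -> float:
        """Average hearing threshold across frequencies and ears (dB)."""
        vals = [self.audiogram[ear][f] for ear in ("left", "right")
                for f in AUDIOMETRY_FREQS]
        return float(np.mean(vals))

    def to_json_dict(self) -> dict:
        return {
            "id": self.id, "age_group": self.age_group,
            "audiogram": {e: {str(f): v for f, v in d.items()}
                          for e, d in self.audiogram.items()},
            "digit_span_forward": self.digit_span_forward,
            "digit_span_backward": self.digit_span_backward,
            "coherence_threshold": self.observer.psychometric.threshold,
            "group": classify_hearing_group(self)[0],
        }


def classify_hearing_group(profile: ParticipantProfile) -> tuple[str, bool]:
    """(group label, excluded flag) from age and the audiogram.

    Elderly listeners with any hearing threshold above 45 dB are labeled
    ``"elderly_hi"`` (mild hearing loss), the rest ``"elderly_nh"``; young
    listeners are ``"young"``.  A maximal inter-ear threshold difference of
    20 dB or more at any frequency sets the exclusion flag.
    """
    for ear in ("left", "right"):
        if ear not in profile.audiogram:
            raise IncompleteAudiogramError(f"missing {ear} ear audiogram")
        missing = [f for f in AUDIOMETRY_FREQS if f not in profile.audiogram[ear]]
        if missing:
            raise IncompleteAudiogramError(
                f"{ear} ear audiogram missing frequencies {missing}")
    left = np.array([profile.audiogram["left"][f] for f in AUDIOMETRY_FREQS])
    right = np.array([profile.audiogram["right"][f] for f in AUDIOMETRY_FREQS])
    excluded = bool(np.max(np.abs(left - right)) >= 20)
    if profile.age_group == "young":
        return "young", excluded
    any_above = bool(np.max(np.concatenate([left, right])) > 45)
    return ("elderly_hi" if any_above else "elderly_nh"), excluded


@dataclass
class CohortConfig:
    """Group sizes and per-group generative distributions.

    Coherence thresholds (the coherence level at which the observer hits
    the 85% point under 20-tone chords) are Gaussian per group; the
    hearing-impaired elderly mean sits 3 coherence units above the
    normal-hearing elderly mean, the built-in group effect the analyses
    should recover.
    """

    n_young: int = 20
    n_elderly_nh: int = 13
    n_elderly_hi: int = 16
    threshold_mean: dict = field(default_factory=lambda: {
        "young": 10.5, "elderly_nh": 11.0, "elderly_hi": 14.0})
    threshold_sd: float = 1.2
    threshold_clip: tuple[float, float] = (4.0, 17.0)
    slope: float = 3.5
    guess: float = 0.2
    lapse: float = 0.02
    master_seed: int = 0

    def __post_init__(self):
        if min(self.n_young, self.n_elderly_nh, self.n_elderly_hi) < 1:
            raise InvalidParameterError("group sizes must be >= 1")


def _sample_audiogram(group: str, rng: np.random.Generator) -> dict:
    """Audiogram consistent with the group label.

    Young: flat, mild thresholds.  Elderly: sloping high-frequency loss;
    the hearing-impaired variant guarantees at least one threshold above
    45 dB (at 4-8 kHz), the normal-hearing variant is capped at 42 dB.
    """
    freqs = np.array(AUDIOMETRY_FREQS, dtype=float)
    if group == "young":
        base = rng.normal(10.0, 3.0, size=len(freqs))
        left = np.clip(base, 0, 25)
    elif group == "elderly_nh":
        slope = np.interp(np.log10(freqs), [np.log10(250), np.log10(8000)],
                          [0.0, 18.0])
        base = rng.normal(16.0, 4.0, size=len(freqs)) + slope
        left = np.clip(base, 5, 42)
    elif group == "elderly_hi":
        slope = np.interp(np.log10(freqs), [np.log10(250), np.log10(8000)],
                          [0.0, 30.0])
        base = rng.normal(25.0, 5.0, size=len(freqs)) + slope
        left = np.clip(base, 10, 70)
        hi_band = freqs >= 4000
        if left[hi_band].max() <= 45:  # enforce the defining criterion
            left[np.argmax(freqs == 4000)] = 46.0 + rng.uniform(0, 10)
    else:
        raise InvalidParameterError(f"unknown group {group!r}")
    right = np.clip(left + rng.normal(0.0, 3.0, size=len(freqs)),
                    left - 15, left + 15)
    to_dict = lambda arr: {int(f): float(round(v, 1))
                           for f, v in zip(AUDIOMETRY_FREQS, arr)}
    return {"left": to_dict(left), "right": to_dict(right)}


def generate_cohort(cfg: CohortConfig,
                    rng: np.random.Generator | None = None
                    ) -> list[ParticipantProfile]:
    """Draw a full cohort of simulated participants.

    Deterministic given ``cfg.master_seed`` (or an explicit generator).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.master_seed))
    plan = ([("young", cfg.n_young), ("elderly_nh", cfg.n_elderly_nh),
             ("elderly_hi", cfg.n_elderly_hi)])
    cohort = []
    counter = 0
    for group, size in plan:
        for _ in range(size):
            counter += 1
            thr = float(np.clip(rng.normal(cfg.threshold_mean[group],
                                           cfg.threshold_sd),
                                *cfg.threshold_clip))
            psych = PsychometricParams(threshold=thr, slope=cfg.slope,
                                       guess=cfg.guess, lapse=cfg.lapse,
                                       target_p=0.85)
            observer = ObserverModel(psychometric=psych,
                                     false_alarm_rate=cfg.guess)
            audiogram = _sample_audiogram(group, rng)
            if group == "young":
                fwd = int(np.clip(round(rng.normal(6.8, 0.9)), 4, 9))
                bwd = int(np.clip(round(rng.normal(5.3, 0.9)), 3, 8))
                template = young_template()
                age_group = "young"
            else:
                fwd = int(np.clip(round(rng.normal(5.8, 0.9)), 3, 9))
                bwd = int(np.clip(round(rng.normal(4.3, 0.9)), 2, 8))
                template = elderly_template(hearing_impaired=(group == "elderly_hi"))
                age_group = "elderly"
            profile = ParticipantProfile(
                id=f"p{counter:03d}", age_group=age_group, audiogram=audiogram,
                digit_span_forward=fwd, digit_span_backward=bwd,
                observer=observer, erp_template=template)
            label, _ = classify_hearing_group(profile)
            if label != group:
                raise InvalidParameterError(
                    f"generated audiogram inconsistent with group {group}")
            cohort.append(profile)
    return cohort


def write_cohort_json(cohort, path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_json_dict() for p in cohort], fh, indent=1)


# ---------------------------------------------------------------------------
# Synthetic continuous EEG

def _pink_noise(n_samples: int, n_channels: int, sd: float,
                sfreq: float, rng: np.random.Generator) -> np.ndarray:
    """Per-channel independent 1/f-amplitude Gaussian noise, scaled to `sd`."""
    if sd == 0:
        return np.zeros((n_channels, n_samples))
    n_fft = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    scale = np.zeros(n_fft)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal((n_channels, n_fft))
            + 1j * rng.standard_normal((n_channels, n_fft))) * scale
    noise = np.fft.irfft(spec, n=n_samples, axis=1)
    noise *= sd / noise.std(axis=1, keepdims=True)
    return noise


def _gaussian_bump(times_ms: np.ndarray, center_ms: float,
                   fwhm_ms: float) -> np.ndarray:
    sigma = fwhm_ms / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return np.exp(-0.5 * ((times_ms - center_ms) / sigma) ** 2)


@dataclass
class SessionTrial:
    """One trial slot of an EEG session schedule (times in ms)."""
    condition: str          # "LN" | "HN"
    has_figure: bool
    stim_start_ms: float
    figure_onset_ms: float  # relative to stimulus start (assigned for no-figure)
    correct: bool


def build_session_schedule(trials, rng: np.random.Generator,
                           lead_in_ms: float = 1000.0,
                           spacing_ms: tuple[float, float] = (4200.0, 4800.0),
                           ) -> list[SessionTrial]:
    """Lay out trials in session time and assign figure onsets.

    `trials` is an iterable of dicts with keys ``condition``, ``has_figure``
    and ``correct``.  Figure trials get an onset drawn uniformly from the
    chord positions 7-31 (300-1550 ms); no-figure trials reuse the figure
    trials' onsets, each exactly once (padded with fresh draws if no-figure
    trials outnumber figure trials).
    """
    trials = list(trials)
    fig_idx = [i for i, t in enumerate(trials) if t["has_figure"]]
    nofig_idx = [i for i, t in enumerate(trials) if not t["has_figure"]]
    chord = 50.0

    def draw_onset():
        return float((rng.integers(7, 32) - 1) * chord)

    onsets = [None] * len(trials)
    fig_onsets = []
    for i in fig_idx:
        onsets[i] = draw_onset()
        fig_onsets.append(onsets[i])
    pool = list(fig_onsets)
    rng.shuffle(pool)
    while len(pool) < len(nofig_idx):
        pool.append(draw_onset())
    for i, onset in zip(nofig_idx, pool):
        onsets[i] = onset

    out = []
    t0 = lead_in_ms
    for i, tr in enumerate(trials):
        out.append(SessionTrial(condition=tr.get("condition", "LN"),
                                has_figure=bool(tr["has_figure"]),
                                stim_start_ms=t0,
                                figure_onset_ms=float(onsets[i]),
                                correct=bool(tr.get("correct", True))))
        t0 += float(rng.uniform(*spacing_ms))
    return out


def generate_session_eeg(profile: ParticipantProfile,
                         schedule: list[SessionTrial],
                         rng: np.random.Generator,
                         sfreq: float = EEG_SFREQ,
                         tail_ms: float = 3500.0):
    """Continuous EEG for one session plus its event list.

    The record is per-channel pink noise; every *correct* figure trial adds
    the profile's ORN and P400 Gaussian bumps time-locked to the figure
    onset, weighted over channels; artifact segments (300 ms Hann bursts on
    all channels) occur as a Poisson process at the template's rate.

    Returns ``(data, events)`` where ``data`` is channels x samples in µV
    over :data:`EEG_CHANNELS` and each event is a dict with the onset
    sample, condition, figure flag and correctness.
    """
    if not schedule:
        raise InvalidParameterError("empty session schedule")
    tpl = profile.erp_template
    end_ms = max(t.stim_start_ms for t in schedule) + 2000.0 + tail_ms
    n_samples = int(round(end_ms / 1000.0 * sfreq))
    n_ch = len(EEG_CHANNELS)
    data = _pink_noise(n_samples, n_ch, tpl.noise_sd_uv, sfreq, rng)

    times_ms = np.arange(n_samples) / sfreq * 1000.0
    events = []
    for tr in schedule:
        onset_ms = tr.stim_start_ms + tr.figure_onset_ms
        sample = int(round(onset_ms / 1000.0 * sfreq))
        if sample >= n_samples:
            raise InvalidParameterError("schedule extends past the record")
        events.append({"sample": sample, "condition": tr.condition,
                       "has_figure": tr.has_figure, "correct": tr.correct})
        if not (tr.has_figure and tr.correct):
            continue
        lo = max(0, sample - int(sfreq))  # bump support window
        hi = min(n_samples, sample + int(2.5 * sfreq))
        seg = times_ms[lo:hi] - onset_ms
        orn = tpl.orn_amplitude_uv * _gaussian_bump(seg, tpl.orn_latency_ms,
                                                    tpl.orn_width_ms)
        p400 = tpl.p400_amplitude_uv * _gaussian_bump(seg, tpl.p400_latency_ms,
                                                      tpl.p400_width_ms)
        for ci, ch in enumerate(EEG_CHANNELS):
            w_orn = tpl.orn_weights.get(ch, 0.0)
            w_p4 = tpl.p400_weights.get(ch, 0.0)
            if w_orn or w_p4:
                data[ci, lo:hi] += w_orn * orn + w_p4 * p400

    # artifacts: Poisson bursts
    if tpl.artifact_rate_per_min > 0 and tpl.artifact_amplitude_uv != 0:
        duration_min = n_samples / sfreq / 60.0
        n_art = rng.poisson(tpl.artifact_rate_per_min * duration_min)
        width = int(0.3 * sfreq)
        burst = np.hanning(width) * tpl.artifact_amplitude_uv
        for _ in range(n_art):
            s = int(rng.integers(0, max(1, n_samples - width)))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            data[:, s:s + width] += sign * burst[: data.shape[1] - s]
    return data, events


def save_session(path_prefix, data: np.ndarray, events: list) -> None:
    """Internal interchange format: .npy array + JSON event list."""
    np.save(str(path_prefix) + "_eeg.npy", data)
    with open(str(path_prefix) + "_events.json", "w") as fh:
        json.dump({"sfreq": EEG_SFREQ, "channels": list(EEG_CHANNELS),
                   "events": events}, fh)


def load_session(path_prefix):
    data = np.load(str(path_prefix) + "_eeg.npy")
    with open(str(path_prefix) + "_events.json") as fh:
        meta = json.load(fh)
    return data, meta["events"]
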