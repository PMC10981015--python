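"""Sensor-level ERP processing on synthetic continuous EEG.

The chain mirrors a conventional ERP workflow: zero-phase band-pass
filtering (Kaiser-windowed FIR), epoch extraction around figure onsets,
pre-stimulus baseline correction, amplitude-threshold artifact rejection,
condition averaging, and window-based component measurement (window-mean
amplitude and peak latency).  A sign-flip permutation paired t-test covers
the design's permutation contrasts at the sensor level.

Conventions: sampling at 1 kHz, epochs span the half-open window
[-800, +2300) ms relative to figure onset (3100 samples), baselines use
[-800, 0).  The ORN is measured 250-350 ms (young) or 350-550 ms (elderly)
at C3/Cz/C4 with negative polarity; the P400 650-850 ms at P3/Pz/P4 with
positive polarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import EmptyConditionError, InvalidParameterError

__all__ = [
    "ContinuousEEG",
    "EpochSet",
    "EvokedResponse",
    "ErpMeasurement",
    "bandpass_filter",
    "extract_epochs",
    "baseline_correct",
    "reject_artifacts",
    "average_evoked",
    "window_measures",
    "permutation_paired_ttest",
    "ORN_WINDOWS_MS",
    "P400_WINDOW_MS",
]

#: Component measurement windows (ms from figure onset).
ORN_WINDOWS_MS = {"young": (250.0, 350.0), "elderly": (350.0, 550.0)}
P400_WINDOW_MS = (650.0, 850.0)

#: Band-pass defaults: 0.5-80 Hz Kaiser-window FIR, beta = 5.65326.
FILTER_LOW_HZ = 0.5
FILTER_HIGH_HZ = 80.0
KAISER_BETA = 5.65326
FILTER_NUMTAPS = 18112


@dataclass
class ContinuousEEG:
    ch_names: list
    sfreq: float
    data: np.ndarray  # channels x samples, µV
    events: list      # dicts: sample, condition, has_figure, correct

    def __post_init__(self):
        if self.sfreq <= 0:
            raise InvalidParameterError("sample rate must be positive")
        n = self.data.shape[1]
        for ev in self.events:
            if not 0 <= ev["sample"] < n:
                raise InvalidParameterError(
                    f"event sample {ev['sample']} outside the record")


def bandpass_filter(eeg: ContinuousEEG, low: float = FILTER_LOW_HZ,
                    high: float = FILTER_HIGH_HZ,
                    numtaps: int = FILTER_NUMTAPS,
                    beta: float = KAISER_BETA) -> ContinuousEEG:
    """Zero-phase band-pass with a Kaiser-windowed linear-phase FIR.

    An even tap count is bumped to the next odd value so the symmetric
    impulse response has an integer group delay and 'same'-mode
    convolution is exactly zero-phase.
    """
    nyq = eeg.sfreq / 2.0
    if not 0 < low < high < nyq:
        raise InvalidParameterError(
            f"need 0 < low < high < Nyquist ({nyq} Hz)")
    if numtaps % 2 == 0:
        numtaps += 1
    if numtaps > eeg.data.shape[1]:
        raise InvalidParameterError("filter longer than the record")
    taps = signal.firwin(numtaps, [low, high], window=("kaiser", beta),
                         pass_zero=False, fs=eeg.sfreq)
    filtered = np.empty_like(eeg.data)
    for ci in range(eeg.data.shape[0]):
        filtered[ci] = signal.fftconvolve(eeg.data[ci], taps, mode="same")
    return ContinuousEEG(ch_names=list(eeg.ch_names), sfreq=eeg.sfreq,
                         data=filtered, events=list(eeg.events))


@dataclass
class EpochSet:
    data: np.ndarray        # epochs x channels x samples, µV
    times_ms: np.ndarray    # per-sample latency from figure onset
    ch_names: list
    meta: pd.DataFrame      # condition, has_figure, accepted
    window_ms: tuple

    def accepted(self) -> np.ndarray:
        return self.meta["accepted"].to_numpy(dtype=bool)


def extract_epochs(eeg: ContinuousEEG,
                   window_ms: tuple = (-800.0, 2300.0),
                   only_correct: bool = True) -> EpochSet:
    """Cut one epoch per (correct-response) event.

    The epoch covers the half-open sample window
    [onset + start, onset + stop) so a [-800, 2300) ms window at 1 kHz
    yields 3100 samples.  Events whose window would cross a record edge
    are skipped with a warning.
    """
    start = int(round(window_ms[0] / 1000.0 * eeg.sfreq))
    stop = int(round(window_ms[1] / 1000.0 * eeg.sfreq))
    n = eeg.data.shape[1]
    epochs, meta = [], []
    for ev in eeg.events:
        if only_correct and not ev.get("correct", True):
            continue
        lo, hi = ev["sample"] + start, ev["sample"] + stop
        if lo < 0 or hi > n:
            warnings.warn(f"event at sample {ev['sample']} too close to the "
                          f"record edge; epoch skipped")
            continue
        epochs.append(eeg.data[:, lo:hi])
        meta.append({"condition": ev.get("condition", ""),
                     "has_figure": bool(ev.get("has_figure", True)),
                     "accepted": True})
    data = (np.stack(epochs) if epochs
            else np.empty((0, eeg.data.shape[0], stop - start)))
    times = (np.arange(start, stop) / eeg.sfreq) * 1000.0
    return EpochSet(data=data, times_ms=times, ch_names=list(eeg.ch_names),
                    meta=pd.DataFrame(meta, columns=["condition", "has_figure",
                                                     "accepted"]),
                    window_ms=tuple(window_ms))


def baseline_correct(epochs: EpochSet,
                     baseline_ms: tuple = (-800.0, 0.0)) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    lo, hi = baseline_ms
    if lo < epochs.window_ms[0] or hi > epochs.window_ms[1]:
        raise InvalidParameterError("baseline outside the epoch window")
    mask = (epochs.times_ms >= lo) & (epochs.times_ms < hi)
    if not mask.any():
        raise InvalidParameterError("baseline window contains no samples")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(data=epochs.data - base, times_ms=epochs.times_ms,
                    ch_names=epochs.ch_names, meta=epochs.meta.copy(),
                    window_ms=epochs.window_ms)


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 100.0,
                     mode: str = "absolute") -> EpochSet:
    """Flag artifact epochs.

    ``mode="absolute"`` (default): reject an epoch whose absolute amplitude
    exceeds the threshold at any sample of any channel.
    ``mode="peak_to_peak"``: reject when any channel's range within the
    epoch exceeds twice the threshold.
    """
    if mode == "absolute":
        bad = np.abs(epochs.data).max(axis=(1, 2)) > threshold_uv
    elif mode == "peak_to_peak":
        ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)
        bad = ptp.max(axis=1) > 2 * threshold_uv
    else:
        raise InvalidParameterError(f"unknown rejection mode {mode!r}")
    meta = epochs.meta.copy()
    meta["accepted"] = epochs.meta["accepted"].to_numpy() & ~bad
    return EpochSet(data=epochs.data, times_ms=epochs.times_ms,
                    ch_names=epochs.ch_names, meta=meta,
                    window_ms=epochs.window_ms)


@dataclass
class EvokedResponse:
    condition: str
    data: np.ndarray      # channels x samples, µV
    times_ms: np.ndarray
    ch_names: list
    n_epochs: int


def average_evoked(epochs: EpochSet,
                   condition: str | None = None) -> EvokedResponse:
    """Pointwise mean over accepted epochs (optionally one condition)."""
    keep = epochs.accepted()
    if condition is not None:
        keep = keep & (epochs.meta["condition"] == condition).to_numpy()
    if not keep.any():
        raise EmptyConditionError(
            f"no accepted epochs for condition {condition!r}")
    return EvokedResponse(condition=condition or "all",
                          data=epochs.data[keep].mean(axis=0),
                          times_ms=epochs.times_ms,
                          ch_names=list(epochs.ch_names),
                          n_epochs=int(keep.sum()))


@dataclass
class ErpMeasurement:
    component: str              # "ORN" | "P400"
    channels: list
    window_ms: tuple
    window_mean_uv: dict        # channel -> mean amplitude
    peak_latency_ms: dict       # channel -> latency of the polarity extremum
    polarity: int               # -1 for ORN, +1 for P400


_COMPONENT_DEFAULTS = {
    "ORN": {"channels": ("C3", "Cz", "C4"), "polarity": -1},
    "P400": {"channels": ("P3", "Pz", "P4"), "polarity": +1},
}


def window_measures(evoked: EvokedResponse, component: str,
                    window_ms: tuple,
                    channels: tuple | None = None) -> ErpMeasurement:
    """Window-mean amplitude and peak latency for one ERP component.

    The peak is the extremum of the component's polarity (most negative
    sample for the ORN, most positive for the P400) within the window,
    found on the averaged waveform per channel.
    """
    if component not in _COMPONENT_DEFAULTS:
        raise InvalidParameterError(f"unknown component {component!r}")
    defaults = _COMPONENT_DEFAULTS[component]
    channels = defaults["channels"] if channels is None else channels
    polarity = defaults["polarity"]
    lo, hi = window_ms
    mask = (evoked.times_ms >= lo) & (evoked.times_ms < hi)
    if not mask.any():
        raise InvalidParameterError("measurement window outside the data")
    t_win = evoked.times_ms[mask]
    means, peaks = {}, {}
    for ch in channels:
        if ch not in evoked.ch_names:
            raise InvalidParameterError(f"channel {ch!r} not in the evoked data")
        trace = evoked.data[evoked.ch_names.index(ch), mask]
        means[ch] = float(trace.mean())
        idx = int(np.argmin(trace) if polarity < 0 else np.argmax(trace))
        peaks[ch] = float(t_win[idx])
    return ErpMeasurement(component=component, channels=list(channels),
                          window_ms=tuple(window_ms), window_mean_uv=means,
                          peak_latency_ms=peaks, polarity=polarity)


def permutation_paired_ttest(a, b, n_perm: int = 1000, alpha: float = 0.01,
                             rng: np.random.Generator | None = None
                             ) -> dict:
    """Paired t-test with a sign-flip permutation null.

    The null distribution is built by randomly flipping the signs of the
    per-subject differences; the two-sided p-value is
    (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1).  Zero-variance differences
    are degenerate and return p = 1 with a flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise InvalidParameterError("need equal-length samples, n >= 3")
    if rng is None:
        rng = np.random.default_rng()
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        return {"t": 0.0 if np.allclose(d, 0) else np.inf, "p": 1.0,
                "significant": False, "degenerate": True, "alpha": alpha}
    t_obs = d.mean() / (sd / np.sqrt(n))
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    flipped = signs * d
    means = flipped.mean(axis=1)
    sds = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = means / (sds / np.sqrt(n))
    count = int(np.sum(np.abs(t_perm) >= abs(t_obs)))
    p = (1 + count) / (n_perm + 1)
    return {"t": float(t_obs), "p": float(p), "significant": bool(p < alpha),
            "degenerate": False, "alpha": alpha}
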