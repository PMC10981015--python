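"""Equal-loudness weighting from the ISO 226:2003 contour parameters.

The standard tabulates three parameters (the exponent ``alpha_f``, the
magnitude of the linear transfer function ``L_U`` in dB, and the hearing
threshold ``T_f`` in dB SPL) at 29 preferred frequencies between 20 Hz and
12.5 kHz.  The sound pressure level of a pure tone perceived as equally loud
as a 1 kHz tone at ``L_N`` phon is

    A_f = 4.47e-3 (10**(0.025 L_N) - 1.15) + (0.4 * 10**((T_f + L_U)/10 - 9))**alpha_f
    L_p = (10 / alpha_f) log10(A_f) - L_U + 94

Gains returned here are linear amplitude factors relative to 1 kHz at the
same phon level, so the gain at 1 kHz is exactly 1.  Parameters are
interpolated on a log-frequency axis for frequencies between the tabulated
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = ["ISO226_FREQS", "iso226_spl", "iso226_gain", "EqualLoudnessTable"]

# ISO 226:2003, Table 1: frequency (Hz), alpha_f, L_U (dB), T_f (dB SPL)
_TABLE = np.array([
    (20.0, 0.532, -31.6, 78.5),
    (25.0, 0.506, -27.2, 68.7),
    (31.5, 0.480, -23.0, 59.5),
    (40.0, 0.455, -19.1, 51.1),
    (50.0, 0.432, -15.9, 44.0),
    (63.0, 0.409, -13.0, 37.5),
    (80.0, 0.387, -10.3, 31.5),
    (100.0, 0.367, -8.1, 26.5),
    (125.0, 0.349, -6.2, 22.1),
    (160.0, 0.330, -4.5, 17.9),
    (200.0, 0.315, -3.1, 14.4),
    (250.0, 0.301, -2.0, 11.4),
    (315.0, 0.288, -1.1, 8.6),
    (400.0, 0.276, -0.4, 6.2),
    (500.0, 0.267, 0.0, 4.4),
    (630.0, 0.259, 0.3, 3.0),
    (800.0, 0.253, 0.5, 2.2),
    (1000.0, 0.250, 0.0, 2.4),
    (1250.0, 0.246, -2.7, 3.5),
    (1600.0, 0.244, -4.1, 1.7),
    (2000.0, 0.243, -1.0, -1.3),
    (2500.0, 0.243, 1.7, -4.2),
    (3150.0, 0.243, 2.5, -6.0),
    (4000.0, 0.242, 1.2, -5.4),
    (5000.0, 0.242, -2.1, -1.5),
    (6300.0, 0.245, -7.1, 6.0),
    (8000.0, 0.254, -11.2, 12.6),
    (10000.0, 0.271, -10.7, 13.9),
    (12500.0, 0.301, -3.1, 12.3),
])

ISO226_FREQS = _TABLE[:, 0]
_LOG_F = np.log10(ISO226_FREQS)


def _params_at(freq):
    """Interpolate (alpha_f, L_U, T_f) on log-frequency."""
    freq = np.asarray(freq, dtype=float)
    if np.any(freq < ISO226_FREQS[0]) or np.any(freq > ISO226_FREQS[-1]):
        raise InvalidParameterError(
            f"frequency outside the 20-12500 Hz range covered by ISO 226: {freq}"
        )
    lf = np.log10(freq)
    alpha = np.interp(lf, _LOG_F, _TABLE[:, 1])
    l_u = np.interp(lf, _LOG_F, _TABLE[:, 2])
    t_f = np.interp(lf, _LOG_F, _TABLE[:, 3])
    return alpha, l_u, t_f


def iso226_spl(freq, phon):
    """SPL (dB) of a pure tone at `freq` Hz equally loud as 1 kHz at `phon`."""
    if not 0 <= phon <= 90:
        raise InvalidParameterError(f"phon level must be in [0, 90], got {phon}")
    alpha, l_u, t_f = _params_at(freq)
    a_f = (4.47e-3 * (10.0 ** (0.025 * phon) - 1.15)
           + (0.4 * 10.0 ** ((t_f + l_u) / 10.0 - 9.0)) ** alpha)
    return (10.0 / alpha) * np.log10(a_f) - l_u + 94.0


def iso226_gain(freq, phon):
    """Linear amplitude gain equalizing loudness relative to 1 kHz.

    A frequency that needs a higher SPL than 1 kHz for equal loudness gets a
    gain > 1.  ``iso226_gain(1000, p) == 1`` for any admissible phon level.
    """
    spl = iso226_spl(freq, phon)
    ref = iso226_spl(1000.0, phon)
    return 10.0 ** ((spl - ref) / 20.0)


@dataclass
class EqualLoudnessTable:
    """Per-frequency gain lookup for a fixed phon level."""

    phon: float = 60.0
    frequencies: np.ndarray = field(default=None)  # type: ignore[assignment]
    gains: np.ndarray = field(default=None)  # type: ignore[assignment]

    @classmethod
    def for_grid(cls, frequencies, phon: float = 60.0) -> "EqualLoudnessTable":
        freqs = np.asarray(frequencies, dtype=float)
        return cls(phon=phon, frequencies=freqs, gains=iso226_gain(freqs, phon))

    def gain_for(self, freq: float) -> float:
        idx = int(np.argmin(np.abs(self.frequencies - freq)))
        if not np.isclose(self.frequencies[idx], freq, rtol=1e-9):
            raise InvalidParameterError(f"{freq} Hz is not a table frequency")
        return float(self.gains[idx])
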