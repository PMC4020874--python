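"""Rapidly changing corneal deformations: opening residual, border signals,
spectra and band decomposition.

The corneal deflection map L_TR mixes the slow air-puff indentation
(tens of milliseconds) with fast oscillations of the corneal surface in
the 150-500 Hz band.  A flat grayscale opening with a 33×33 structuring
element -- large compared with one oscillation period, small compared
with the puff -- passes only the slow content, so the residual

    L_Q = L_TR - opening(L_TR)

retains the fast deformations.  Two scalar time signals L_QL(i) and
L_QR(i) average L_Q over lateral column bands left and right of the
corneal apex (the image borders themselves are identically zero after the
eyeball separation, and the apex is dominated by the indentation).  Their
one-sided FFT magnitude spectra F_QL/F_QR quantify the oscillation, and
inverse-FFT band masks split each signal into a slow component (region I,
below 150 Hz) and a fast component (region II, 200-500 Hz).  Frequencies
in the deliberate 150-200 Hz gap between the regions belong to neither.

Spectral conventions: no window (rectangular), no zero padding; array
index k of the one-sided spectrum is the harmonic number, i.e. frequency
k / (I · frame_interval_s), with DC at k = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_sequences import ConfigError, DimensionError, Map2D, TooShortError

__all__ = [
    "SE2_DEFAULT",
    "REGION_I_MAX_HZ",
    "REGION_II_HZ",
    "FastDynamics",
    "grayscale_opening",
    "fast_component",
    "default_border_bands",
    "border_signals",
    "spectrum",
    "band_components",
    "compute_fast_dynamics",
]

#: Flat structuring element for the opening, (columns, frames).  33 frames
#: at 231 µs span ~7.6 ms, longer than one period of any 150-500 Hz
#: oscillation, so the opening removes the fast content from its output.
SE2_DEFAULT = (33, 33)

#: Region I: constant and slowly changing content, strictly below this (Hz).
REGION_I_MAX_HZ = 150.0

#: Region II: periodic rapidly changing content, from this frequency up (Hz).
#: The upper limit is open (None = up to Nyquist): the region is defined by
#: its lower edge; 150-500 Hz is the empirically observed oscillation range,
#: not a mask edge, and cutting the mask at 500 Hz would smear the time
#: support of short oscillation bursts over the few harmonics that remain.
REGION_II_HZ = (200.0, None)

_MIN_FRAMES = 16


@dataclass
class FastDynamics:
    """Fast-deformation products for one eye."""

    L_Q: Map2D
    L_QL: np.ndarray
    L_QR: np.ndarray
    F_QL: np.ndarray
    F_QR: np.ndarray
    freqs_hz: np.ndarray
    comp_I_L: np.ndarray
    comp_II_L: np.ndarray
    comp_I_R: np.ndarray
    comp_II_R: np.ndarray

    @property
    def comp_I_plus_II_L(self) -> np.ndarray:
        return self.comp_I_L + self.comp_II_L

    @property
    def comp_I_plus_II_R(self) -> np.ndarray:
        return self.comp_I_R + self.comp_II_R


def grayscale_opening(m: Map2D, se: tuple[int, int] = SE2_DEFAULT) -> Map2D:
    """Flat grayscale opening (erosion then dilation) with edge replication."""
    if any(d % 2 == 0 or d < 1 for d in se):
        raise ValueError(f"structuring element dims must be odd and >= 1, got {se}")
    if any(s < d for s, d in zip(m.shape, se)):
        raise DimensionError(f"structuring element {se} does not fit map shape {m.shape}")
    opened = ndimage.grey_opening(m.values, size=se, mode="nearest")
    return Map2D(opened, m.role)


def fast_component(L_TR: Map2D, se: tuple[int, int] = SE2_DEFAULT) -> Map2D:
    """Residual of the opening: structures shorter than the SE in (n, i) extent."""
    opened = grayscale_opening(L_TR, se)
    return Map2D(L_TR.values - opened.values, "fast")


def default_border_bands(n_cols: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Lateral column bands [N/8, 3N/8) and [5N/8, 7N/8), half-open, 0-based.

    They sample the peripheral cornea on each side while excluding both the
    apex region and the borders zeroed by the eyeball separation.
    """
    return (n_cols // 8, 3 * n_cols // 8), (5 * n_cols // 8, 7 * n_cols // 8)


def border_signals(
    L_Q: Map2D,
    bands: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average the fast map over left/right lateral column bands.

    Returns the two length-I time signals (L_QL, L_QR).  ``bands`` gives
    half-open 0-based column ranges; a single column per side can be
    selected with a width-1 band.
    """
    n_cols = L_Q.shape[0]
    if bands is None:
        bands = default_border_bands(n_cols)
    (l0, l1), (r0, r1) = bands
    for lo, hi in ((l0, l1), (r0, r1)):
        if not (0 <= lo < hi <= n_cols):
            raise ConfigError(f"band [{lo}, {hi}) outside valid columns [0, {n_cols})")
    left = L_Q.values[l0:l1, :].mean(axis=0)
    right = L_Q.values[r0:r1, :].mean(axis=0)
    return left, right


def spectrum(signal: np.ndarray, frame_interval_s: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT magnitude spectrum of a real time signal.

    Returns ``(freqs_hz, magnitude)`` of length I//2 + 1; index k is
    harmonic number k, frequency k / (I · frame_interval_s).  The raw
    (unnormalised) FFT magnitude is reported.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise DimensionError("spectrum expects a 1-D time signal")
    if signal.size < _MIN_FRAMES:
        raise TooShortError(f"need at least {_MIN_FRAMES} frames, got {signal.size}")
    mags = np.abs(np.fft.rfft(signal))
    freqs = np.fft.rfftfreq(signal.size, d=frame_interval_s)
    return freqs, mags


def band_components(
    signal: np.ndarray,
    frame_interval_s: float,
    region_i_max_hz: float = REGION_I_MAX_HZ,
    region_ii_hz: tuple[float, float | None] = REGION_II_HZ,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a signal into its region-I and region-II band components.

    comp_I keeps harmonics with |f| < ``region_i_max_hz``; comp_II keeps
    |f| >= ``region_ii_hz[0]`` and, when an upper limit is given,
    |f| <= ``region_ii_hz[1]``.  Masks are applied to the one-sided FFT
    and inverted with the conjugate-symmetric inverse, so the outputs are
    real.  Returns (comp_I, comp_II, their sum).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise DimensionError("band_components expects a 1-D time signal")
    n = signal.size
    if n < _MIN_FRAMES:
        raise TooShortError(f"need at least {_MIN_FRAMES} frames, got {n}")
    coeffs = np.fft.rfft(signal)
    freqs = np.fft.rfftfreq(n, d=frame_interval_s)
    lo, hi = region_ii_hz
    mask_ii = freqs >= lo
    if hi is not None:
        mask_ii &= freqs <= hi
    comp_i = np.fft.irfft(np.where(freqs < region_i_max_hz, coeffs, 0.0), n=n)
    comp_ii = np.fft.irfft(np.where(mask_ii, coeffs, 0.0), n=n)
    return comp_i, comp_ii, comp_i + comp_ii


def compute_fast_dynamics(
    L_TR: Map2D,
    frame_interval_s: float,
    se: tuple[int, int] = SE2_DEFAULT,
    bands: tuple[tuple[int, int], tuple[int, int]] | None = None,
    region_i_max_hz: float = REGION_I_MAX_HZ,
    region_ii_hz: tuple[float, float | None] = REGION_II_HZ,
) -> FastDynamics:
    """Run the full fast-deformation stage on a corneal-deflection map."""
    if L_TR.shape[1] < _MIN_FRAMES:
        raise TooShortError(
            f"spectral analysis needs at least {_MIN_FRAMES} frames, got {L_TR.shape[1]}"
        )
    L_Q = fast_component(L_TR, se)
    L_QL, L_QR = border_signals(L_Q, bands)
    freqs, F_QL = spectrum(L_QL, frame_interval_s)
    _, F_QR = spectrum(L_QR, frame_interval_s)
    ci_l, cii_l, _ = band_components(L_QL, frame_interval_s, region_i_max_hz, region_ii_hz)
    ci_r, cii_r, _ = band_components(L_QR, frame_interval_s, region_i_max_hz, region_ii_hz)
    return FastDynamics(
        L_Q=L_Q,
        L_QL=L_QL,
        L_QR=L_QR,
        F_QL=F_QL,
        F_QR=F_QR,
        freqs_hz=freqs,
        comp_I_L=ci_l,
        comp_II_L=cii_l,
        comp_I_R=ci_r,
        comp_II_R=cii_r,
    )
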