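"""Morlet continuous wavelet transform and wavelet transform coherence (WTC).

Inter-brain synchrony (IBS) between two hemodynamic time series is measured
here as the squared wavelet coherence

    R^2(s, t) = |S(s^-1 W_xy)|^2 / ( S(s^-1 |W_x|^2) * S(s^-1 |W_y|^2) )

where ``W_x`` is the continuous wavelet transform (CWT) of ``x`` with a Morlet
mother wavelet, ``W_xy = W_x W_y*`` the cross-wavelet spectrum, and ``S`` a
smoothing operator acting in time (Gaussian, width proportional to scale) and
in scale (boxcar over a fixed number of octaves).  Because the same
non-negative kernel smooths numerator and denominator, the Cauchy-Schwarz
inequality bounds R^2 by 1 up to floating-point round-off.

Coherence values are Fisher r-to-z transformed (``z = arctanh(R)``) before any
averaging downstream, which makes means of coherence better behaved near 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy.ndimage import uniform_filter1d

__all__ = [
    "WaveletSpec",
    "CoherenceSpectrum",
    "cwt_morlet",
    "wavelet_coherence",
    "fisher_z",
]

#: clipping applied before arctanh so that R = 1 maps to a finite z
FISHER_EPS = 1e-7


def _morlet_fourier_factor(omega0: float) -> float:
    """Ratio of Fourier period to wavelet scale for the Morlet wavelet."""
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0**2))


@dataclass(frozen=True)
class WaveletSpec:
    """Configuration of the Morlet CWT scale grid.

    Parameters
    ----------
    sampling_rate:
        Sampling rate of the analysed series in Hz.
    omega0:
        Nondimensional Morlet centre frequency.  6 is the field default and
        keeps the wavelet approximately analytic.
    voices_per_octave:
        Number of geometric scale steps per octave (>= 8).
    freq_min, freq_max:
        Frequency band covered by the scale grid, in Hz.  Defaults span the
        analysis range 0.01-0.7 Hz: above 0.7 Hz the signal is dominated by
        cardiac pulsation (0.8-2.5 Hz) and below 0.01 Hz by slow drifts.
    scale_smoothing_octaves:
        Width, in octaves, of the boxcar applied across scales when smoothing
        cross- and auto-spectra (0.6 is the conventional Morlet value).
    """

    sampling_rate: float
    omega0: float = 6.0
    voices_per_octave: int = 12
    freq_min: float = 0.01
    freq_max: float = 0.7
    scale_smoothing_octaves: float = 0.6

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.voices_per_octave < 8:
            raise ValueError("voices_per_octave must be >= 8")
        if not (0 < self.freq_min < self.freq_max):
            raise ValueError("require 0 < freq_min < freq_max")
        if self.freq_max > self.sampling_rate / 2:
            raise ValueError("freq_max exceeds the Nyquist frequency")

    @property
    def fourier_factor(self) -> float:
        return _morlet_fourier_factor(self.omega0)

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def scales(self) -> np.ndarray:
        """Geometric scale grid, smallest (highest frequency) first."""
        s_min = 1.0 / (self.freq_max * self.fourier_factor)
        s_max = 1.0 / (self.freq_min * self.fourier_factor)
        dj = 1.0 / self.voices_per_octave
        n = int(np.ceil(np.log2(s_max / s_min) / dj)) + 1
        return s_min * 2.0 ** (dj * np.arange(n))

    @property
    def frequencies(self) -> np.ndarray:
        """Equivalent Fourier frequency (Hz) of each scale, descending."""
        return 1.0 / (self.fourier_factor * self.scales)

    @property
    def scale_boxcar_size(self) -> int:
        return max(1, round(self.scale_smoothing_octaves * self.voices_per_octave))


@dataclass
class CoherenceSpectrum:
    """Time-frequency coherence between two equally sampled series.

    ``r2`` holds squared coherence in [0, 1]; ``z`` its Fisher transform
    ``arctanh(sqrt(r2))``.  ``coi_mask`` is True where the point lies inside
    the cone of influence (i.e. far enough from the record edges for the
    estimate to be reliable); edge points are retained but flagged.
    """

    r2: np.ndarray  # (n_scales, n_times)
    frequencies: np.ndarray  # (n_scales,) Hz
    times: np.ndarray  # (n_times,) s
    coi_mask: np.ndarray  # (n_scales, n_times) bool
    spec: WaveletSpec
    z: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.z = fisher_z(np.sqrt(self.r2))


def _validate_series(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains NaN or infinite values")
    return x


def cwt_morlet(x: np.ndarray, spec: WaveletSpec) -> np.ndarray:
    """Morlet CWT of ``x`` on ``spec``'s scale grid.

    Returns a complex array of shape ``(n_scales, len(x))``.  Computed in the
    frequency domain with zero padding to the next fast FFT length; the
    transform is linear in its input.
    """
    x = _validate_series(x, "x")
    n = x.size
    if n < 2:
        raise ValueError("series too short for a wavelet transform")
    scales = spec.scales
    longest_period = 1.0 / spec.frequencies.min()
    if n < 2 * longest_period * spec.sampling_rate:
        warnings.warn(
            "series shorter than twice the longest analysed period; "
            "low-frequency estimates are dominated by edge effects",
            stacklevel=2,
        )
    nfft = sp_fft.next_fast_len(2 * n)
    xhat = sp_fft.fft(x - x.mean(), nfft)
    omega = 2.0 * np.pi * sp_fft.fftfreq(nfft, spec.dt)
    # Morlet daughter in frequency domain, analytic (positive frequencies only)
    arg = scales[:, None] * omega[None, :]
    psi_hat = (
        np.pi**-0.25
        * np.sqrt(2.0 * np.pi * scales[:, None] / spec.dt)
        * np.exp(-0.5 * (arg - spec.omega0) ** 2)
        * (omega[None, :] > 0)
    )
    w = sp_fft.ifft(xhat[None, :] * psi_hat, axis=1)[:, :n]
    return w


def coi_mask(spec: WaveletSpec, n_times: int) -> np.ndarray:
    """Boolean mask, True inside the cone of influence.

    The Morlet e-folding time is ``sqrt(2) * scale``; a point is inside the
    cone when its distance to the nearer record edge exceeds that time.
    """
    t_edge = np.minimum(np.arange(n_times), n_times - 1 - np.arange(n_times)) * spec.dt
    return t_edge[None, :] >= np.sqrt(2.0) * spec.scales[:, None]


def _smooth(field_arr: np.ndarray, spec: WaveletSpec, scales: np.ndarray | None = None) -> np.ndarray:
    """Grinsted-style smoothing: Gaussian in time (sigma = scale), boxcar in scale.

    Operates on arrays of shape (n_scales, n_times); complex input allowed.
    ``scales`` defaults to the spec's full grid but may be a contiguous
    subgrid when the input rows are scale-restricted.  The time smoothing is
    a circular convolution on a zero-padded grid, so the same kernel
    multiplies every spectral term and coherence stays <= 1.
    """
    if scales is None:
        scales = spec.scales
    n = field_arr.shape[1]
    nfft = sp_fft.next_fast_len(2 * n)
    omega = 2.0 * np.pi * sp_fft.fftfreq(nfft, spec.dt)
    fa = sp_fft.fft(field_arr, nfft, axis=1)
    kernel = np.exp(-0.5 * (scales[:, None] * omega[None, :]) ** 2)
    if fa.dtype == np.complex64:
        kernel = kernel.astype(np.float32)  # keep the fast single-precision path
    out = sp_fft.ifft(fa * kernel, axis=1)[:, :n]
    if not np.iscomplexobj(field_arr):
        out = out.real
    size = spec.scale_boxcar_size
    if size > 1:
        if np.iscomplexobj(out):
            out = uniform_filter1d(out.real, size, axis=0, mode="nearest") + 1j * uniform_filter1d(
                out.imag, size, axis=0, mode="nearest"
            )
        else:
            out = uniform_filter1d(out, size, axis=0, mode="nearest")
    return out


def smoothed_autopower(w: np.ndarray, spec: WaveletSpec, scales: np.ndarray | None = None) -> np.ndarray:
    """``S(s^-1 |W|^2)`` for a single CWT, the WTC denominator term."""
    s = spec.scales if scales is None else scales
    power = np.abs(w) ** 2
    return _smooth(power / s[:, None].astype(power.dtype), spec, scales=s)


def coherence_from_transforms(
    wx: np.ndarray,
    wy: np.ndarray,
    px: np.ndarray,
    py: np.ndarray,
    spec: WaveletSpec,
    scales: np.ndarray | None = None,
) -> np.ndarray:
    """Squared coherence given two CWTs and their smoothed auto-powers.

    Splitting the computation this way lets cohort-level callers (notably the
    pseudogroup permutation) cache the per-participant transforms and only
    redo the cross-spectrum smoothing per pairing.
    """
    s = spec.scales if scales is None else scales
    cross = wx * np.conj(wy)
    sxy = _smooth(cross / s[:, None].astype(cross.real.dtype), spec, scales=s)
    denom = px * py
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.abs(sxy) ** 2 / denom
    r2 = np.where(denom > 0, r2, 0.0)
    # Cauchy-Schwarz bounds R^2 by 1 analytically; anything beyond round-off
    # (single precision on the cohort path) is a smoothing bug
    tol = 1e-3 if cross.dtype == np.complex64 else 1e-6
    overshoot = np.max(r2) - 1.0
    if overshoot > tol:
        raise AssertionError(f"coherence exceeded 1 by {overshoot:.2e}")
    return np.clip(r2, 0.0, 1.0)


def wavelet_coherence(x: np.ndarray, y: np.ndarray, spec: WaveletSpec) -> CoherenceSpectrum:
    """Wavelet transform coherence between two series.

    Symmetric in its arguments. Raises on constant input, for which coherence
    is undefined.
    """
    x = _validate_series(x, "x")
    y = _validate_series(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("coherence undefined for a constant series")
    wx = cwt_morlet(x, spec)
    wy = cwt_morlet(y, spec)
    px = smoothed_autopower(wx, spec)
    py = smoothed_autopower(wy, spec)
    r2 = coherence_from_transforms(wx, wy, px, py, spec)
    times = np.arange(x.size) * spec.dt
    return CoherenceSpectrum(
        r2=r2,
        frequencies=spec.frequencies,
        times=times,
        coi_mask=coi_mask(spec, x.size),
        spec=spec,
    )


def fisher_z(r, tol: float = 1e-6):
    """Fisher r-to-z transform, ``arctanh(min(r, 1 - 1e-7))``.

    Accepts scalars or arrays of coherence values in [0, 1]; values of exactly
    1 map to the finite ``arctanh(1 - 1e-7)``. Inputs outside [0, 1] beyond
    ``tol`` raise.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < -tol) or np.any(r_arr > 1.0 + tol):
        raise ValueError("coherence values must lie in [0, 1]")
    z = np.arctanh(np.clip(r_arr, 0.0, 1.0 - FISHER_EPS))
    return float(z) if np.isscalar(r) or r_arr.ndim == 0 else z
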