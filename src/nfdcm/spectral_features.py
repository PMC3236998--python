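"""Cross-spectral data features from raw time series.

Observed spectra are summarized by fitting a vector autoregression (order
eight by default, matching common practice for steady-state LFP analyses)
and evaluating its implied spectral density on a frequency grid.  The
package-wide spectral convention is a one-sided density with per-Hz
scaling: for a VAR with coefficient matrices ``A_1..A_p`` and innovation
covariance ``S``, the cross-spectral matrix at frequency ``f`` is

    g(f) = 2/fs * H(f) S H(f)^*,   H(f) = (I - sum_m A_m z^m)^{-1},
    z = exp(-2i pi f / fs).

Only the relative spectral shape matters downstream, since the generative
model carries free input and noise amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import signal


class IllConditionedError(RuntimeError):
    """Autoregression design matrix is numerically rank deficient."""


@dataclass(frozen=True)
class TimeSeries:
    """Multichannel raw recording: ``samples`` is (n_samples, n_channels),
    ``fs`` the sampling rate in Hz."""

    samples: NDArray[np.float64]
    fs: float

    def __post_init__(self):
        samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if samples.shape[0] == 1 and samples.shape[1] > 1:
            samples = samples.T
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass
class SpectralData:
    """Complex cross-spectral matrices on a temporal frequency grid.

    ``values`` has shape (n_freq, n_channels, n_channels); every
    per-frequency matrix is Hermitian with real nonnegative diagonal.
    ``meta`` records provenance (estimated | simulated | predicted).
    """

    freqs_hz: NDArray[np.float64]
    values: NDArray[np.complex128]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        values = np.asarray(self.values, dtype=complex)
        if values.ndim == 1:
            values = values[:, None, None]
        self.values = values
        if self.values.shape[0] != self.freqs_hz.shape[0]:
            raise ValueError("values and frequency grid length mismatch")

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def auto(self, channel: int = 0) -> NDArray[np.float64]:
        """Real auto-spectrum of one channel."""
        return self.values[:, channel, channel].real

    def validate(self, tol: float = 1e-8):
        """Check Hermitian symmetry and nonnegative diagonals."""
        scale = np.abs(self.values).max() or 1.0
        herm = np.abs(self.values - self.values.conj().transpose(0, 2, 1))
        if herm.max() > tol * scale:
            raise ValueError("cross-spectral matrices are not Hermitian")
        diags = np.diagonal(self.values, axis1=1, axis2=2)
        if np.abs(diags.imag).max() > tol * scale:
            raise ValueError("auto-spectra are not real")


def _fit_var(samples: NDArray[np.float64], order: int):
    """OLS fit of a VAR(order); returns (coeffs (p, c, c), innovation cov)."""
    n, c = samples.shape
    if n <= order * c + order:
        raise ValueError("series too short for requested model order")
    x = samples - samples.mean(axis=0)
    design = np.concatenate(
        [x[order - m - 1:n - m - 1] for m in range(order)], axis=1)
    target = x[order:]
    cond = np.linalg.cond(design)
    if cond > 1e10:
        # ridge fallback for near-collinear channels
        gram = design.T @ design
        ridge = 1e-8 * np.trace(gram) / gram.shape[0]
        coef = np.linalg.solve(gram + ridge * np.eye(gram.shape[0]),
                               design.T @ target)
        if not np.all(np.isfinite(coef)):
            raise IllConditionedError(
                "autoregression normal equations are singular")
    else:
        coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coef
    sigma = resid.T @ resid / resid.shape[0]
    coeffs = coef.reshape(order, c, c).transpose(0, 2, 1)
    return coeffs, sigma


def var_cross_spectrum(ts: TimeSeries, order: int = 8,
                       freqs_hz: ArrayLike | None = None) -> SpectralData:
    """Cross-spectral density estimated through a VAR(order) fit.

    Coefficients come from ordinary least squares on lagged regressors
    (channel means removed first); the spectrum is the transfer-filtered
    innovation covariance on ``freqs_hz`` (default 1-60 Hz at 0.5 Hz).
    """
    if order < 1:
        raise ValueError("order must be at least 1")
    if freqs_hz is None:
        freqs_hz = np.arange(1.0, 60.5, 0.5)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    coeffs, sigma = _fit_var(ts.samples, order)
    c = ts.n_channels
    z = np.exp(-2j * np.pi * freqs_hz[:, None] / ts.fs
               * np.arange(1, order + 1)[None, :])
    a = np.eye(c)[None] - np.einsum("wm,mij->wij", z, coeffs)
    h = np.linalg.inv(a)
    values = 2.0 / ts.fs * np.einsum("wij,jk,wlk->wil", h, sigma, h.conj())
    # symmetrize away rounding asymmetry
    values = 0.5 * (values + values.conj().transpose(0, 2, 1))
    out = SpectralData(freqs_hz, values,
                       meta={"provenance": "estimated", "order": order,
                             "fs": ts.fs})
    out.validate()
    return out


def preprocess(ts: TimeSeries, band: tuple[float, float] | None = None,
               target_fs: float | None = None) -> TimeSeries:
    """Band-pass filter and resample a recording.

    ``band`` is a (low, high) passband in Hz (zero-phase Butterworth);
    ``target_fs`` the output sampling rate.  With no band and an unchanged
    rate the input is passed through untouched.
    """
    fs_out = ts.fs if target_fs is None else float(target_fs)
    if band is not None and band[1] >= fs_out / 2:
        raise ValueError(
            f"band upper edge {band[1]} Hz exceeds Nyquist of {fs_out} Hz")
    if band is None and fs_out == ts.fs:
        return ts
    x = ts.samples
    if band is not None:
        sos = signal.butter(4, band, btype="bandpass", fs=ts.fs,
                            output="sos")
        x = signal.sosfiltfilt(sos, x, axis=0)
    if fs_out != ts.fs:
        ratio = Fraction(fs_out / ts.fs).limit_denominator(10000)
        x = signal.resample_poly(x, ratio.numerator, ratio.denominator,
                                 axis=0)
    return TimeSeries(np.ascontiguousarray(x), fs_out)
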