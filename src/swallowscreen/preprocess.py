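"""Artifact removal applied to each accelerometry axis before segmentation.

Three stages, in the order they run:

1. **Inverse (calibration) filtering** — a linear-prediction whitening FIR
   filter estimated from a swallow-free rest segment, compensating the
   coloring imposed by the device/tissue transmission path.
2. **Wavelet denoising** — discrete Meyer ('dmey') decomposition to depth L,
   soft thresholding of detail coefficients at the universal threshold
   lambda = sigma * sqrt(2 ln N), with sigma estimated as
   MAD(finest-level details)/0.6745, then reconstruction.
3. **Low-frequency removal** — a least-squares cubic spline with uniform
   knots fit to the series and subtracted, targeting head-motion drift
   (components well below the swallow vibration band).

Each stage operates on a single axis; the two axes of a recording are
processed independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy import interpolate, linalg, signal

from .signal_io import Recording

WAVELET = "dmey"


@dataclass(frozen=True)
class DenoiseConfig:
    """Wavelet-shrinkage parameters.

    level : decomposition depth L (default 10, sized for 10 kHz recordings
        so the approximation band sits below ~5 Hz).
    wavelet : discrete wavelet family; discrete Meyer by default.
    """

    level: int = 10
    wavelet: str = WAVELET

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("decomposition depth must be >= 1")


@dataclass(frozen=True)
class DetrendConfig:
    """Spline detrend parameters.

    knot_spacing_s : uniform interior-knot spacing in seconds (default 0.5 s,
        so the spline tracks components up to roughly 1 Hz and leaves the
        swallow vibration band untouched).
    order : spline order; cubic.
    """

    knot_spacing_s: float = 0.5
    order: int = 3

    def __post_init__(self) -> None:
        if self.knot_spacing_s <= 0:
            raise ValueError("knot spacing must be positive")


@dataclass(frozen=True)
class InverseFilter:
    """FIR whitening filter; ``identity=True`` passes input through unchanged."""

    coefficients: np.ndarray
    identity: bool = False

    def apply(self, x: np.ndarray) -> np.ndarray:
        if self.identity:
            return np.asarray(x, dtype=float).copy()
        return signal.lfilter(self.coefficients, [1.0], x)


def identity_filter() -> InverseFilter:
    return InverseFilter(coefficients=np.array([1.0]), identity=True)


def estimate_inverse_filter(calibration: Recording, order: int = 10) -> InverseFilter:
    """Estimate a whitening FIR filter from a swallow-free calibration recording.

    Fits an autoregressive model of the given order to the mean of the two
    axes' autocorrelations (autocorrelation method, Toeplitz solve) and
    returns the corresponding prediction-error (whitening) filter
    ``[1, -a_1, ..., -a_p]``.  Filtering the calibration signal with it
    flattens its spectrum.
    """
    if order < 1:
        raise ValueError("filter order must be >= 1")
    n = calibration.n_samples
    if n < 10 * order:
        raise ValueError(
            f"calibration of {n} samples is shorter than 10x order ({10 * order})"
        )

    def ar_coeffs(x: np.ndarray) -> np.ndarray:
        x = x - x.mean()
        r = np.correlate(x, x, mode="full")[n - 1 : n + order] / n
        if r[0] <= 0:
            return np.zeros(order)
        return linalg.solve_toeplitz((r[:-1], r[:-1]), r[1:])

    a = 0.5 * (ar_coeffs(calibration.ap) + ar_coeffs(calibration.si))
    coeffs = np.concatenate(([1.0], -a))
    return InverseFilter(coefficients=coeffs, identity=False)


def soft_threshold(w: np.ndarray | float, lam: float) -> np.ndarray | float:
    """Soft-shrinkage operator sign(w) * max(|w| - lam, 0)."""
    if lam < 0:
        raise ValueError("threshold must be non-negative")
    w = np.asarray(w, dtype=float)
    out = np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)
    return out if out.ndim else float(out)


def universal_threshold(finest_detail: np.ndarray, n_samples: int) -> float:
    """Universal threshold sigma*sqrt(2 ln N), sigma = MAD(d_1)/0.6745."""
    sigma = np.median(np.abs(finest_detail - np.median(finest_detail))) / 0.6745
    return float(sigma * np.sqrt(2.0 * np.log(max(n_samples, 2))))


def wavedec(x: np.ndarray, wavelet: str, level: int) -> list[np.ndarray]:
    """Multilevel DWT; suppresses the max-useful-level warning the long dmey
    filter triggers (the n >= 2^L precondition is enforced by callers)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return pywt.wavedec(x, wavelet, level=level)


def denoise(x: np.ndarray, cfg: DenoiseConfig = DenoiseConfig()) -> np.ndarray:
    """Wavelet-shrinkage denoise of one axis; output length equals input length."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 ** cfg.level:
        raise ValueError(
            f"series of {n} samples too short for decomposition depth {cfg.level}"
        )
    coeffs = wavedec(x, cfg.wavelet, cfg.level)
    lam = universal_threshold(coeffs[-1], n)
    thresholded = [coeffs[0]] + [soft_threshold(c, lam) for c in coeffs[1:]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rec = pywt.waverec(thresholded, cfg.wavelet)
    return rec[:n]


def remove_low_freq(
    x: np.ndarray, fs: float, cfg: DetrendConfig = DetrendConfig()
) -> np.ndarray:
    """Fit a least-squares cubic spline with uniform knots and subtract it.

    Removes slow drift (head motion) while preserving vibration-band energy.
    Requires at least two knot spacings of data.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    duration = n / fs
    if duration < 2 * cfg.knot_spacing_s:
        raise ValueError(
            f"duration {duration:.3g}s shorter than two knot spacings "
            f"({2 * cfg.knot_spacing_s:.3g}s)"
        )
    t = np.arange(n) / fs
    # interior knots strictly inside (t[0], t[-1])
    knots = np.arange(cfg.knot_spacing_s, t[-1], cfg.knot_spacing_s)
    knots = knots[(knots > t[0]) & (knots < t[-1])]
    spline = interpolate.LSQUnivariateSpline(t, x, knots, k=cfg.order)
    return x - spline(t)


def preprocess_recording(
    rec: Recording,
    inv: InverseFilter | None = None,
    dcfg: DenoiseConfig = DenoiseConfig(),
    tcfg: DetrendConfig = DetrendConfig(),
) -> Recording:
    """Run inverse filter -> denoise -> detrend on each axis independently.

    Returns a new Recording of identical length and sampling rate; the
    metadata ``processing`` list records the stage chain.
    """
    if inv is None:
        inv = identity_filter()

    def chain(x: np.ndarray) -> np.ndarray:
        y = inv.apply(x)
        y = denoise(y, dcfg)
        return remove_low_freq(y, rec.fs, tcfg)

    meta = replace(
        rec.meta,
        processing=rec.meta.processing
        + [
            f"inverse_filter(identity={inv.identity},order={len(inv.coefficients) - 1})",
            f"denoise(wavelet={dcfg.wavelet},level={dcfg.level},threshold=universal,mode=soft)",
            f"detrend(spline=cubic,knot_spacing_s={tcfg.knot_spacing_s})",
        ],
    )
    return Recording(ap=chain(rec.ap), si=chain(rec.si), fs=rec.fs, meta=meta)
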