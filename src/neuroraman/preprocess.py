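"""Preprocessing of raw Raman accumulation stacks.

The chain mirrors standard probe-spectroscopy practice: cosmic-ray spikes are
detected by comparing each accumulation against its neighbours (the other
accumulations of the same sample) at every channel; the broad fluorescence
background is removed with an iteratively re-weighted smoothing spline that
tracks the lower envelope of the spectrum (11 nodes by default); spectra are
then linearly resampled/truncated onto a common analysis grid and optionally
normalised. Peak-height and band-ratio utilities support the 1447/1660
injury metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .spectra import DegenerateInputError, InvalidInputError, Spectrum
from .synthetic import robust_scale

__all__ = [
    "PreprocessConfig",
    "remove_cosmic_rays",
    "subtract_baseline",
    "resample_truncate",
    "normalize",
    "peak_height",
    "band_ratio",
    "preprocess_stack",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters for the despike -> baseline -> resample -> normalise chain."""

    spike_threshold: float = 8.0     # robust z cutoff for spike detection
    baseline_nodes: int = 11         # spline node count used by the probe software
    baseline_iterations: int = 50
    target_axis: np.ndarray = None   # None: keep source axis
    normalization: str = "none"      # one of {none, vector, area}

    def __post_init__(self):
        if self.spike_threshold <= 0:
            raise InvalidInputError("spike_threshold must be > 0")
        if self.baseline_nodes < 4:
            raise InvalidInputError("baseline_nodes must be >= 4")
        if self.normalization not in ("none", "vector", "area"):
            raise InvalidInputError("normalization must be none, vector or area")


def _despike_single(axis, y, threshold) -> np.ndarray:
    """Within-spectrum fallback: spikes stand out in the second difference."""
    y = y.copy()
    d2 = np.zeros_like(y)
    d2[1:-1] = y[1:-1] - 0.5 * (y[:-2] + y[2:])
    scale = robust_scale(d2[1:-1])
    if scale <= 0:
        # perfectly smooth signal: any curvature blip is a spike
        scale = 1e-9 * max(1.0, float(np.max(np.abs(y))) / threshold)
    bad = np.abs(d2) > threshold * scale
    idx = np.flatnonzero(bad)
    good = np.flatnonzero(~bad)
    if idx.size and good.size >= 2:
        y[idx] = np.interp(axis[idx], axis[good], y[good])
    return y


def remove_cosmic_rays(accumulations, spike_threshold: float = 8.0,
                       axis=None) -> np.ndarray:
    """Remove cosmic-ray spikes from an accumulation stack and average it.

    For each channel of each accumulation, the value is compared against the
    median over the *other* accumulations at that channel (its nearest
    neighbours in acquisition order): deviations beyond ``spike_threshold``
    robust scales are replaced by that neighbour median. Returns the mean over
    the cleaned stack as a 1-D intensity array.

    With a single accumulation there is no neighbour stack; the function
    falls back to within-spectrum neighbour interpolation and warns.
    """
    stack = np.asarray(accumulations, dtype=float)
    if stack.ndim == 1:
        stack = stack[None, :]
    if stack.ndim != 2:
        raise InvalidInputError("accumulations must be a 2-D stack")
    n_acc, n_chan = stack.shape
    if n_acc == 1:
        warnings.warn("single accumulation: falling back to within-spectrum "
                      "neighbour interpolation", stacklevel=2)
        ax = np.arange(n_chan) if axis is None else np.asarray(axis, dtype=float)
        return _despike_single(ax, stack[0], spike_threshold)

    med = np.median(stack, axis=0)
    dev = stack - med
    # Per-channel robust scale across accumulations, floored by the global
    # scale so constant (noise-free) channels do not produce zero thresholds.
    chan_scale = 1.4826 * np.median(np.abs(dev), axis=0)
    global_scale = np.median(chan_scale[chan_scale > 0]) if np.any(chan_scale > 0) else 0.0
    floor = max(global_scale, 1e-9 * max(1.0, float(np.max(np.abs(stack)))))
    chan_scale = np.maximum(chan_scale, floor)

    spikes = dev > spike_threshold * chan_scale  # cosmic rays are additive
    cleaned = stack.copy()
    if np.any(spikes):
        masked = np.where(spikes, np.nan, stack)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            neighbour_med = np.nanmedian(masked, axis=0)
        # channels where every accumulation spiked: keep the plain median
        neighbour_med = np.where(np.isnan(neighbour_med), med, neighbour_med)
        rows, cols = np.nonzero(spikes)
        cleaned[rows, cols] = neighbour_med[cols]
    return cleaned.mean(axis=0)


def _spline_basis(x: np.ndarray, n_nodes: int, k: int = 3) -> np.ndarray:
    """Cubic B-spline design matrix on ``n_nodes`` equally spaced nodes."""
    nodes = np.linspace(x[0], x[-1], n_nodes)
    t = np.concatenate([[x[0]] * k, nodes, [x[-1]] * k])
    return BSpline.design_matrix(x, t, k).toarray()


def subtract_baseline(spectrum: Spectrum, baseline_nodes: int = 11,
                      baseline_iterations: int = 50,
                      smoothness: float = 1.0) -> Spectrum:
    """Subtract a fluorescence baseline fitted by an asymmetric spline.

    The baseline is a cubic spline on ``baseline_nodes`` equally spaced nodes,
    fitted by iteratively re-weighted penalised least squares: after each
    pass, points lying well above the current fit (relative to the spread of
    the negative residuals) are smoothly down-weighted, so the spline settles
    onto the lower envelope — the fluorescence background — while the Raman
    bands are ignored. A second-difference penalty on the spline coefficients
    (``smoothness``) keeps the fit smooth across band-dense regions where few
    baseline-only channels remain. Iteration stops when the fitted curve is
    stable or after ``baseline_iterations`` passes (with a warning).

    The result may contain small negatives; they are deliberately retained so
    later least-squares fits are unbiased.
    """
    x, y = spectrum.axis, spectrum.intensity
    if len(spectrum) <= baseline_nodes:
        raise InvalidInputError("spectrum must have more points than baseline nodes")
    if not np.any(y != 0):
        return spectrum.with_intensity(np.zeros_like(y))

    B = _spline_basis(x, baseline_nodes)
    D = np.diff(np.eye(B.shape[1]), 2, axis=0)
    P = smoothness * D.T @ D
    w = np.ones_like(y)
    fit = np.zeros_like(y)
    fit_prev = None
    fit_tol = 1e-5 * max(1.0, float(np.max(np.abs(y))))
    converged = False
    for _ in range(baseline_iterations):
        WB = w[:, None] * B
        coef = np.linalg.solve(B.T @ WB + P, WB.T @ y)
        fit = B @ coef
        if fit_prev is not None and np.abs(fit - fit_prev).max() < fit_tol:
            converged = True
            break
        fit_prev = fit
        d = y - fit
        below = d[d < 0]
        if below.size < 10:
            converged = True
            break
        m, s = below.mean(), below.std()
        if s <= 0:
            converged = True
            break
        # logistic down-weighting of points far above the fit (arPLS-style)
        z = np.clip(2.0 * (d - (2.0 * s - m)) / s, -50.0, 50.0)
        w = 1.0 / (1.0 + np.exp(z))
    if not converged:
        warnings.warn("baseline fit did not converge; returning last iterate",
                      stacklevel=2)
    return spectrum.with_intensity(y - fit)


def resample_truncate(spectrum: Spectrum, target_axis) -> Spectrum:
    """Linear interpolation onto ``target_axis``; never extrapolates."""
    target = np.asarray(target_axis, dtype=float)
    src = spectrum.axis
    if target[0] < src[0] or target[-1] > src[-1]:
        raise InvalidInputError(
            f"target axis [{target[0]}, {target[-1]}] extends beyond source "
            f"range [{src[0]}, {src[-1]}]")
    return Spectrum(target, np.interp(target, src, spectrum.intensity))


def normalize(spectrum: Spectrum, mode: str = "vector") -> Spectrum:
    """Normalise intensity: ``vector`` (unit L2 norm), ``area`` (unit
    trapezoidal integral) or ``none``."""
    if mode == "none":
        return spectrum
    y = spectrum.intensity
    if mode == "vector":
        nrm = float(np.linalg.norm(y))
    elif mode == "area":
        nrm = float(np.trapezoid(y, spectrum.axis))
    else:
        raise InvalidInputError(f"unknown normalization mode {mode!r}")
    if nrm == 0:
        raise DegenerateInputError("cannot normalise an all-zero spectrum")
    return spectrum.with_intensity(y / nrm)


def _window_slice(spectrum: Spectrum, center: float, half_window: float):
    lo, hi = center - half_window, center + half_window
    if lo < spectrum.axis[0] or hi > spectrum.axis[-1]:
        raise InvalidInputError(
            f"window [{lo}, {hi}] lies outside axis "
            f"[{spectrum.axis[0]}, {spectrum.axis[-1]}]")
    mask = (spectrum.axis >= lo) & (spectrum.axis <= hi)
    if not np.any(mask):
        raise InvalidInputError("window contains no grid points")
    return mask


def peak_height(spectrum: Spectrum, center: float, half_window: float = 10.0) -> float:
    """Maximum intensity within ``center +/- half_window`` (baseline-corrected
    input assumed)."""
    mask = _window_slice(spectrum, center, half_window)
    return float(spectrum.intensity[mask].max())


def band_ratio(spectrum: Spectrum, num_center: float, den_center: float,
               half_window: float = 10.0) -> float:
    """Peak-height ratio between two bands, e.g. 1447/1660 for injury grading."""
    num = peak_height(spectrum, num_center, half_window)
    den = peak_height(spectrum, den_center, half_window)
    if den <= 0:
        raise DegenerateInputError("denominator peak height is not positive")
    return num / den


def preprocess_stack(axis, stack, config: PreprocessConfig) -> Spectrum:
    """Full chain for one sample: despike+average, baseline, resample, normalise."""
    cleaned = remove_cosmic_rays(stack, config.spike_threshold, axis=axis)
    spec = Spectrum(axis, cleaned)
    spec = subtract_baseline(spec, config.baseline_nodes, config.baseline_iterations)
    if config.target_axis is not None:
        spec = resample_truncate(spec, config.target_axis)
    return normalize(spec, config.normalization)
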