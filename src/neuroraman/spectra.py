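"""Core spectral containers: single spectra, band specifications, component libraries.

A Raman spectrum is a pair of equal-length arrays: a strictly increasing
wavenumber axis (Raman shift, cm^-1) and the measured intensity (counts).
Reference components (lipids, protein) live on a shared axis in a
:class:`ComponentLibrary`, which is the basis for non-negative unmixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "BandSpec",
    "ComponentLibrary",
    "pseudo_voigt",
]


class InvalidInputError(ValueError):
    """Raised when an operation receives structurally invalid input."""


class InvalidAxisError(InvalidInputError):
    """Raised when a wavenumber axis is not strictly increasing."""


class DegenerateInputError(ValueError):
    """Raised for inputs that are valid in shape but degenerate in value
    (all-zero spectrum asked for unit normalization, zero denominator, ...)."""


def _as_axis(axis) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise InvalidAxisError("axis must be a 1-D array with at least 2 points")
    if not np.all(np.diff(axis) > 0):
        raise InvalidAxisError("wavenumber axis must be strictly increasing")
    return axis


@dataclass(frozen=True)
class Spectrum:
    """One Raman measurement: wavenumber axis (cm^-1) and intensity (counts)."""

    axis: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        axis = _as_axis(self.axis)
        intensity = np.asarray(self.intensity, dtype=float)
        if intensity.shape != axis.shape:
            raise InvalidInputError(
                f"intensity length {intensity.shape} does not match axis {axis.shape}"
            )
        if not np.all(np.isfinite(intensity)):
            raise InvalidInputError("intensity contains non-finite values")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)

    def __len__(self) -> int:
        return self.axis.size

    def with_intensity(self, intensity) -> "Spectrum":
        return Spectrum(self.axis, intensity)


def pseudo_voigt(axis, center: float, fwhm: float, amplitude: float,
                 lorentz_fraction: float = 0.5) -> np.ndarray:
    """Amplitude-normalised pseudo-Voigt band profile.

    A convex mix of a Lorentzian and a Gaussian of common full width at half
    maximum; ``lorentz_fraction`` is the Lorentzian weight. Peak value equals
    ``amplitude`` at ``center``.
    """
    if fwhm <= 0:
        raise InvalidInputError("band width (FWHM) must be positive")
    if amplitude < 0:
        raise InvalidInputError("band amplitude must be non-negative")
    if not 0.0 <= lorentz_fraction <= 1.0:
        raise InvalidInputError("lorentz_fraction must lie in [0, 1]")
    x = np.asarray(axis, dtype=float)
    u = (x - center) / (fwhm / 2.0)
    lorentz = 1.0 / (1.0 + u * u)
    gauss = np.exp(-np.log(2.0) * u * u)
    return amplitude * (lorentz_fraction * lorentz + (1.0 - lorentz_fraction) * gauss)


@dataclass(frozen=True)
class BandSpec:
    """One vibrational band: center (cm^-1), FWHM (cm^-1), relative amplitude,
    and Lorentzian fraction of the pseudo-Voigt profile."""

    center: float
    width: float
    amplitude: float
    shape_mix: float = 0.5

    def __post_init__(self):
        if self.width <= 0:
            raise InvalidInputError("BandSpec.width must be > 0")
        if self.amplitude < 0:
            raise InvalidInputError("BandSpec.amplitude must be >= 0")
        if not 0.0 <= self.shape_mix <= 1.0:
            raise InvalidInputError("BandSpec.shape_mix must lie in [0, 1]")

    def evaluate(self, axis) -> np.ndarray:
        return pseudo_voigt(axis, self.center, self.width, self.amplitude,
                            self.shape_mix)


@dataclass(frozen=True)
class ComponentLibrary:
    """Named reference spectra on a common wavenumber axis.

    ``components`` preserves insertion order; that order defines coefficient
    order everywhere downstream.
    """

    axis: np.ndarray
    components: dict = field(default_factory=dict)

    def __post_init__(self):
        axis = _as_axis(self.axis)
        if not self.components:
            raise InvalidInputError("component library must hold at least one component")
        comps = {}
        for name, vec in self.components.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != axis.shape:
                raise InvalidInputError(
                    f"component {name!r} length {vec.size} != axis length {axis.size}"
                )
            if np.any(vec < 0):
                raise InvalidInputError(f"component {name!r} has negative intensities")
            comps[name] = vec
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "components", comps)

    @property
    def names(self) -> list:
        return list(self.components.keys())

    @property
    def matrix(self) -> np.ndarray:
        """(n_components, n_channels) stack in library order."""
        return np.vstack([self.components[n] for n in self.names])

    def __contains__(self, name) -> bool:
        return name in self.components

    def __getitem__(self, name) -> np.ndarray:
        return self.components[name]

    def max_normalized(self) -> "ComponentLibrary":
        """Each component rescaled to unit peak height (zero components kept)."""
        comps = {}
        for name, vec in self.components.items():
            peak = vec.max()
            comps[name] = vec / peak if peak > 0 else vec.copy()
        return ComponentLibrary(self.axis, comps)
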