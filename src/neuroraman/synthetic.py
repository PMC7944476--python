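"""Synthetic cohort generator emulating intracranial Raman probe acquisition.

Each simulated sample is a non-negative linear mixture of reference brain-lipid
components (cardiolipin, ganglioside, hemoglobin, cholesterol, generic protein)
sitting on a broad fluorescence background, acquired as a stack of noisy
accumulations contaminated by cosmic-ray spikes. Class structure follows the
biochemistry of traumatic brain injury: the TBI classes deplete cardiolipin,
which carries the 1266 and 1660 cm^-1 bands, so the 1447/1660 peak-height
ratio rises with injury severity.

The generator records per-sample ground-truth mixing coefficients, so every
downstream stage (despiking, baseline subtraction, SOM classification, NNLS
unmixing) can be validated against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import (
    BandSpec,
    ComponentLibrary,
    InvalidInputError,
    Spectrum,
    _as_axis,
)

__all__ = [
    "BaselineParams",
    "CohortConfig",
    "LabeledCohort",
    "generate_component_library",
    "default_library",
    "default_cohort_config",
    "generate_cohort",
    "inject_cosmic_rays",
    "fluorescence_baseline",
    "robust_scale",
    "DEFAULT_AXIS_START",
    "DEFAULT_AXIS_STOP",
    "default_axis",
    "full_probe_axis",
]

# Fingerprint region: contains every band this analysis interprets.
DEFAULT_AXIS_START = 600.0
DEFAULT_AXIS_STOP = 1800.0


def default_axis(step: float = 1.0) -> np.ndarray:
    """600-1800 cm^-1 fingerprint grid (default 1 cm^-1 spacing)."""
    return np.arange(DEFAULT_AXIS_START, DEFAULT_AXIS_STOP + step / 2, step)


def full_probe_axis(step: float = 1.0) -> np.ndarray:
    """Full probe spectral domain, -200 to 3723 cm^-1."""
    return np.arange(-200.0, 3723.0 + step / 2, step)


def generate_component_library(band_table, axis) -> ComponentLibrary:
    """Build a component library from band tables.

    Parameters
    ----------
    band_table
        Sequence of ``(name, [BandSpec, ...])`` pairs; each component's
        spectrum is the sum of its pseudo-Voigt bands evaluated on ``axis``.
    axis
        Strictly increasing wavenumber grid (cm^-1).
    """
    axis = _as_axis(axis)
    comps = {}
    for name, bands in band_table:
        if name in comps:
            raise InvalidInputError(f"duplicate component name {name!r}")
        bands = list(bands)
        if not bands:
            raise InvalidInputError(f"component {name!r} has an empty band list")
        vec = np.zeros_like(axis)
        for band in bands:
            if not isinstance(band, BandSpec):
                band = BandSpec(*band)
            vec += band.evaluate(axis)
        comps[name] = vec
    return ComponentLibrary(axis, comps)


# Band tables for the five-component brain basis. Cardiolipin carries the
# unsaturated-lipid bands at 1266 (=C-H in-plane) and 1660 cm^-1 (C=C stretch);
# the shared CH2/CH3 bending band at ~1447 cm^-1 is dominated by protein,
# cholesterol and ganglioside; protein carries the 1003 cm^-1 phenylalanine
# marker; hemoglobin and ganglioside contribute around 1337 cm^-1.
_DEFAULT_BAND_TABLE = [
    ("cardiolipin", [
        BandSpec(1266.0, 22.0, 1.00),
        BandSpec(1660.0, 20.0, 0.95),
        BandSpec(1440.0, 18.0, 0.35),
        BandSpec(1080.0, 24.0, 0.20),
    ]),
    ("ganglioside", [
        BandSpec(1337.0, 24.0, 0.80),
        BandSpec(1447.0, 20.0, 0.55),
        BandSpec(1063.0, 20.0, 0.30),
        BandSpec(1656.0, 22.0, 0.25),
    ]),
    ("hemoglobin", [
        BandSpec(754.0, 16.0, 0.80, 0.7),
        BandSpec(1337.0, 18.0, 0.55, 0.7),
        BandSpec(1545.0, 20.0, 0.45, 0.7),
        BandSpec(1620.0, 18.0, 0.35, 0.7),
    ]),
    ("cholesterol", [
        BandSpec(700.0, 14.0, 0.65),
        BandSpec(1440.0, 20.0, 0.90),
        BandSpec(1130.0, 18.0, 0.30),
        BandSpec(1672.0, 18.0, 0.25),
    ]),
    ("protein", [
        BandSpec(1003.0, 10.0, 1.00, 0.6),
        BandSpec(1447.0, 22.0, 0.70),
        BandSpec(1660.0, 26.0, 0.55),
        BandSpec(1240.0, 30.0, 0.35),
    ]),
]


def default_library(axis=None) -> ComponentLibrary:
    """Five-component brain basis (max-normalised so coefficients compare)."""
    if axis is None:
        axis = default_axis()
    return generate_component_library(_DEFAULT_BAND_TABLE, axis).max_normalized()


@dataclass(frozen=True)
class BaselineParams:
    """Smooth fluorescence background: ``amplitude * exp(-(x-x0)/decay)``
    plus a broad dome ``amplitude * curvature * (1 - u^2)`` with ``u`` the
    axis rescaled to [-1, 1]. Amplitude is in the same counts as the peaks."""

    amplitude: float = 5.0
    decay: float = 800.0
    curvature: float = 0.3

    def evaluate(self, axis) -> np.ndarray:
        axis = np.asarray(axis, dtype=float)
        lo, hi = axis[0], axis[-1]
        u = 2.0 * (axis - lo) / (hi - lo) - 1.0
        return self.amplitude * (np.exp(-(axis - lo) / self.decay)
                                 + self.curvature * (1.0 - u * u))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Mean mixing coefficients are per class per component; samples draw their
    coefficients from a zero-truncated normal around the class mean with
    coefficient of variation ``coefficient_cv``. Each sample is emitted as
    ``n_accumulations`` replicates with independent Gaussian channel noise and
    Poisson-count cosmic-ray spikes.
    """

    n_per_class: int
    class_names: tuple
    mean_coefficients: dict  # class -> {component -> mean coefficient}
    coefficient_cv: float = 0.15
    baseline_params: BaselineParams = field(default_factory=BaselineParams)
    noise_sd: float = 0.01
    spike_rate: float = 0.2
    n_accumulations: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise InvalidInputError("n_per_class must be >= 1")
        if self.n_accumulations < 1:
            raise InvalidInputError("n_accumulations must be >= 1")
        if self.noise_sd < 0 or self.spike_rate < 0 or self.coefficient_cv < 0:
            raise InvalidInputError("noise_sd, spike_rate and coefficient_cv must be >= 0")
        if set(self.mean_coefficients) != set(self.class_names):
            raise InvalidInputError("mean_coefficients must cover exactly the class names")
        for cls, means in self.mean_coefficients.items():
            for comp, m in means.items():
                if m < 0:
                    raise InvalidInputError(
                        f"mean coefficient for {cls}/{comp} must be >= 0")


# Control composition for the five-component basis; TBI classes scale
# cardiolipin down (50% for severe injury emulation).
_CONTROL_MEANS = {
    "cardiolipin": 1.0,
    "ganglioside": 0.8,
    "hemoglobin": 0.5,
    "cholesterol": 0.9,
    "protein": 1.0,
}


def default_cohort_config(n_per_class: int = 20, seed: int = 0,
                          cardiolipin_factor: float = 0.5,
                          noise_sd: float = 0.01,
                          spike_rate: float = 0.2,
                          coefficient_cv: float = 0.15) -> CohortConfig:
    """Two-class TBI-vs-control study conditions.

    The TBI class depletes cardiolipin to ``cardiolipin_factor`` of the
    control mean, which lowers the 1266 and 1660 cm^-1 bands.
    """
    tbi = dict(_CONTROL_MEANS)
    tbi["cardiolipin"] = _CONTROL_MEANS["cardiolipin"] * cardiolipin_factor
    return CohortConfig(
        n_per_class=n_per_class,
        class_names=("control", "TBI"),
        mean_coefficients={"control": dict(_CONTROL_MEANS), "TBI": tbi},
        coefficient_cv=coefficient_cv,
        noise_sd=noise_sd,
        spike_rate=spike_rate,
        seed=seed,
    )


@dataclass(frozen=True)
class LabeledCohort:
    """Raw synthetic cohort: per-sample accumulation stacks plus labels and
    (synthetic only) ground-truth mixing coefficients."""

    axis: np.ndarray
    accumulations: np.ndarray       # (n_samples, n_accumulations, n_channels)
    labels: tuple                   # class name per sample
    truth_coefficients: np.ndarray  # (n_samples, n_components)
    component_names: tuple
    clean: np.ndarray = None        # (n_samples, n_channels) noise-free truth

    def __post_init__(self):
        axis = _as_axis(self.axis)
        acc = np.asarray(self.accumulations, dtype=float)
        if acc.ndim != 3 or acc.shape[2] != axis.size:
            raise InvalidInputError("accumulations must be (samples, accs, channels)")
        if len(self.labels) != acc.shape[0]:
            raise InvalidInputError("labels length must equal sample count")
        truth = np.asarray(self.truth_coefficients, dtype=float)
        if np.any(truth < 0):
            raise InvalidInputError("truth coefficients must be >= 0")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "accumulations", acc)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "truth_coefficients", truth)
        object.__setattr__(self, "component_names", tuple(self.component_names))

    @property
    def n_samples(self) -> int:
        return self.accumulations.shape[0]

    def sample_stack(self, i: int) -> np.ndarray:
        return self.accumulations[i]

    def mean_spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.axis, self.accumulations[i].mean(axis=0))


def fluorescence_baseline(axis, params: BaselineParams) -> np.ndarray:
    return params.evaluate(axis)


def robust_scale(values) -> float:
    """MAD-based robust spread estimate (consistent with sigma for Gaussians)."""
    values = np.asarray(values, dtype=float)
    mad = np.median(np.abs(values - np.median(values)))
    return 1.4826 * mad


def inject_cosmic_rays(intensity, rate: float, seed) -> np.ndarray:
    """Add Poisson(rate) narrow high-amplitude spikes to a spectrum.

    Spikes are 1-3 channels wide with peak amplitude at least 10x the
    spectrum's robust scale, so downstream detection is well-posed. ``seed``
    may be an int or a ``numpy.random.Generator``.
    """
    if rate < 0:
        raise InvalidInputError("spike rate must be >= 0")
    y = np.asarray(intensity, dtype=float).copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_spikes = rng.poisson(rate)
    if n_spikes == 0:
        return y
    scale = robust_scale(y)
    if scale <= 0:
        scale = max(1.0, float(np.max(np.abs(y))) if y.size else 1.0)
    for _ in range(n_spikes):
        pos = int(rng.integers(0, y.size))
        width = int(rng.integers(1, 4))
        amp = scale * rng.uniform(10.0, 30.0)
        for k in range(width):
            j = pos + k
            if j < y.size:
                y[j] += amp * (1.0 - 0.5 * k)  # decaying shoulder over 1-3 channels
    return y


def _draw_truncated_normal(rng, mean: float, cv: float) -> float:
    """Zero-truncated normal around ``mean`` with relative spread ``cv``."""
    if mean == 0 or cv == 0:
        return mean
    sd = cv * mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0:
            return x
    return 0.0  # pathological cv; truncate hard


def generate_cohort(config: CohortConfig, library: ComponentLibrary) -> LabeledCohort:
    """Simulate one labelled cohort from the study conditions in ``config``.

    Fully reproducible from ``config.seed``; samples are ordered class by
    class in ``config.class_names`` order.
    """
    for cls in config.class_names:
        unknown = set(config.mean_coefficients[cls]) - set(library.names)
        if unknown:
            raise InvalidInputError(
                f"class {cls!r} references unknown components {sorted(unknown)}")
    axis = library.axis
    comp_names = library.names
    comp_matrix = library.matrix
    baseline = config.baseline_params.evaluate(axis)
    rng = np.random.default_rng(config.seed)

    stacks, labels, truths, cleans = [], [], [], []
    for cls in config.class_names:
        means = config.mean_coefficients[cls]
        for _ in range(config.n_per_class):
            coeffs = np.array([
                _draw_truncated_normal(rng, means.get(name, 0.0),
                                       config.coefficient_cv)
                for name in comp_names
            ])
            clean = coeffs @ comp_matrix + baseline
            stack = np.empty((config.n_accumulations, axis.size))
            for a in range(config.n_accumulations):
                y = clean + rng.normal(0.0, config.noise_sd, size=axis.size) \
                    if config.noise_sd > 0 else clean.copy()
                stack[a] = inject_cosmic_rays(y, config.spike_rate, rng)
            stacks.append(stack)
            labels.append(cls)
            truths.append(coeffs)
            cleans.append(clean)

    return LabeledCohort(
        axis=axis,
        accumulations=np.array(stacks),
        labels=tuple(labels),
        truth_coefficients=np.array(truths),
        component_names=tuple(comp_names),
        clean=np.array(cleans),
    )
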