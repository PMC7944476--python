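"""SKiNET: hexagonal self-organizing map with per-neuron class labels.

The map is a 2-D hexagonal array of neurons (pointy-top, axial coordinates).
Each neuron carries a spectral weight vector of the same length as the input
spectra and a non-negative label vector over classes. Training is online
Kohonen learning: for each presented spectrum the best-matching unit (BMU) is
found by Euclidean distance and the weights of the BMU and its hex
neighbourhood move toward the spectrum under a Gaussian kernel with decaying
learning rate and radius. Label vectors are co-trained toward the sample's
one-hot class with the same kernel, which makes the map simultaneously a
classifier (BMU label argmax) and an interpretable projection.

The SOM discriminant index (SOMDI) summarises, per class, which wavenumbers
drive activation toward that class: each neuron's weight vector is weighted
by the contrast between its label weight for the class and the mean label
weight of the other classes, summed over neurons and normalised to unit
Euclidean norm. Positive entries mark class-characteristic bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import DegenerateInputError, InvalidInputError

__all__ = [
    "TrainConfig",
    "SOMModel",
    "SOMDIResult",
    "hex_distance",
    "grid_coordinates",
    "train_som",
    "map_positions",
    "classify",
    "compute_somdi",
]


class StateError(RuntimeError):
    """Operation requires a trained model."""


def _axial_to_cube(coord):
    q, r = coord
    return q, -q - r, r


def hex_distance(coord_a, coord_b) -> int:
    """Shortest-path length between two hexes in axial coordinates."""
    ax, ay, az = _axial_to_cube(coord_a)
    bx, by, bz = _axial_to_cube(coord_b)
    return int((abs(ax - bx) + abs(ay - by) + abs(az - bz)) // 2)


def grid_coordinates(width: int, height: int) -> np.ndarray:
    """Axial (q, r) coordinates of a width x height pointy-top hex grid.

    Rows use odd-r offset layout converted to axial, so the grid tiles a
    roughly rectangular region. Linear index = r * width + q_offset.
    """
    coords = np.empty((width * height, 2), dtype=int)
    for row in range(height):
        for col in range(width):
            coords[row * width + col] = (col - (row - (row & 1)) // 2, row)
    return coords


@dataclass(frozen=True)
class TrainConfig:
    """SOM training schedule. Learning rate and neighbourhood radius decay
    exponentially from their initial to their final value over all updates."""

    grid_width: int = 10
    grid_height: int = 10
    n_iterations: int = 100          # epochs over the training set
    initial_learning_rate: float = 0.5
    final_learning_rate: float = 0.01
    initial_radius: float = None     # None: max(grid)/2
    final_radius: float = 1.0
    init_mode: str = "random-sample"  # or "pca-span"
    seed: int = 0

    def __post_init__(self):
        if self.grid_width < 1 or self.grid_height < 1 or self.n_iterations < 1:
            raise InvalidInputError("grid dimensions and iterations must be positive")
        if self.init_mode not in ("random-sample", "pca-span"):
            raise InvalidInputError("init_mode must be random-sample or pca-span")
        radius = self.initial_radius
        if radius is None:
            radius = max(self.grid_width, self.grid_height) / 2.0
            object.__setattr__(self, "initial_radius", radius)
        if radius <= 0 or radius > max(self.grid_width, self.grid_height):
            raise InvalidInputError("radius must be positive and <= max grid dimension")


@dataclass
class SOMModel:
    """Trained hexagonal SOM with spectral weights and class-label vectors."""

    grid_width: int
    grid_height: int
    axis: np.ndarray
    weights: np.ndarray        # (n_neurons, n_channels)
    label_weights: np.ndarray  # (n_neurons, n_classes), entries >= 0, row sums <= 1
    class_names: tuple
    coords: np.ndarray         # (n_neurons, 2) axial
    trained_iterations: int = 0
    seed: int = 0

    @property
    def n_neurons(self) -> int:
        return self.grid_width * self.grid_height

    def _check_spectra(self, spectra) -> np.ndarray:
        arr = np.asarray(spectra, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.shape[1] != self.axis.size:
            raise InvalidInputError(
                f"spectrum length {arr.shape[1]} does not match model axis "
                f"length {self.axis.size}")
        return arr

    def bmu_indices(self, spectra) -> np.ndarray:
        """Linear index of the best-matching unit per spectrum (ties resolve
        to the lowest linear index)."""
        arr = self._check_spectra(spectra)
        d2 = ((arr[:, None, :] - self.weights[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


@dataclass(frozen=True)
class SOMDIResult:
    """Per-class signed discriminant spectra on the model axis."""

    axis: np.ndarray
    class_names: tuple
    vectors: np.ndarray  # (n_classes, n_channels), each unit-norm

    def vector(self, class_name) -> np.ndarray:
        return self.vectors[self.class_names.index(class_name)]


def _pairwise_hex_distance(coords: np.ndarray) -> np.ndarray:
    q = coords[:, 0]
    r = coords[:, 1]
    s = -q - r
    dq = np.abs(q[:, None] - q[None, :])
    dr = np.abs(r[:, None] - r[None, :])
    ds = np.abs(s[:, None] - s[None, :])
    return (dq + dr + ds) // 2


def _init_weights(spectra, n_neurons, mode, rng) -> np.ndarray:
    n, p = spectra.shape
    if mode == "random-sample":
        idx = rng.integers(0, n, size=n_neurons)
        w = spectra[idx].copy()
        # tiny jitter so duplicate picks are not bit-identical attractor ties
        w += rng.normal(0.0, 1e-6 * max(1.0, float(np.abs(spectra).max())),
                        size=w.shape)
        return w
    # pca-span: grid laid out along the first two principal axes
    mean = spectra.mean(axis=0)
    centered = spectra - mean
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(2, vt.shape[0])
    g1 = np.linspace(-1, 1, int(np.sqrt(n_neurons)) or 1)
    grid = np.array(np.meshgrid(g1, g1)).reshape(2, -1).T
    grid = grid[:n_neurons]
    if grid.shape[0] < n_neurons:
        grid = np.vstack([grid, np.zeros((n_neurons - grid.shape[0], 2))])
    scale = centered.std(axis=0).mean() * np.sqrt(spectra.shape[1])
    return mean + scale * grid[:, :k] @ vt[:k]


def train_som(spectra, labels, config: TrainConfig, axis=None) -> SOMModel:
    """Train a hexagonal SOM with co-trained label vectors.

    ``spectra`` is an (n_samples, n_channels) matrix (normalised upstream);
    ``labels`` the class per row. Deterministic for a fixed config and seed.
    """
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise InvalidInputError("spectra must be a non-empty 2-D matrix")
    labels = list(labels)
    if len(labels) != X.shape[0]:
        raise InvalidInputError("labels length must match number of spectra")
    class_names = tuple(dict.fromkeys(labels))  # first-appearance order
    for cls in class_names:
        if labels.count(cls) < 1:
            raise InvalidInputError(f"class {cls!r} has no spectra")
    if axis is None:
        axis = np.arange(X.shape[1], dtype=float)
    axis = np.asarray(axis, dtype=float)
    if axis.size != X.shape[1]:
        raise InvalidInputError("axis length does not match spectra")

    onehot = np.zeros((X.shape[0], len(class_names)))
    for i, lab in enumerate(labels):
        onehot[i, class_names.index(lab)] = 1.0

    n_neurons = config.grid_width * config.grid_height
    coords = grid_coordinates(config.grid_width, config.grid_height)
    hex_d = _pairwise_hex_distance(coords)
    rng = np.random.default_rng(config.seed)

    W = _init_weights(X, n_neurons, config.init_mode, rng)
    L = np.zeros((n_neurons, len(class_names)))

    n = X.shape[0]
    total = config.n_iterations * n
    lr0, lr1 = config.initial_learning_rate, config.final_learning_rate
    r0, r1 = config.initial_radius, config.final_radius
    t = 0
    for _ in range(config.n_iterations):
        order = rng.permutation(n)
        for i in order:
            frac = t / max(total - 1, 1)
            lr = lr0 * (lr1 / lr0) ** frac
            sigma = r0 * (r1 / r0) ** frac
            x = X[i]
            d2 = ((W - x) ** 2).sum(axis=1)
            bmu = int(d2.argmin())
            h = np.exp(-(hex_d[bmu].astype(float) ** 2) / (2.0 * sigma * sigma))
            step = (lr * h)[:, None]
            W += step * (x - W)
            L += step * (onehot[i] - L)
            t += 1

    return SOMModel(
        grid_width=config.grid_width,
        grid_height=config.grid_height,
        axis=axis,
        weights=W,
        label_weights=L,
        class_names=class_names,
        coords=coords,
        trained_iterations=config.n_iterations,
        seed=config.seed,
    )


def map_positions(model: SOMModel, spectra) -> list:
    """Axial BMU coordinates per spectrum (tie-break: lowest linear index)."""
    idx = model.bmu_indices(spectra)
    return [tuple(model.coords[i]) for i in idx]


def classify(model: SOMModel, spectrum):
    """Classify one spectrum: (class label, confidence in [0, 1]).

    The label is the BMU's label-weight argmax (ties to the first-listed
    class); confidence is the BMU's label weight for that class normalised
    over classes, 1/n_classes when the BMU carries no label mass.
    """
    if model.trained_iterations < 1:
        raise StateError("model has not been trained")
    bmu = int(model.bmu_indices(spectrum)[0])
    lw = model.label_weights[bmu]
    k = int(lw.argmax())
    total = lw.sum()
    conf = float(lw[k] / total) if total > 0 else 1.0 / len(model.class_names)
    return model.class_names[k], conf


def compute_somdi(model: SOMModel) -> SOMDIResult:
    """SOM discriminant index: per-class signed feature spectra.

    For class c the discriminant vector is
    ``sum_n (L[n, c] - mean_{c' != c} L[n, c']) * W[n]``, normalised by the
    total weight-vector mass ``sum_n ||W[n]||`` so the result is dimensionless
    and comparable across maps. Positive entries mark wavenumbers that pull
    neurons toward class c; when the class distributions are identical the
    label contrasts vanish and the discriminant magnitude collapses toward
    zero (the permutation noise floor).
    """
    n_classes = len(model.class_names)
    if n_classes < 2:
        raise DegenerateInputError("SOMDI needs at least two classes to contrast")
    L, W = model.label_weights, model.weights
    mass = float(np.linalg.norm(W, axis=1).sum())
    if mass <= 0:
        mass = 1.0
    vectors = np.empty((n_classes, model.axis.size))
    for c in range(n_classes):
        others = [j for j in range(n_classes) if j != c]
        contrast = L[:, c] - L[:, others].mean(axis=1)
        vectors[c] = (contrast @ W) / mass
    return SOMDIResult(axis=model.axis, class_names=model.class_names,
                       vectors=vectors)
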