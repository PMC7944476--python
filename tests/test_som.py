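"""Hexagonal SOM training, BMU search, classification and SOMDI."""

import collections

import numpy as np
import pytest

from neuroraman import (
    BandSpec,
    DegenerateInputError,
    InvalidInputError,
    TrainConfig,
    classify,
    compute_somdi,
    generate_component_library,
    hex_distance,
    map_positions,
    train_som,
)
from neuroraman.som import SOMModel, StateError, grid_coordinates

AXIAL_NEIGHBOURS = [(1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)]


def bfs_hex_distance(a, b, limit=30):
    """Breadth-first search over the hex adjacency graph (oracle)."""
    frontier, seen, d = [tuple(a)], {tuple(a)}, 0
    while frontier and d <= limit:
        if tuple(b) in frontier:
            return d
        nxt = []
        for q, r in frontier:
            for dq, dr in AXIAL_NEIGHBOURS:
                c = (q + dq, r + dr)
                if c not in seen:
                    seen.add(c)
                    nxt.append(c)
        frontier, d = nxt, d + 1
    raise AssertionError("BFS limit exceeded")


class TestHexDistance:
    def test_zero_for_identical(self):
        assert hex_distance((3, -1), (3, -1)) == 0

    @pytest.mark.parametrize("offset", AXIAL_NEIGHBOURS)
    def test_adjacent_is_one(self, offset):
        assert hex_distance((0, 0), offset) == 1

    def test_matches_bfs_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            a = tuple(rng.integers(-5, 6, size=2))
            b = tuple(rng.integers(-5, 6, size=2))
            assert hex_distance(a, b) == bfs_hex_distance(a, b)

    def test_grid_coordinates_unique_and_adjacent_rows(self):
        coords = grid_coordinates(6, 5)
        assert len({tuple(c) for c in coords}) == 30
        # consecutive neurons in a row are hex-adjacent
        for r in range(5):
            for c in range(5):
                i = r * 6 + c
                assert hex_distance(coords[i], coords[i + 1]) == 1


def _two_class_data(n_per_class=12, seed=0, sep=1.0, normalize=True):
    """Spectra with disjoint dominant bands per class, low noise."""
    axis = np.arange(600.0, 1201.0)
    lib = generate_component_library([
        ("A", [BandSpec(800.0, 20.0, 1.0)]),
        ("B", [BandSpec(1000.0, 20.0, 1.0)]),
    ], axis)
    rng = np.random.default_rng(seed)
    X, labels = [], []
    for cls, comp in (("a", "A"), ("b", "B")):
        for _ in range(n_per_class):
            y = (1.0 + 0.1 * rng.normal()) * lib[comp] * sep \
                + 0.3 * (lib["A"] + lib["B"]) + rng.normal(0, 0.01, axis.size)
            if normalize:
                y = y / np.linalg.norm(y)
            X.append(y)
            labels.append(cls)
    return axis, np.vstack(X), labels


def _one_band_difference_data(n_per_class=12, seed=0):
    """Two classes sharing one band, differing only in the 800 cm^-1 band
    amplitude (unnormalised, so the difference stays local)."""
    axis = np.arange(600.0, 1201.0)
    lib = generate_component_library([
        ("A", [BandSpec(800.0, 20.0, 1.0)]),
        ("B", [BandSpec(1000.0, 20.0, 1.0)]),
    ], axis)
    rng = np.random.default_rng(seed)
    X, labels = [], []
    for cls, amp in (("high", 1.3), ("low", 0.7)):
        for _ in range(n_per_class):
            y = amp * (1.0 + 0.05 * rng.normal()) * lib["A"] \
                + (1.0 + 0.05 * rng.normal()) * lib["B"] \
                + rng.normal(0, 0.01, axis.size)
            X.append(y)
            labels.append(cls)
    return axis, np.vstack(X), labels


class TestTrainSOM:
    def test_identical_spectra_single_attractor(self):
        x = np.abs(np.sin(np.linspace(0, 5, 200))) + 0.1
        X = np.tile(x, (10, 1))
        model = train_som(X, ["only"] * 10,
                          TrainConfig(grid_width=4, grid_height=4,
                                      n_iterations=150, seed=1))
        assert np.max(np.abs(model.weights - x)) < 1e-2

    def test_deterministic_given_seed(self):
        axis, X, labels = _two_class_data(6, seed=2)
        cfg = TrainConfig(grid_width=5, grid_height=4, n_iterations=30, seed=9)
        m1 = train_som(X, labels, cfg, axis=axis)
        m2 = train_som(X, labels, cfg, axis=axis)
        assert np.array_equal(m1.weights, m2.weights)
        assert np.array_equal(m1.label_weights, m2.label_weights)

    def test_separated_classes_occupy_disjoint_map_regions(self):
        axis, X, labels = _two_class_data(12, seed=3)
        model = train_som(X, labels, TrainConfig(grid_width=6, grid_height=6,
                                                 n_iterations=60, seed=4),
                          axis=axis)
        regions = collections.defaultdict(set)
        for pos, lab in zip(map_positions(model, X), labels):
            regions[lab].add(pos)
        assert not regions["a"] & regions["b"]

    def test_label_weights_bounded_throughout(self):
        axis, X, labels = _two_class_data(8, seed=5)
        model = train_som(X, labels, TrainConfig(grid_width=4, grid_height=4,
                                                 n_iterations=40, seed=6),
                          axis=axis)
        assert np.all(model.label_weights >= 0)
        assert np.all(model.label_weights.sum(axis=1) <= 1 + 1e-12)

    def test_empty_or_mismatched_input_rejected(self):
        with pytest.raises(InvalidInputError):
            train_som(np.empty((0, 5)), [], TrainConfig(seed=0))
        with pytest.raises(InvalidInputError):
            train_som(np.ones((3, 5)), ["a", "b"], TrainConfig(seed=0))


class TestBMUAndClassify:
    def test_spectrum_equal_to_weight_maps_to_that_neuron(self):
        axis, X, labels = _two_class_data(6, seed=7)
        model = train_som(X, labels, TrainConfig(grid_width=4, grid_height=3,
                                                 n_iterations=20, seed=8),
                          axis=axis)
        for n in (0, 5, 11):
            pos = map_positions(model, model.weights[n])[0]
            assert pos == tuple(model.coords[n])

    def test_tie_breaks_to_lowest_linear_index(self):
        coords = grid_coordinates(2, 2)
        weights = np.ones((4, 10))  # all neurons equidistant from anything
        model = SOMModel(grid_width=2, grid_height=2, axis=np.arange(10.0),
                         weights=weights, label_weights=np.zeros((4, 1)),
                         class_names=("x",), coords=coords, trained_iterations=1)
        assert map_positions(model, np.zeros(10))[0] == tuple(coords[0])

    def test_bmu_matches_brute_force_oracle(self):
        axis, X, labels = _two_class_data(8, seed=10)
        model = train_som(X, labels, TrainConfig(grid_width=5, grid_height=5,
                                                 n_iterations=25, seed=11),
                          axis=axis)
        rng = np.random.default_rng(12)
        probes = rng.normal(0, 1, size=(40, axis.size))
        for p in probes:
            best, best_d = 0, np.inf
            for n in range(model.n_neurons):
                d = float(((model.weights[n] - p) ** 2).sum())
                if d < best_d - 1e-15:
                    best, best_d = n, d
            assert model.bmu_indices(p)[0] == best

    def test_training_spectra_classified_correctly(self):
        axis, X, labels = _two_class_data(10, seed=13)
        model = train_som(X, labels, TrainConfig(grid_width=6, grid_height=6,
                                                 n_iterations=60, seed=14),
                          axis=axis)
        pred = [classify(model, x)[0] for x in X]
        assert np.mean([p == l for p, l in zip(pred, labels)]) == 1.0

    def test_uniform_label_weights_confidence(self):
        coords = grid_coordinates(2, 2)
        model = SOMModel(grid_width=2, grid_height=2, axis=np.arange(5.0),
                         weights=np.zeros((4, 5)),
                         label_weights=np.full((4, 4), 0.25),
                         class_names=("a", "b", "c", "d"), coords=coords,
                         trained_iterations=1)
        _, conf = classify(model, np.zeros(5))
        assert conf == pytest.approx(0.25)

    def test_untrained_model_raises_state_error(self):
        coords = grid_coordinates(2, 2)
        model = SOMModel(grid_width=2, grid_height=2, axis=np.arange(5.0),
                         weights=np.zeros((4, 5)),
                         label_weights=np.zeros((4, 2)),
                         class_names=("a", "b"), coords=coords,
                         trained_iterations=0)
        with pytest.raises(StateError):
            classify(model, np.zeros(5))

    def test_axis_mismatch_rejected(self):
        axis, X, labels = _two_class_data(6, seed=15)
        model = train_som(X, labels, TrainConfig(grid_width=3, grid_height=3,
                                                 n_iterations=10, seed=16),
                          axis=axis)
        with pytest.raises(InvalidInputError):
            map_positions(model, np.zeros(17))


class TestSOMDI:
    def test_single_differential_band_localized(self):
        """Classes differing in one band put the SOMDI |max| within 10 cm^-1
        of that band center."""
        axis, X, labels = _one_band_difference_data(12, seed=17)
        model = train_som(X, labels, TrainConfig(grid_width=6, grid_height=6,
                                                 n_iterations=60, seed=18),
                          axis=axis)
        somdi = compute_somdi(model)
        for cls in ("high", "low"):
            v = somdi.vector(cls)
            assert abs(axis[np.abs(v).argmax()] - 800.0) <= 10.0

    def test_identical_distributions_collapse_to_noise_floor(self):
        """Labels carrying no information leave only permutation noise."""
        axis = np.arange(600.0, 901.0)
        rng = np.random.default_rng(19)
        base = np.abs(np.sin(axis / 40.0)) + 0.5
        X = np.vstack([base + rng.normal(0, 0.02, axis.size) for _ in range(20)])
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        labels = ["a"] * 10 + ["b"] * 10
        cfg = dict(grid_width=5, grid_height=5, n_iterations=40)
        null = train_som(X, labels, TrainConfig(seed=20, **cfg), axis=axis)
        null_norm = np.linalg.norm(compute_somdi(null).vectors, axis=1).max()
        # permutation floor on genuinely structured data
        axis2, X2, labels2 = _two_class_data(10, seed=21)
        real = train_som(X2, labels2, TrainConfig(seed=22, **cfg), axis=axis2)
        real_norm = np.linalg.norm(compute_somdi(real).vectors, axis=1).max()
        perm_norms = []
        for s in range(3):
            rng2 = np.random.default_rng(100 + s)
            shuffled = list(rng2.permutation(labels2))
            m = train_som(X2, shuffled, TrainConfig(seed=200 + s, **cfg),
                          axis=axis2)
            perm_norms.append(
                np.linalg.norm(compute_somdi(m).vectors, axis=1).max())
        floor = max(perm_norms)
        assert null_norm <= 2 * floor
        assert real_norm > 3 * floor

    def test_single_class_model_degenerate(self):
        x = np.ones(50)
        model = train_som(np.tile(x, (5, 1)), ["only"] * 5,
                          TrainConfig(grid_width=3, grid_height=3,
                                      n_iterations=5, seed=23))
        with pytest.raises(DegenerateInputError):
            compute_somdi(model)


def test_neighborhood_update_monotone_in_hex_distance():
    """One online update moves closer neurons further: the update magnitude
    is non-increasing in hex distance from the BMU."""
    axis, X, labels = _two_class_data(4, seed=24)
    cfg = TrainConfig(grid_width=5, grid_height=5, n_iterations=1, seed=25)
    before = train_som(X[:1], labels[:1],
                       TrainConfig(grid_width=5, grid_height=5,
                                   n_iterations=1, seed=25,
                                   initial_learning_rate=1e-9,
                                   final_learning_rate=1e-9), axis=axis)
    after = train_som(X[:1], labels[:1], cfg, axis=axis)
    # same seed => same init; the movement fraction toward the spectrum is
    # exactly learning_rate x kernel, so it must decay with hex distance
    gap = np.linalg.norm(X[0] - before.weights, axis=1)
    move = np.linalg.norm(after.weights - before.weights, axis=1)
    frac = move / np.where(gap > 0, gap, 1.0)
    bmu = int(before.bmu_indices(X[0])[0])
    d = np.array([hex_distance(before.coords[bmu], c) for c in before.coords])
    for dist in range(d.max()):
        assert frac[d == dist].min() >= frac[d == dist + 1].max() - 1e-9
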