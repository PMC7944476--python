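"""End-to-end pipeline: simulate/read -> preprocess -> SOM -> SOMDI -> unmix.

One seeded run produces, under the output directory: the preprocessed
per-sample spectra, the trained-map export (neuron coordinates, majority
class, label weights), held-out classification results, SOMDI discriminant
spectra with their top bands, the NNLS coefficient table with per-component
ANOVA, a JSON report and a manifest with checksums of every artifact.
Deterministic stages reproduce identical checksums for identical config and
seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score
from sklearn.model_selection import train_test_split

from . import __version__
from .io import (
    cohort_config_from_yaml,
    read_labels,
    read_spectrum,
    write_spectrum_csv,
)
from .preprocess import PreprocessConfig, preprocess_stack
from .som import TrainConfig, classify, compute_somdi, map_positions, train_som
from .spectra import InvalidInputError, Spectrum
from .synthetic import default_library, generate_cohort
from .unmixing import group_compare, unmix_cohort

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "top_somdi_bands"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one input source: a synthetic cohort config XOR a directory of
    measured spectra (with a labels CSV). The global seed drives cohort
    generation, the train/test split and SOM initialisation.
    """

    seed: int
    output_dir: Path
    synthetic: dict = None           # CohortConfig-shaped mapping
    spectra_dir: Path = None
    labels_file: Path = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    train: dict = field(default_factory=dict)   # TrainConfig overrides
    include_offset: bool = True
    test_fraction: float = 0.3
    som_normalization: str = "vector"
    log_level: str = "info"

    def __post_init__(self):
        if (self.synthetic is None) == (self.spectra_dir is None):
            raise InvalidInputError(
                "exactly one input source required: synthetic config XOR spectra_dir")
        if self.spectra_dir is not None and self.labels_file is None:
            raise InvalidInputError("spectra_dir input requires a labels_file")
        if self.seed is None:
            raise InvalidInputError("pipeline config must state a seed")
        object.__setattr__(self, "output_dir", Path(self.output_dir))

    @classmethod
    def from_mapping(cls, cfg: dict, output_dir=None, seed=None) -> "PipelineConfig":
        cfg = dict(cfg)
        pp = cfg.pop("preprocess", {})
        if isinstance(pp, dict) and pp.get("target_axis") is not None:
            ta = pp["target_axis"]
            pp["target_axis"] = np.arange(float(ta["start"]),
                                          float(ta["stop"]) + 1e-9,
                                          float(ta.get("step", 1.0)))
        preprocess = pp if isinstance(pp, PreprocessConfig) else PreprocessConfig(**pp)
        return cls(
            seed=int(seed if seed is not None else cfg.pop("seed")),
            output_dir=Path(output_dir or cfg.pop("output_dir", "results/run")),
            synthetic=cfg.pop("synthetic", None),
            spectra_dir=cfg.pop("spectra_dir", None),
            labels_file=cfg.pop("labels_file", None),
            preprocess=preprocess,
            train=cfg.pop("train", {}),
            include_offset=bool(cfg.pop("include_offset", True)),
            test_fraction=float(cfg.pop("test_fraction", 0.3)),
            som_normalization=cfg.pop("som_normalization", "vector"),
            log_level=cfg.pop("log_level", "info"),
        )


@dataclass
class RunManifest:
    """Record of one pipeline run: config hash, seed, artifact checksums."""

    config_hash: str
    version: str
    seed: int
    checksums: dict = field(default_factory=dict)  # relative path -> sha256
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps({
            "config_hash": self.config_hash,
            "version": self.version,
            "seed": self.seed,
            "checksums": self.checksums,
            "timestamp": self.timestamp,
        }, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _hash_config(config: PipelineConfig) -> str:
    payload = repr((config.seed, config.synthetic, str(config.spectra_dir),
                    config.preprocess, sorted(config.train.items()),
                    config.include_offset, config.test_fraction,
                    config.som_normalization))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def top_somdi_bands(somdi, class_name, n_bands: int = 5,
                    min_separation: float = 20.0) -> list:
    """Wavenumbers of the strongest |SOMDI| local features for one class,
    greedily picked with a minimum separation so one broad band is not
    reported five times."""
    v = np.abs(somdi.vector(class_name))
    axis = somdi.axis
    order = np.argsort(v)[::-1]
    picked = []
    for i in order:
        x = axis[i]
        if all(abs(x - p) >= min_separation for p in picked):
            picked.append(float(x))
        if len(picked) >= n_bands:
            break
    return picked


def _load_measured(config: PipelineConfig):
    labels_df = read_labels(config.labels_file)
    spectra, labels, ids = [], [], []
    for _, row in labels_df.iterrows():
        sid = str(row["sample_id"])
        path = Path(config.spectra_dir) / f"{sid}.csv"
        spec = read_spectrum(path)
        spectra.append(np.atleast_2d(spec.intensity))
        labels.append(str(row["class"]))
        ids.append(sid)
        axis = spec.axis
    return axis, spectra, labels, ids


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis and write all artifacts plus a manifest."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # --- input stage: synthetic cohort or measured spectra -----------------
    library = None
    if config.synthetic is not None:
        cohort_cfg = cohort_config_from_yaml(dict(config.synthetic,
                                                  seed=config.seed))
        library = default_library()
        cohort = generate_cohort(cohort_cfg, library)
        axis = cohort.axis
        stacks = [cohort.sample_stack(i) for i in range(cohort.n_samples)]
        labels = list(cohort.labels)
        ids = [f"s{i:03d}" for i in range(cohort.n_samples)]
    else:
        axis, stacks, labels, ids = _load_measured(config)
        library = default_library(axis=axis)

    # --- preprocess --------------------------------------------------------
    pp_none = PreprocessConfig(
        spike_threshold=config.preprocess.spike_threshold,
        baseline_nodes=config.preprocess.baseline_nodes,
        baseline_iterations=config.preprocess.baseline_iterations,
        target_axis=config.preprocess.target_axis,
        normalization="none",
    )
    clean = [preprocess_stack(axis, s, pp_none) for s in stacks]
    spec_dir = out / "preprocessed"
    spec_dir.mkdir(exist_ok=True)
    for sid, spec in zip(ids, clean):
        write_spectrum_csv(spec, spec_dir / f"{sid}.csv")
    if config.preprocess.target_axis is not None:
        axis_out = clean[0].axis
        library = default_library(axis=axis_out)

    # --- split + SOM training ---------------------------------------------
    X = np.vstack([s.intensity for s in clean])
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    Xn = X / np.where(norms > 0, norms, 1.0) if config.som_normalization == "vector" else X
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx, test_size=config.test_fraction, stratify=labels,
        random_state=int(rng.integers(0, 2**31 - 1)), shuffle=True)
    tc = TrainConfig(seed=int(rng.integers(0, 2**31 - 1)), **config.train)
    model = train_som(Xn[train_idx], [labels[i] for i in train_idx], tc,
                      axis=clean[0].axis)

    positions = map_positions(model, Xn)
    pred = [classify(model, Xn[i])[0] for i in test_idx]
    truth = [labels[i] for i in test_idx]
    accuracy = float(accuracy_score(truth, pred))

    pd.DataFrame({
        "sample_id": ids, "class": labels,
        "q": [p[0] for p in positions], "r": [p[1] for p in positions],
        "split": ["test" if i in set(test_idx) else "train" for i in idx],
    }).to_csv(out / "map_positions.csv", index=False)

    # map export: per-neuron coordinates, majority class, label weights
    lw = model.label_weights
    majority = [model.class_names[int(k)] if lw[n].sum() > 0 else ""
                for n, k in enumerate(lw.argmax(axis=1))]
    map_df = pd.DataFrame({"q": model.coords[:, 0], "r": model.coords[:, 1],
                           "majority_class": majority})
    for c, name in enumerate(model.class_names):
        map_df[f"w_{name}"] = lw[:, c]
    map_df.to_csv(out / "som_map.csv", index=False, float_format="%.10g")

    # --- SOMDI --------------------------------------------------------------
    somdi = compute_somdi(model)
    somdi_df = pd.DataFrame({"wavenumber_cm-1": somdi.axis})
    for name in model.class_names:
        somdi_df[name] = somdi.vector(name)
    somdi_df.to_csv(out / "somdi.csv", index=False, float_format="%.10g")
    top_bands = {name: top_somdi_bands(somdi, name)
                 for name in model.class_names}

    # --- unmixing + group statistics ---------------------------------------
    results = unmix_cohort(clean, labels, library, sample_ids=ids,
                           include_offset=config.include_offset)
    results.to_csv(out / "coefficients.csv", index=False, float_format="%.10g")
    comparison = group_compare(results)
    comparison.table.to_csv(out / "group_stats.csv", float_format="%.10g")

    # --- report -------------------------------------------------------------
    per_class_acc = {}
    for cls in model.class_names:
        mask = [t == cls for t in truth]
        if any(mask):
            per_class_acc[cls] = float(np.mean(
                [p == t for p, t, m in zip(pred, truth, mask) if m]))
    boxplot = {
        comp: {cls: sorted(results.loc[(results["component"] == comp)
                                       & (results["class"] == cls),
                                       "coefficient"].tolist())
               for cls in model.class_names}
        for comp in library.names
    }
    report = {
        "n_samples": len(ids),
        "classes": list(model.class_names),
        "held_out_accuracy": accuracy,
        "per_class_accuracy": per_class_acc,
        "top_somdi_bands": top_bands,
        "anova_p_values": {c: comparison.p_value(c) for c in library.names},
        "coefficient_boxplot_data": boxplot,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    # --- manifest ------------------------------------------------------------
    manifest = RunManifest(
        config_hash=_hash_config(config),
        version=__version__,
        seed=config.seed,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.checksums[str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
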