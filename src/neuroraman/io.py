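"""Readers and writers: CSV spectra, JCAMP-DX, cohort tables, YAML config.

CSV dialect: comma-separated, dot decimal, UTF-8; a header row is
auto-detected (first field non-numeric). JCAMP-DX support covers the plain
``##XYDATA=(XY..XY)`` form, enough to round-trip spectra written by this
package and exchange with other chemometrics tools.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectra import InvalidInputError, Spectrum
from .synthetic import BaselineParams, CohortConfig, LabeledCohort

__all__ = [
    "ParseError",
    "read_spectrum",
    "write_spectrum_csv",
    "write_spectrum_jcamp",
    "write_cohort",
    "read_labels",
    "cohort_config_from_yaml",
    "load_config",
]


class ParseError(ValueError):
    """Malformed spectrum or config file; message names the offending line."""


def _sorted_spectrum(axis, intensity, source: str) -> Spectrum:
    axis = np.asarray(axis, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if axis.size >= 2 and np.all(np.diff(axis) < 0):
        warnings.warn(f"{source}: descending wavenumber axis; re-sorting ascending",
                      stacklevel=3)
        axis, intensity = axis[::-1].copy(), intensity[::-1].copy()
    elif axis.size >= 2 and not np.all(np.diff(axis) > 0):
        order = np.argsort(axis, kind="stable")
        axis, intensity = axis[order], intensity[order]
        warnings.warn(f"{source}: unsorted wavenumber axis; re-sorting ascending",
                      stacklevel=3)
    return Spectrum(axis, intensity)


def _read_csv_spectrum(path: Path) -> Spectrum:
    axis, intensity = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected two comma-separated fields")
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1 and not axis:  # header row
                    continue
                raise ParseError(f"{path}:{lineno}: non-numeric value in {line!r}")
            axis.append(x)
            intensity.append(y)
    if len(axis) < 2:
        raise ParseError(f"{path}: fewer than 2 data rows")
    return _sorted_spectrum(axis, intensity, str(path))


def _read_jcamp_spectrum(path: Path) -> Spectrum:
    axis, intensity = [], []
    in_xy = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.upper().startswith("##XYDATA"):
                in_xy = True
                continue
            if line.startswith("##"):
                in_xy = False
                continue
            if in_xy:
                for pair in line.replace(";", " ").split():
                    fields = pair.split(",")
                    if len(fields) != 2:
                        raise ParseError(
                            f"{path}:{lineno}: expected 'x,y' pairs, got {pair!r}")
                    try:
                        axis.append(float(fields[0]))
                        intensity.append(float(fields[1]))
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: non-numeric value in {pair!r}")
    if len(axis) < 2:
        raise ParseError(f"{path}: no XYDATA block with >= 2 points found")
    return _sorted_spectrum(axis, intensity, str(path))


def read_spectrum(path, format: str = None) -> Spectrum:
    """Read one spectrum from CSV or JCAMP-DX (format inferred from suffix
    when not given). A descending axis is re-sorted ascending with a warning."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    if format is None:
        format = "jcamp-dx" if path.suffix.lower() in (".jdx", ".dx") else "csv"
    if format == "csv":
        return _read_csv_spectrum(path)
    if format == "jcamp-dx":
        return _read_jcamp_spectrum(path)
    raise InvalidInputError(f"unknown spectrum format {format!r}")


def write_spectrum_csv(spectrum: Spectrum, path, header: bool = True) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("wavenumber_cm-1,intensity\n")
        for x, y in zip(spectrum.axis, spectrum.intensity):
            fh.write(f"{x:.10g},{y:.10g}\n")


def write_spectrum_jcamp(spectrum: Spectrum, path, title: str = "spectrum") -> None:
    """Write a minimal JCAMP-DX file with an (XY..XY) data table."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"##TITLE={title}\n")
        fh.write("##JCAMP-DX=4.24\n")
        fh.write("##DATA TYPE=RAMAN SPECTRUM\n")
        fh.write("##XUNITS=1/CM\n")
        fh.write("##YUNITS=ARBITRARY UNITS\n")
        fh.write(f"##FIRSTX={spectrum.axis[0]:.10g}\n")
        fh.write(f"##LASTX={spectrum.axis[-1]:.10g}\n")
        fh.write(f"##NPOINTS={len(spectrum)}\n")
        fh.write("##XYDATA=(XY..XY)\n")
        for x, y in zip(spectrum.axis, spectrum.intensity):
            fh.write(f"{x:.10g},{y:.17g}\n")
        fh.write("##END=\n")


def write_cohort(cohort: LabeledCohort, outdir, jcamp_average: bool = False) -> dict:
    """Write a cohort to disk: one CSV per sample (wavenumber + one column per
    accumulation), a labels CSV and a ground-truth coefficient CSV. Returns a
    dict of the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"samples": []}
    for i in range(cohort.n_samples):
        sid = f"s{i:03d}"
        cols = {"wavenumber_cm-1": cohort.axis}
        for a in range(cohort.accumulations.shape[1]):
            cols[f"acc{a:02d}"] = cohort.accumulations[i, a]
        p = outdir / f"{sid}.csv"
        pd.DataFrame(cols).to_csv(p, index=False, float_format="%.10g")
        paths["samples"].append(p)
        if jcamp_average:
            write_spectrum_jcamp(cohort.mean_spectrum(i),
                                 outdir / f"{sid}.jdx", title=sid)
    labels = pd.DataFrame({
        "sample_id": [f"s{i:03d}" for i in range(cohort.n_samples)],
        "class": list(cohort.labels),
    })
    paths["labels"] = outdir / "labels.csv"
    labels.to_csv(paths["labels"], index=False)
    truth_rows = []
    for i in range(cohort.n_samples):
        for j, comp in enumerate(cohort.component_names):
            truth_rows.append({"sample_id": f"s{i:03d}", "component": comp,
                               "coefficient": cohort.truth_coefficients[i, j]})
    paths["truth"] = outdir / "truth.csv"
    pd.DataFrame(truth_rows).to_csv(paths["truth"], index=False,
                                    float_format="%.10g")
    return paths


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"sample_id", "class"} <= set(df.columns):
        raise ParseError(f"{path}: labels CSV needs sample_id and class columns")
    return df


def cohort_config_from_yaml(mapping: dict) -> CohortConfig:
    """Build a CohortConfig from a YAML mapping mirroring its fields."""
    m = dict(mapping)
    if "seed" not in m:
        raise InvalidInputError("cohort config must state a seed")
    baseline = m.pop("baseline_params", None)
    if isinstance(baseline, dict):
        baseline = BaselineParams(**baseline)
    kwargs = dict(
        n_per_class=int(m.pop("n_per_class")),
        class_names=tuple(m.pop("class_names")),
        mean_coefficients={k: dict(v) for k, v in m.pop("mean_coefficients").items()},
        seed=int(m.pop("seed")),
    )
    if baseline is not None:
        kwargs["baseline_params"] = baseline
    for key in ("coefficient_cv", "noise_sd", "spike_rate"):
        if key in m:
            kwargs[key] = float(m.pop(key))
    if "n_accumulations" in m:
        kwargs["n_accumulations"] = int(m.pop("n_accumulations"))
    if m:
        raise InvalidInputError(f"unknown cohort config keys: {sorted(m)}")
    return CohortConfig(**kwargs)


def load_config(path) -> dict:
    """Load a YAML pipeline config into a plain mapping."""
    with open(path, encoding="utf-8") as fh:
        try:
            cfg = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ParseError(f"{path}: invalid YAML ({exc})")
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    return cfg
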