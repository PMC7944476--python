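"""Non-negative least-squares unmixing of tissue spectra into lipid components.

A measured brain spectrum is modelled as a non-negative combination of
reference component spectra (cardiolipin, ganglioside, hemoglobin,
cholesterol, protein), optionally plus a constant offset absorbing residual
baseline. The fitted coefficients are concentration proxies: group-level
shifts (e.g. cardiolipin depletion after traumatic brain injury) are tested
per component with one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .spectra import (
    ComponentLibrary,
    DegenerateInputError,
    InvalidInputError,
    Spectrum,
)

__all__ = [
    "UnmixResult",
    "GroupComparison",
    "nnls_fit",
    "unmix_cohort",
    "fit_somdi_components",
    "group_compare",
]

_OFFSET_NAME = "__offset__"


@dataclass(frozen=True)
class UnmixResult:
    """Non-negative coefficients per component plus fit residual norm."""

    coefficients: dict          # component name -> coefficient >= 0
    residual_norm: float
    include_offset: bool
    offset: float = 0.0

    def as_array(self, names) -> np.ndarray:
        return np.array([self.coefficients[n] for n in names])


@dataclass(frozen=True)
class GroupComparison:
    """Per-component one-way ANOVA across class groups."""

    groups: tuple
    table: pd.DataFrame  # index: component; columns: per-group mean/var, F, p

    def p_value(self, component) -> float:
        return float(self.table.loc[component, "p_value"])


def _design_matrix(library: ComponentLibrary, include_offset: bool,
                   normalize_components: bool):
    lib = library.max_normalized() if normalize_components else library
    A = lib.matrix.T  # (n_channels, n_components)
    if np.any(A.max(axis=0) <= 0):
        bad = [n for n, v in lib.components.items() if v.max() <= 0]
        raise DegenerateInputError(f"all-zero library component(s): {bad}")
    names = list(lib.names)
    if include_offset:
        A = np.column_stack([A, np.ones(A.shape[0])])
        names.append(_OFFSET_NAME)
    return A, names


def nnls_fit(spectrum: Spectrum, library: ComponentLibrary,
             include_offset: bool = True,
             normalize_components: bool = True) -> UnmixResult:
    """Fit the component library to one spectrum with non-negative
    least squares.

    Minimises ``||y - sum_i c_i K_i (+ c0 * 1)||_2`` subject to ``c_i >= 0``
    (the offset coefficient, when fitted, is likewise non-negative).
    Components are peak-normalised before fitting by default so coefficients
    are comparable across components.
    """
    if not np.array_equal(spectrum.axis, library.axis):
        raise InvalidInputError("spectrum and library must share an identical axis")
    A, names = _design_matrix(library, include_offset, normalize_components)
    coeffs, rnorm = nnls(A, spectrum.intensity)
    offset = 0.0
    if include_offset:
        offset = float(coeffs[-1])
        coeffs = coeffs[:-1]
        names = names[:-1]
    return UnmixResult(
        coefficients=dict(zip(names, (float(c) for c in coeffs))),
        residual_norm=float(rnorm),
        include_offset=include_offset,
        offset=offset,
    )


def unmix_cohort(spectra, labels, library: ComponentLibrary,
                 sample_ids=None, include_offset: bool = True,
                 normalize_components: bool = True) -> pd.DataFrame:
    """Fit every per-sample average spectrum and tabulate the coefficients.

    ``spectra`` is a sequence of :class:`Spectrum` (one per sample, already
    preprocessed onto the library axis). Returns a long-format table with
    columns sample_id, class, component, coefficient, residual_norm.
    """
    spectra = list(spectra)
    labels = list(labels)
    if not spectra:
        raise InvalidInputError("cohort is empty")
    if len(labels) != len(spectra):
        raise InvalidInputError("labels length must match number of spectra")
    if sample_ids is None:
        sample_ids = [f"s{i:03d}" for i in range(len(spectra))]
    rows = []
    for sid, lab, spec in zip(sample_ids, labels, spectra):
        res = nnls_fit(spec, library, include_offset=include_offset,
                       normalize_components=normalize_components)
        for comp, coeff in res.coefficients.items():
            rows.append({
                "sample_id": sid,
                "class": lab,
                "component": comp,
                "coefficient": coeff,
                "residual_norm": res.residual_norm,
            })
    return pd.DataFrame(rows)


def fit_somdi_components(somdi, library: ComponentLibrary, class_name,
                         normalize_components: bool = True) -> UnmixResult:
    """NNLS of the component library onto the positive part of a class's
    SOM discriminant vector — the components driving that class's activation."""
    if not np.array_equal(somdi.axis, library.axis):
        raise InvalidInputError("SOMDI and library must share an identical axis")
    v = somdi.vector(class_name)
    positive = np.clip(v, 0.0, None)
    if not np.any(positive > 0):
        raise DegenerateInputError(
            f"discriminant vector for {class_name!r} has no positive part")
    return nnls_fit(Spectrum(library.axis, positive), library,
                    include_offset=False,
                    normalize_components=normalize_components)


def group_compare(results: pd.DataFrame, bonferroni: bool = False) -> GroupComparison:
    """One-way ANOVA per component across class groups.

    Expects the long-format table from :func:`unmix_cohort`. Zero
    between-group variance is reported as F = 0, p = 1. No multiple-testing
    correction by default; ``bonferroni=True`` multiplies p by the number of
    components (capped at 1).
    """
    required = {"class", "component", "coefficient"}
    if not required <= set(results.columns):
        raise InvalidInputError(f"results table must have columns {sorted(required)}")
    groups = tuple(dict.fromkeys(results["class"]))
    if len(groups) < 2:
        raise InvalidInputError("need at least two groups")
    components = list(dict.fromkeys(results["component"]))
    rows = []
    for comp in components:
        sub = results[results["component"] == comp]
        samples = [sub.loc[sub["class"] == g, "coefficient"].to_numpy()
                   for g in groups]
        for g, arr in zip(groups, samples):
            if arr.size < 2:
                raise InvalidInputError(
                    f"group {g!r} has fewer than 2 samples for component {comp!r}")
        grand = np.concatenate(samples)
        row = {"component": comp}
        for g, arr in zip(groups, samples):
            row[f"mean_{g}"] = arr.mean()
            row[f"var_{g}"] = arr.var(ddof=1)
        if np.ptp([arr.mean() for arr in samples]) == 0 or np.ptp(grand) == 0:
            # degenerate: no between-group signal (or no variance at all)
            row["F"], row["p_value"] = 0.0, 1.0
        else:
            f, p = stats.f_oneway(*samples)
            if not np.isfinite(f):  # zero within-group variance, groups differ
                f, p = np.inf, 0.0
            row["F"], row["p_value"] = float(f), float(p)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("component")
    if bonferroni:
        table["p_value"] = np.minimum(table["p_value"] * len(components), 1.0)
    return GroupComparison(groups=groups, table=table)
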