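"""Class assignment and multivariate summaries of annotated phenolics.

Annotated compounds are grouped into five reporting classes (phenol
sulfates, phenolic acids, phenolic acid sulfates, coumarins, phlorotannins;
sulfated and non-sulfated coumarins/phlorotannins are pooled because of
their low numbers).  One regrouping rule is applied exactly once:
phloroglucinol sulfate — structurally a phenol sulfate, but the monomer of
the phlorotannins and tightly correlated with them — is reported with the
phlorotannin class.

The multivariate toolbox mirrors a MetaboAnalyst-style session: optional
IQR-based column filtering, autoscaling (zero mean, unit variance per
column), SVD-based PCA, agglomerative hierarchical clustering and a Pearson
correlation heatmap.
"""

from __future__ import annotations

import re
import warnings as _warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA as _SkPCA

from .database import Aglycone, build_aglycone_registry
from .rules import RuleLibrary, load_rule_library

__all__ = [
    "ClassAssignment",
    "FIVE_CLASSES",
    "classify_compound",
    "classify_entry",
    "classify_table",
    "class_counts",
    "iqr_filter",
    "autoscale",
    "pca",
    "hca",
    "correlation_heatmap",
    "class_abundance_report",
    "plot_pca_scores",
    "plot_dendrogram",
    "plot_correlation_heatmap",
    "read_abundance_matrix",
    "write_abundance_matrix",
]

FIVE_CLASSES = (
    "phenol_sulfate",
    "phenolic_acid",
    "phenolic_acid_sulfate",
    "coumarin",
    "phlorotannin",
)

_SULFATE_NAME = re.compile(r"\b(sulfate|disulfate|trisulfate)\b", re.IGNORECASE)
_ISOMER_SUFFIX = re.compile(r"(\s+isomer(\s*\d+)?|\s+\d+)$", re.IGNORECASE)


@dataclass(frozen=True)
class ClassAssignment:
    """Subclass and reporting-class labels for one annotated compound."""

    compound_id: str
    base_aglycone: str
    subclass: str
    sulfated: bool
    pre_regroup: str
    compound_class: str


def _subclass_lookup(library: RuleLibrary, registry: Sequence[Aglycone]) -> dict[str, str]:
    lookup = {a.name.lower(): a.subclass for a in registry}
    for rule in library.rules.values():
        lookup.setdefault(rule.aglycone_name.lower(), rule.subclass)
    return lookup


def _strip_name(name: str) -> tuple[str, bool]:
    """Reduce a compound name to its aglycone key and sulfation flag."""
    sulfated = bool(_SULFATE_NAME.search(name))
    base = _SULFATE_NAME.sub("", name)
    base = re.sub(r"\s+", " ", base).strip()
    base = _ISOMER_SUFFIX.sub("", base).strip()
    return base, sulfated


def classify_compound(
    name: str,
    library: RuleLibrary | None = None,
    registry: Sequence[Aglycone] | None = None,
    regroup: bool = True,
) -> ClassAssignment:
    """Assign the reporting class of one compound from its name.

    The aglycone key is resolved against the rule library and the aglycone
    registry; names that resolve nowhere raise ``KeyError``.  With
    ``regroup=True`` (default) the phloroglucinol-sulfate regrouping rule is
    applied and phenolic acids are split by sulfation into the five final
    classes; ``pre_regroup`` always carries the raw grouping (phenol
    sulfates / phenolic acids / coumarins / phlorotannins).
    """
    registry = registry if registry is not None else build_aglycone_registry()
    library = library or load_rule_library(registry=registry)
    lookup = _subclass_lookup(library, registry)

    base, sulfated = _strip_name(name)
    key = base.lower()
    if key not in lookup:
        # tolerate names written without the trailing "acid"
        if f"{key} acid" in lookup:
            key = f"{key} acid"
        else:
            raise KeyError(f"cannot resolve compound name {name!r} to an aglycone")
    return _assign(name, key, lookup[key], sulfated, regroup)


def _assign(
    compound_id: str, key: str, subclass: str, sulfated: bool, regroup: bool
) -> ClassAssignment:
    if subclass == "phenol":
        pre = "phenol_sulfate" if sulfated else "phenol"
    elif subclass == "phenolic_acid":
        pre = "phenolic_acid"
    else:
        pre = subclass

    final = pre
    if regroup:
        if subclass == "phenolic_acid":
            final = "phenolic_acid_sulfate" if sulfated else "phenolic_acid"
        if key == "phloroglucinol" and sulfated:
            final = "phlorotannin"
    return ClassAssignment(
        compound_id=compound_id,
        base_aglycone=key,
        subclass=subclass,
        sulfated=sulfated,
        pre_regroup=pre,
        compound_class=final,
    )


def classify_entry(
    entry,
    registry: Sequence[Aglycone] | None = None,
    regroup: bool = True,
) -> ClassAssignment:
    """Classify a suspect-database entry via its aglycone's subclass."""
    registry = registry if registry is not None else build_aglycone_registry()
    by_name = {a.name: a for a in registry}
    aglycone = by_name.get(entry.aglycone_name)
    if aglycone is None:
        raise KeyError(f"entry aglycone {entry.aglycone_name!r} not in registry")
    return _assign(
        entry.id, aglycone.name.lower(), aglycone.subclass, entry.n_sulfates > 0, regroup
    )


def classify_table(
    names: Sequence[str],
    library: RuleLibrary | None = None,
    registry: Sequence[Aglycone] | None = None,
) -> list[ClassAssignment]:
    """Classify many compound names, resolving the registry/library once."""
    registry = registry if registry is not None else build_aglycone_registry()
    library = library or load_rule_library(registry=registry)
    return [classify_compound(n, library, registry) for n in names]


def class_counts(assignments: Sequence[ClassAssignment], regroup: bool = True) -> dict[str, int]:
    """Compound counts per class, pre- or post-regrouping."""
    counts: dict[str, int] = {}
    for a in assignments:
        label = a.compound_class if regroup else a.pre_regroup
        counts[label] = counts.get(label, 0) + 1
    return counts


def iqr_filter(matrix: pd.DataFrame, fraction: float = 0.0) -> pd.DataFrame:
    """Drop the ``fraction`` of columns with the smallest interquartile range.

    ``fraction=0`` is the identity (the sensible default for small matrices,
    where aggressive variance filtering would discard real compounds).
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0 or matrix.shape[1] == 0:
        return matrix.copy()
    iqr = matrix.quantile(0.75) - matrix.quantile(0.25)
    n_drop = int(np.floor(fraction * matrix.shape[1]))
    if n_drop == 0:
        return matrix.copy()
    drop = iqr.sort_values(kind="stable").index[:n_drop]
    return matrix.drop(columns=drop)


def autoscale(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-column standardization to mean 0, SD 1 (unit-variance scaling).

    Zero-variance columns cannot be scaled and are dropped with a warning.
    The operation is idempotent up to numerical tolerance.
    """
    sd = matrix.std(ddof=ddof)
    constant = sd[(sd == 0) | sd.isna()].index
    if len(constant):
        _warnings.warn(
            f"dropping {len(constant)} zero-variance column(s): "
            f"{list(map(str, constant[:5]))}...",
            stacklevel=2,
        )
        matrix = matrix.drop(columns=constant)
        sd = sd.drop(constant)
    return (matrix - matrix.mean()) / sd


def pca(matrix: pd.DataFrame, n_components: int | None = None):
    """SVD-based PCA: (scores, loadings, explained_variance_ratio).

    The matrix is used as given (autoscale beforehand for the usual
    metabolomics workflow).  Scores/loadings are DataFrames indexed like the
    input; explained variance ratios are non-increasing and sum to <= 1.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    k = n_components or min(matrix.shape[0] - 1, matrix.shape[1])
    model = _SkPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(matrix.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(model.n_components_)]
    return (
        pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        pd.DataFrame(model.components_.T, index=matrix.columns, columns=comp_names),
        model.explained_variance_ratio_.copy(),
    )


def hca(matrix: pd.DataFrame, distance: str = "euclidean", linkage: str = "ward"):
    """Agglomerative clustering of samples: (linkage matrix, leaf labels)."""
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs at least 2 samples")
    dists = pdist(matrix.to_numpy(), metric=distance)
    link = hierarchy.linkage(dists, method=linkage)
    return link, list(matrix.index)


def correlation_heatmap(matrix: pd.DataFrame, method: str = "pearson"):
    """Column-wise correlation matrix with a clustering of the columns.

    Returns (correlation DataFrame, linkage matrix over columns using
    1 - correlation as distance).  Plot with seaborn/matplotlib if needed;
    the numerical objects are the artifact.
    """
    corr = matrix.corr(method=method)
    dist = squareform(np.clip(1.0 - corr.to_numpy(), 0.0, 2.0), checks=False)
    link = hierarchy.linkage(dist, method="average")
    return corr, link


def class_abundance_report(
    matrix: pd.DataFrame,
    assignments: Mapping[str, str] | Sequence[ClassAssignment],
) -> pd.DataFrame:
    """Per-class per-sample totals (columns summed within each class).

    ``assignments`` maps column name -> class label (or is a sequence of
    :class:`ClassAssignment`).  Every column must be covered; class totals
    conserve the grand total exactly.
    """
    if not isinstance(assignments, Mapping):
        assignments = {a.compound_id: a.compound_class for a in assignments}
    uncovered = [c for c in matrix.columns if c not in assignments]
    if uncovered:
        raise KeyError(f"columns without class assignment: {uncovered[:5]}")
    by_class: dict[str, list[str]] = {}
    for col in matrix.columns:
        by_class.setdefault(assignments[col], []).append(col)
    report = pd.DataFrame(
        {label: matrix[cols].sum(axis=1) for label, cols in sorted(by_class.items())},
        index=matrix.index,
    )
    return report


def plot_pca_scores(
    scores: pd.DataFrame, groups: pd.Series, path: str | Path, evr=None
) -> None:
    """Scatter of PC1 vs PC2 colored by group, saved to ``path`` (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for group in sorted(set(groups)):
        mask = groups.loc[scores.index] == group
        ax.scatter(scores.loc[mask, "PC1"], scores.loc[mask, "PC2"], label=group, s=40)
    xlab = "PC1" if evr is None else f"PC1 ({evr[0] * 100:.1f}%)"
    ylab = "PC2" if evr is None else f"PC2 ({evr[1] * 100:.1f}%)"
    ax.set_xlabel(xlab)
    ax.set_ylabel(ylab)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dendrogram(link, labels, path: str | Path) -> None:
    """Save the HCA dendrogram of samples to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    hierarchy.dendrogram(link, labels=labels, ax=ax, leaf_rotation=90, leaf_font_size=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_correlation_heatmap(corr: pd.DataFrame, link, path: str | Path) -> None:
    """Save the clustered correlation heatmap to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = hierarchy.leaves_list(link)
    reordered = corr.iloc[order, order]
    fig, ax = plt.subplots(figsize=(6, 5))
    image = ax.imshow(reordered.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(reordered)), reordered.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(reordered)), reordered.index, fontsize=6)
    fig.colorbar(image, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def read_abundance_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a samples x compounds CSV (first column sample id, second group).

    Returns (matrix, group labels); the layout matches the comma-separated
    files consumed by common metabolomics statistics portals.
    """
    table = pd.read_csv(path, index_col=0)
    groups = table.iloc[:, 0]
    matrix = table.iloc[:, 1:].astype(float)
    if (matrix.to_numpy() < 0).any():
        raise ValueError("abundance matrix contains negative values")
    return matrix, groups


def write_abundance_matrix(
    matrix: pd.DataFrame, groups: pd.Series, path: str | Path
) -> None:
    """Inverse of :func:`read_abundance_matrix`."""
    out = matrix.copy()
    out.insert(0, "group", groups)
    out.index.name = "sample"
    out.to_csv(path)
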