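"""Per-function feature associations and their clustering.

After the penalized fit selects a sparse feature set for each function, an
unpenalized logistic regression is refit on just those features and the Wald
t-statistic (coefficient / standard error) of each is extracted.  Unselected
features get t = 0.  The resulting functions x features matrix is filtered to
features with at least one t-statistic at or above a threshold (3 by default)
and hierarchically clustered under uncentered correlation distance with
average linkage, emitting a clustered text table viewable in standard
dendrogram/heatmap viewers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .io import FaidrFit, FeatureTable
from .model import _row_labels

__all__ = [
    "AssociationMatrix",
    "refit_tstats",
    "assemble_matrix",
    "filter_features",
    "uncentered_correlation_distance",
    "hierarchical_cluster",
    "ClusterResult",
    "write_cdt",
]

T_CAP = 50.0  # |t| returned when the unpenalized refit quasi-separates


@dataclass
class AssociationMatrix:
    """functions x features t-statistic matrix with the selection mask."""

    values: pd.DataFrame  # rows = functions, columns = features
    selected: pd.DataFrame  # boolean, same shape

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("duplicate function names")
        self.values = self.values.astype(float)
        self.selected = self.selected.astype(bool)
        if self.values.size:
            unselected = self.values.to_numpy()[~self.selected.to_numpy()]
            if unselected.size and np.any(unselected != 0.0):
                raise ValueError("unselected features must have t = 0")

    @property
    def function_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


def refit_tstats(
    table: FeatureTable,
    labels,
    fit: FaidrFit,
    mode: str = "responsibility",
) -> tuple[np.ndarray, bool]:
    """Wald t-statistics from an unpenalized refit on the selected features.

    Per-IDR rows inherit their protein's label; with ``mode="responsibility"``
    each row is weighted by its final responsibility <X_ij> (so the weighted
    Fisher information matches the model's soft assignment), while
    ``mode="max_idr"`` keeps only the maximum-responsibility IDR of each
    protein at unit weight.  Features with zero penalized coefficients get
    t = 0.  On quasi-separation or non-convergence the affected t-statistics
    are capped at sign(coefficient) * 50 and the returned flag is set.
    """
    if mode not in ("responsibility", "max_idr"):
        raise ValueError(f"unknown refit mode {mode!r}")
    t = np.zeros(len(fit.feature_names))
    sel = np.flatnonzero(fit.coefficients)
    if sel.size == 0:
        return t, False
    _, y_row = _row_labels(table, labels)
    Xs = table.X[:, sel]
    if mode == "responsibility":
        rows = np.arange(table.n_idrs)
        w = fit.responsibilities
    else:
        rows = np.array(
            [
                r[int(np.argmax(fit.responsibilities[r]))]
                for r in (np.asarray(v) for v in table.protein_index.values())
            ]
        )
        w = np.ones(rows.size)
    design = sm.add_constant(Xs[rows], has_constant="add")
    capped = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(
                y_row[rows], design, family=sm.families.Binomial(), var_weights=w
            ).fit(maxiter=500, tol=1e-13)
        params = np.asarray(res.params)
        tvals = params[1:] / np.asarray(res.bse[1:])
        if not np.all(np.isfinite(tvals)):
            raise ValueError("non-finite t-statistics")
        # (quasi-)separation degenerates the Wald statistic: the deviance
        # collapses to ~0 and/or coefficients run away on standardized
        # features while standard errors explode — cap instead
        if (
            not res.converged
            or np.abs(params[1:]).max() > 30.0
            or res.deviance < 1e-6 * len(rows)
        ):
            raise ValueError("quasi-separation")
        over = np.abs(tvals) > T_CAP
        if over.any():
            tvals[over] = np.sign(tvals[over]) * T_CAP
            capped = True
        t[sel] = tvals
    except Exception:
        # report capped magnitudes, signed like the penalized coefficients
        t[sel] = np.sign(fit.coefficients[sel]) * T_CAP
        capped = True
    return t, capped


def assemble_matrix(
    per_function: Sequence[tuple[str, np.ndarray]],
    feature_names: Sequence[str],
) -> AssociationMatrix:
    """Stack per-function t-vectors into a functions x features matrix.

    Column order follows ``feature_names`` (the feature-table order);
    zero entries are treated as unselected.
    """
    names = [f for f, _ in per_function]
    if len(set(names)) != len(names):
        raise ValueError("duplicate function names")
    mat = np.vstack([np.asarray(t, dtype=float) for _, t in per_function])
    if mat.shape[1] != len(feature_names):
        raise ValueError("t-vector length does not match feature names")
    values = pd.DataFrame(mat, index=names, columns=list(feature_names))
    return AssociationMatrix(values=values, selected=values != 0.0)


def filter_features(
    matrix: AssociationMatrix, threshold: float = 3.0, mode: str = "signed"
) -> AssociationMatrix:
    """Keep features with at least one t-statistic >= threshold.

    ``mode="signed"`` (default) compares the signed maximum over functions;
    ``mode="absolute"`` compares max |t| instead, retaining strong negative
    associations as well.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if mode == "signed":
        keep = matrix.values.max(axis=0) >= threshold
    elif mode == "absolute":
        keep = matrix.values.abs().max(axis=0) >= threshold
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    cols = matrix.values.columns[keep]
    return AssociationMatrix(
        values=matrix.values[cols].copy(), selected=matrix.selected[cols].copy()
    )


def uncentered_correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """d = 1 - (x . y) / (||x|| ||y||), in [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("uncentered correlation undefined for zero-norm vectors")
    return float(1.0 - (x @ y) / (nx * ny))


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: list[int]
    item_names: list[str]

    @property
    def ordered_names(self) -> list[str]:
        return [self.item_names[i] for i in self.leaf_order]


def hierarchical_cluster(
    matrix: AssociationMatrix, axis: str = "columns", method: str = "average"
) -> ClusterResult:
    """Agglomerative clustering under uncentered correlation distance.

    ``axis="columns"`` clusters features; ``axis="rows"`` clusters functions.
    Leaf ordering is fully deterministic for a given input.
    """
    if axis == "columns":
        data = matrix.values.to_numpy().T
        names = matrix.feature_names
    elif axis == "rows":
        data = matrix.values.to_numpy()
        names = matrix.function_names
    else:
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    norms = np.linalg.norm(data, axis=1)
    if np.any(norms == 0.0):
        bad = names[int(np.argmin(norms))]
        raise ValueError(f"item {bad!r} is all zeros; filter before clustering")
    # cosine distance == uncentered correlation distance
    d = np.clip(pdist(data, metric="cosine"), 0.0, 2.0)
    Z = linkage(d, method=method)
    return ClusterResult(linkage=Z, leaf_order=list(leaves_list(Z)), item_names=names)


def write_cdt(
    matrix: AssociationMatrix,
    path: str,
    row_cluster: ClusterResult | None = None,
    col_cluster: ClusterResult | None = None,
) -> None:
    """Write a clustered-data-table (CDT-like) text file.

    Rows are functions and columns features, reordered by the supplied
    clusterings; the layout follows the plain-text convention understood by
    Java TreeView-style viewers (GID / UNIQID / NAME / GWEIGHT columns and an
    EWEIGHT row).
    """
    rows = row_cluster.ordered_names if row_cluster else matrix.function_names
    cols = col_cluster.ordered_names if col_cluster else matrix.feature_names
    df = matrix.values.loc[rows, cols]
    with open(path, "w") as fh:
        fh.write("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(cols) + "\n")
        fh.write("EWEIGHT\t\t\t\t" + "\t".join(["1"] * len(cols)) + "\n")
        for k, name in enumerate(rows):
            vals = "\t".join(f"{v:.6g}" for v in df.loc[name])
            fh.write(f"GENE{k}X\t{name}\t{name}\t1\t{vals}\n")
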