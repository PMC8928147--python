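"""Pairwise beta diversity matrices and group-centroid distances.

Four dissimilarities between samples i and j:

* Bray-Curtis  BC = 1 - 2 sum_f min(x_if, x_jf) / (S_i + S_j), on counts
  as given (no proportion normalisation);
* Jaccard distance 1 - |i n j| / |i u j| on presence/absence;
* unweighted UniFrac — branch length found on the paths to exactly one of
  the two samples' leaves, divided by the branch length on the paths to
  either (a fraction in [0, 1]);
* weighted UniFrac — sum_e b_e |A_e/A_T - B_e/B_T| over edges e, where
  A_e is the abundance descending through e in sample A and A_T its total;
  raw by default, optionally normalised by sum_e b_e (A_e/A_T + B_e/B_T).

UniFrac is computed from an edge-by-leaf incidence matrix (see
:class:`~divpower.alpha.TreeIncidence`), one matrix product for all samples
and a loop over pairs, which keeps the resampling engine fast.
"""

from __future__ import annotations

import warnings

import numpy as np
import skbio
from scipy.spatial.distance import squareform, pdist
from skbio import TreeNode

from .alpha import TreeIncidence
from .community import (
    CountTable,
    GroupDesign,
    ValidationError,
    as_distance_matrix,
    check_features_in_tree,
)

BETA_METRICS = ("braycurtis", "jaccard", "unweighted_unifrac", "weighted_unifrac")


def _check_table(table: CountTable) -> np.ndarray:
    X = table.values
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    zero = np.flatnonzero(X.sum(axis=1) == 0)
    if zero.size:
        bad = [table.sample_ids[i] for i in zero[:5]]
        raise ValidationError(f"all-zero samples have undefined distances: {bad}")
    return X


def bray_curtis(table: CountTable) -> skbio.DistanceMatrix:
    X = _check_table(table)
    d = pdist(X, metric="braycurtis")
    return as_distance_matrix(squareform(d), table.sample_ids)


def jaccard(table: CountTable) -> skbio.DistanceMatrix:
    X = _check_table(table)
    d = pdist(X > 0, metric="jaccard")
    return as_distance_matrix(squareform(d), table.sample_ids)


def _unifrac_edges(table: CountTable, tree: TreeNode) -> TreeIncidence:
    check_features_in_tree(table, tree)
    return TreeIncidence(tree, table.feature_ids)


def unweighted_unifrac(table: CountTable, tree: TreeNode) -> skbio.DistanceMatrix:
    X = _check_table(table)
    inc = _unifrac_edges(table, tree)
    P = inc.edge_presence(X > 0)  # (edges, samples)
    b = inc.lengths
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        pi = P[:, i, None]
        rest = P[:, i + 1:]
        unshared = b @ (pi ^ rest)
        union = b @ (pi | rest)
        with np.errstate(invalid="ignore"):
            d = np.where(union > 0, unshared / np.maximum(union, 1e-300), 0.0)
        out[i, i + 1:] = d
    out = out + out.T
    return as_distance_matrix(out, table.sample_ids)


def weighted_unifrac(table: CountTable, tree: TreeNode,
                     normalized: bool = False) -> skbio.DistanceMatrix:
    X = _check_table(table)
    inc = _unifrac_edges(table, tree)
    Q = X / X.sum(axis=1, keepdims=True)
    A = inc.edge_abundance(Q)  # (edges, samples) proportions per edge
    b = inc.lengths
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        ai = A[:, i, None]
        rest = A[:, i + 1:]
        raw = b @ np.abs(ai - rest)
        if normalized:
            denom = b @ (ai + rest)
            with np.errstate(invalid="ignore"):
                raw = np.where(denom > 0, raw / np.maximum(denom, 1e-300), 0.0)
        out[i, i + 1:] = raw
    out = out + out.T
    return as_distance_matrix(out, table.sample_ids)


def beta_distance(table: CountTable, metric: str, tree: TreeNode = None,
                  normalized: bool = False) -> skbio.DistanceMatrix:
    """Dispatch on metric name; tree required for the UniFrac pair."""
    if metric not in BETA_METRICS:
        raise ValidationError(
            f"unknown beta metric {metric!r}; valid: {list(BETA_METRICS)}"
        )
    if metric == "braycurtis":
        return bray_curtis(table)
    if metric == "jaccard":
        return jaccard(table)
    if tree is None:
        raise ValidationError(f"metric {metric!r} requires a phylogenetic tree")
    if metric == "unweighted_unifrac":
        return unweighted_unifrac(table, tree)
    return weighted_unifrac(table, tree, normalized=normalized)


# ---------------------------------------------------------------------------
# Distance to group centroid (multivariate dispersion)
# ---------------------------------------------------------------------------

def group_centroid_distances(dm: skbio.DistanceMatrix,
                             design: GroupDesign):
    """Per-sample distance to its group centroid in PCoA space.

    The dissimilarity matrix is embedded by principal-coordinate
    decomposition keeping the axes of negative eigenvalue as imaginary
    coordinates.  A sample's squared distance to its group centroid is the
    squared distance accumulated on the real axes minus that on the
    imaginary axes, clipped at zero before the square root — the standard
    dispersion-analysis convention for semi-metric dissimilarities like
    Bray-Curtis.

    Returns
    -------
    distances : pandas.Series indexed by sample identifier
    group_means : dict group -> mean member-to-centroid distance
    """
    import pandas as pd

    ids = list(dm.ids)
    labels = design.labels_for(ids)
    D2 = dm.data ** 2
    n = len(ids)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    # drop numerically-zero axes, keep genuinely negative ones
    keep = np.abs(eigvals) > 1e-10 * max(1.0, np.abs(eigvals).max())
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    coords = eigvecs * np.sqrt(np.abs(eigvals))
    is_real = eigvals > 0

    sq = np.zeros(n)
    for g in np.unique(labels):
        members = np.flatnonzero(labels == g)
        if members.size == 1:
            warnings.warn(f"group {g!r} has a single member; distance set to 0")
            continue
        centroid = coords[members].mean(axis=0)
        delta2 = (coords[members] - centroid) ** 2
        sq[members] = delta2[:, is_real].sum(axis=1) - delta2[:, ~is_real].sum(axis=1)
    dist = np.sqrt(np.clip(sq, 0.0, None))
    series = pd.Series(dist, index=ids, name="centroid_distance")
    group_means = {
        g: float(series[labels == g].mean()) for g in np.unique(labels)
    }
    return series, group_means
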