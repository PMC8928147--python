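"""Per-sample alpha diversity metrics.

Five metrics, one number per sample:

* ``observed`` — number of features with abundance > 0;
* ``pd`` — Faith's phylogenetic diversity, the total branch length of the
  subtree spanning the observed leaves, including the path to the root of
  the supplied rooted tree;
* ``chao1`` — bias-corrected richness estimator s + F1(F1-1)/(2(F2+1)),
  where F1/F2 are singleton/doubleton counts (integer counts required);
* ``shannon`` — entropy -sum(p_i ln p_i) in nats;
* ``simpson`` — Gini-Simpson 1 - sum(p_i^2) by default; the inverse
  (1/sum p_i^2) and dominance (sum p_i^2) forms are selectable.

Standard estimator implementations are delegated to scikit-bio; the
tree-spanning computation used by :func:`alpha_table` is vectorised over
samples via an edge-by-leaf incidence matrix so that large tables and
resampling loops stay cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.diversity import alpha as _skb

from .community import CountTable, ValidationError, check_features_in_tree

ALPHA_METRICS = ("observed", "pd", "chao1", "shannon", "simpson")

SIMPSON_FORMS = ("gini", "inverse", "dominance")


def _as_counts(sample_counts) -> np.ndarray:
    x = np.asarray(sample_counts, dtype=float)
    if x.ndim != 1:
        raise ValidationError("expected a 1-D abundance vector")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValidationError("abundances must be finite and nonnegative")
    return x


def observed_richness(sample_counts) -> float:
    """Number of features observed (abundance strictly > 0)."""
    return float(np.count_nonzero(_as_counts(sample_counts)))


def chao1(sample_counts) -> float:
    """Bias-corrected Chao1 richness estimate; requires integer counts."""
    x = _as_counts(sample_counts)
    if not np.allclose(x, np.round(x), atol=1e-9):
        raise ValidationError("chao1 requires integer-valued abundances")
    return float(_skb.chao1(np.round(x).astype(np.int64), bias_corrected=True))


def shannon(sample_counts) -> float:
    """Shannon entropy in nats (0 * ln 0 = 0)."""
    x = _as_counts(sample_counts)
    if x.sum() == 0:
        raise ValidationError("shannon undefined for an all-zero sample")
    return float(_skb.shannon(x, base=np.e))


def simpson(sample_counts, form: str = "gini") -> float:
    """Simpson's index in one of three conventions.

    ``gini`` (default) is 1 - sum(p^2), in [0, 1]; ``inverse`` is
    1 / sum(p^2); ``dominance`` is sum(p^2) itself.
    """
    if form not in SIMPSON_FORMS:
        raise ValidationError(f"form must be one of {SIMPSON_FORMS}")
    x = _as_counts(sample_counts)
    total = x.sum()
    if total == 0:
        raise ValidationError("simpson undefined for an all-zero sample")
    p = x / total
    dom = float(np.sum(p * p))
    if form == "dominance":
        return dom
    if form == "inverse":
        return 1.0 / dom
    return 1.0 - dom


# ---------------------------------------------------------------------------
# Faith's PD
# ---------------------------------------------------------------------------

class TreeIncidence:
    """Edge-by-leaf incidence of a rooted tree, for vectorised PD/UniFrac.

    Row e of ``matrix`` marks the leaves that descend through edge e;
    ``lengths[e]`` is that edge's branch length.  The root's stem edge is
    included (length 0 when absent), so PD counts the path to the root.
    """

    def __init__(self, tree: TreeNode, feature_ids):
        order = {f: i for i, f in enumerate(feature_ids)}
        leaf_set = {t.name for t in tree.tips()}
        missing = [f for f in feature_ids if f not in leaf_set]
        if missing:
            raise ValidationError(
                f"features absent from tree: {missing[:5]}"
            )
        nodes = list(tree.postorder(include_self=True))
        rows, lengths = [], []
        below: dict = {}
        m = len(feature_ids)
        for node in nodes:
            if node.is_tip():
                vec = np.zeros(m, dtype=bool)
                if node.name in order:  # tree may carry extra leaves
                    vec[order[node.name]] = True
            else:
                vec = np.zeros(m, dtype=bool)
                for child in node.children:
                    vec |= below[id(child)]
            below[id(node)] = vec
            length = node.length if node.length is not None else 0.0
            rows.append(vec)
            lengths.append(length)
        self.matrix = np.array(rows)            # (edges, features) bool
        self.lengths = np.asarray(lengths)      # (edges,)
        self.feature_ids = list(feature_ids)

    def edge_presence(self, presence: np.ndarray) -> np.ndarray:
        """Boolean (edges, samples): does any observed leaf descend here."""
        return self.matrix @ presence.T > 0

    def edge_abundance(self, proportions: np.ndarray) -> np.ndarray:
        """Float (edges, samples): summed proportion descending each edge."""
        return self.matrix @ proportions.T

    def pd_values(self, counts: np.ndarray) -> np.ndarray:
        present = self.edge_presence(counts > 0)
        return self.lengths @ present


def faith_pd(sample_counts, tree: TreeNode, feature_ids=None) -> float:
    """Faith's PD for a single sample.

    ``feature_ids`` maps abundance positions to leaf labels; if omitted the
    tree's leaves in tip order are assumed.
    """
    x = _as_counts(sample_counts)
    if feature_ids is None:
        feature_ids = [t.name for t in tree.tips()]
    if len(feature_ids) != x.size:
        raise ValidationError("feature_ids and abundance vector length differ")
    inc = TreeIncidence(tree, list(feature_ids))
    return float(inc.pd_values(x[None, :])[0])


# ---------------------------------------------------------------------------
# Table-level driver
# ---------------------------------------------------------------------------

def alpha_table(table: CountTable, metrics=ALPHA_METRICS, tree: TreeNode = None,
                simpson_form: str = "gini") -> pd.DataFrame:
    """Alpha diversity per sample, one column per requested metric."""
    metrics = list(metrics)
    unknown = [m for m in metrics if m not in ALPHA_METRICS]
    if unknown:
        raise ValidationError(
            f"unknown metrics {unknown}; valid: {list(ALPHA_METRICS)}"
        )
    if "pd" in metrics and tree is None:
        raise ValidationError("metric 'pd' requires a phylogenetic tree")

    X = table.values
    out = {}
    for metric in metrics:
        if metric == "observed":
            out[metric] = np.count_nonzero(X > 0, axis=1).astype(float)
        elif metric == "pd":
            check_features_in_tree(table, tree)
            inc = TreeIncidence(tree, table.feature_ids)
            out[metric] = inc.pd_values(X)
        elif metric == "chao1":
            out[metric] = np.array([chao1(row) for row in X])
        elif metric == "shannon":
            out[metric] = np.array([shannon(row) for row in X])
        elif metric == "simpson":
            out[metric] = np.array([simpson(row, simpson_form) for row in X])
    return pd.DataFrame(out, index=pd.Index(table.sample_ids, name="sample_id"))


def alpha_summary(values: pd.DataFrame, design=None) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) per metric, optionally by group."""
    if design is None:
        return values.agg(["mean", lambda s: s.std(ddof=1)]).set_axis(
            ["mean", "sd"]
        )
    labels = design.labels_for(list(values.index))
    grouped = values.groupby(pd.Series(labels, index=values.index))
    return pd.concat(
        {"mean": grouped.mean(), "sd": grouped.std(ddof=1)}, axis=1
    )
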