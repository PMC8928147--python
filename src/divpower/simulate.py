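"""Synthetic microbial communities and the two perturbation scenarios.

The generator emulates a sparse, heavily skewed gut-like amplicon dataset:
169 samples by 1,995 features at default, with a log-normal rank-abundance
curve, Dirichlet-multinomial per-sample counts at negative-binomial
sequencing depths, and a random rooted bifurcating phylogeny (sequential
random joins, exponential branch lengths) over the features.  The default
skew and concentration are calibrated so the mean per-sample observed
richness lands near 70 of the 1,995 features, the scale of the community
the analysis pipeline is designed for.

Two perturbation scenarios derive a second table X2 from a base table X1:

* presence/absence — a random fraction of features is removed (zeroed in
  every sample) from X2; only presence/absence structure changes;
* differential abundance — a random fraction (default one-fourth) of
  features is made q% more abundant in X2 by multiplying their counts;
  presence/absence is preserved exactly, which is why purely qualitative
  metrics (Jaccard, unweighted UniFrac) are structurally blind to it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .community import CountTable, ValidationError


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of the base community generator.

    ``skew_sigma`` is the SD of the log-normal rank-abundance curve (larger
    = more dominance, fewer observed features per sample);
    ``concentration`` the total mass of the per-sample Dirichlet (smaller =
    more sample-to-sample variation and sparsity); depth is negative
    binomial with the given mean and dispersion (number of successes r).
    ``sharpness`` is an optional exponent applied to the base proportions
    (p_i^tau, renormalised) used to dial in alpha-diversity effects
    between two groups sharing a rank-abundance curve.
    """

    n_samples: int = 169
    n_features: int = 1995
    model: str = "dirichlet_multinomial"  # or "lognormal_counts"
    skew_sigma: float = 3.0
    concentration: float = 100.0
    depth_mean: float = 2000.0
    depth_dispersion: float = 5.0
    sharpness: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2 or self.n_features < 2:
            raise ValidationError("need at least 2 samples and 2 features")
        if self.depth_mean <= 0:
            raise ValidationError("sequencing depth must be positive")
        if self.model not in ("dirichlet_multinomial", "lognormal_counts"):
            raise ValidationError(f"unknown abundance model {self.model!r}")


def _base_proportions(spec: CommunitySpec, rng: np.random.Generator):
    logp = rng.normal(0.0, spec.skew_sigma, size=spec.n_features)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    if spec.sharpness != 1.0:
        p = p ** spec.sharpness
        p /= p.sum()
    return p


def _draw_depths(spec: CommunitySpec, rng: np.random.Generator):
    r = spec.depth_dispersion
    prob = r / (r + spec.depth_mean)
    depths = rng.negative_binomial(r, prob, size=spec.n_samples)
    return np.maximum(depths, 1)


def _sample_counts(spec: CommunitySpec, p: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    depths = _draw_depths(spec, rng)
    X = np.zeros((spec.n_samples, spec.n_features))
    if spec.model == "dirichlet_multinomial":
        alpha = spec.concentration * p
        for i in range(spec.n_samples):
            w = rng.gamma(alpha)  # tiny shapes underflow to 0: sparsity
            total = w.sum()
            if total == 0:  # pragma: no cover - pathological spec
                w[rng.integers(spec.n_features)] = 1.0
                total = 1.0
            X[i] = rng.multinomial(depths[i], w / total)
    else:  # lognormal_counts: truncated-normal-like positive abundances
        for i in range(spec.n_samples):
            mu = np.log(np.maximum(p * depths[i], 1e-12))
            raw = rng.lognormal(mu, 1.0)
            raw[raw < 1.0] = 0.0  # detection floor
            X[i] = np.round(raw)
    return X


def random_tree(feature_ids, rng: np.random.Generator,
                rate: float = 1.0) -> TreeNode:
    """Rooted bifurcating tree by sequential random joins.

    Branch lengths are exponential with the given rate; every leaf is
    labelled by a feature identifier.
    """
    nodes = []
    for f in feature_ids:
        leaf = TreeNode(name=str(f))
        leaf.length = float(rng.exponential(1.0 / rate))
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.exponential(1.0 / rate))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


def generate_base(spec: CommunitySpec) -> tuple[CountTable, TreeNode]:
    """Generate a base community table and a matching random phylogeny."""
    rng = np.random.default_rng(spec.seed)
    feature_ids = [f"F{i:04d}" for i in range(spec.n_features)]
    sample_ids = [f"S{i:03d}" for i in range(spec.n_samples)]
    p = _base_proportions(spec, rng)
    X = _sample_counts(spec, p, rng)
    tree = random_tree(feature_ids, rng)
    table = CountTable(
        pd.DataFrame(X, index=sample_ids, columns=feature_ids)
    )
    return table, tree


# ---------------------------------------------------------------------------
# Perturbation scenarios
# ---------------------------------------------------------------------------

def apply_presence_absence(X1: CountTable, fraction_removed: float,
                           rng) -> CountTable:
    """Scenario 1: zero out a random fraction of features in every sample."""
    if not 0 < fraction_removed < 1:
        raise ValidationError("fraction_removed must be in (0, 1)")
    rng = np.random.default_rng(rng)
    m = X1.n_features
    n_remove = round(fraction_removed * m)
    if n_remove >= m:
        raise ValidationError("would remove every feature")
    removed = rng.choice(m, size=n_remove, replace=False)
    data = X1.data.copy()
    data.iloc[:, removed] = 0.0
    return CountTable(data)


def apply_differential_abundance(X1: CountTable, fold_increase_percent: float,
                                 affected_fraction: float = 0.25,
                                 rng=None) -> CountTable:
    """Scenario 2: multiply a random fraction of features by (1 + q/100)."""
    if fold_increase_percent <= 0:
        raise ValidationError("fold_increase_percent must be positive")
    if not 0 < affected_fraction <= 1:
        raise ValidationError("affected_fraction must be in (0, 1]")
    rng = np.random.default_rng(rng)
    m = X1.n_features
    n_affected = round(affected_fraction * m)
    affected = rng.choice(m, size=n_affected, replace=False)
    data = X1.data.copy()
    data.iloc[:, affected] *= 1.0 + fold_increase_percent / 100.0
    return CountTable(data)


# ---------------------------------------------------------------------------
# Calibrated two-group alpha effects
# ---------------------------------------------------------------------------

def realized_cohens_d(values1: np.ndarray, values2: np.ndarray) -> float:
    s1 = np.std(values1, ddof=1)
    s2 = np.std(values2, ddof=1)
    pooled = np.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
    if pooled == 0:
        return 0.0
    return float(abs(np.mean(values1) - np.mean(values2)) / pooled)


def two_group_alpha_effect(spec: CommunitySpec, target_d: float,
                           metric: str = "shannon", tolerance: float = 0.15,
                           max_iter: int = 30):
    """Generate two tables whose realised Cohen's d on an alpha metric
    approximates ``target_d``.

    Group 2 is produced from the same rank-abundance curve with the
    sharpness exponent tau adjusted by bisection until the realised d (on
    per-sample metric values, equal-weight pooled SD) is within
    ``tolerance * target_d`` of the target.  Returns (X1, X2, tree,
    realized_d).
    """
    from .alpha import alpha_table

    if target_d < 0:
        raise ValidationError("target_d must be >= 0")
    # Both groups share one rank-abundance curve and phylogeny; only the
    # sharpness of group 2's proportions (and its count sampling) differs.
    X1, tree = generate_base(spec)
    base_rng = np.random.default_rng(spec.seed)
    p = _base_proportions(spec, base_rng)
    seed2 = int(np.random.default_rng(spec.seed + 1).integers(2 ** 31))
    vals1 = alpha_table(X1, [metric], tree=tree)[metric].to_numpy()
    feature_ids, sample_ids = X1.feature_ids, X1.sample_ids

    def make_x2(tau: float):
        p2 = p ** tau
        p2 = p2 / p2.sum()
        counts = _sample_counts(spec, p2, np.random.default_rng(seed2))
        X2 = CountTable(
            pd.DataFrame(counts, index=sample_ids, columns=feature_ids)
        )
        vals2 = alpha_table(X2, [metric], tree=tree)[metric].to_numpy()
        return X2, realized_cohens_d(vals1, vals2)

    X2, d0 = make_x2(1.0)
    if target_d == 0:
        return X1, X2, tree, d0
    lo, d_lo = 1.0, d0
    hi = 1.0
    d_hi = d0
    for _ in range(max_iter):  # expand until the target is bracketed
        if d_hi >= target_d:
            break
        hi *= 1.3
        X2, d_hi = make_x2(hi)
    else:
        raise ValidationError(
            f"target d={target_d} not attainable within {max_iter} expansions"
        )
    best = (X2, d_hi, hi)
    for _ in range(max_iter):
        if abs(best[1] - target_d) <= tolerance * target_d:
            break
        mid = (lo + hi) / 2.0
        X2m, d_mid = make_x2(mid)
        if abs(d_mid - target_d) < abs(best[1] - target_d):
            best = (X2m, d_mid, mid)
        if d_mid < target_d:
            lo = mid
        else:
            hi = mid
    X2, d_real, _tau = best
    if abs(d_real - target_d) > tolerance * target_d:
        raise ValidationError(
            f"could not reach d={target_d} (best {d_real:.3f}) "
            f"after {max_iter} iterations"
        )
    return X1, X2, tree, d_real
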