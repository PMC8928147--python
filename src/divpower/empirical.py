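"""Empirical power estimation by resampling.

From two pools of samples X1 and X2 (pilot or simulated data sharing a
feature set), the engine draws, for each per-group size n on a grid, K
replicate pairs of n samples *with replacement* from each pool, applies
the chosen test (Kruskal-Wallis on an alpha metric, PERMANOVA on a beta
metric) at significance level alpha, and reports the empirical power

    EPr(n) = (number of replicates with p < alpha) / K.

Defaults follow common practice for this design: n = 5..50 in steps of 5,
K = 1000 for alpha metrics, K = 100 (with 999 permutations) for beta
metrics, alpha = 0.01.

Reproducibility: one master seed spawns an independent random stream per
(n, replicate) cell, so a curve is bit-reproducible and insensitive to
evaluation order.  Replicates whose test is degenerate (all values tied,
or zero within-group dissimilarity) count as non-rejections; the
denominator K is fixed.

Because every resampled row is an exact copy of a pool row, per-sample
alpha values and pairwise dissimilarities can be computed once on the
pools and sliced per replicate; this fast path is exactly equivalent to
recomputing from the subsampled tables (``recompute=True``, cross-tested).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .alpha import ALPHA_METRICS, alpha_table
from .beta import BETA_METRICS, beta_distance
from .community import CountTable, GroupDesign, ValidationError
from .stats import kruskal_wallis, permanova, permuted_f_pvalue

DEFAULT_GRID = tuple(range(5, 55, 5))


@dataclass(frozen=True)
class SubsampleScheme:
    """Resampling design for an empirical power estimate."""

    n_grid: tuple = DEFAULT_GRID
    K: int = 1000
    alpha_level: float = 0.01
    seed: int = 0

    def __post_init__(self):
        grid = tuple(int(n) for n in self.n_grid)
        if any(n < 2 for n in grid):
            raise ValidationError("all grid sizes must be >= 2")
        if list(grid) != sorted(grid):
            raise ValidationError("n_grid must be increasing")
        object.__setattr__(self, "n_grid", grid)
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        if not 0 < self.alpha_level < 1:
            raise ValidationError("alpha_level must be in (0, 1)")

    def replicate_rngs(self):
        """One independent Generator per (n, replicate) cell."""
        children = np.random.SeedSequence(self.seed).spawn(
            len(self.n_grid) * self.K
        )
        it = iter(children)
        return {
            (n, k): np.random.default_rng(next(it))
            for n in self.n_grid for k in range(self.K)
        }


@dataclass(frozen=True)
class PowerCurve:
    """Empirical power along a grid of per-group sample sizes."""

    metric: str
    test: str
    points: pd.DataFrame  # columns: n, K, rejections, EPr, ci_low, ci_high
    alpha_level: float
    seed: int

    def to_tsv(self, path) -> None:
        df = self.points.copy()
        df.insert(0, "metric", self.metric)
        df.to_csv(path, sep="\t", index=False)


def _check_pools(X1: CountTable, X2: CountTable):
    if X1.n_samples == 0 or X2.n_samples == 0:
        raise ValidationError("pools must be nonempty")
    if X1.feature_ids != X2.feature_ids:
        raise ValidationError("X1 and X2 must share the same feature set")


def _draw_indices(rng, N1: int, N2: int, n: int):
    idx1 = rng.integers(0, N1, size=n)
    idx2 = rng.integers(0, N2, size=n)
    return idx1, idx2


def subsample_pair(X1: CountTable, X2: CountTable, n: int, rng):
    """Draw n rows with replacement from each pool.

    Sample identifiers are suffixed with the draw index to stay unique;
    the returned design labels the groups ``group1``/``group2``.
    """
    _check_pools(X1, X2)
    if n < 2:
        raise ValidationError("n must be >= 2")
    rng = np.random.default_rng(rng)
    idx1, idx2 = _draw_indices(rng, X1.n_samples, X2.n_samples, n)
    sub1 = X1.take(idx1)
    sub2 = X2.take(idx2)
    # guard against identifier collisions between the two groups
    sub1 = CountTable(sub1.data.set_axis(
        [f"g1.{s}" for s in sub1.sample_ids], axis=0))
    sub2 = CountTable(sub2.data.set_axis(
        [f"g2.{s}" for s in sub2.sample_ids], axis=0))
    design = GroupDesign.from_labels(
        sub1.sample_ids + sub2.sample_ids,
        ["group1"] * n + ["group2"] * n,
    )
    return sub1, sub2, design


def _binom_ci(rejections: int, K: int):
    lo, hi = proportion_confint(rejections, K, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def _curve_frame(rows):
    return pd.DataFrame(
        rows, columns=["n", "K", "rejections", "EPr", "ci_low", "ci_high"]
    )


# ---------------------------------------------------------------------------
# Alpha metrics / Kruskal-Wallis
# ---------------------------------------------------------------------------

def empirical_power_alpha(X1: CountTable, X2: CountTable, metric: str,
                          scheme: SubsampleScheme = None, tree=None,
                          recompute: bool = False) -> PowerCurve:
    """Empirical power of the two-group Kruskal-Wallis test on an alpha
    metric, over the scheme's grid of per-group sizes."""
    if metric not in ALPHA_METRICS:
        raise ValidationError(
            f"unknown alpha metric {metric!r}; valid: {list(ALPHA_METRICS)}"
        )
    _check_pools(X1, X2)
    scheme = scheme or SubsampleScheme(K=1000)
    if not recompute:
        vals1 = alpha_table(X1, [metric], tree=tree)[metric].to_numpy()
        vals2 = alpha_table(X2, [metric], tree=tree)[metric].to_numpy()
    rngs = scheme.replicate_rngs()
    rows = []
    for n in scheme.n_grid:
        rejections = 0
        for k in range(scheme.K):
            rng = rngs[(n, k)]
            if recompute:
                sub1, sub2, _ = subsample_pair(X1, X2, n, rng)
                g1 = alpha_table(sub1, [metric], tree=tree)[metric].to_numpy()
                g2 = alpha_table(sub2, [metric], tree=tree)[metric].to_numpy()
            else:
                idx1, idx2 = _draw_indices(rng, X1.n_samples,
                                           X2.n_samples, n)
                g1, g2 = vals1[idx1], vals2[idx2]
            res = kruskal_wallis([g1, g2])
            if res.p_value < scheme.alpha_level:
                rejections += 1
        epr = rejections / scheme.K
        lo, hi = _binom_ci(rejections, scheme.K)
        rows.append((n, scheme.K, rejections, epr, lo, hi))
    return PowerCurve(metric=metric, test="kruskal_wallis",
                      points=_curve_frame(rows),
                      alpha_level=scheme.alpha_level, seed=scheme.seed)


# ---------------------------------------------------------------------------
# Beta metrics / PERMANOVA
# ---------------------------------------------------------------------------

def _pooled_squared_distances(X1: CountTable, X2: CountTable, metric: str,
                              tree, normalized: bool) -> np.ndarray:
    pooled = pd.concat(
        [
            X1.data.set_axis([f"p1.{s}" for s in X1.sample_ids], axis=0),
            X2.data.set_axis([f"p2.{s}" for s in X2.sample_ids], axis=0),
        ]
    )
    dm = beta_distance(CountTable(pooled), metric, tree=tree,
                       normalized=normalized)
    return dm.data ** 2


def empirical_power_beta(X1: CountTable, X2: CountTable, metric: str,
                         scheme: SubsampleScheme = None, tree=None,
                         n_permutations: int = 999,
                         normalized: bool = False,
                         recompute: bool = False,
                         collect_effects: bool = False):
    """Empirical power of PERMANOVA on a beta metric over the size grid.

    With ``collect_effects=True`` additionally returns, per grid point,
    the observed effect sizes (f^2 and omega^2) across replicates — the
    ingredients of a multivariate power-analysis protocol.
    """
    if metric not in BETA_METRICS:
        raise ValidationError(
            f"unknown beta metric {metric!r}; valid: {list(BETA_METRICS)}"
        )
    _check_pools(X1, X2)
    scheme = scheme or SubsampleScheme(K=100)
    if not recompute:
        D2 = _pooled_squared_distances(X1, X2, metric, tree, normalized)
    N1 = X1.n_samples
    rngs = scheme.replicate_rngs()
    rows, effect_rows = [], []
    for n in scheme.n_grid:
        codes = np.repeat([0, 1], n)
        rejections = 0
        f2s, w2s = [], []
        for k in range(scheme.K):
            rng = rngs[(n, k)]
            if recompute:
                sub1, sub2, design = subsample_pair(X1, X2, n, rng)
                pooled = CountTable(pd.concat([sub1.data, sub2.data]))
                dm = beta_distance(pooled, metric, tree=tree,
                                   normalized=normalized)
                res = permanova(dm, design, n_permutations, seed=rng)
                p, F_obs = res.p_value, res.pseudo_F
                ss_b, ss_w, ss_t = res.SS_B, res.SS_W, res.SS_T
            else:
                idx1, idx2 = _draw_indices(rng, N1, X2.n_samples, n)
                sel = np.concatenate([idx1, idx2 + N1])
                D2sub = D2[np.ix_(sel, sel)]
                F_obs, p, ss_b, ss_w, ss_t = permuted_f_pvalue(
                    D2sub, codes, 2, n_permutations, rng
                )
            if np.isfinite(F_obs) and p < scheme.alpha_level:
                rejections += 1
            if collect_effects and np.isfinite(F_obs) and ss_w > 0:
                ms_w = ss_w / (2 * n - 2)
                f2s.append(ss_b / ss_w)
                w2s.append((ss_b - ms_w) / (ss_t + ms_w))
        epr = rejections / scheme.K
        lo, hi = _binom_ci(rejections, scheme.K)
        rows.append((n, scheme.K, rejections, epr, lo, hi))
        if collect_effects:
            effect_rows.append({
                "n": n,
                "f2_mean": float(np.mean(f2s)) if f2s else np.nan,
                "f2_min": float(np.min(f2s)) if f2s else np.nan,
                "f2_max": float(np.max(f2s)) if f2s else np.nan,
                "omega2_mean": float(np.mean(w2s)) if w2s else np.nan,
                "omega2_min": float(np.min(w2s)) if w2s else np.nan,
                "omega2_max": float(np.max(w2s)) if w2s else np.nan,
            })
    curve = PowerCurve(metric=metric, test="permanova",
                       points=_curve_frame(rows),
                       alpha_level=scheme.alpha_level, seed=scheme.seed)
    if collect_effects:
        return curve, pd.DataFrame(effect_rows)
    return curve


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def power_report(curves, threshold: float = 0.8) -> pd.DataFrame:
    """Smallest grid n reaching EPr >= threshold per curve.

    ``n_required`` is NaN ("not reached") for curves that never attain
    the threshold on their grid.
    """
    curves = list(curves)
    if not curves:
        raise ValidationError("no curves supplied")
    rows = []
    for c in curves:
        hit = c.points.loc[c.points["EPr"] >= threshold, "n"]
        rows.append({
            "metric": c.metric,
            "test": c.test,
            "n_required": float(hit.iloc[0]) if len(hit) else np.nan,
            "reached": bool(len(hit)),
        })
    return pd.DataFrame(rows)
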