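"""Group-difference tests with effect sizes.

Univariate (alpha diversity): Kruskal-Wallis H with midrank tie correction,
chi-square p-value on k-1 df, eta-squared effect size
``(H - k + 1)/(N - k)`` and, for two groups, Cohen's d from the group
means and SDs with the equal-weight pooled SD.

Multivariate (beta diversity): PERMANOVA on a dissimilarity matrix.  With
n samples in g groups and d_ij the dissimilarities,

    SS_T = (1/n) sum_{i<j} d_ij^2
    SS_W = sum_groups (1/n_g) sum_{i<j in group} d_ij^2
    SS_B = SS_T - SS_W
    pseudo-F = (SS_B/(g-1)) / (SS_W/(n-g))

The p-value permutes group labels, using the (b+1)/(k+1) convention so the
smallest attainable p is 1/(n_permutations+1).  Effect sizes: Cohen's
f^2 = SS_B/SS_W and omega-squared
``(SS_B - df_B * MS_W) / (SS_T + MS_W)``.

Exchangeability caveat: duplicated samples created by with-replacement
resampling are permuted as ordinary units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import skbio
from scipy import stats as sps

from .community import GroupDesign, ValidationError


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p_value: float
    N: int
    k: int
    eta_squared: float
    cohens_d: float | None = None  # two-group designs only

    @property
    def statistic(self) -> float:
        return self.H


def _group_arrays(values, design: GroupDesign = None):
    """Accept either (values, design) or a sequence of per-group arrays."""
    if design is not None:
        import pandas as pd

        if isinstance(values, pd.Series):
            ids = list(values.index)
            vals = values.to_numpy(dtype=float)
        else:
            raise ValidationError(
                "with a GroupDesign, pass values as a pandas Series "
                "indexed by sample identifier"
            )
        labels = design.labels_for(ids)
        return [vals[labels == g] for g in design.groups]
    return [np.asarray(g, dtype=float) for g in values]


def kruskal_wallis(values, design: GroupDesign = None,
                   alpha_level: float = 0.01) -> KWResult:
    """Kruskal-Wallis test across groups of alpha diversity values.

    ``values`` is either a pandas Series indexed by sample id (with
    ``design`` supplying labels) or a sequence of per-group arrays.
    """
    groups = _group_arrays(values, design)
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    if any(len(g) < 1 for g in groups):
        raise ValidationError("every group needs at least one observation")
    N = sum(len(g) for g in groups)
    k = len(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # All observations tied: H undefined under the tie correction.
        return KWResult(H=0.0, df=k - 1, p_value=1.0, N=N, k=k,
                        eta_squared=_eta_squared(0.0, k, N),
                        cohens_d=0.0 if k == 2 else None)
    H, p = sps.kruskal(*groups)
    d = None
    if k == 2:
        m1, m2 = groups[0].mean(), groups[1].mean()
        s1 = groups[0].std(ddof=1) if len(groups[0]) > 1 else 0.0
        s2 = groups[1].std(ddof=1) if len(groups[1]) > 1 else 0.0
        pooled_sd = np.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
        d = float(abs(m1 - m2) / pooled_sd) if pooled_sd > 0 else 0.0
    return KWResult(H=float(H), df=k - 1, p_value=float(p), N=N, k=k,
                    eta_squared=_eta_squared(float(H), k, N), cohens_d=d)


def _eta_squared(H: float, k: int, N: int) -> float:
    return (H - k + 1) / (N - k)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    df_between: int
    df_within: int
    SS_B: float
    SS_W: float
    SS_T: float
    p_value: float
    n_permutations: int
    cohens_f2: float
    omega_squared: float

    @property
    def statistic(self) -> float:
        return self.pseudo_F


def _permanova_ss(D2: np.ndarray, group_masks) -> tuple[float, float]:
    n = D2.shape[0]
    ss_t = D2.sum() / (2.0 * n)
    ss_w = 0.0
    for mask in group_masks:
        n_g = mask.sum()
        ss_w += D2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    return ss_t, ss_w


def permanova_f(D2: np.ndarray, codes: np.ndarray, g: int) -> float:
    """Pseudo-F from a squared-dissimilarity matrix and integer labels."""
    masks = [codes == c for c in range(g)]
    ss_t, ss_w = _permanova_ss(D2, masks)
    n = D2.shape[0]
    ss_b = ss_t - ss_w
    with np.errstate(divide="ignore"):
        return float((ss_b / (g - 1)) / (ss_w / (n - g)))


def permuted_f_pvalue(D2: np.ndarray, codes: np.ndarray, g: int,
                      n_permutations: int, rng):
    """Observed pseudo-F, permutation p-value, and sums of squares.

    Shared by :func:`permanova` and the resampling engine so that both
    draw identical permutation streams from the same generator.  A zero
    within-group sum of squares yields an infinite F; callers decide how
    to score such degenerate replicates.
    """
    n = D2.shape[0]
    sizes = np.bincount(codes, minlength=g)
    masks = [codes == c for c in range(g)]
    ss_t, ss_w = _permanova_ss(D2, masks)
    ss_b = ss_t - ss_w
    df_b, df_w = g - 1, n - g
    with np.errstate(divide="ignore", invalid="ignore"):
        F_obs = (ss_b / df_b) / (ss_w / df_w)

    perms = np.empty((n_permutations, n), dtype=np.intp)
    for i in range(n_permutations):
        perms[i] = rng.permutation(n)
    perm_codes = codes[perms]  # labels after permuting
    ss_w_perm = np.zeros(n_permutations)
    for c in range(g):
        M = (perm_codes == c).astype(float)  # (P, n)
        ss_w_perm += ((M @ D2) * M).sum(axis=1) / (2.0 * sizes[c])
    ss_b_perm = ss_t - ss_w_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        F_perm = (ss_b_perm / df_b) / (ss_w_perm / df_w)
    b = int(np.count_nonzero(F_perm >= F_obs))
    p = (b + 1) / (n_permutations + 1)
    return float(F_obs), float(p), float(ss_b), float(ss_w), float(ss_t)


def permanova(dm: skbio.DistanceMatrix, design: GroupDesign,
              n_permutations: int = 9999, seed=None) -> PermanovaResult:
    """PERMANOVA with a label-permutation p-value.

    ``seed`` may be an int or a numpy Generator; a fixed seed makes the
    p-value bit-reproducible.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    ids = list(dm.ids)
    labels = design.labels_for(ids)
    uniq, codes = np.unique(labels, return_inverse=True)
    g = uniq.size
    if g < 2:
        raise ValidationError("need at least 2 groups")
    sizes = np.bincount(codes)
    if np.any(sizes < 2):
        raise ValidationError("singleton groups are not allowed in PERMANOVA")
    n = len(ids)
    D2 = dm.data ** 2

    rng = np.random.default_rng(seed)
    F_obs, p, ss_b, ss_w, ss_t = permuted_f_pvalue(
        D2, codes, g, n_permutations, rng
    )
    df_b, df_w = g - 1, n - g
    ms_w = ss_w / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f2 = ss_b / ss_w if ss_w > 0 else np.inf
        w2 = (ss_b - df_b * ms_w) / (ss_t + ms_w) if ss_t + ms_w > 0 else 0.0
    return PermanovaResult(
        pseudo_F=float(F_obs), df_between=df_b, df_within=df_w,
        SS_B=float(ss_b), SS_W=float(ss_w), SS_T=float(ss_t),
        p_value=float(p), n_permutations=n_permutations,
        cohens_f2=float(f2), omega_squared=float(w2),
    )


# ---------------------------------------------------------------------------
# APA-style one-line reports
# ---------------------------------------------------------------------------

def report_line(result) -> str:
    """Single-line APA-style summary of a test result."""
    if isinstance(result, KWResult):
        line = (f"H({result.df}) = {result.H:.2f}, "
                f"p = {result.p_value:.4f}, "
                f"eta2 = {result.eta_squared:.2f}")
        if result.cohens_d is not None:
            line += f", d = {result.cohens_d:.2f}"
        return line
    if isinstance(result, PermanovaResult):
        return (f"F({result.df_between}, {result.df_within}) = "
                f"{result.pseudo_F:.2f}, p = {result.p_value:.4f}, "
                f"f2 = {result.cohens_f2:.3f}")
    raise ValidationError(f"cannot report {type(result).__name__}")
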