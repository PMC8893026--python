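"""Pairwise community dissimilarity and the permutation tests run on it.

Distances are Bray-Curtis on relative abundances or weighted UniFrac on a
rooted phylogeny (normalized by default so distances lie in [0, 1] and
similarity = 1 − d is well defined).  The tests — PERMANOVA, PERMDISP, ANOSIM —
permute whole samples only; all permutation loops are vectorised and seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity as _skbio_beta

from ._util import gower_eig, random_permutations
from .table import OtuTable

__all__ = [
    "bray_curtis",
    "weighted_unifrac",
    "pcoa",
    "permanova",
    "pairwise_permanova",
    "permdisp",
    "anosim",
    "simper",
    "distance_decay",
    "PcoaResult",
    "PermanovaResult",
    "PermdispResult",
    "SimperResult",
    "DistanceDecayResult",
]


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d_ij = Σ|y_i − y_j| / Σ(y_i + y_j) on
    per-sample relative abundances."""
    rel = table.relative_abundance()
    return DistanceMatrix(squareform(pdist(rel, metric="braycurtis")), table.sample_ids)


def weighted_unifrac(
    table: OtuTable, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac: branch lengths weighted by the difference in the
    fraction of each sample's reads descending from the branch.

    The normalized variant divides Σℓ_b|A_b − B_b| by Σℓ_b(A_b + B_b) so that
    distances lie in [0, 1].
    """
    tips = {t.name for t in tree.tips()}
    used = {o for o, c in zip(table.otu_ids, table.counts.sum(axis=0)) if c > 0}
    missing = sorted(used - tips)
    if missing:
        raise ValueError(f"OTUs absent from the tree: {missing}")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError("tree has negative branch lengths")
    return _skbio_beta(
        "weighted_unifrac",
        table.counts,
        ids=table.sample_ids,
        taxa=table.otu_ids,
        tree=tree,
        normalized=normalized,
    )


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    """Principal coordinates of a distance matrix.

    ``coordinates`` carries the positive-eigenvalue axes (scaled by √λ);
    columns for negative eigenvalues are zeroed but their magnitudes are kept
    in ``eigenvalues`` so downstream consumers can correct for them.
    """

    ids: list[str]
    eigenvalues: np.ndarray  # descending, negatives retained
    coordinates: np.ndarray  # samples x axes
    proportion_explained: np.ndarray
    eigenvectors: np.ndarray = field(repr=False)  # unit-norm, all axes

    @property
    def negative_inertia(self) -> float:
        return float(-self.eigenvalues[self.eigenvalues < 0].sum())


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    vals, vecs = gower_eig(dm.data)
    pos = vals > 0
    coords = np.zeros_like(vecs)
    coords[:, pos] = vecs[:, pos] * np.sqrt(vals[pos])
    total_pos = vals[pos].sum()
    prop = np.where(pos, vals / total_pos if total_pos > 0 else 0.0, 0.0)
    return PcoaResult(list(dm.ids), vals, coords, prop, vecs)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    p: float
    n_permutations: int
    ss_among: float
    ss_within: float
    ss_total: float
    df_among: int
    df_within: int


def _group_codes(ids, groups: Mapping[str, str]) -> np.ndarray:
    g = pd.Series(groups).reindex(list(ids))
    if g.isna().any():
        raise ValueError(f"samples without group labels: {list(g.index[g.isna()])}")
    return pd.Categorical(g).codes.astype(np.int64)


def _permanova_stats(d2: np.ndarray, onehot: np.ndarray) -> tuple[float, float, float]:
    """(ss_total, ss_within) given squared distances and (n, a) one-hot labels."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    n_g = onehot.sum(axis=0)
    within = np.einsum("ig,ij,jg->g", onehot, d2, onehot) / (2.0 * n_g)
    return ss_total, float(within.sum())


def permanova(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational MANOVA on a distance matrix.

    SS_total = (1/N)Σ_{i<j} d²; SS_within pools per-group sums scaled by group
    size; pseudo-F = (SS_among/(a−1)) / (SS_within/(N−a)).  The p-value counts
    whole-sample label permutations with F as extreme as observed, with the
    (observed ≥ observed) inclusion so p ≥ 1/(n_perm+1).
    """
    codes = _group_codes(dm.ids, groups)
    a = codes.max() + 1
    n = len(codes)
    if a < 2:
        raise ValueError("need at least 2 groups")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d2 = dm.data ** 2
    onehot = np.eye(a)[codes]
    ss_total, ss_within = _permanova_stats(d2, onehot)
    ss_among = ss_total - ss_within
    df_among, df_within = a - 1, n - a
    f_obs = (ss_among / df_among) / (ss_within / df_within) if ss_within > 0 else np.inf

    rng = np.random.default_rng(seed)
    perms = random_permutations(rng, n, n_perm)
    oh = np.eye(a)[codes[perms]]  # (n_perm, n, a)
    n_g = onehot.sum(axis=0)
    within_p = np.einsum("pig,ij,pjg->pg", oh, d2, oh) / (2.0 * n_g)
    ss_within_p = within_p.sum(axis=1)
    ss_among_p = ss_total - ss_within_p
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ss_among_p / df_among) / (ss_within_p / df_within)
    p = (np.count_nonzero(f_perm >= f_obs) + 1) / (n_perm + 1)
    return PermanovaResult(
        float(f_obs), float(p), n_perm,
        float(ss_among), float(ss_within), float(ss_total), df_among, df_within,
    )


def pairwise_permanova(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int | None = None,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """PERMANOVA restricted to each pair of groups; unadjusted p by default."""
    g = pd.Series(groups).reindex(list(dm.ids))
    levels = sorted(g.dropna().unique())
    rng = np.random.default_rng(seed)
    rows = []
    for g1, g2 in combinations(levels, 2):
        ids = [s for s in dm.ids if g.loc[s] in (g1, g2)]
        sub = dm.filter(ids)
        res = permanova(sub, g.loc[ids], n_perm=n_perm,
                        seed=int(rng.integers(2 ** 31)))
        rows.append(
            {"group_1": g1, "group_2": g2, "n": len(ids),
             "pseudo_F": res.pseudo_F, "p": res.p}
        )
    out = pd.DataFrame(rows)
    if bonferroni:
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------

@dataclass
class PermdispResult:
    F: float
    p: float
    n_permutations: int
    distances: pd.Series  # per-sample distance to its group center


def _spatial_median(y: np.ndarray, n_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Weiszfeld geometric median of the rows of y."""
    c = y.mean(axis=0)
    for _ in range(n_iter):
        d = np.linalg.norm(y - c, axis=1)
        d = np.where(d < 1e-12, 1e-12, d)
        new = (y / d[:, None]).sum(axis=0) / (1.0 / d).sum()
        if np.linalg.norm(new - c) < tol:
            return new
        c = new
    return c


def permdisp(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int | None = None,
    center: str = "centroid",
) -> PermdispResult:
    """Homogeneity of multivariate dispersions.

    Samples are embedded by PCoA, keeping negative-eigenvalue axes as
    imaginary coordinates; the distance of a sample to its group center is
    z = sqrt(max(0, Σ_real(y−c)² − Σ_imag(y−c)²)).  A one-way ANOVA F on z is
    compared against permutations of z across groups.
    """
    codes = _group_codes(dm.ids, groups)
    a = codes.max() + 1
    if a < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 samples")
    vals, vecs = gower_eig(dm.data)
    real = vecs[:, vals > 0] * np.sqrt(vals[vals > 0])
    imag = vecs[:, vals < 0] * np.sqrt(-vals[vals < 0])

    z = np.empty(len(codes))
    for g in range(a):
        idx = codes == g
        if center == "centroid":
            c_r, c_i = real[idx].mean(axis=0), imag[idx].mean(axis=0)
        elif center == "median":
            c_r = _spatial_median(real[idx])
            c_i = _spatial_median(imag[idx]) if imag.shape[1] else imag[:0].sum(axis=0)
        else:
            raise ValueError(f"unknown center {center!r}")
        sq = ((real[idx] - c_r) ** 2).sum(axis=1) - ((imag[idx] - c_i) ** 2).sum(axis=1)
        z[idx] = np.sqrt(np.maximum(sq, 0.0))

    f_obs = _anova_f(z, codes, a)
    rng = np.random.default_rng(seed)
    perms = random_permutations(rng, len(z), n_perm)
    f_perm = _anova_f_batch(z[perms], codes, a)
    p = (np.count_nonzero(f_perm >= f_obs) + 1) / (n_perm + 1)
    return PermdispResult(
        float(f_obs), float(p), n_perm, pd.Series(z, index=list(dm.ids))
    )


def _anova_f(z: np.ndarray, codes: np.ndarray, a: int) -> float:
    return float(_anova_f_batch(z[None, :], codes, a)[0])


def _anova_f_batch(z: np.ndarray, codes: np.ndarray, a: int) -> np.ndarray:
    """One-way ANOVA F for each row of z with fixed group codes."""
    n = z.shape[1]
    onehot = np.eye(a)[codes]
    n_g = onehot.sum(axis=0)
    gsum = z @ onehot
    total = z.sum(axis=1)
    ss_between = (gsum ** 2 / n_g).sum(axis=1) - total ** 2 / n
    ss_within = (z ** 2).sum(axis=1) - (gsum ** 2 / n_g).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return np.where(ss_within <= 0, np.inf, f)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def anosim(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """ANOSIM R = (mean between-group rank − mean within-group rank)/(M/2)."""
    codes = _group_codes(dm.ids, groups)
    if codes.max() + 1 < 2:
        raise ValueError("need at least 2 groups")
    n = len(codes)
    iu, ju = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dm.data[iu, ju])
    m = len(ranks)
    within = codes[iu] == codes[ju]
    r_obs = (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    rng = np.random.default_rng(seed)
    perms = random_permutations(rng, n, n_perm)
    pc = codes[perms]
    w = pc[:, iu] == pc[:, ju]  # (n_perm, m)
    n_w = w.sum(axis=1)
    sum_w = (ranks[None, :] * w).sum(axis=1)
    mean_w = sum_w / n_w
    mean_b = (ranks.sum() - sum_w) / (m - n_w)
    r_perm = (mean_b - mean_w) / (m / 2.0)
    p = (np.count_nonzero(r_perm >= r_obs) + 1) / (n_perm + 1)
    return float(r_obs), float(p)


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

@dataclass
class SimperResult:
    group_1: str
    group_2: str
    contributions: pd.Series  # per-taxon mean % contribution, descending
    overall_dissimilarity: float  # mean Bray-Curtis x 100
    n_pairs: int

    @property
    def cumulative(self) -> pd.Series:
        return self.contributions.cumsum()


def simper(
    table: OtuTable,
    groups: Mapping[str, str],
    crossed_factor: Mapping[str, str] | None = None,
) -> list[SimperResult]:
    """Similarity-percentage decomposition of between-group Bray-Curtis.

    For each between-group sample pair the per-taxon contribution is
    100·|y_ik − y_jk| / Σ_k(y_ik + y_jk); contributions are averaged over
    pairs and sum to the mean pairwise dissimilarity (×100).  In two-way mode
    only pairs sharing the same level of ``crossed_factor`` are compared.
    """
    rel = table.relative_abundance()
    g = pd.Series(groups).reindex(table.sample_ids)
    levels = sorted(g.dropna().unique())
    cf = (
        pd.Series(crossed_factor).reindex(table.sample_ids)
        if crossed_factor is not None
        else None
    )
    results = []
    for g1, g2 in combinations(levels, 2):
        i_idx = np.flatnonzero(np.asarray(g == g1))
        j_idx = np.flatnonzero(np.asarray(g == g2))
        pairs = [
            (i, j)
            for i in i_idx
            for j in j_idx
            if cf is None or cf.iloc[i] == cf.iloc[j]
        ]
        if not pairs:
            import warnings

            warnings.warn(
                f"no admissible sample pairs for groups ({g1}, {g2}); skipped",
                stacklevel=2,
            )
            continue
        contrib = np.zeros(len(table.otu_ids))
        for i, j in pairs:
            denom = (rel[i] + rel[j]).sum()  # = 2 on relative abundances
            contrib += 100.0 * np.abs(rel[i] - rel[j]) / denom
        contrib /= len(pairs)
        ser = pd.Series(contrib, index=table.otu_ids).sort_values(ascending=False)
        results.append(SimperResult(g1, g2, ser, float(contrib.sum()), len(pairs)))
    return results


# ---------------------------------------------------------------------------
# Distance decay
# ---------------------------------------------------------------------------

@dataclass
class DistanceDecayResult:
    slope: float
    intercept: float
    r_squared: float
    F: float
    df: tuple[int, int]
    p: float
    n_points: int


def distance_decay(
    dm: DistanceMatrix, geo: DistanceMatrix, pairs: str = "ordered"
) -> DistanceDecayResult:
    """OLS of community similarity (1 − d) on geographic distance.

    With ``pairs="ordered"`` both (i, j) and (j, i) enter the regression, so
    n_points = N(N−1) and the residual df is N(N−1) − 2.  This doubles each
    observation (a pseudo-replication caveat) but is the convention under
    which the reported F degrees of freedom arise.  ``pairs="unordered"``
    uses each pair once.
    """
    if list(dm.ids) != list(geo.ids):
        geo = geo.filter(dm.ids)
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 samples")
    iu, ju = np.triu_indices(n, k=1)
    x = geo.data[iu, ju]
    y = 1.0 - dm.data[iu, ju]
    if pairs == "ordered":
        x = np.concatenate([x, x])
        y = np.concatenate([y, y])
    elif pairs != "unordered":
        raise ValueError(f"unknown pairs convention {pairs!r}")
    n_points = len(x)
    df = (1, n_points - 2)
    if np.ptp(y) == 0:
        return DistanceDecayResult(0.0, float(y[0]), 0.0, 0.0, df, 1.0, n_points)
    fit = stats.linregress(x, y)
    r2 = fit.rvalue ** 2
    if r2 >= 1.0:
        f = np.inf
    else:
        f = r2 / (1 - r2) * df[1]
    # recompute p at the ordered-pair df (linregress already uses n_points)
    p = float(stats.f.sf(f, *df)) if np.isfinite(f) else 0.0
    return DistanceDecayResult(
        float(fit.slope), float(fit.intercept), float(r2), float(f), df, p, n_points
    )
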