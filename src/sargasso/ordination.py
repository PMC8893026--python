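"""Partial distance-based redundancy analysis and variation partitioning.

db-RDA regresses the principal coordinates of a community distance matrix on
environmental predictors, optionally after partialling out conditioning
variables (here: spatial eigenfunctions).  Variation partitioning decomposes
the adjusted R² of the joint model into pure-environmental [a], shared [b],
pure-spatial [c] and residual [d] fractions; when collinearity between
environment and space drives [b] negative, proportional apportioning
reallocates the combined explained variance to the pure fractions in their
raw ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from ._util import gower_eig, random_permutations

__all__ = [
    "dbrda",
    "forward_select",
    "variation_partition",
    "proportional_apportion",
    "DbRdaResult",
    "VariationPartition",
]


@dataclass
class DbRdaResult:
    constrained_inertia: float
    residual_inertia: float
    total_inertia: float
    r_squared: float
    adj_r_squared: float
    pseudo_F: float
    p: float
    n: int
    m: int  # rank of constrained predictors (after conditioning)
    q: int  # rank of conditioning variables
    n_permutations: int


def _standardize(X: pd.DataFrame) -> np.ndarray:
    arr = X.to_numpy(dtype=float)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (arr - mu) / sd


def _align(dm: DistanceMatrix, *tables) -> tuple[DistanceMatrix, list[pd.DataFrame]]:
    """Subset everything to complete-case samples present in all inputs."""
    ids = [s for s in dm.ids]
    frames = []
    for t in tables:
        if t is None:
            frames.append(None)
            continue
        t = t.reindex(ids)
        frames.append(t)
    ok = np.ones(len(ids), dtype=bool)
    for t in frames:
        if t is not None:
            ok &= ~t.isna().any(axis=1).to_numpy()
    kept = [s for s, k in zip(ids, ok) if k]
    if len(kept) < len(ids):
        frames = [t.loc[kept] if t is not None else None for t in frames]
        dm = dm.filter(kept)
    return dm, frames


def _orthonormal_basis(A: np.ndarray) -> np.ndarray:
    """Orthonormal basis of col(A) via SVD, rank-truncated."""
    if A.size == 0:
        return np.empty((A.shape[0], 0))
    u, s, _ = np.linalg.svd(A, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    return u[:, :rank]


def dbrda(
    dm: DistanceMatrix,
    X: pd.DataFrame,
    Z: pd.DataFrame | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> DbRdaResult:
    """Distance-based RDA of ``dm`` on predictors ``X``, conditioned on ``Z``.

    The positive-eigenvalue PCoA axes of ``dm`` form the response; response
    and predictors are residualized on [intercept, Z]; the constrained inertia
    is the sum of squared fitted values of the least-squares fit on the
    residualized predictors.  Significance is assessed by permuting rows of
    the residualized response (reduced-model permutation).  adj R² uses the
    Ezekiel correction with conditioning degrees of freedom.
    """
    dm, (X, Z) = _align(dm, X, Z)
    n = len(dm.ids)
    vals, vecs = gower_eig(dm.data)
    pos = vals > vals.max() * 1e-12 if vals.max() > 0 else vals > 0
    Y = vecs[:, pos] * np.sqrt(vals[pos])
    neg_inertia = float(-vals[vals < 0].sum())
    if neg_inertia > 0:
        logging.getLogger(__name__).debug(
            "dropping negative-eigenvalue inertia %.4g before regression",
            neg_inertia,
        )

    Xs = _standardize(X)
    if Z is not None and Z.shape[1] > 0:
        Zs = _standardize(Z)
        Zc = Zs - Zs.mean(axis=0)
        Qz = _orthonormal_basis(Zc)
        q = Qz.shape[1]
    else:
        Qz, q = np.empty((n, 0)), 0

    def _residualize(A: np.ndarray) -> np.ndarray:
        A = A - A.mean(axis=0)  # intercept
        if q:
            A = A - Qz @ (Qz.T @ A)
        return A

    Yr = _residualize(Y)
    Xr = _residualize(Xs)
    Qx = _orthonormal_basis(Xr)
    m = Qx.shape[1]
    if m < X.shape[1]:
        warnings.warn(
            f"collinear predictors after conditioning: rank {m} < {X.shape[1]}",
            stacklevel=2,
        )
    if m == 0:
        raise ValueError("predictors have rank 0 after conditioning")
    df_resid = n - m - q - 1
    if df_resid < 1:
        raise ValueError(
            f"too few samples (n={n}) for m={m} predictors and q={q} conditions"
        )

    total = float((Yr ** 2).sum())
    H = Qx @ Qx.T
    constrained = float(np.einsum("ij,ik,jk->", H, Yr, Yr))
    residual = total - constrained
    r2 = constrained / total if total > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1 - q) / (n - 1 - q - m)
    f_obs = (constrained / m) / (residual / df_resid) if residual > 0 else np.inf

    p = np.nan
    if n_perm >= 1:
        rng = np.random.default_rng(seed)
        perms = random_permutations(rng, n, n_perm)
        G = Yr @ Yr.T
        # tr(Yp' H Yp) = Σ_ij H_ij G[perm_i, perm_j]
        c_perm = np.einsum(
            "ij,pij->p", H, G[perms[:, :, None], perms[:, None, :]]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = (c_perm / m) / ((total - c_perm) / df_resid)
        p = float((np.count_nonzero(f_perm >= f_obs) + 1) / (n_perm + 1))
    return DbRdaResult(
        constrained, residual, total, float(r2), float(adj), float(f_obs), p,
        n, m, q, max(n_perm, 0),
    )


def forward_select(
    dm: DistanceMatrix,
    candidates: pd.DataFrame,
    Z: pd.DataFrame | None = None,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy forward selection of predictors by adjusted R² gain.

    Double stopping rule: a candidate whose marginal permutation p exceeds
    ``alpha`` is rejected and selection ends; selection also ends once the
    accepted model's adjusted R² reaches the global (all-candidate) adjusted
    R² ceiling.
    """
    if candidates.shape[1] < 1:
        raise ValueError("need at least one candidate predictor")
    rng = np.random.default_rng(seed)
    global_adj = dbrda(dm, candidates, Z, n_perm=0).adj_r_squared
    selected: list[str] = []
    records = []
    remaining = list(candidates.columns)
    current_adj = -np.inf
    while remaining:
        scores = {}
        for c in remaining:
            try:
                scores[c] = dbrda(
                    dm, candidates[selected + [c]], Z, n_perm=0
                ).adj_r_squared
            except ValueError:
                continue
        if not scores:
            break
        best = max(scores, key=scores.get)
        best_adj = scores[best]
        if best_adj <= current_adj and selected:
            break  # no gain from any remaining candidate
        cond = candidates[selected]
        Zfull = cond if Z is None else pd.concat([Z, cond], axis=1)
        if Zfull.shape[1] == 0:
            Zfull = None
        marg = dbrda(
            dm, candidates[[best]], Zfull, n_perm=n_perm,
            seed=int(rng.integers(2 ** 31)),
        )
        if marg.p > alpha:
            break
        selected.append(best)
        remaining = [
            c for c in remaining
            if c != best
            and np.linalg.matrix_rank(
                _standardize(candidates[selected + [c]])
            ) > len(selected)
        ]
        records.append({"variable": best, "adj_r_squared": best_adj, "p": marg.p})
        current_adj = best_adj
        if best_adj > global_adj + 1e-12:
            break  # model has reached the all-candidate ceiling
    return selected, pd.DataFrame(records, columns=["variable", "adj_r_squared", "p"])


@dataclass
class VariationPartition:
    """Adjusted-R² decomposition into pure/shared/residual fractions."""

    a: float  # pure environment
    b: float  # shared
    c: float  # pure space
    d: float  # residual
    adj_env: float
    adj_space: float
    adj_combined: float
    apportioned: bool
    a_corrected: float | None = None
    b_corrected: float | None = None
    c_corrected: float | None = None

    @property
    def environmental_fraction(self) -> float:
        return self.a_corrected if self.apportioned else self.a

    @property
    def spatial_fraction(self) -> float:
        return self.c_corrected if self.apportioned else self.c


def proportional_apportion(
    a: float, c: float, combined: float
) -> tuple[float, float, float]:
    """Reallocate the combined adjusted R² to the pure fractions in the a:c
    ratio, zeroing the (negative) shared fraction.

    Returns (a', c', b' = 0) with a' + c' = combined and a'/c' = a/c.
    """
    if a + c <= 0:
        raise ValueError("proportional apportioning undefined for a + c <= 0")
    if combined < 0:
        raise ValueError("combined adjusted R-squared must be non-negative")
    a_p = combined * a / (a + c)
    c_p = combined * c / (a + c)
    return a_p, c_p, 0.0


def variation_partition(
    dm: DistanceMatrix,
    E: pd.DataFrame,
    S: pd.DataFrame,
    n_perm: int = 0,
    seed: int | None = None,
) -> VariationPartition:
    """Partition community variation into environmental and spatial fractions.

    Fits the three unconditioned models E, S and E∪S; in adjusted-R² units
    a = adj(E∪S) − adj(S), c = adj(E∪S) − adj(E), b = adj(E) + adj(S) −
    adj(E∪S), d = 1 − adj(E∪S).  Proportional apportioning is applied iff the
    shared fraction b is negative.
    """
    both = pd.concat([E, S], axis=1)
    adj_e = dbrda(dm, E, None, n_perm=0).adj_r_squared
    adj_s = dbrda(dm, S, None, n_perm=0).adj_r_squared
    adj_es = dbrda(dm, both, None, n_perm=n_perm, seed=seed).adj_r_squared
    a = adj_es - adj_s
    c = adj_es - adj_e
    b = adj_e + adj_s - adj_es
    d = 1.0 - adj_es
    if b < 0 and a + c > 0 and adj_es >= 0:
        a_p, c_p, b_p = proportional_apportion(a, c, adj_es)
        return VariationPartition(
            a, b, c, d, adj_e, adj_s, adj_es, True, a_p, b_p, c_p
        )
    return VariationPartition(a, b, c, d, adj_e, adj_s, adj_es, False)
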