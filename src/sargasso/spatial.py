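"""Geographic distances, Mantel correlation and PCNM spatial eigenfunctions.

Samples span ~15° of latitude, so distances are great-circle (haversine, IUGG
mean Earth radius) rather than Euclidean.  PCNM (principal coordinates of
neighbour matrices) builds spatial predictor variables by eigendecomposing a
geographic distance matrix truncated at the longest minimum-spanning-tree
edge; the positive-eigenvalue eigenvectors describe spatial patterns from
broad trends to fine-scale structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from skbio import DistanceMatrix

from ._util import gower_eig, random_permutations

EARTH_RADIUS_KM = 6371.0088  # IUGG mean radius

__all__ = ["haversine_matrix", "mantel", "pcnm", "PcnmBasis", "EARTH_RADIUS_KM"]


def haversine_matrix(metadata: pd.DataFrame) -> DistanceMatrix:
    """Great-circle distances (km) between samples from latitude/longitude."""
    missing = metadata.index[
        metadata["latitude"].isna() | metadata["longitude"].isna()
    ]
    if len(missing):
        raise ValueError(f"samples with missing coordinates: {list(missing)}")
    lat = np.radians(metadata["latitude"].to_numpy(dtype=float))
    lon = np.radians(metadata["longitude"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(d, list(metadata.index))


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    Pearson r over the lower-triangle entries; the p-value permutes the
    row/column order of the first matrix.  Permuting rows and columns jointly
    only re-pairs entries, so the permuted vector is a rearrangement of the
    same values and the correlation can be evaluated by gathering.
    """
    if list(dm1.ids) != list(dm2.ids):
        dm2 = dm2.filter(dm1.ids)
    n = len(dm1.ids)
    if n < 3:
        raise ValueError("need at least 3 samples")
    iu, ju = np.triu_indices(n, k=1)
    v1 = dm1.data[iu, ju]
    v2 = dm2.data[iu, ju]
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("Mantel correlation undefined for a constant matrix")
    g1 = (v1 - v1.mean()) / v1.std()
    g2 = (v2 - v2.mean()) / v2.std()
    m = len(v1)
    r_obs = float(g1 @ g2 / m)

    rng = np.random.default_rng(seed)
    perms = random_permutations(rng, n, n_perm)
    flat = np.empty((n, n))
    flat[iu, ju] = g1
    flat[ju, iu] = g1
    vals = flat[perms[:, iu], perms[:, ju]]  # (n_perm, m) standardized already
    r_perm = vals @ g2 / m
    p = (np.count_nonzero(np.abs(r_perm) >= abs(r_obs)) + 1) / (n_perm + 1)
    return r_obs, float(p)


@dataclass
class PcnmBasis:
    """Spatial eigenfunctions from a truncated geographic distance matrix."""

    ids: list[str]
    eigenfunctions: np.ndarray  # samples x axes, unit-norm columns
    eigenvalues: np.ndarray
    threshold: float  # truncation distance t (longest MST edge, km)

    def as_dataframe(self) -> pd.DataFrame:
        cols = [f"PCNM{i + 1}" for i in range(self.eigenfunctions.shape[1])]
        return pd.DataFrame(self.eigenfunctions, index=self.ids, columns=cols)


def pcnm(geo: DistanceMatrix, replacement_factor: float = 4.0) -> PcnmBasis:
    """PCNM spatial eigenfunctions.

    The truncation threshold t is the longest edge of the minimum spanning
    tree of the distance matrix (the smallest t keeping the neighbour graph
    connected).  Distances above t are replaced by ``replacement_factor``·t,
    the truncated matrix is Gower-centered and eigendecomposed, and the
    unit-norm eigenvectors with positive eigenvalues are retained.
    """
    d = geo.data
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    off = d[np.triu_indices(n, k=1)]
    if np.all(off == 0):
        raise ValueError("all points coincident: PCNM geometry degenerate")
    mst = minimum_spanning_tree(d).toarray()
    t = float(mst.max())
    trunc = np.where(d <= t, d, replacement_factor * t)
    np.fill_diagonal(trunc, 0.0)
    vals, vecs = gower_eig(trunc)
    keep = vals > 1e-9 * vals.max()
    return PcnmBasis(list(geo.ids), vecs[:, keep], vals[keep], t)
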