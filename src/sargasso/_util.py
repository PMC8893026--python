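"""Shared numerical helpers."""

from __future__ import annotations

import numpy as np


def random_permutations(rng: np.random.Generator, n: int, n_perm: int) -> np.ndarray:
    """(n_perm, n) array of independent permutations of range(n)."""
    return rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered matrix −½·C·D²·C with C = I − 11'/n."""
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    return a - row - row.T + a.mean()


def gower_eig(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the Gower-centered matrix, descending eigenvalues."""
    vals, vecs = np.linalg.eigh(gower_center(d))
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]
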