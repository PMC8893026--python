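"""Per-sample α-diversity metrics and the univariate tests applied to them.

Metrics follow the conventions common in 16S survey work: Shannon diversity in
bits (base 2), Heip's evenness E = (e^H − 1)/(S − 1) with H in natural-log
units, and the Chao1 richness estimator with its bias-corrected fallback when
no doubletons are observed.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "observed_otus",
    "shannon",
    "heip_evenness",
    "chao1",
    "alpha_table",
    "kruskal_wallis",
    "spearman",
    "diversity_regression",
]


def _as_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.size and c.min() < 0:
        raise ValueError("counts must be non-negative")
    return c


def observed_otus(counts) -> int:
    """Number of taxa with a positive count (richness S)."""
    c = _as_counts(counts)
    s = int((c > 0).sum())
    if s == 0:
        warnings.warn("all-zero sample: S = 0", stacklevel=2)
    return s


def shannon(counts, base: float = 2.0) -> float:
    """Shannon diversity H' = −Σ p_i log_base p_i over positive counts."""
    c = _as_counts(counts)
    total = c.sum()
    if total == 0:
        raise ValueError("Shannon diversity undefined for an empty sample")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum() / math.log(base))


def heip_evenness(counts=None, *, H: float | None = None, S: int | None = None,
                  base: float = 2.0) -> float:
    """Heip's evenness E = (e^H − 1)/(S − 1), H converted to nats.

    Either pass a count vector, or pass precomputed ``H`` (in ``base`` units,
    bits by default) and ``S`` directly — useful for published summary tables.
    """
    if counts is not None:
        S = observed_otus(counts)
        if S < 2:
            raise ValueError("Heip's evenness requires at least 2 observed taxa")
        H = shannon(counts, base=base)
    if H is None or S is None:
        raise ValueError("provide counts, or both H and S")
    if S < 2:
        raise ValueError("Heip's evenness requires S >= 2")
    h_nats = H * math.log(base)
    return float((math.exp(h_nats) - 1.0) / (S - 1))


def chao1(counts, bias_corrected: bool = False) -> float:
    """Chao1 richness: S + F1²/(2·F2); S + F1(F1−1)/2 when F2 = 0.

    F1 and F2 are singleton and doubleton counts.  ``bias_corrected`` applies
    the small-sample form S + F1(F1+1)/(2(F2+1)) regardless of F2.
    """
    c = np.asarray(counts)
    if not np.issubdtype(c.dtype, np.integer):
        if not np.allclose(c, np.rint(c)):
            raise ValueError("Chao1 requires integer counts")
        c = np.rint(c).astype(int)
    if c.size and c.min() < 0:
        raise ValueError("counts must be non-negative")
    s = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected:
        return s + f1 * (f1 + 1) / (2.0 * (f2 + 1))
    if f2 > 0:
        return s + f1 * f1 / (2.0 * f2)
    return s + f1 * (f1 - 1) / 2.0


def alpha_table(table, base: float = 2.0) -> pd.DataFrame:
    """Per-sample S, Shannon H' (bits), Chao1 and Heip's evenness."""
    rows = []
    for sid, counts in zip(table.sample_ids, table.counts):
        s = int((counts > 0).sum())
        rows.append(
            {
                "sample_id": sid,
                "observed_otus": s,
                "shannon": shannon(counts, base=base) if s else np.nan,
                "chao1": chao1(counts),
                "heip_evenness": heip_evenness(counts) if s >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def kruskal_wallis(values, groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p-value.

    Returns ``(H, df, p)`` with df = number of groups − 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values) & ~pd.isna(groups)
    values, groups = values[ok], groups[ok]
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.ptp(values) == 0:
        # all observations tied: H = 0 by definition, scipy would raise
        return 0.0, len(levels) - 1, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), len(levels) - 1, float(p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation over complete pairs, t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def diversity_regression(
    metric_values,
    covariates: pd.DataFrame,
    transform: str = "square",
) -> pd.DataFrame:
    """OLS of (square-transformed) α-diversity on environmental covariates.

    Rows with any missing value are dropped.  Returns the statsmodels
    coefficient table (coef, std err, t, p) as a DataFrame.
    """
    y = pd.Series(np.asarray(metric_values, dtype=float), index=covariates.index)
    frame = pd.concat([y.rename("_y"), covariates], axis=1).dropna()
    if len(frame) < covariates.shape[1] + 2:
        raise ValueError("too few complete-case rows for the requested model")
    resp = frame["_y"] ** 2 if transform == "square" else frame["_y"]
    X = sm.add_constant(frame.drop(columns="_y"))
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        aliased = [
            c for c in corr.columns
            if (corr.loc[c, corr.columns != c] > 1 - 1e-10).any()
        ]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    fit = sm.OLS(resp, X).fit()
    return pd.DataFrame(
        {"coef": fit.params, "stderr": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )
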