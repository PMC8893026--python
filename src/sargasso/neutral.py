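"""Sloan neutral community model: occurrence frequency vs mean abundance.

The model treats each local community of N individuals as assembled by
neutral birth/death with immigration from a common source pool at probability
m per death.  At stationarity the local relative abundance x of a taxon with
source abundance p follows Beta(N·m·p, N·m·(1−p)), so the chance of detecting
the taxon (x above a detection limit d) is

    F(p) = 1 − I_d(N·m·p, N·m·(1−p)),

with I the regularized incomplete beta function.  The default detection limit
is d = ln(2)/N: a taxon at relative abundance x is missed by N reads with
probability (1 − x)^N ≈ e^{−Nx}, which crosses ½ at x = ln2/N, so thresholding
there matches realized count-based detection with negligible bias (the
alternative convention d = 1/N overestimates m by ~25% on data generated by
the model itself).  m is fitted by least squares
of observed occurrence frequencies on F(p); the R² of that fit measures how
much of the occupancy-abundance relationship neutral dynamics explain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .table import OtuTable

__all__ = [
    "frequency_abundance",
    "predict_frequency",
    "fit_ncm",
    "ncm_by_stratum",
    "NcmFit",
]


def frequency_abundance(table: OtuTable) -> tuple[pd.DataFrame, int]:
    """Per-taxon mean relative abundance and occurrence frequency.

    Returns a DataFrame indexed by OTU id with columns ``p`` (mean over
    samples of within-sample relative abundance) and ``f_obs`` (fraction of
    samples with a positive count), plus N, the (mean) reads per sample.
    Taxa absent from every sample are excluded.  The model assumes uniform
    sample totals (a rarefied table); a spread above 1% triggers a warning.
    """
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    totals = table.sample_totals().astype(float)
    spread = (totals.max() - totals.min()) / totals.mean()
    if spread > 0.01:
        warnings.warn(
            f"sample totals vary by {spread:.1%}; the model assumes a rarefied "
            "table with uniform depth",
            stacklevel=2,
        )
    rel = table.counts / totals[:, None]
    p = rel.mean(axis=0)
    f_obs = (table.counts > 0).mean(axis=0)
    present = p > 0
    df = pd.DataFrame(
        {"p": p[present], "f_obs": f_obs[present]},
        index=[o for o, k in zip(table.otu_ids, present) if k],
    )
    return df, int(round(totals.mean()))


def predict_frequency(p, m: float, N: int, d: float) -> np.ndarray:
    """Neutral prediction of occurrence frequency, 1 − I_d(Nmp, Nm(1−p))."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("relative abundances must lie strictly in (0, 1)")
    if not (0 < m <= 1):
        raise ValueError("migration probability m must be in (0, 1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    if not (0 < d < 1):
        raise ValueError("detection limit d must be in (0, 1)")
    nm = N * m
    return special.betaincc(nm * p, nm * (1.0 - p), d)


@dataclass
class NcmFit:
    m: float
    N: int
    detection_limit: float
    r_squared: float
    sse: float
    n_samples: int
    taxa: pd.DataFrame  # p, f_obs, f_pred, lower, upper, class

    @property
    def Nm(self) -> float:
        return self.m * self.N

    def class_counts(self) -> pd.Series:
        return self.taxa["class"].value_counts()

    def summary(self) -> dict:
        return {
            "m": self.m,
            "Nm": self.Nm,
            "N": self.N,
            "detection_limit": self.detection_limit,
            "r_squared": self.r_squared,
            "n_taxa": len(self.taxa),
            "n_samples": self.n_samples,
            "class_counts": self.class_counts().to_dict(),
        }


def fit_ncm(
    freq_data: pd.DataFrame,
    N: int,
    d: float | None = None,
    n_samples: int | None = None,
) -> NcmFit:
    """Fit the migration parameter m by least squares.

    ``freq_data`` must have columns ``p`` and ``f_obs`` (from
    :func:`frequency_abundance`).  m is found by bounded scalar minimization
    of Σ(F_obs − F_pred)² over (1e−6, 1].  The 95% envelope around the fitted
    curve is the Wilson score interval for a binomial proportion with point
    value F_pred and n = number of samples; taxa are classified below/within/
    above the envelope.
    """
    if d is None:
        d = np.log(2.0) / N
    data = freq_data[(freq_data["p"] > 0) & (freq_data["p"] < 1)]
    if len(data) < 10:
        raise ValueError("need at least 10 taxa with 0 < p < 1")
    p = data["p"].to_numpy()
    f_obs = data["f_obs"].to_numpy()
    sst = float(((f_obs - f_obs.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("observed frequencies are constant; R-squared undefined")

    def sse(m: float) -> float:
        return float(((f_obs - predict_frequency(p, m, N, d)) ** 2).sum())

    res = optimize.minimize_scalar(
        sse, bounds=(1e-6, 1.0), method="bounded",
        options={"xatol": 1e-8},
    )
    m_hat = float(res.x)
    f_pred = predict_frequency(p, m_hat, N, d)
    r2 = 1.0 - res.fun / sst

    if n_samples is None:
        # infer from the granularity of observed frequencies if possible
        n_samples = int(round(1.0 / np.min(f_obs[f_obs > 0])))
    lower, upper = _wilson_interval(f_pred, n_samples)
    cls = np.where(f_obs < lower, "below", np.where(f_obs > upper, "above", "within"))
    taxa = pd.DataFrame(
        {
            "p": p,
            "f_obs": f_obs,
            "f_pred": f_pred,
            "lower": lower,
            "upper": upper,
            "class": cls,
        },
        index=data.index,
    )
    return NcmFit(m_hat, int(N), float(d), float(r2), float(res.fun), n_samples, taxa)


def _wilson_interval(p_hat: np.ndarray, n: int, conf: float = 0.95):
    z = stats.norm.ppf(0.5 + conf / 2.0)
    denom = 1.0 + z ** 2 / n
    center = (p_hat + z ** 2 / (2 * n)) / denom
    half = z * np.sqrt(p_hat * (1 - p_hat) / n + z ** 2 / (4 * n ** 2)) / denom
    return np.clip(center - half, 0, 1), np.clip(center + half, 0, 1)


def ncm_by_stratum(
    table: OtuTable,
    metadata: pd.DataFrame,
    stratum: str = "all",
    d: float | None = None,
) -> NcmFit:
    """Fit the model to all samples or to one depth stratum.

    ``stratum`` is ``"all"`` or a level of the metadata ``depth_category``
    column (e.g. ``"surface"`` or ``"DCM"``).
    """
    if stratum != "all":
        keep = [
            s for s in table.sample_ids
            if metadata.loc[s, "depth_category"] == stratum
        ]
        if not keep:
            raise ValueError(f"no samples in stratum {stratum!r}")
        table = table.select_samples(keep).drop_empty_otus()
    freq, N = frequency_abundance(table)
    return fit_ncm(freq, N, d=d, n_samples=len(table.sample_ids))
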