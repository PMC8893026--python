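"""Synthetic bacterioplankton communities with known assembly processes.

The generator emulates an oceanographic transect: stations spaced along a
latitude gradient, two depth strata (surface and deep chlorophyll maximum), a
temperature field correlated with latitude, and per-sample OTU counts drawn
from a shared source pool under one of three assembly regimes:

* **neutral** — local relative abundances are Dirichlet(N·m·p), the
  stationary distribution of Sloan's neutral model, followed by multinomial
  read sampling; the marginal of each taxon is Beta(Nmp, Nm(1−p)), exactly
  the distribution the downstream model fit assumes;
* **niche** — the source pool is first filtered by a Gaussian response to the
  local environment (temperature), with a mixture weight w sliding from pure
  neutrality (w = 0) to full niche filtering (w = 1);
* **dispersal-limited** — the source pool itself drifts along the transect as
  a log-abundance random walk, producing distance decay of similarity.

A small set of pool taxa can be designated contaminants: they are removed
from the assembly pool, given reads in a simulated negative-control sample,
and spiked into real samples at sub-threshold levels so the contaminant
screen has a ground truth to recover.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .table import OtuTable

__all__ = [
    "SourcePool",
    "NicheTraits",
    "SimConfig",
    "SimulatedDataset",
    "generate_source_pool",
    "simulate_neutral_sample",
    "simulate_niche_sample",
    "generate_metadata",
    "simulate_dataset",
    "simulate_dispersal_limited",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class SourcePool:
    """Source ('metacommunity') relative abundances and their phylogeny."""

    taxon_ids: list[str]
    p: np.ndarray
    tree: TreeNode

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if len(self.taxon_ids) != len(self.p):
            raise ValueError("taxon_ids and p lengths differ")
        if (self.p < 0).any():
            raise ValueError("source abundances must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("source abundances must sum to 1")
        tips = {t.name for t in self.tree.tips()}
        if tips != set(self.taxon_ids):
            raise ValueError("tree tips must equal taxon_ids exactly")


@dataclass
class NicheTraits:
    """Gaussian environmental response per taxon (same units as the driver)."""

    optimum: np.ndarray
    tolerance: np.ndarray

    def __post_init__(self):
        self.optimum = np.asarray(self.optimum, dtype=float)
        self.tolerance = np.asarray(self.tolerance, dtype=float)
        if len(self.optimum) != len(self.tolerance):
            raise ValueError("optimum and tolerance lengths differ")
        if (self.tolerance <= 0).any():
            raise ValueError("tolerances must be positive")


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic transect.

    Defaults emulate the surveyed design: ~20 stations over ~15° of latitude,
    surface + DCM strata (40 samples), 15,468 reads per sample, temperature
    declining ~0.7 °C per degree of latitude with 0.8 °C of local noise.
    """

    n_stations: int = 20
    n_depth_strata: int = 2
    reads_per_sample: int = 15_468
    migration_m: float = 0.1
    niche_weight: float = 0.0
    transect: tuple[float, float, float, float] = (23.5, -76.0, 40.5, -70.0)
    temp_intercept: float = 43.0
    temp_slope: float = -0.7  # °C per degree latitude
    temp_noise_sd: float = 0.8
    dcm_temp_offset: float = -2.5
    region_breaks: Sequence[float] = (28.0, 33.0, 38.0)
    region_labels: Sequence[str] = ("SSS", "NSS", "AC", "NA")
    n_contaminants: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        if not (0 < self.migration_m <= 1):
            raise ValueError("migration_m must be in (0, 1]")
        if not (0 <= self.niche_weight <= 1):
            raise ValueError("niche_weight must be in [0, 1]")
        if self.n_depth_strata not in (1, 2):
            raise ValueError("n_depth_strata must be 1 or 2")


@dataclass
class SimulatedDataset:
    table: OtuTable
    metadata: pd.DataFrame
    tree: TreeNode
    truth: dict
    negative_control: pd.Series | None = None
    pools: np.ndarray | None = field(default=None, repr=False)  # per-sample pools

    def __post_init__(self):
        if list(self.table.sample_ids) != list(self.metadata.index):
            raise ValueError("table and metadata sample ids differ")


# ---------------------------------------------------------------------------
# Source pool
# ---------------------------------------------------------------------------

def _random_bifurcating_newick(names: list[str], rng: np.random.Generator) -> str:
    """Random topology by iterative pairwise joining, exp(1) branch lengths."""
    nodes = [f"{n}:{rng.exponential():.6f}" for n in names]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        merged = f"({a},{b}):{rng.exponential():.6f}"
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    # strip the root branch length
    return nodes[0].rsplit(":", 1)[0] + ";"


def generate_source_pool(
    n_taxa: int, abundance_sd: float = 2.0, seed: int | np.random.Generator = 0
) -> SourcePool:
    """Lognormal rank-abundance source pool with a random bifurcating tree."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if abundance_sd < 0:
        raise ValueError("abundance_sd must be >= 0")
    rng = _rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=abundance_sd, size=n_taxa)
    p = raw / raw.sum()
    names = [f"OTU_{i + 1:04d}" for i in range(n_taxa)]
    tree = TreeNode.read(
        _io.StringIO(_random_bifurcating_newick(names, rng)),
        convert_underscores=False,
    )
    return SourcePool(names, p, tree)


# ---------------------------------------------------------------------------
# Per-sample assembly
# ---------------------------------------------------------------------------

def _dirichlet(alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # gamma(shape=0) is identically 0, so zero-mass taxa stay at zero
    g = rng.gamma(alpha)
    total = g.sum()
    if total == 0:
        raise ValueError("degenerate pool: all concentrations zero")
    return g / total


def simulate_neutral_sample(
    pool: SourcePool | np.ndarray,
    Nm: float,
    reads: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One neutral community: Dirichlet(Nm·p) abundances, multinomial reads.

    The marginal relative abundance of taxon i is Beta(Nm·p_i, Nm·(1−p_i)),
    matching the stationary distribution assumed by the fitted neutral model.
    """
    p = pool.p if isinstance(pool, SourcePool) else np.asarray(pool, dtype=float)
    if np.any(~np.isfinite(p)):
        raise ValueError("source abundances must be finite")
    if Nm <= 0:
        raise ValueError("Nm must be positive")
    if reads < 1:
        raise ValueError("reads must be >= 1")
    rng = _rng(seed)
    x = _dirichlet(Nm * p, rng)
    return rng.multinomial(reads, x)


def simulate_niche_sample(
    pool: SourcePool,
    traits: NicheTraits,
    env_value: float,
    w: float,
    Nm: float,
    reads: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Neutral sampling from a Gaussian-niche-filtered source pool.

    The effective pool is q_i ∝ p_i·exp(−w·(env − opt_i)²/(2·tol_i²)); w = 0
    recovers pure neutrality, w = 1 applies the full filter.
    """
    if not (0 <= w <= 1):
        raise ValueError("niche weight w must be in [0, 1]")
    z = (env_value - traits.optimum) / traits.tolerance
    q = pool.p * np.exp(-w * z ** 2 / 2.0)
    total = q.sum()
    if total == 0:
        raise ValueError("degenerate pool: all taxa filtered out")
    return simulate_neutral_sample(q / total, Nm, reads, seed)


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def generate_metadata(config: SimConfig) -> pd.DataFrame:
    """Per-sample metadata for the synthetic transect.

    Stations are spaced evenly between the transect endpoints; temperature is
    a linear function of latitude plus Gaussian noise (with a fixed offset at
    the DCM); regions are assigned by latitude break-points.
    """
    rng = np.random.default_rng(config.seed)
    lat0, lon0, lat1, lon1 = config.transect
    lats = np.linspace(lat0, lat1, config.n_stations)
    lons = np.linspace(lon0, lon1, config.n_stations)
    strata = ["surface", "DCM"][: config.n_depth_strata]
    breaks = np.asarray(config.region_breaks)
    rows = []
    start = pd.Timestamp("2018-04-21")
    for s, (lat, lon) in enumerate(zip(lats, lons)):
        region = config.region_labels[int(np.searchsorted(breaks, lat))]
        surface_temp = (
            config.temp_intercept
            + config.temp_slope * lat
            + rng.normal(0.0, config.temp_noise_sd)
        )
        for depth_cat in strata:
            is_dcm = depth_cat == "DCM"
            temp = surface_temp + (config.dcm_temp_offset if is_dcm else 0.0)
            rows.append(
                {
                    "sample_id": f"ST{s + 1:02d}-{'DCM' if is_dcm else 'SRF'}",
                    "station": f"ST{s + 1:02d}",
                    "region": region,
                    "depth_category": depth_cat,
                    "latitude": lat,
                    "longitude": lon,
                    "depth_m": float(rng.normal(100, 25)) if is_dcm else 0.0,
                    "temperature": temp,
                    "salinity": 36.5 - 0.05 * abs(lat - lats.mean())
                    + rng.normal(0, 0.1),
                    "nitrate": max(0.0, rng.normal(0.5, 0.3)) if is_dcm
                    else max(0.0, rng.normal(0.02, 0.03)),
                    "chla": max(0.005, rng.normal(0.22, 0.06)) if is_dcm
                    else max(0.005, rng.normal(0.05, 0.03)),
                    "sargassum_density": 0.0 if is_dcm
                    else float(rng.lognormal(-2.5, 0.6)),
                    "date": (start + pd.Timedelta(days=int(s * 27 / max(config.n_stations - 1, 1)))).date().isoformat(),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Whole datasets
# ---------------------------------------------------------------------------

def _contaminant_setup(pool: SourcePool, n_contaminants: int, rng):
    """Zero designated contaminant taxa out of the assembly pool."""
    p = pool.p.copy()
    contam_idx = np.arange(len(p) - n_contaminants, len(p))
    p[contam_idx] = 0.0
    p /= p.sum()
    neg_counts = np.zeros(len(p), dtype=np.int64)
    neg_counts[contam_idx] = rng.integers(20, 80, size=n_contaminants)
    return p, contam_idx, neg_counts


def simulate_dataset(
    config: SimConfig,
    pool: SourcePool,
    traits: NicheTraits | None = None,
) -> SimulatedDataset:
    """Assemble one table: a count vector per metadata row, using that row's
    temperature as the environmental driver when niche filtering is active."""
    if config.niche_weight > 0 and traits is None:
        raise ValueError("niche_weight > 0 requires NicheTraits")
    if traits is not None and len(traits.optimum) != len(pool.p):
        raise ValueError("traits and pool dimensions differ")
    rng = np.random.default_rng(config.seed)
    metadata = generate_metadata(config)
    Nm = config.migration_m * config.reads_per_sample

    base_p = pool.p
    negctrl = None
    contam_idx = np.empty(0, dtype=int)
    if config.n_contaminants > 0:
        base_p, contam_idx, neg_counts = _contaminant_setup(
            pool, config.n_contaminants, rng
        )
        negctrl = pd.Series(neg_counts, index=pool.taxon_ids)

    counts = np.empty((len(metadata), len(pool.p)), dtype=np.int64)
    pools = np.empty_like(counts, dtype=float)
    for i, (_, row) in enumerate(metadata.iterrows()):
        if config.niche_weight > 0:
            z = (row["temperature"] - traits.optimum) / traits.tolerance
            q = base_p * np.exp(-config.niche_weight * z ** 2 / 2.0)
            q = q / q.sum()
        else:
            q = base_p
        pools[i] = q
        counts[i] = simulate_neutral_sample(q, Nm, config.reads_per_sample, rng)
    if config.n_contaminants > 0:
        # spike each contaminant below the 10x screen threshold
        for j, c in zip(contam_idx, negctrl.iloc[contam_idx]):
            counts[:, j] = rng.integers(0, max(1, int(10 * c * 0.8)), size=len(metadata))
    table = OtuTable(counts, list(metadata.index), pool.taxon_ids)
    truth = {
        "config": {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in vars(config).items()
        },
        "Nm": Nm,
        "contaminant_ids": [pool.taxon_ids[j] for j in contam_idx],
        "regime": "niche" if config.niche_weight > 0 else "neutral",
    }
    return SimulatedDataset(table, metadata, pool.tree, truth, negctrl, pools)


def simulate_dispersal_limited(
    config: SimConfig,
    pool: SourcePool,
    drift_sd: float = 0.4,
) -> SimulatedDataset:
    """Neutral assembly from a source pool that drifts along the transect.

    Per-station pools follow a log-abundance Gaussian random walk (step
    ``drift_sd`` per station); both depth strata at a station share its pool.
    Nearby stations therefore draw from similar pools, producing dispersal-
    limited spatial structure (distance decay) without any environmental
    filtering.
    """
    rng = np.random.default_rng(config.seed)
    metadata = generate_metadata(config)
    Nm = config.migration_m * config.reads_per_sample
    logp = np.log(np.where(pool.p > 0, pool.p, 1e-300))
    steps = rng.normal(0.0, drift_sd, size=(config.n_stations, len(pool.p)))
    walk = np.cumsum(steps, axis=0)
    station_pools = np.exp(logp[None, :] + walk)
    station_pools[:, pool.p == 0] = 0.0
    station_pools /= station_pools.sum(axis=1, keepdims=True)

    counts = np.empty((len(metadata), len(pool.p)), dtype=np.int64)
    pools = np.empty_like(counts, dtype=float)
    stations = {st: k for k, st in enumerate(dict.fromkeys(metadata["station"]))}
    for i, (_, row) in enumerate(metadata.iterrows()):
        q = station_pools[stations[row["station"]]]
        pools[i] = q
        counts[i] = simulate_neutral_sample(q, Nm, config.reads_per_sample, rng)
    table = OtuTable(counts, list(metadata.index), pool.taxon_ids)
    truth = {
        "config": {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in vars(config).items()
        },
        "Nm": Nm,
        "drift_sd": drift_sd,
        "regime": "dispersal_limited",
    }
    return SimulatedDataset(table, metadata, pool.tree, truth, None, pools)
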