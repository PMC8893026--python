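"""OTU count tables: containers, I/O, contaminant screening, rarefaction and summaries.

The :class:`OtuTable` is the single currency passed between pipeline stages: a
samples × OTUs matrix of non-negative integer read counts with unique sample and
OTU identifiers.  Two on-disk representations are supported:

* a tab-separated matrix with OTU ids in the first column and sample ids in the
  header row (the layout most OTU-picking tools emit), and
* BIOM v1 (JSON).  BIOM v2 (HDF5) is intentionally unsupported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "read_table",
    "write_table",
    "remove_contaminants",
    "rarefy",
    "shared_unique_counts",
    "group_relative_abundance",
    "OtuOverlap",
    "ContaminantReport",
]


class OtuTable:
    """Samples × OTUs matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        2-D array-like, shape (n_samples, n_otus).  Must be integral and >= 0.
    sample_ids, otu_ids
        Unique identifiers for rows and columns respectively.
    """

    def __init__(self, counts, sample_ids, otu_ids):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples x OTUs matrix")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValueError("counts must be integral")
            counts = rounded.astype(np.int64)
        counts = counts.astype(np.int64, copy=False)
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        sample_ids = [str(s) for s in sample_ids]
        otu_ids = [str(o) for o in otu_ids]
        if len(sample_ids) == 0:
            raise ValueError("table must contain at least one sample")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(otu_ids)) != len(otu_ids):
            raise ValueError("duplicate OTU ids")
        if counts.shape != (len(sample_ids), len(otu_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"({len(sample_ids)} samples, {len(otu_ids)} OTUs)"
            )
        self.counts = counts
        self.sample_ids = list(sample_ids)
        self.otu_ids = list(otu_ids)

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances (rows sum to 1)."""
        totals = self.sample_totals().astype(float)
        if (totals == 0).any():
            bad = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            raise ValueError(f"samples with zero total counts: {bad}")
        return self.counts / totals[:, None]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def select_samples(self, sample_ids) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(self.counts[idx], list(sample_ids), self.otu_ids)

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.sum(axis=0) > 0
        return OtuTable(
            self.counts[:, keep],
            self.sample_ids,
            [o for o, k in zip(self.otu_ids, keep) if k],
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OtuTable)
            and self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"OtuTable({self.shape[0]} samples x {self.shape[1]} OTUs)"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_table(path, format: str = "tsv") -> OtuTable:
    """Read an :class:`OtuTable` from ``tsv`` or ``biom-json``."""
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ValueError(f"could not parse TSV OTU table {path}: {exc}") from exc
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError(f"{path}: empty OTU table")
        bad = df.columns[~df.map(lambda v: float(v) == int(v)).all(axis=0)]
        if len(bad):
            raise ValueError(f"{path}: non-integer counts in samples {list(bad)}")
        # file layout is OTUs x samples
        return OtuTable.from_dataframe(df.T)
    if format == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        return _from_biom_v1(doc)
    raise ValueError(f"unknown table format: {format!r}")


def write_table(table: OtuTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        df = table.to_dataframe().T
        df.index.name = "#OTU ID"
        df.to_csv(path, sep="\t")
    elif format == "biom-json":
        with open(path, "w") as fh:
            json.dump(_to_biom_v1(table), fh)
    else:
        raise ValueError(f"unknown table format: {format!r}")


def _to_biom_v1(table: OtuTable) -> dict:
    # BIOM rows are observations (OTUs), columns are samples.
    rows, cols = np.nonzero(table.counts.T)
    data = [[int(r), int(c), int(table.counts.T[r, c])] for r, c in zip(rows, cols)]
    return {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "sargasso",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [len(table.otu_ids), len(table.sample_ids)],
        "rows": [{"id": o, "metadata": None} for o in table.otu_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }


def _from_biom_v1(doc: dict) -> OtuTable:
    try:
        n_obs, n_samp = doc["shape"]
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        mat = np.zeros((n_obs, n_samp))
        if doc["matrix_type"] == "sparse":
            for r, c, v in doc["data"]:
                mat[r, c] = v
        elif doc["matrix_type"] == "dense":
            mat = np.asarray(doc["data"], dtype=float)
        else:
            raise ValueError(f"unknown BIOM matrix_type {doc['matrix_type']!r}")
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed BIOM v1 document: missing {exc}") from exc
    return OtuTable(mat.T, sample_ids, otu_ids)


# ---------------------------------------------------------------------------
# Contaminant screening
# ---------------------------------------------------------------------------

@dataclass
class ContaminantReport:
    """Per-OTU record of the negative-control screen."""

    removed: pd.DataFrame  # columns: otu_id, negctrl_count, max_sample_count

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def remove_contaminants(
    table: OtuTable,
    negctrl: Mapping[str, int] | pd.Series,
    factor: float = 10.0,
) -> tuple[OtuTable, ContaminantReport]:
    """Drop OTUs attributable to reagent/handling contamination.

    An OTU observed in the negative control (count ``c > 0``) is treated as a
    contaminant when no real sample reaches ``factor * c`` reads, i.e. when
    ``max_s count[s] < factor * c``.  OTUs absent from the negative control are
    never removed.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    neg = pd.Series(negctrl).reindex(table.otu_ids).fillna(0).to_numpy(dtype=float)
    max_counts = table.counts.max(axis=0)
    contaminant = (neg > 0) & (max_counts < factor * neg)
    removed = pd.DataFrame(
        {
            "otu_id": [o for o, f in zip(table.otu_ids, contaminant) if f],
            "negctrl_count": neg[contaminant].astype(int),
            "max_sample_count": max_counts[contaminant],
        }
    )
    keep = ~contaminant
    filtered = OtuTable(
        table.counts[:, keep],
        table.sample_ids,
        [o for o, k in zip(table.otu_ids, keep) if k],
    )
    return filtered, ContaminantReport(removed)


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int, seed: int | None = None) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning; if all
    samples fall below ``depth`` a :class:`ValueError` is raised.  Subsampling
    is hypergeometric (without replacement), so a sample already at ``depth``
    is returned unchanged.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below rarefaction depth {depth}: "
            f"{dropped}",
            stacklevel=2,
        )
    out = np.empty((int(keep.sum()), len(table.otu_ids)), dtype=np.int64)
    row = 0
    for i, k in enumerate(keep):
        if not k:
            continue
        counts = table.counts[i]
        if totals[i] == depth:
            out[row] = counts
        else:
            out[row] = rng.multivariate_hypergeometric(counts, depth)
        row += 1
    return OtuTable(out, [s for s, k in zip(table.sample_ids, keep) if k], table.otu_ids)


# ---------------------------------------------------------------------------
# Presence/absence overlap and group summaries
# ---------------------------------------------------------------------------

@dataclass
class OtuOverlap:
    """Venn-style decomposition of OTU presence across sample categories.

    ``lattice`` maps each non-empty subset of categories to the number of OTUs
    present in exactly those categories; the cells partition the observed OTUs.
    """

    categories: list[str]
    lattice: dict[frozenset, int]
    unique: dict[str, int]
    shared_all: int

    @property
    def n_observed(self) -> int:
        return sum(self.lattice.values())


def shared_unique_counts(table: OtuTable, groups: Mapping[str, str]) -> OtuOverlap:
    """Count OTUs unique to and shared among sample categories.

    An OTU belongs to a category iff any sample of that category has a
    positive count.
    """
    groups = pd.Series(groups).reindex(table.sample_ids)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])
        raise ValueError(f"samples without a category: {missing}")
    cats = sorted(groups.unique())
    if len(cats) < 2:
        raise ValueError("need at least 2 categories")
    presence = {}
    for cat in cats:
        rows = np.asarray(groups == cat)
        if not rows.any():
            raise ValueError(f"category {cat!r} has no samples")
        presence[cat] = table.counts[rows].sum(axis=0) > 0
    lattice: dict[frozenset, int] = {}
    for r in range(1, len(cats) + 1):
        for subset in combinations(cats, r):
            inside = np.logical_and.reduce([presence[c] for c in subset])
            outside = np.logical_or.reduce(
                [presence[c] for c in cats if c not in subset] or [np.zeros(len(table.otu_ids), bool)]
            )
            lattice[frozenset(subset)] = int((inside & ~outside).sum())
    unique = {c: lattice[frozenset([c])] for c in cats}
    return OtuOverlap(cats, lattice, unique, lattice[frozenset(cats)])


def group_relative_abundance(
    table: OtuTable,
    groups: Mapping[str, str],
    level_map: Mapping[str, str] | None = None,
    min_frac: float = 0.0,
) -> pd.DataFrame:
    """Mean relative abundance per taxon label within each sample group.

    ``level_map`` collapses OTU ids to coarser labels (e.g. family) before
    averaging; labels whose mean abundance is below ``min_frac`` in every
    group are suppressed, so the retained columns need not sum to 1.
    """
    if not (0 <= min_frac < 1):
        raise ValueError("min_frac must be in [0, 1)")
    groups = pd.Series(groups).reindex(table.sample_ids)
    rel = pd.DataFrame(
        table.relative_abundance(), index=table.sample_ids, columns=table.otu_ids
    )
    if level_map is not None:
        labels = [level_map.get(o, o) for o in table.otu_ids]
        rel = rel.T.groupby(labels).sum().T
    means = rel.groupby(groups).mean().T  # labels x groups
    keep = (means >= min_frac).any(axis=1) if min_frac > 0 else means.index
    return means.loc[keep]
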