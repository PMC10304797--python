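"""Tabular and graph I/O, plus the two count-preprocessing steps.

The central container is :class:`OtuTable`, an integer count matrix with
samples as rows and OTUs as columns (the regression-design orientation used
throughout the package).  Preprocessing follows the usual amplicon workflow:
drop rare OTUs by total count, then rarefy every sample to a common depth by
subsampling reads without replacement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import DataError

__all__ = [
    "OtuTable",
    "PhenotypeVector",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "read_phenotype",
    "filter_rare_otus",
    "rarefy_counts",
    "write_graph",
    "read_graphml",
]

DEFAULT_MIN_TOTAL = 10
DEFAULT_RAREFACTION_DEPTH = 6698


@dataclass(frozen=True)
class OtuTable:
    """Non-negative integer count matrix, samples x OTUs.

    Parameters
    ----------
    data:
        DataFrame whose index holds unique sample ids and whose columns hold
        unique OTU ids.  Values must be non-negative integers.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate OTU ids: {dups}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise DataError("counts must be numeric")
        if arr.size and (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise DataError(
                f"negative count at sample {df.index[r]!r}, OTU {df.columns[c]!r}"
            )
        if arr.size and not np.allclose(arr, np.round(arr)):
            frac = np.abs(arr - np.round(arr))
            r, c = np.argwhere(frac > 1e-9)[0]
            raise DataError(
                f"non-integer count at sample {df.index[r]!r}, OTU {df.columns[c]!r}"
            )
        object.__setattr__(self, "data", df.astype(np.int64))

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def otu_ids(self) -> list[str]:
        return [str(o) for o in self.data.columns]

    @property
    def counts(self) -> np.ndarray:
        """Counts as an (n_samples, n_otus) int array."""
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def otu_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised proportions; all-zero rows stay zero."""
        sums = self.data.sum(axis=1).to_numpy(dtype=float)
        sums[sums == 0] = 1.0
        return self.data.div(sums, axis=0)


@dataclass(frozen=True)
class PhenotypeVector:
    """Per-sample numeric phenotype (e.g. marketable yield) with a unit label."""

    values: pd.Series
    units: str = ""

    def __post_init__(self) -> None:
        vals = self.values.astype(float)
        if not np.isfinite(vals.to_numpy()).all():
            raise DataError("phenotype contains non-finite values")
        if vals.index.has_duplicates:
            raise DataError("duplicate sample ids in phenotype vector")
        object.__setattr__(self, "values", vals)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    def aligned_to(self, table: OtuTable) -> pd.Series:
        """Phenotype values reindexed to the table's samples.

        Every phenotype sample must exist in the table; samples lacking a
        phenotype are dropped from the returned series.
        """
        missing = set(self.values.index) - set(table.data.index)
        if missing:
            raise DataError(f"phenotype samples absent from OTU table: {sorted(missing)}")
        keep = [s for s in table.data.index if s in self.values.index]
        return self.values.loc[keep]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path, format: str = "tsv") -> OtuTable:
    """Read an OTU count table from TSV or BIOM-JSON.

    TSV layout: header row of OTU ids, first column sample ids.  BIOM-JSON
    stores OTUs as rows ("observations") and samples as columns; the matrix is
    transposed on read so samples are rows.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        for col in df.columns:
            if not pd.api.types.is_numeric_dtype(df[col]):
                bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
                sample = bad.index[0] if len(bad) else "?"
                raise DataError(
                    f"non-numeric count at sample {sample!r}, OTU {col!r}"
                )
        return OtuTable(df)
    if format == "biom-json":
        return _read_biom_json(path)
    raise DataError(f"unknown OTU-table format: {format!r}")


def _read_biom_json(path: Path) -> OtuTable:
    # BIOM 1.0 JSON: rows are observations (OTUs), columns are samples.
    with open(path) as fh:
        doc = json.load(fh)
    try:
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        n_otus, n_samples = doc["shape"]
        dense = np.zeros((n_otus, n_samples), dtype=float)
        if doc.get("matrix_type") == "dense":
            dense[:] = np.asarray(doc["data"], dtype=float)
        else:  # sparse [row, col, value] triplets
            for r, c, v in doc["data"]:
                dense[int(r), int(c)] = v
    except (KeyError, TypeError, ValueError) as exc:
        raise DataError(f"malformed BIOM-JSON file {path}: {exc}") from exc
    df = pd.DataFrame(dense.T, index=sample_ids, columns=otu_ids)
    return OtuTable(df)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV (first column sample id, factors as columns)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise DataError("duplicate sample ids in metadata")
    return df


def read_phenotype(path: str | Path, column: str | None = None,
                   units: str = "") -> PhenotypeVector:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if column is None:
        column = df.columns[0]
    if column not in df.columns:
        raise DataError(f"phenotype column {column!r} not in {list(df.columns)}")
    return PhenotypeVector(df[column], units=units)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def filter_rare_otus(table: OtuTable, min_total: int = DEFAULT_MIN_TOTAL) -> OtuTable:
    """Drop OTUs whose total count across all samples is below ``min_total``.

    Rare OTUs (conventionally < 10 reads community-wide) contribute mostly
    sequencing noise and inflate the zero fraction the compositional model
    must absorb.
    """
    if min_total < 0:
        raise DataError("min_total must be >= 0")
    totals = table.otu_sums()
    keep = totals[totals >= min_total].index
    if len(keep) == 0:
        raise DataError(
            f"min_total={min_total} removed every OTU; lower the threshold"
        )
    return OtuTable(table.data[keep])


def rarefy_counts(table: OtuTable, depth: int = DEFAULT_RAREFACTION_DEPTH,
                  seed: int | np.random.Generator = 0) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Each row is drawn from a multivariate hypergeometric distribution on its
    own counts, the convention of mothur/vegan rarefaction.  Rows already at
    exactly ``depth`` are returned unchanged.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sums = table.sample_sums()
    short = sums[sums < depth]
    if len(short):
        raise DataError(
            f"rarefaction depth {depth} exceeds the total count of samples: "
            f"{dict(short)}"
        )
    out = np.empty_like(table.counts)
    for i, row in enumerate(table.counts):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(pd.DataFrame(out, index=table.data.index, columns=table.data.columns))


# ---------------------------------------------------------------------------
# Graph export
# ---------------------------------------------------------------------------

EDGE_LIST_COLUMNS = ["source", "target", "weight", "sign", "edge_kind"]


def write_graph(graph: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a PhONA graph as GraphML or an edge-list TSV.

    Edge-list columns: source, target, weight, sign,
    edge_kind (otu-otu | otu-phenotype).  Node attributes (taxonomy, module,
    role) survive only in GraphML.
    """
    path = Path(path)
    if format == "graphml":
        g = graph.copy()
        for _, _, d in g.edges(data=True):
            d.setdefault("weight", 1.0)
        nx.write_graphml(g, path, named_key_ids=True)
    elif format == "edge-list-tsv":
        rows = [
            {
                "source": u,
                "target": v,
                "weight": d.get("weight", 1.0),
                "sign": d.get("sign", "positive"),
                "edge_kind": d.get("edge_kind", "otu-otu"),
            }
            for u, v, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=EDGE_LIST_COLUMNS).to_csv(path, sep="\t", index=False)
    else:
        raise DataError(f"unknown graph format: {format!r}")


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(Path(path))
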