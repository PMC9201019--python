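"""Data model and CSV I/O for wide-format metabolite concentration tables.

A table holds one column per GC-MS run (an "independent analysis" or
replicate) and one row per metabolite.  Every sample column is annotated
with its *origin* (geographic source), *region* (an independent sample of
that origin) and a 1-based replicate index.  Regions nest inside origins:
one region never spans two origins.

On-disk layout (see :func:`read_table`)::

    #scale=raw
    metabolite,Manado|M1|1,Manado|M1|2,...
    glucose,0.0021,0.0019,...

The first column carries metabolite identifiers; every other header cell is
``origin|region|replicate``.  An optional leading comment line records
whether values are raw concentrations or log-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataFormatError, DomainError, MetadataError

__all__ = [
    "MetaboliteTable",
    "RegionBlock",
    "ReducedDataset",
    "read_table",
    "write_table",
    "split_regions",
]

REDUCER_TAGS = ("mwa", "pca", "cmds", "le", "lle", "median", "mean")


@dataclass
class MetaboliteTable:
    """A metabolites x samples concentration matrix with sample metadata.

    Parameters
    ----------
    values : ndarray of shape (d_metabolites, n_samples)
        Concentrations (raw scale) or log-concentrations (log scale).
    metabolite_ids : list of str
        Unique row identifiers, length ``d``.
    sample_meta : DataFrame with columns ``origin``, ``region``, ``replicate``
        One row per sample column, in column order.
    scale : {"raw", "log"}
        Raw tables must be entrywise non-negative.
    """

    values: np.ndarray
    metabolite_ids: list[str]
    sample_meta: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.metabolite_ids = [str(m) for m in self.metabolite_ids]
        self.validate()

    # -- contract checks -------------------------------------------------
    def validate(self) -> None:
        if self.values.ndim != 2:
            raise DataFormatError("values must be a 2-D matrix")
        d, n = self.values.shape
        if len(self.metabolite_ids) != d:
            raise DataFormatError(
                f"{len(self.metabolite_ids)} metabolite ids for {d} rows"
            )
        if len(set(self.metabolite_ids)) != d:
            raise MetadataError("duplicate metabolite ids")
        required = {"origin", "region", "replicate"}
        if not required.issubset(self.sample_meta.columns):
            raise MetadataError(f"sample_meta needs columns {sorted(required)}")
        if len(self.sample_meta) != n:
            raise DataFormatError(
                f"{len(self.sample_meta)} metadata rows for {n} sample columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise DomainError("table contains missing or non-finite entries")
        if self.scale not in ("raw", "log"):
            raise DataFormatError(f"unknown scale {self.scale!r}")
        if self.scale == "raw" and np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise DomainError(
                f"negative concentration at metabolite {self.metabolite_ids[i]!r},"
                f" sample column {j}"
            )
        reps = self.sample_meta["replicate"].to_numpy()
        if np.any(reps < 1) or not np.issubdtype(reps.dtype, np.integer):
            raise MetadataError("replicate indices must be positive integers")
        # regions nest in origins
        origins_per_region = self.sample_meta.groupby("region")["origin"].nunique()
        bad = origins_per_region[origins_per_region > 1]
        if len(bad):
            raise MetadataError(
                f"region(s) {list(bad.index)} span more than one origin"
            )
        dup = self.sample_meta.duplicated(subset=["region", "replicate"])
        if dup.any():
            raise MetadataError("duplicate (region, replicate) sample labels")

    # -- conveniences -----------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def regions(self) -> list[str]:
        """Distinct region labels in sorted order."""
        return sorted(self.sample_meta["region"].unique())

    def sample_labels(self) -> list[str]:
        return [
            f"{r.origin}|{r.region}|{r.replicate}"
            for r in self.sample_meta.itertuples()
        ]

    def copy(self) -> "MetaboliteTable":
        return MetaboliteTable(
            self.values.copy(),
            list(self.metabolite_ids),
            self.sample_meta.copy(),
            self.scale,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.metabolite_ids, columns=self.sample_labels()
        )

    def equals(self, other: "MetaboliteTable", atol: float = 1e-12) -> bool:
        return (
            self.scale == other.scale
            and self.metabolite_ids == other.metabolite_ids
            and self.sample_labels() == other.sample_labels()
            and np.allclose(self.values, other.values, atol=atol, rtol=0.0)
        )


@dataclass
class RegionBlock:
    """One region's replicate vectors as columns of a d x n_rep matrix."""

    values: np.ndarray
    region: str
    origin: str
    scale: str = "raw"
    replicates: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise DataFormatError("region block must be a non-empty d x n_rep matrix")
        if not self.replicates:
            self.replicates = list(range(1, self.values.shape[1] + 1))

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[0]


@dataclass
class ReducedDataset:
    """Regions x metabolites matrix of representatives (one row per region)."""

    Z: np.ndarray
    region_labels: list[str]
    origin_labels: list[str]
    method: str
    metabolite_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2:
            raise DataFormatError("Z must be 2-D (regions x metabolites)")
        if len(self.region_labels) != self.Z.shape[0]:
            raise DataFormatError("one row per region label required")
        if len(self.origin_labels) != self.Z.shape[0]:
            raise DataFormatError("one origin label per region required")
        if self.method not in REDUCER_TAGS:
            raise DataFormatError(f"unknown reduction method tag {self.method!r}")
        if not self.metabolite_ids:
            self.metabolite_ids = [f"m{i + 1}" for i in range(self.Z.shape[1])]

    @property
    def n_regions(self) -> int:
        return self.Z.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Z, columns=self.metabolite_ids)
        df.insert(0, "origin", self.origin_labels)
        df.insert(0, "region", self.region_labels)
        return df


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def _parse_sample_header(cell: str) -> tuple[str, str, int]:
    parts = cell.split("|")
    if len(parts) != 3:
        raise DataFormatError(
            f"malformed sample header {cell!r}: expected 'origin|region|replicate'"
        )
    origin, region, rep = (p.strip() for p in parts)
    if not origin or not region:
        raise DataFormatError(f"malformed sample header {cell!r}: empty field")
    try:
        rep_i = int(rep)
    except ValueError as exc:
        raise DataFormatError(
            f"malformed sample header {cell!r}: replicate {rep!r} is not an integer"
        ) from exc
    if rep_i < 1:
        raise DataFormatError(
            f"malformed sample header {cell!r}: replicate index must be >= 1"
        )
    return origin, region, rep_i


def read_table(path: str | Path, sep: str = ",") -> MetaboliteTable:
    """Read a wide metabolite CSV/TSV into a validated :class:`MetaboliteTable`.

    The first column must be named ``metabolite``; every other header cell is
    ``origin|region|replicate``.  An optional first line ``#scale=raw|log``
    sets the scale flag (default ``raw``).  Column order is preserved.
    """
    path = Path(path)
    scale = "raw"
    skiprows = 0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        skiprows = 1
        token = first.strip().lstrip("#").strip()
        if token.startswith("scale="):
            scale = token.split("=", 1)[1]
        else:
            raise DataFormatError(f"unrecognised comment line {first.strip()!r}")
    df = pd.read_csv(
        path, sep=sep, skiprows=skiprows, dtype={0: str},
        float_precision="round_trip",
    )
    if df.shape[1] < 2:
        raise DataFormatError("table needs a metabolite column and >=1 sample column")
    if df.columns[0] != "metabolite":
        raise DataFormatError(
            f"first column must be 'metabolite', got {df.columns[0]!r}"
        )
    meta_rows = [_parse_sample_header(c) for c in df.columns[1:]]
    sample_meta = pd.DataFrame(meta_rows, columns=["origin", "region", "replicate"])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return MetaboliteTable(values, list(df.iloc[:, 0]), sample_meta, scale=scale)


def write_table(table: MetaboliteTable, path: str | Path, sep: str = ",") -> None:
    """Write a table so that :func:`read_table` reproduces it exactly.

    Values are rendered with ``repr``-level precision (17 significant digits),
    so the decimal round-trip is bit-identical for doubles.
    """
    if table.n_metabolites == 0:
        raise DataFormatError("refusing to write a table with zero metabolites")
    table.validate()
    path = Path(path)
    df = table.to_frame()
    df.index.name = "metabolite"
    with open(path, "w") as fh:
        fh.write(f"#scale={table.scale}\n")
        df.to_csv(fh, sep=sep, float_format="%.17g")


def split_regions(table: MetaboliteTable) -> list[RegionBlock]:
    """Split a table into one :class:`RegionBlock` per distinct region.

    Blocks are ordered by sorted region label; within a block, columns are
    ordered by ascending replicate index.  Concatenating the blocks recovers
    every sample exactly once.
    """
    blocks: list[RegionBlock] = []
    for region in table.regions():
        mask = table.sample_meta["region"] == region
        sub = table.sample_meta[mask].sort_values("replicate")
        cols = sub.index.to_numpy()
        blocks.append(
            RegionBlock(
                values=table.values[:, cols],
                region=region,
                origin=sub["origin"].iloc[0],
                scale=table.scale,
                replicates=[int(r) for r in sub["replicate"]],
            )
        )
    return blocks


def write_reduced(ds: ReducedDataset, path: str | Path, sep: str = ",") -> None:
    """Write a reduced (regions x metabolites) dataset with a method tag."""
    with open(path, "w") as fh:
        fh.write(f"#method={ds.method}\n")
        ds.to_frame().to_csv(fh, sep=sep, index=False, float_format="%.17g")


def read_reduced(path: str | Path, sep: str = ",") -> ReducedDataset:
    """Read a reduced dataset written by :func:`write_reduced`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#method="):
        raise DataFormatError("reduced CSV must start with '#method=<tag>'")
    method = first.strip().split("=", 1)[1]
    df = pd.read_csv(path, sep=sep, skiprows=1, float_precision="round_trip")
    if list(df.columns[:2]) != ["region", "origin"]:
        raise DataFormatError("reduced CSV must start with region,origin columns")
    return ReducedDataset(
        Z=df.iloc[:, 2:].to_numpy(dtype=float),
        region_labels=[str(r) for r in df["region"]],
        origin_labels=[str(o) for o in df["origin"]],
        method=method,
        metabolite_ids=[str(c) for c in df.columns[2:]],
    )
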