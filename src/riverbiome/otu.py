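"""OTU count tables, sample metadata, filtering and normalization.

The OTU table — a non-negative integer matrix of operational taxonomic
units (rows) by samples (columns), optionally annotated with a ranked
taxonomy lineage per OTU — is the universal currency of the pipeline.
This module provides the validated in-memory container, readers/writers
for the classic tab-separated dialect, and the abundance-based filtering
rules applied before every downstream statistic:

* exclusion of singletons and doubletons (OTUs with a table-wide total
  of one or two reads), which are indistinguishable from sequencing
  artifacts;
* exclusion of OTUs whose overall relative abundance falls below a
  configurable threshold (default 0.01%);
* rarefaction-style subsampling of every sample to a common depth, drawn
  without replacement (multivariate hypergeometric).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HABITATS",
    "SEASONS",
    "LANDFORMS",
    "OtuTableFormatError",
    "OtuTable",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "filter_otus",
    "relative_abundance",
    "subsample_to_depth",
    "occupancy",
]

HABITATS = ("water", "sediment")
SEASONS = ("spring", "autumn")
#: Landform classes in downstream order along the mainstem.
LANDFORMS = ("mountain", "foothill", "basin", "foothill-mountain", "plain")

METADATA_COLUMNS = (
    "sample_id",
    "station_id",
    "habitat",
    "season",
    "landform",
    "river_position_km",
)


class OtuTableFormatError(ValueError):
    """Raised when an OTU table or metadata file violates the format contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise OtuTableFormatError(f"duplicate {what} {x!r}")
        seen.add(x)


@dataclasses.dataclass
class OtuTable:
    """Integer count matrix of OTUs (rows) by samples (columns).

    Parameters
    ----------
    otu_ids : list of str
        Unique OTU identifiers, one per row of ``counts``.
    sample_ids : list of str
        Unique sample identifiers, one per column of ``counts``.
    counts : ndarray of int, shape (n_otus, n_samples)
        Non-negative read counts.
    taxonomy : list of str, optional
        Per-OTU ranked lineage, ranks separated by ``"; "``
        (domain → species; unassigned trailing ranks may be omitted).
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: list[str] | None = None

    def __post_init__(self) -> None:
        self.otu_ids = list(self.otu_ids)
        self.sample_ids = list(self.sample_ids)
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise OtuTableFormatError(
                f"counts shape {counts.shape} does not match "
                f"({len(self.otu_ids)} OTUs, {len(self.sample_ids)} samples)"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.array_equal(rounded, counts):
                raise OtuTableFormatError("counts must be integers")
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64, copy=False)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise OtuTableFormatError(
                f"negative count for OTU {self.otu_ids[i]!r} in sample {self.sample_ids[j]!r}"
            )
        self.counts = counts
        _check_unique(self.otu_ids, "OTU id")
        _check_unique(self.sample_ids, "sample id")
        if self.taxonomy is not None:
            self.taxonomy = list(self.taxonomy)
            if len(self.taxonomy) != len(self.otu_ids):
                raise OtuTableFormatError(
                    f"taxonomy has {len(self.taxonomy)} entries for {len(self.otu_ids)} OTUs"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def otu_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def taxonomy_rank(self, level: int) -> list[str]:
        """Return the taxonomy name at `level` (0 = domain, 1 = phylum, ...).

        OTUs without taxonomy, or with a lineage shorter than `level`,
        report ``"unassigned"``.
        """
        if self.taxonomy is None:
            return ["unassigned"] * self.n_otus
        out = []
        for lineage in self.taxonomy:
            ranks = [r.strip() for r in lineage.split(";")]
            out.append(ranks[level] if level < len(ranks) and ranks[level] else "unassigned")
        return out

    @property
    def phyla(self) -> list[str]:
        return self.taxonomy_rank(1)

    # -- subsetting --------------------------------------------------------

    def select_otus(self, mask: np.ndarray | Sequence[int]) -> "OtuTable":
        """Row-subset by boolean mask or integer indices; sample set unchanged."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        tax = [self.taxonomy[i] for i in idx] if self.taxonomy is not None else None
        return OtuTable(
            [self.otu_ids[i] for i in idx], self.sample_ids, self.counts[idx], tax
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        wanted = list(sample_ids)
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        cols = [pos[s] for s in wanted]
        return OtuTable(self.otu_ids, wanted, self.counts[:, cols], self.taxonomy)


# -- I/O -------------------------------------------------------------------


def read_otu_table(path: str | Path, taxonomy_column: str | None = "taxonomy") -> OtuTable:
    """Read a classic tab-separated OTU table.

    Layout: header ``#OTU ID<TAB>sample...[<TAB>taxonomy]``, one row per
    OTU, integer count cells, optional trailing taxonomy column with
    ``"; "``-separated ranks. A column whose header equals
    `taxonomy_column` is treated as taxonomy; pass ``None`` to disable.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        raise OtuTableFormatError(f"{path}: empty file")
    header = rows[0]
    ncol = len(header)
    tax_idx = None
    if taxonomy_column is not None and taxonomy_column in header[1:]:
        tax_idx = header.index(taxonomy_column)
        if tax_idx != ncol - 1:
            raise OtuTableFormatError(
                f"{path}: taxonomy column must be last, found at position {tax_idx}"
            )
    sample_cols = [j for j in range(1, ncol) if j != tax_idx]
    sample_ids = [header[j] for j in sample_cols]
    _check_unique(sample_ids, "sample header")

    otu_ids: list[str] = []
    taxonomy: list[str] = []
    data = np.zeros((len(rows) - 1, len(sample_cols)), dtype=np.int64)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise OtuTableFormatError(
                f"{path}: line {r} has {len(row)} fields, expected {ncol}"
            )
        otu_ids.append(row[0])
        for k, j in enumerate(sample_cols):
            cell = row[j]
            try:
                val = int(cell)
            except ValueError:
                raise OtuTableFormatError(
                    f"{path}: non-integer count {cell!r} for OTU {row[0]!r}, "
                    f"sample {header[j]!r} (line {r})"
                ) from None
            if val < 0:
                raise OtuTableFormatError(
                    f"{path}: negative count {val} for OTU {row[0]!r}, "
                    f"sample {header[j]!r} (line {r})"
                )
            data[r - 2, k] = val
        if tax_idx is not None:
            taxonomy.append(row[tax_idx])
    return OtuTable(otu_ids, sample_ids, data, taxonomy if tax_idx is not None else None)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write `table` in the dialect accepted by :func:`read_otu_table`."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        header = ["#OTU ID", *table.sample_ids]
        if table.taxonomy is not None:
            header.append("taxonomy")
        fh.write("\t".join(header) + "\n")
        for i, otu in enumerate(table.otu_ids):
            cells = [otu, *(str(int(c)) for c in table.counts[i])]
            if table.taxonomy is not None:
                cells.append(table.taxonomy[i])
            fh.write("\t".join(cells) + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV and validate the closed vocabularies."""
    meta = pd.read_csv(path, sep="\t", dtype={c: str for c in METADATA_COLUMNS[:5]})
    missing = [c for c in METADATA_COLUMNS[:5] if c not in meta.columns]
    if missing:
        raise OtuTableFormatError(f"{path}: missing metadata columns {missing}")
    if "river_position_km" not in meta.columns:
        meta["river_position_km"] = np.nan
    meta["river_position_km"] = pd.to_numeric(meta["river_position_km"])
    validate_metadata(meta)
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False, float_format="%.6g")


def validate_metadata(meta: pd.DataFrame, table: OtuTable | None = None) -> None:
    """Check enum membership, uniqueness and (optionally) coverage of `table`."""
    dup = meta["sample_id"][meta["sample_id"].duplicated()]
    if len(dup):
        raise OtuTableFormatError(f"duplicate sample_id in metadata: {sorted(set(dup))}")
    for col, allowed in (("habitat", HABITATS), ("season", SEASONS), ("landform", LANDFORMS)):
        bad = sorted(set(meta[col]) - set(allowed))
        if bad:
            raise OtuTableFormatError(f"invalid {col} value(s) {bad}; allowed: {allowed}")
    if ((meta["river_position_km"].dropna()) < 0).any():
        raise OtuTableFormatError("river_position_km must be non-negative")
    if table is not None:
        missing = set(table.sample_ids) - set(meta["sample_id"])
        if missing:
            raise OtuTableFormatError(f"samples without metadata: {sorted(missing)}")


# -- filtering and normalization ------------------------------------------


def filter_otus(
    table: OtuTable,
    min_rel_abundance: float = 1e-4,
    drop_singletons_doubletons: bool = True,
    per_sample: bool = False,
) -> OtuTable:
    """Apply the standard pre-analysis OTU filters.

    Removes OTUs with a table-wide total of one or two reads (when
    `drop_singletons_doubletons`) and OTUs whose overall relative
    abundance — OTU total divided by the grand total — is below
    `min_rel_abundance` (default 0.01%). With ``per_sample=True`` the
    abundance criterion is instead satisfied if the OTU reaches the
    threshold within at least one sample.

    Raises
    ------
    ValueError
        If no OTUs survive, rather than returning a silent empty table.
    """
    if not 0 <= min_rel_abundance < 1:
        raise ValueError(f"min_rel_abundance must be in [0, 1), got {min_rel_abundance}")
    totals = table.otu_totals
    keep = np.ones(table.n_otus, dtype=bool)
    if drop_singletons_doubletons:
        keep &= totals > 2
    if min_rel_abundance > 0:
        if per_sample:
            sample_totals = table.sample_totals.astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                rel = table.counts / np.where(sample_totals > 0, sample_totals, np.nan)
            keep &= np.nanmax(rel, axis=1) >= min_rel_abundance
        else:
            grand = float(table.total)
            if grand == 0:
                raise ValueError("cannot filter an all-zero table by relative abundance")
            keep &= totals / grand >= min_rel_abundance
    if not keep.any():
        raise ValueError("no OTUs survive filters")
    return table.select_otus(keep)


def relative_abundance(table: OtuTable, per: str = "sample") -> np.ndarray:
    """Relative abundances, per sample (matrix) or table-wide (vector).

    ``per="sample"`` divides each column by its total (columns sum to 1);
    ``per="table"`` divides OTU totals by the grand total.
    """
    if per == "sample":
        totals = table.sample_totals
        zero = np.flatnonzero(totals == 0)
        if len(zero):
            names = [table.sample_ids[j] for j in zero]
            raise ValueError(f"zero-total sample(s): {names}")
        return table.counts / totals.astype(float)
    if per == "table":
        grand = float(table.total)
        if grand == 0:
            raise ValueError("all-zero table")
        return table.otu_totals / grand
    raise ValueError(f"per must be 'sample' or 'table', got {per!r}")


def subsample_to_depth(
    table: OtuTable, depth: int, seed: int | np.random.Generator, drop_shallow: bool = False
) -> OtuTable:
    """Subsample every sample to exactly `depth` reads without replacement.

    Each retained column is an independent multivariate-hypergeometric
    draw of `depth` reads from that sample's counts; an identical seed
    reproduces the table bit-for-bit. Samples with fewer than `depth`
    reads raise an error unless ``drop_shallow=True``, in which case
    they are removed (the behaviour is stated, not silent).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    totals = table.sample_totals
    if depth > totals.max(initial=0):
        raise ValueError(f"depth {depth} exceeds the deepest sample ({totals.max(initial=0)})")
    shallow = np.flatnonzero(totals < depth)
    if len(shallow) and not drop_shallow:
        names = [table.sample_ids[j] for j in shallow]
        raise ValueError(
            f"sample(s) below depth {depth}: {names}; pass drop_shallow=True to remove them"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = [j for j in range(table.n_samples) if totals[j] >= depth]
    out = np.zeros((table.n_otus, len(keep)), dtype=np.int64)
    for k, j in enumerate(keep):
        out[:, k] = rng.multivariate_hypergeometric(table.counts[:, j], depth)
    return OtuTable(
        table.otu_ids, [table.sample_ids[j] for j in keep], out, table.taxonomy
    )


def occupancy(table: OtuTable) -> pd.Series:
    """Occurrence frequency per OTU: fraction of samples with count > 0."""
    if table.n_samples == 0:
        raise ValueError("occupancy requires at least one sample")
    frac = (table.counts > 0).mean(axis=1)
    return pd.Series(frac, index=table.otu_ids, name="occupancy")
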