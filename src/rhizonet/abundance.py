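"""ASV abundance tables: parsing, validation, prevalence filtering.

The universal input of the pipeline is a taxa-by-samples count matrix with
per-sample metadata (genotype, phosphorus condition, replicate). Tables are
stored taxa-as-rows, the dominant amplicon-table dialect; a transposed input
is detectable only through a metadata mismatch and is reported as an error,
never silently fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "RelativeAbundanceTable",
    "AbundanceTableError",
    "read_table",
    "write_table",
    "filter_mean_relabund",
    "to_relative",
]

METADATA_COLUMNS = ("genotype", "condition", "replicate")


class AbundanceTableError(ValueError):
    """Raised on malformed or inconsistent abundance input."""


@dataclass
class AbundanceTable:
    """Taxa × samples count matrix plus sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix; index = taxon ids, columns = sample ids.
    metadata : pandas.DataFrame
        Indexed by sample id with at least ``genotype``, ``condition`` and
        ``replicate`` columns, covering every sample of ``counts``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        validate_table(self.counts, self.metadata)
        self.counts = self.counts.astype(np.int64)
        # align metadata to sample order; extra metadata rows are tolerated
        self.metadata = self.metadata.loc[self.counts.columns]

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.counts.columns)
        if missing:
            raise AbundanceTableError(f"unknown samples: {sorted(missing)}")
        return AbundanceTable(self.counts[sample_ids].copy(),
                              self.metadata.loc[sample_ids].copy())


@dataclass
class RelativeAbundanceTable:
    """Column-closed fractions with a provenance link to the source counts."""

    fractions: pd.DataFrame
    source: AbundanceTable | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        vals = self.fractions.to_numpy(dtype=float)
        if (vals < 0).any() or (vals > 1 + 1e-12).any():
            raise AbundanceTableError("fractions must lie in [0, 1]")
        colsums = vals.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            bad = self.fractions.columns[np.abs(colsums - 1.0) > 1e-9]
            raise AbundanceTableError(
                f"columns do not sum to 1: {list(bad)[:5]}")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.columns)

    def mean_abundance(self) -> pd.Series:
        """Per-taxon mean relative abundance across samples (the node
        weight b_j used by robustness and cohesion)."""
        return self.fractions.mean(axis=1)


def validate_table(counts: pd.DataFrame, metadata: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise AbundanceTableError(f"duplicate taxon id: {dup!r}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise AbundanceTableError(f"duplicate sample id: {dup!r}")
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise AbundanceTableError(
            f"need at least 2 taxa and 2 samples, got shape {counts.shape}")
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        # tolerate float representations of whole numbers, reject fractions
        if not np.all(np.equal(np.mod(vals, 1), 0)):
            frac_rows = counts.index[(np.mod(vals, 1) != 0).any(axis=1)]
            raise AbundanceTableError(
                f"non-integer counts in taxon rows: {list(frac_rows)[:5]}")
    if (vals < 0).any():
        neg_rows = counts.index[(vals < 0).any(axis=1)]
        raise AbundanceTableError(
            f"negative counts in taxon rows: {list(neg_rows)[:5]}")
    missing = set(counts.columns) - set(metadata.index)
    if missing:
        raise AbundanceTableError(
            f"samples missing from metadata: {sorted(missing)}")
    absent = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if absent:
        raise AbundanceTableError(f"metadata lacks columns: {absent}")


def read_table(path: str | Path, metadata_path: str | Path) -> AbundanceTable:
    """Read a tab-separated ASV table and its metadata.

    The first column holds taxon ids and the header row sample ids; a
    leading ``#OTU ID`` header (classic BIOM TSV export) is tolerated.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    for p in (path, metadata_path):
        if not p.exists():
            raise AbundanceTableError(f"no such file: {p}")
    counts = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    if counts.index.name and counts.index.name.lstrip("#").strip() in (
            "OTU ID", "ASV ID", "OTU_ID", "ASV_ID"):
        counts.index.name = "taxon_id"
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    metadata.index = metadata.index.astype(str)
    return AbundanceTable(counts, metadata)


def write_table(table: AbundanceTable, path: str | Path,
                metadata_path: str | Path | None = None) -> None:
    """Write the table (and optionally metadata) as TSV."""
    out = table.counts.copy()
    out.index.name = out.index.name or "taxon_id"
    out.to_csv(path, sep="\t")
    if metadata_path is not None:
        md = table.metadata.copy()
        md.index.name = md.index.name or "sample_id"
        md.to_csv(metadata_path, sep="\t")


def filter_mean_relabund(table: AbundanceTable,
                         threshold: float = 1e-4) -> AbundanceTable:
    """Keep taxa whose mean per-sample relative abundance exceeds *threshold*.

    This is the low-abundance pre-filter applied before network inference:
    the mean (across samples) of each taxon's per-sample fraction must be
    strictly greater than ``threshold`` (default 0.01%). The mean-of-ratios
    reading is used, not ratio-of-sums. Surviving counts are unchanged.
    """
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        bad = table.counts.columns[totals == 0][0]
        raise AbundanceTableError(f"sample {bad!r} has zero total count")
    mean_frac = (table.counts / totals).mean(axis=1)
    keep = mean_frac > threshold
    if not keep.any():
        raise AbundanceTableError(
            f"no taxon passes the {threshold:g} mean relative-abundance filter")
    return AbundanceTable(table.counts.loc[keep].copy(), table.metadata.copy())


def to_relative(table: AbundanceTable) -> RelativeAbundanceTable:
    """Close each sample (column) to fractions summing to 1."""
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        bad = table.counts.columns[totals == 0][0]
        raise AbundanceTableError(f"sample {bad!r} has zero total count")
    fractions = table.counts / totals
    return RelativeAbundanceTable(fractions, source=table)
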