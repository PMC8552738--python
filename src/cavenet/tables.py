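"""Feature, taxonomy, and sample-metadata tables.

The root object of the pipeline is a :class:`FeatureTable`: a features x
samples matrix of non-negative integer counts (OTUs/ASVs by amplicon
libraries).  This module reads and writes the QIIME-style "classic" TSV
dialects, converts counts to relative abundances, rarefies every sample to a
common sequencing depth, and applies the prevalence/abundance filter that
precedes network construction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "RelAbundanceTable",
    "TaxonomyMap",
    "SampleMetadata",
    "read_feature_table",
    "write_feature_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "to_relative_abundance",
    "rarefy",
    "prevalence_filter",
]


class TableError(ValueError):
    """Raised for malformed or inconsistent tables."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise TableError(f"duplicate {what} ids: {dups}")


@dataclass
class FeatureTable:
    """Non-negative integer counts, features as rows, samples as columns."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_features, n_samples) integer

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise TableError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise TableError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(self.feature_ids) < 1:
            raise TableError("no features")
        if len(self.sample_ids) < 2:
            raise TableError("no samples (need at least 2)")
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise TableError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise TableError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_features(self, keep: Sequence[str]) -> "FeatureTable":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in keep]
        return FeatureTable(list(keep), list(self.sample_ids), self.counts[rows])

    def select_samples(self, keep: Sequence[str]) -> "FeatureTable":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in keep]
        return FeatureTable(list(self.feature_ids), list(keep), self.counts[:, cols])


@dataclass
class RelAbundanceTable:
    """Per-sample proportions on the same axes as a FeatureTable."""

    feature_ids: list[str]
    sample_ids: list[str]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        sums = self.proportions.sum(axis=0)
        ok = np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0, atol=1e-12)
        if not ok.all():
            bad = [self.sample_ids[j] for j in np.where(~ok)[0]]
            raise TableError(f"sample proportions do not sum to 1: {bad}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.feature_ids, columns=self.sample_ids)


class TaxonomyMap:
    """feature id -> ordered lineage (domain ... genus/clade label).

    Unknown levels are recorded as ``"unclassified"``.  ``label()`` returns the
    deepest informative level, which is what network node tables and keystone
    summaries report (e.g. ``"USCgamma"``, ``"Gaiella"``).
    """

    UNCLASSIFIED = "unclassified"

    def __init__(self, lineages: Mapping[str, Sequence[str]]):
        self._lineages: dict[str, tuple[str, ...]] = {}
        for fid, lineage in lineages.items():
            levels = tuple(
                (str(x).strip() or self.UNCLASSIFIED) for x in lineage
            )
            if not levels:
                levels = (self.UNCLASSIFIED,)
            self._lineages[str(fid)] = levels

    def __contains__(self, fid: str) -> bool:
        return fid in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    def lineage(self, fid: str) -> tuple[str, ...]:
        return self._lineages.get(fid, (self.UNCLASSIFIED,))

    def label(self, fid: str) -> str:
        for level in reversed(self.lineage(fid)):
            if level != self.UNCLASSIFIED:
                return level
        return self.UNCLASSIFIED

    def items(self):
        return self._lineages.items()


class SampleMetadata:
    """Per-sample environmental variables and categorical factors."""

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            raise TableError("duplicate sample ids in metadata")
        self.df = df.copy()
        self.df.index = self.df.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def numeric(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        num = self.df.select_dtypes(include=[np.number])
        if variables is not None:
            missing = [v for v in variables if v not in self.df.columns]
            if missing:
                raise TableError(f"unknown metadata variables: {missing}")
            num = self.df[list(variables)].apply(pd.to_numeric)
        if not np.isfinite(num.to_numpy(dtype=float)).all():
            bad = num.index[num.isna().any(axis=1) | ~np.isfinite(num).all(axis=1)].tolist()
            raise TableError(f"non-finite metadata values for samples: {bad}")
        return num

    def check_covers(self, table: FeatureTable) -> None:
        missing = [s for s in table.sample_ids if s not in set(self.df.index)]
        if missing:
            raise TableError(f"samples without metadata rows: {missing}")


# ---------------------------------------------------------------------------
# readers / writers (QIIME-style classic TSV dialects)
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path | io.TextIOBase) -> FeatureTable:
    """Read a classic TSV feature table (rows = features, header = samples)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        raise TableError("no samples: file is empty") from None
    if df.shape[1] == 0:
        raise TableError("no samples: header has no sample columns")
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                val = int(str(raw))
            except (TypeError, ValueError):
                raise TableError(
                    f"non-integer count {raw!r} at feature {df.index[i]!r}, "
                    f"sample {col!r}"
                ) from None
            if val < 0:
                raise TableError(
                    f"negative count {val} at feature {df.index[i]!r}, sample {col!r}"
                )
            counts[i, j] = val
    return FeatureTable(list(df.index.astype(str)), list(df.columns.astype(str)), counts)


def write_feature_table(t: FeatureTable, path: str | Path) -> None:
    t.to_frame().to_csv(path, sep="\t", index_label="#OTU ID")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a 2+-column TSV: feature id, then a ';'-separated lineage."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise TableError("taxonomy file needs at least 2 columns (id, lineage)")
    ids = df.iloc[:, 0].astype(str)
    _check_unique(list(ids), "taxonomy feature")
    lineages = {
        fid: [lvl.strip() for lvl in str(lin).split(";")]
        for fid, lin in zip(ids, df.iloc[:, 1])
    }
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    rows = [(fid, ";".join(lineage)) for fid, lineage in tax.items()]
    pd.DataFrame(rows, columns=["feature_id", "lineage"]).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMetadata(df)


def write_metadata(m: SampleMetadata, path: str | Path) -> None:
    m.df.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def to_relative_abundance(t: FeatureTable) -> RelAbundanceTable:
    """Divide each sample column by its total count."""
    sums = t.sample_sums()
    zero = np.where(sums == 0)[0]
    if zero.size:
        bad = [t.sample_ids[j] for j in zero]
        raise TableError(f"all-zero samples cannot be normalized: {bad}")
    props = t.counts / sums[np.newaxis, :]
    return RelAbundanceTable(list(t.feature_ids), list(t.sample_ids), props)


def rarefy(
    t: FeatureTable,
    depth: int,
    seed: int,
    *,
    drop_small: bool = False,
) -> FeatureTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Uses multivariate hypergeometric draws per sample, so each output column
    sums exactly to ``depth`` and is a sub-multiset of the input column.
    Samples with fewer than ``depth`` reads raise an error unless
    ``drop_small`` is set, in which case they are removed.
    """
    if depth <= 0:
        raise TableError("rarefaction depth must be positive")
    sums = t.sample_sums()
    shallow = [t.sample_ids[j] for j in np.where(sums < depth)[0]]
    if shallow:
        if not drop_small:
            raise TableError(
                f"samples shallower than depth {depth}: {shallow}"
            )
        keep = [s for s in t.sample_ids if s not in set(shallow)]
        t = t.select_samples(keep)
        sums = t.sample_sums()
    rng = np.random.default_rng(seed)
    out = np.empty_like(t.counts)
    for j in range(t.n_samples):
        out[:, j] = rng.multivariate_hypergeometric(t.counts[:, j], depth)
    return FeatureTable(list(t.feature_ids), list(t.sample_ids), out)


def prevalence_filter(
    t: FeatureTable,
    min_mean_relabund: float = 0.001,
    min_occurrence: float = 0.2,
) -> FeatureTable:
    """Keep features abundant and prevalent enough for network inference.

    A feature is retained iff its mean relative abundance across samples is
    strictly greater than ``min_mean_relabund`` and it is non-zero in strictly
    more than ``min_occurrence`` of the samples.  Both thresholds are strict,
    so a feature sitting exactly on a boundary is removed.
    """
    for name, v in (("min_mean_relabund", min_mean_relabund), ("min_occurrence", min_occurrence)):
        if not 0 <= v <= 1:
            raise TableError(f"{name} must be in [0, 1], got {v}")
    rel = to_relative_abundance(t)
    mean_ra = rel.proportions.mean(axis=1)
    occurrence = (t.counts > 0).mean(axis=1)
    keep_mask = (mean_ra > min_mean_relabund) & (occurrence > min_occurrence)
    keep = [f for f, k in zip(t.feature_ids, keep_mask) if k]
    if not keep:
        raise TableError(
            "no feature passes the abundance/occurrence filter; "
            "a co-occurrence network cannot be built"
        )
    return t.select_features(keep)
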