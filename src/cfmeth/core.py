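"""Core containers for pooled bisulfite methylomes and genomic annotation.

The unit of observation is a single cytosine in CpG context: a genomic
position with methylated / unmethylated read counts.  A pool of plasma
samples sequenced together yields one :class:`PoolMethylome` — a sorted
per-cytosine count table.  Annotation is carried as named interval tracks
(CpG islands, TSS1500, 5'UTR, first exons, gene bodies).

Coordinate convention: positions are 1-based cytosine coordinates
everywhere inside the package; intervals follow BED 0-based half-open
semantics and the conversion happens exactly once, at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: Annotation categories understood by the context summariser.
CONTEXT_CATEGORIES = ("CPGI", "TSS1500", "UTR5", "Exon1", "GeneBody")

#: Chromosomes dropped by default before differential testing.
SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY"})

POOL_COLUMNS = ("chrom", "pos", "strand", "meth", "unmeth")


class CfMethError(Exception):
    """Base class for all package errors."""


class ParseError(CfMethError):
    """A malformed input row; carries the offending line number."""


class ConfigError(CfMethError):
    """Invalid configuration or cross-reference (bad parameter, missing file)."""


@dataclass(frozen=True, order=True)
class CpGLocus:
    """A single cytosine position: chromosome, 1-based position, strand."""

    chrom: str
    pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with a free-text name (gene symbol, island id)."""

    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def contains_position(self, pos_1based: int) -> bool:
        """Point containment of a 1-based cytosine position."""
        return self.start <= pos_1based - 1 < self.end


@dataclass
class AnnotationTrack:
    """A named genomic-context interval set (e.g. the CPGI track).

    Overlapping intervals are kept as-is, never merged; membership of a
    locus in the track means "overlaps at least one interval".
    """

    category: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CONTEXT_CATEGORIES:
            raise ConfigError(
                f"unknown annotation category {self.category!r}; "
                f"expected one of {CONTEXT_CATEGORIES}"
            )
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def chromosomes(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(iv.chrom, iv.start, iv.end, iv.name) for iv in self.intervals],
            columns=["chrom", "start", "end", "name"],
        )


class PoolMethylome:
    """Per-cytosine methylation counts for one plasma pool.

    Wraps a DataFrame with columns ``chrom, pos, strand, meth, unmeth``,
    kept sorted by (chrom, pos, strand) with unique loci.  ``pos`` is the
    1-based coordinate of the cytosine itself (for a CpG dyad the minus
    strand cytosine sits at the plus position + 1).
    """

    def __init__(self, label: str, df: pd.DataFrame, strand_known: bool = True):
        missing = [c for c in POOL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"pool table missing columns: {missing}")
        df = df.loc[:, list(POOL_COLUMNS)].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["meth"] = df["meth"].astype(np.int64)
        df["unmeth"] = df["unmeth"].astype(np.int64)
        if (df["pos"] < 1).any():
            raise ValueError("positions must be >= 1")
        if (df[["meth", "unmeth"]] < 0).to_numpy().any():
            raise ValueError("read counts must be non-negative")
        bad_strand = ~df["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise ValueError(
                f"invalid strand value(s): {sorted(df.loc[bad_strand, 'strand'].unique())}"
            )
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError(f"duplicate loci in pool {label!r}")
        self.label = label
        self.df = df.reset_index(drop=True)
        #: False for the coverage-file dialect, where strand is not recorded.
        self.strand_known = strand_known

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PoolMethylome):
            return NotImplemented
        return self.label == other.label and self.df.equals(other.df)

    @property
    def coverage(self) -> pd.Series:
        return self.df["meth"] + self.df["unmeth"]

    @property
    def percent_methylation(self) -> pd.Series:
        """100 * meth / coverage; NaN where coverage is zero."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.df["meth"] / cov
        return pct.where(cov > 0)

    @property
    def n_zero_coverage(self) -> int:
        return int((self.coverage == 0).sum())

    def chromosomes(self) -> set[str]:
        return set(self.df["chrom"].unique())

    def drop_chromosomes(self, chroms: Iterable[str]) -> "PoolMethylome":
        chroms = set(chroms)
        kept = self.df[~self.df["chrom"].isin(chroms)]
        return PoolMethylome(self.label, kept, strand_known=self.strand_known)

    def filter_coverage(self, min_coverage: int) -> "PoolMethylome":
        kept = self.df[self.coverage >= min_coverage]
        return PoolMethylome(self.label, kept, strand_known=self.strand_known)


def make_pool(
    label: str,
    chrom: Sequence[str] | str,
    pos: Sequence[int],
    meth: Sequence[int],
    unmeth: Sequence[int],
    strand: Sequence[str] | str = "+",
) -> PoolMethylome:
    """Convenience constructor used heavily in tests and examples."""
    n = len(pos)
    if isinstance(chrom, str):
        chrom = [chrom] * n
    if isinstance(strand, str):
        strand = [strand] * n
    return PoolMethylome(
        label,
        pd.DataFrame(
            {"chrom": chrom, "pos": pos, "strand": strand, "meth": meth, "unmeth": unmeth}
        ),
    )
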