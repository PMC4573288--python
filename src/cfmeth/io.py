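"""Readers and writers for the external formats the pipeline touches.

Two count dialects are supported, matching the Bismark ecosystem:

* cytosine report — 7 columns: chrom, 1-based position, strand,
  count-methylated, count-unmethylated, context, trinucleotide;
* coverage file — 6 columns: chrom, start, end (1-based inclusive, start ==
  end for a single cytosine), percent methylation, count-methylated,
  count-unmethylated.  Strand is not recorded in this dialect.

Interval tracks are BED3+ (0-based half-open).  Internal coordinates are
always 1-based cytosine positions; the BED conversion is applied exactly
once here.  All writers emit a single ``#`` header line recording the
package version and the writer's parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .core import (
    AnnotationTrack,
    GenomicInterval,
    ParseError,
    PoolMethylome,
)
from .version import __version__

logger = logging.getLogger(__name__)

DML_COLUMNS = [
    "chrom", "pos", "strand",
    "meth_a", "unmeth_a", "meth_b", "unmeth_b",
    "pct_a", "pct_b", "dmv", "p_value", "q_value", "direction",
]

_STRANDS = {"+", "-"}


def _header(kind: str, **params: Any) -> str:
    items = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# cfmeth {__version__} {kind} {items}".rstrip()


def _read_lines(path: str | Path):
    """Yield (1-based line number, stripped line), skipping blanks and comments."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _int_field(value: str, what: str, path, lineno: int) -> int:
    try:
        out = int(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer {what}: {value!r}") from None
    if out < 0:
        raise ParseError(f"{path}:{lineno}: negative {what}: {value!r}")
    return out


def read_cytosine_report(
    path: str | Path, label: str | None = None, context_filter: str = "CpG"
) -> PoolMethylome:
    """Read a Bismark-style cytosine report into a :class:`PoolMethylome`.

    Only rows whose context column equals ``context_filter`` are retained.
    Zero-coverage rows are kept — they carry position information and are
    removed later by the explicit coverage filter.
    """
    rows = []
    for lineno, line in _read_lines(path):
        fields = line.split("\t")
        if len(fields) != 7:
            raise ParseError(
                f"{path}:{lineno}: expected 7 tab-separated columns, got {len(fields)}"
            )
        chrom, pos_s, strand, meth_s, unmeth_s, context, _tri = fields
        if context != context_filter:
            continue
        if strand not in _STRANDS:
            raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
        rows.append(
            (
                chrom,
                _int_field(pos_s, "position", path, lineno),
                strand,
                _int_field(meth_s, "methylated count", path, lineno),
                _int_field(unmeth_s, "unmethylated count", path, lineno),
            )
        )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth", "unmeth"])
    pool = PoolMethylome(label or Path(path).stem, df)
    if pool.n_zero_coverage:
        logger.info(
            "%s: %d of %d loci have zero coverage (retained; removed by the "
            "coverage filter downstream)", path, pool.n_zero_coverage, len(pool),
        )
    return pool


def write_cytosine_report(pool: PoolMethylome, path: str | Path) -> None:
    """Write the 7-column cytosine-report dialect (context fixed to CpG)."""
    with open(path, "w") as fh:
        fh.write(_header("cytosine_report", pool=pool.label) + "\n")
        for row in pool.df.itertuples(index=False):
            tri = "CGN" if row.strand == "+" else "CGN"
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.strand}\t{row.meth}\t{row.unmeth}\tCpG\t{tri}\n"
            )


def read_coverage_file(path: str | Path, label: str | None = None) -> PoolMethylome:
    """Read the 6-column Bismark coverage dialect.

    Counts come from columns 5-6; the percent-methylation column is ignored
    and recomputed (a discrepancy > 0.5 is logged as a warning, not fatal).
    The dialect carries no strand: loci are recorded as '+' and the pool is
    flagged ``strand_known=False``.
    """
    rows = []
    n_mismatch = 0
    for lineno, line in _read_lines(path):
        fields = line.split("\t")
        if len(fields) != 6:
            raise ParseError(
                f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}"
            )
        chrom, start_s, _end_s, pct_s, meth_s, unmeth_s = fields
        pos = _int_field(start_s, "position", path, lineno)
        meth = _int_field(meth_s, "methylated count", path, lineno)
        unmeth = _int_field(unmeth_s, "unmethylated count", path, lineno)
        cov = meth + unmeth
        if cov > 0:
            try:
                file_pct = float(pct_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric %meth: {pct_s!r}") from None
            if abs(100.0 * meth / cov - file_pct) > 0.5:
                n_mismatch += 1
                logger.warning(
                    "%s:%d: %%meth column (%s) disagrees with counts (%d/%d); "
                    "recomputed value used", path, lineno, pct_s, meth, unmeth,
                )
        rows.append((chrom, pos, "+", meth, unmeth))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth", "unmeth"])
    pool = PoolMethylome(label or Path(path).stem, df, strand_known=False)
    if n_mismatch:
        logger.warning("%s: %d rows had inconsistent %%meth columns", path, n_mismatch)
    return pool


def write_coverage_file(pool: PoolMethylome, path: str | Path) -> None:
    """Write the 6-column coverage dialect (1-based inclusive positions)."""
    with open(path, "w") as fh:
        fh.write(_header("coverage", pool=pool.label) + "\n")
        for row in pool.df.itertuples(index=False):
            cov = row.meth + row.unmeth
            pct = 100.0 * row.meth / cov if cov else 0.0
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.pos}\t{pct:.6g}\t{row.meth}\t{row.unmeth}\n"
            )


def read_bed_track(path: str | Path, category: str) -> AnnotationTrack:
    """Read a BED3+ file (0-based half-open) as an annotation track."""
    intervals = []
    for lineno, line in _read_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
        chrom = fields[0]
        start = _int_field(fields[1], "start", path, lineno)
        try:
            end = int(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer end: {fields[2]!r}") from None
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
        name = fields[3] if len(fields) > 3 else "."
        intervals.append(GenomicInterval(chrom, start, end, name))
    return AnnotationTrack(category, intervals)


def write_bed_track(track: AnnotationTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header("bed", category=track.category) + "\n")
        for iv in track:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def write_dml_table(records: pd.DataFrame, path: str | Path, **params: Any) -> None:
    """Write a DML table as TSV with a fixed, deterministic column order.

    Extra columns (e.g. ``contexts`` from annotation) are appended after the
    canonical ones.
    """
    cols = [c for c in DML_COLUMNS if c in records.columns]
    cols += [c for c in records.columns if c not in cols]
    with open(path, "w") as fh:
        fh.write(_header("dml_table", **params) + "\n")
        records.loc[:, cols].to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_dml_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty and list(df.columns) and "chrom" not in df.columns:
        raise ParseError(f"{path}: not a DML table (missing 'chrom' column)")
    return df


def write_hotspot_bed(calls, path: str | Path, **params: Any) -> None:
    """Write hotspot calls as BED: island coordinates, name, support stats."""
    with open(path, "w") as fh:
        fh.write(_header("hotspots", **params) + "\n")
        for call in calls:
            iv = call.island
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                f"{call.n_qualifying}\t{call.mean_dmv:.6g}\t{call.max_dmv:.6g}\t"
                f"{call.core_start}\t{call.core_end}\n"
            )


def write_summary_json(summary: Mapping[str, Any] | Any, path: str | Path) -> None:
    """JSON dump that round-trips losslessly for plain dict/list/scalar content."""
    if is_dataclass(summary) and not isinstance(summary, type):
        summary = asdict(summary)

    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if is_dataclass(obj) and not isinstance(obj, type):
            return asdict(obj)
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_summary_json(path: str | Path) -> Any:
    with open(path) as fh:
        return json.load(fh)
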