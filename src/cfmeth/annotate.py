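"""Genomic-context annotation of DML and per-context direction summaries.

Assignment is multi-label: a locus inside both a CpG island and a TSS1500
window counts in both categories (per-context percentages are reported per
context, not as a partition of the genome — this changes denominators and
is therefore stated prominently).  Loci overlapping no track contribute to
the genome-wide summary only.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .core import AnnotationTrack, CONTEXT_CATEGORIES, ConfigError

GENOME_WIDE = "genome_wide"
SUMMARY_CATEGORIES = (GENOME_WIDE,) + CONTEXT_CATEGORIES


def build_interval_index(
    tracks: Iterable[AnnotationTrack],
) -> dict[str, dict[str, IntervalTree]]:
    """category -> chromosome -> interval tree (0-based half-open)."""
    index: dict[str, dict[str, IntervalTree]] = {}
    for track in tracks:
        per_chrom = index.setdefault(track.category, {})
        for iv in track:
            per_chrom.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.name)
    return index


def annotate_dml(
    records: pd.DataFrame, tracks: Mapping[str, AnnotationTrack] | Iterable[AnnotationTrack]
) -> pd.DataFrame:
    """Attach a ``contexts`` column: comma-joined categories overlapping each locus.

    Containment uses the 1-based cytosine position converted to a 0-based
    point.  Records overlapping nothing get an empty string.
    """
    track_list = list(tracks.values()) if isinstance(tracks, Mapping) else list(tracks)
    for track in track_list:
        if track.category not in CONTEXT_CATEGORIES:
            raise ConfigError(f"unknown category {track.category!r}")
    index = build_interval_index(track_list)
    out = records.copy()
    labels = []
    for chrom, pos in zip(out["chrom"], out["pos"]):
        point = pos - 1
        hits = [
            cat
            for cat in CONTEXT_CATEGORIES
            if cat in index and chrom in index[cat] and index[cat][chrom][point]
        ]
        labels.append(",".join(hits))
    out["contexts"] = labels
    return out


def summarize_contexts(annotated: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Per-category DML counts and hyper/hypo percentages.

    ``genome_wide`` counts every record exactly once; each context category
    counts the records whose ``contexts`` label set includes it.
    """
    if "contexts" not in annotated.columns:
        raise ConfigError("records are not annotated (no 'contexts' column)")
    sets = annotated["contexts"].fillna("").map(lambda s: set(s.split(",")) - {""})
    summary: dict[str, dict[str, float]] = {}
    for cat in SUMMARY_CATEGORIES:
        if cat == GENOME_WIDE:
            mask = pd.Series(True, index=annotated.index)
        else:
            mask = sets.map(lambda s, c=cat: c in s)
        sub = annotated[mask]
        n = len(sub)
        n_hyper = int((sub["direction"] == "hyper").sum()) if n else 0
        n_hypo = n - n_hyper
        summary[cat] = {
            "n_dml": n,
            "n_hyper": n_hyper,
            "n_hypo": n_hypo,
            "pct_hyper": 100.0 * n_hyper / n if n else float("nan"),
            "pct_hypo": 100.0 * n_hypo / n if n else float("nan"),
        }
    return summary
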