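"""CpG-island hypermethylation hotspot calling and recovery scoring.

A hotspot is a CpG island containing at least ``min_dml`` hypermethylated
DML whose DMV meets ``min_dmv`` (inclusive, default >= 50 on the percent
scale; the direction requirement can be relaxed).  The call reports the
full island interval; the minimal window spanning the qualifying loci is
carried as auxiliary coordinates, not as the primary extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .core import AnnotationTrack, CfMethError, GenomicInterval
from .simulate import SimulationTruth


@dataclass
class HotspotParams:
    min_dml: int = 8
    min_dmv: float = 50.0
    require_hyper: bool = True

    def __post_init__(self) -> None:
        if self.min_dml < 1:
            raise CfMethError("min_dml must be >= 1")
        if not 0 < self.min_dmv <= 100:
            raise CfMethError("min_dmv must lie in (0, 100]")


@dataclass
class HotspotCall:
    """One island passing the hotspot criterion, with its supporting loci."""

    island: GenomicInterval
    n_qualifying: int
    mean_dmv: float
    max_dmv: float
    supporting_loci: pd.DataFrame = field(repr=False)
    #: minimal 0-based half-open window spanning the qualifying loci
    core_start: int = 0
    core_end: int = 0


def call_hotspots(
    records: pd.DataFrame,
    islands: AnnotationTrack,
    params: HotspotParams | None = None,
) -> list[HotspotCall]:
    """Scan called DML against the CpG-island track for hotspot islands.

    ``records`` must be a called-DML table (already past the P / DMV-20
    filters) with columns chrom, pos, dmv, direction.  Returns calls sorted
    by (chrom, start).
    """
    params = params or HotspotParams()
    if len(islands) == 0:
        raise CfMethError("empty island track: hotspot calling is defined on CPGIs")
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(islands):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)

    qualifying = records[records["dmv"] >= params.min_dmv]
    if params.require_hyper:
        qualifying = qualifying[qualifying["direction"] == "hyper"]

    per_island: dict[int, list[int]] = {}
    for row_idx, chrom, pos in zip(qualifying.index, qualifying["chrom"], qualifying["pos"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in tree[pos - 1]:
            per_island.setdefault(hit.data, []).append(row_idx)

    island_list = list(islands)
    calls = []
    for island_i, row_ids in per_island.items():
        if len(row_ids) < params.min_dml:
            continue
        support = qualifying.loc[sorted(row_ids)]
        calls.append(
            HotspotCall(
                island=island_list[island_i],
                n_qualifying=len(support),
                mean_dmv=float(support["dmv"].mean()),
                max_dmv=float(support["dmv"].max()),
                supporting_loci=support,
                core_start=int(support["pos"].min() - 1),
                core_end=int(support["pos"].max()),
            )
        )
    calls.sort(key=lambda c: (c.island.chrom, c.island.start))
    return calls


def intersect_calls(
    calls_a: list[HotspotCall], calls_b: list[HotspotCall]
) -> list[HotspotCall]:
    """Islands called in both runs (exact island identity); stats from run A."""
    keys_b = {(c.island.chrom, c.island.start, c.island.end) for c in calls_b}
    return [
        c for c in calls_a if (c.island.chrom, c.island.start, c.island.end) in keys_b
    ]


def score_recovery(
    calls: list[HotspotCall], truth: SimulationTruth
) -> dict[str, object]:
    """Sensitivity / false-positive accounting against planted ground truth.

    Match is exact island identity.  Raises if the called and planted
    chromosome namespaces are disjoint while both are non-empty.
    """
    planted = {
        (iv.chrom, iv.start, iv.end): iv.name for iv in truth.planted_hotspot_islands
    }
    called = {(c.island.chrom, c.island.start, c.island.end) for c in calls}
    if calls and planted:
        chroms_called = {k[0] for k in called}
        chroms_planted = {k[0] for k in planted}
        if not chroms_called & chroms_planted:
            raise CfMethError(
                f"chromosome namespaces disjoint between calls ({sorted(chroms_called)}) "
                f"and truth ({sorted(chroms_planted)})"
            )
    recovered = sorted(planted[k] for k in called & set(planted))
    false_pos = sorted(k for k in called - set(planted))
    return {
        "n_planted": len(planted),
        "n_called": len(called),
        "n_recovered": len(recovered),
        "sensitivity": len(recovered) / len(planted) if planted else float("nan"),
        "false_positives": len(false_pos),
        "recovered_islands": recovered,
        "false_positive_islands": [f"{c}:{s}-{e}" for c, s, e in false_pos],
    }
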