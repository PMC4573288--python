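"""Cross-platform concordance analytics.

Compares per-locus percent methylation measured by two platforms — e.g. a
whole-genome run against deep targeted amplicon sequencing of the same
regions — over a set of named target intervals (amplicons): pairing by
exact locus identity after destranding both platforms identically, pooled
Pearson r with R^2 defined as r^2, per-platform depth summaries, and
per-amplicon aggregated Fisher tests between case and control pools with
Benjamini-Hochberg correction across amplicons.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .core import AnnotationTrack, CfMethError, GenomicInterval, PoolMethylome
from .diffmeth import bh_qvalues, destrand_merge, fisher_exact_2x2

logger = logging.getLogger(__name__)


def _target_list(
    targets: AnnotationTrack | Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    ivs = list(targets)
    if not ivs:
        raise CfMethError("empty target-region set")
    return ivs


def _restrict(pool: PoolMethylome, targets: list[GenomicInterval]) -> pd.DataFrame:
    df = pool.df
    pos0 = df["pos"].to_numpy() - 1
    chroms = df["chrom"].to_numpy()
    amplicon = np.full(len(df), "", dtype=object)
    for iv in targets:
        inside = (chroms == iv.chrom) & (pos0 >= iv.start) & (pos0 < iv.end)
        amplicon[inside] = iv.name
    out = df[amplicon != ""].copy()
    out["amplicon"] = amplicon[amplicon != ""]
    return out


def pair_platforms(
    pool_p1: PoolMethylome,
    pool_p2: PoolMethylome,
    targets: AnnotationTrack | Iterable[GenomicInterval],
    pool_label: str | None = None,
) -> pd.DataFrame:
    """Pair loci inside the target regions measured by both platforms.

    Both platforms are destranded first (where strand is recorded).
    Returns one row per paired locus with percent methylation and coverage
    on each platform; loci seen by only one platform are recorded in
    ``df.attrs["dropped"]``.  Raises if no locus pairs.
    """
    targets = _target_list(targets)
    p1 = destrand_merge(pool_p1) if pool_p1.strand_known else pool_p1
    p2 = destrand_merge(pool_p2) if pool_p2.strand_known else pool_p2
    t1 = _restrict(p1, targets)
    t2 = _restrict(p2, targets)
    t1 = t1[(t1["meth"] + t1["unmeth"]) >= 1]
    t2 = t2[(t2["meth"] + t2["unmeth"]) >= 1]
    merged = t1.merge(
        t2, on=["chrom", "pos", "amplicon"], how="outer", suffixes=("_1", "_2")
    )
    paired = merged.dropna(subset=["meth_1", "meth_2"]).copy()
    dropped = merged[merged["meth_1"].isna() | merged["meth_2"].isna()]
    if paired.empty:
        raise CfMethError("no locus measured by both platforms inside the targets")
    cov1 = paired["meth_1"] + paired["unmeth_1"]
    cov2 = paired["meth_2"] + paired["unmeth_2"]
    out = pd.DataFrame(
        {
            "chrom": paired["chrom"],
            "pos": paired["pos"].astype(int),
            "amplicon": paired["amplicon"],
            "pool": pool_label or pool_p1.label,
            "pct_platform1": 100.0 * paired["meth_1"] / cov1,
            "pct_platform2": 100.0 * paired["meth_2"] / cov2,
            "cov_platform1": cov1.astype(int),
            "cov_platform2": cov2.astype(int),
        }
    ).reset_index(drop=True)
    out.attrs["dropped"] = (
        dropped[["chrom", "pos", "amplicon"]].astype({"pos": int}).to_dict(orient="records")
    )
    if len(dropped):
        logger.info("%d loci measured on one platform only (drop report)", len(dropped))
    return out


def concordance_stats(pairs: pd.DataFrame) -> dict:
    """Pooled Pearson r and R^2 = r^2 over paired measurements, plus depth
    and per-amplicon methylation summaries.

    ``pairs`` may concatenate several pools (rows carry a ``pool`` column);
    the headline correlation pools all pairs, as a cross-platform scatter
    over every group does.
    """
    if len(pairs) < 3:
        raise CfMethError("need at least three paired loci")
    x = pairs["pct_platform1"].to_numpy(float)
    y = pairs["pct_platform2"].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero variance on one platform; correlation undefined")
        r = float("nan")
    else:
        r = float(pearsonr(x, y).statistic)
    depth = pairs.groupby("pool")[["cov_platform1", "cov_platform2"]].mean()
    per_amplicon = (
        pairs.groupby(["pool", "amplicon"])[["pct_platform1", "pct_platform2"]]
        .mean()
        .round(10)
    )
    return {
        "n_loci": int(len(pairs)),
        "pearson_r": r,
        "r_squared": r * r if not np.isnan(r) else float("nan"),
        "mean_depth_per_pool": {
            pool: {
                "platform1": float(row["cov_platform1"]),
                "platform2": float(row["cov_platform2"]),
                "log10_platform1": float(np.log10(row["cov_platform1"])),
                "log10_platform2": float(np.log10(row["cov_platform2"])),
            }
            for pool, row in depth.iterrows()
        },
        "per_amplicon_mean_pct": {
            f"{pool}/{amp}": {
                "platform1": float(row["pct_platform1"]),
                "platform2": float(row["pct_platform2"]),
            }
            for (pool, amp), row in per_amplicon.iterrows()
        },
    }


def per_group_test(
    case: PoolMethylome,
    control: PoolMethylome,
    targets: AnnotationTrack | Iterable[GenomicInterval],
    q_threshold: float = 0.5,
) -> pd.DataFrame:
    """Amplicon-aggregated case/control Fisher exact tests.

    Counts are summed over all loci of each target region per pool, tested
    with a two-sided Fisher exact on the aggregated 2x2, and corrected with
    Benjamini-Hochberg across amplicons.  ``significant`` applies p <= 0.05
    and q <= ``q_threshold``.
    """
    targets = _target_list(targets)
    rows = []
    ca = _restrict(destrand_merge(case) if case.strand_known else case, targets)
    co = _restrict(destrand_merge(control) if control.strand_known else control, targets)
    for iv in targets:
        a = ca[ca["amplicon"] == iv.name]
        b = co[co["amplicon"] == iv.name]
        ma, ua = int(a["meth"].sum()), int(a["unmeth"].sum())
        mb, ub = int(b["meth"].sum()), int(b["unmeth"].sum())
        if ma + ua == 0 or mb + ub == 0:
            logger.warning("amplicon %s uncovered in one pool; skipped", iv.name)
            continue
        rows.append(
            {
                "amplicon": iv.name,
                "meth_case": ma, "unmeth_case": ua,
                "meth_control": mb, "unmeth_control": ub,
                "pct_case": 100.0 * ma / (ma + ua),
                "pct_control": 100.0 * mb / (mb + ub),
                "p_value": fisher_exact_2x2(ma, ua, mb, ub),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q_value"] = bh_qvalues(out["p_value"].to_numpy())
    out["significant"] = (out["p_value"] <= 0.05) & (out["q_value"] <= q_threshold)
    return out
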