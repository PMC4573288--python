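"""Per-base two-group differential methylation.

The calling rule mirrors the classic methylKit-style per-base analysis of
pooled bisulfite data: destrand CpG dyads, keep loci covered by at least
``min_coverage_per_group`` reads in *both* pools, test each 2x2 count table
with a two-sided Fisher exact test, compute the differential methylation
value (DMV = percent methylation in the case minus the control, on a 0-100
scale), and call a differentially methylated locus (DML) when |DMV| >= 20
and P < 0.05 (inclusive on the DMV boundary, with both thresholds
configurable).  Sex chromosomes are removed before testing.  Benjamini-
Hochberg q-values are always computed; the q-value threshold is off by
default for the genome-wide call and set to 0.5 when emulating targeted
amplicon validation.

Direction convention: group A is the case; ``hyper`` means DMV > 0
(the case is more methylated than the control).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import CfMethError, PoolMethylome, SEX_CHROMOSOMES

logger = logging.getLogger(__name__)

UNITED_COLUMNS = ["chrom", "pos", "strand", "meth_a", "unmeth_a", "meth_b", "unmeth_b"]


@dataclass
class DiffMethParams:
    """Thresholds of the per-base DML call.

    Defaults are the standard pooled-WGBS settings: minimum coverage 5 per
    group, DMV threshold 20 (percent scale), P < 0.05, X/Y excluded, no
    FDR cut-off (set ``q_threshold`` to e.g. 0.5 for amplicon-style calls).
    """

    min_coverage_per_group: int = 5
    dmv_threshold: float = 20.0
    p_threshold: float = 0.05
    q_threshold: float | None = None
    exclude_chromosomes: frozenset[str] = field(default_factory=lambda: SEX_CHROMOSOMES)
    destrand: bool = True

    def __post_init__(self) -> None:
        if self.min_coverage_per_group < 1:
            raise CfMethError("min_coverage_per_group must be >= 1")
        if not 0 < self.dmv_threshold <= 100:
            raise CfMethError("dmv_threshold must lie in (0, 100]")
        if not 0 < self.p_threshold < 1:
            raise CfMethError("p_threshold must lie in (0, 1)")
        if self.q_threshold is not None and not 0 < self.q_threshold <= 1:
            raise CfMethError("q_threshold must lie in (0, 1]")
        self.exclude_chromosomes = frozenset(self.exclude_chromosomes)


def destrand_merge(pool: PoolMethylome) -> PoolMethylome:
    """Merge the two cytosines of each CpG dyad into one plus-strand locus.

    The minus-strand cytosine at position p belongs to the dyad whose
    plus-strand cytosine sits at p-1; its counts are added there.  A minus
    locus with no plus partner becomes its own plus-strand record at the
    dyad position (logged).
    """
    df = pool.df
    plus = df[df["strand"] == "+"]
    minus = df[df["strand"] == "-"].copy()
    if minus.empty:
        return PoolMethylome(pool.label, plus, strand_known=True)
    minus["pos"] = (minus["pos"] - 1).clip(lower=1)
    merged = plus.merge(
        minus, on=["chrom", "pos"], how="outer", suffixes=("_p", "_m"), sort=False
    )
    n_orphan = int(merged["meth_p"].isna().sum())
    if n_orphan:
        logger.info(
            "%s: %d minus-strand loci had no plus partner; emitted at their "
            "dyad position", pool.label, n_orphan,
        )
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "strand": "+",
            "meth": merged["meth_p"].fillna(0) + merged["meth_m"].fillna(0),
            "unmeth": merged["unmeth_p"].fillna(0) + merged["unmeth_m"].fillna(0),
        }
    )
    return PoolMethylome(pool.label, out, strand_known=True)


def unite_pools(
    a: PoolMethylome, b: PoolMethylome, params: DiffMethParams | None = None
) -> pd.DataFrame:
    """Pair loci measured in both pools at sufficient depth.

    Returns the united count table: loci present in both pools with
    coverage >= ``min_coverage_per_group`` in each.  Group A is the case.
    """
    params = params or DiffMethParams()
    m = a.df.merge(
        b.df, on=["chrom", "pos", "strand"], how="inner", suffixes=("_a", "_b")
    )
    cov_a = m["meth_a"] + m["unmeth_a"]
    cov_b = m["meth_b"] + m["unmeth_b"]
    united = m[
        (cov_a >= params.min_coverage_per_group)
        & (cov_b >= params.min_coverage_per_group)
    ].reset_index(drop=True)
    logger.info(
        "unite %s vs %s: %d shared loci, %d at coverage >= %d in both",
        a.label, b.label, len(m), len(united), params.min_coverage_per_group,
    )
    if united.empty:
        logger.warning("unite %s vs %s: empty intersection", a.label, b.label)
    return united.loc[:, UNITED_COLUMNS]


@lru_cache(maxsize=1_000_000)
def _fisher_cached(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int) -> float:
    n1 = meth_a + unmeth_a
    n2 = meth_b + unmeth_b
    r = meth_a + meth_b
    lo = max(0, r - n2)
    hi = min(r, n1)
    w_obs = comb(n1, meth_a) * comb(n2, r - meth_a)
    acc = 0
    for k in range(lo, hi + 1):
        w = comb(n1, k) * comb(n2, r - k)
        if w <= w_obs:
            acc += w
    p = acc / comb(n1 + n2, r)
    # acc >= w_obs >= 1, so the true p is strictly positive; guard against
    # float underflow on very large aggregated tables.
    return p if p > 0.0 else 5e-324


def fisher_exact_2x2(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int) -> float:
    """Two-sided Fisher exact p-value for one 2x2 methylation count table.

    Computed by exact integer enumeration of the hypergeometric
    distribution over the fixed margins (two-sided rule: sum the
    probabilities of all tables no more probable than the observed one), so
    tie decisions at equal-probability tables are exact, p is never 0, and
    p equals at least the probability of the observed table.
    """
    counts = (meth_a, unmeth_a, meth_b, unmeth_b)
    if any(c < 0 for c in counts):
        raise CfMethError(f"negative count in table {counts}")
    if meth_a + unmeth_a == 0 or meth_b + unmeth_b == 0:
        raise CfMethError(f"zero coverage margin in table {counts}")
    return _fisher_cached(*(int(c) for c in counts))


def fisher_exact_many(
    meth_a: np.ndarray, unmeth_a: np.ndarray, meth_b: np.ndarray, unmeth_b: np.ndarray
) -> np.ndarray:
    """Vectorised Fisher exact over parallel count arrays (memoised)."""
    return np.array(
        [
            _fisher_cached(int(ma), int(ua), int(mb), int(ub))
            for ma, ua, mb, ub in zip(meth_a, unmeth_a, meth_b, unmeth_b)
        ]
    )


def compute_dmv(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int) -> float:
    """Differential methylation value: pct(case) - pct(control), percent scale."""
    cov_a = meth_a + unmeth_a
    cov_b = meth_b + unmeth_b
    if cov_a == 0 or cov_b == 0:
        raise CfMethError("DMV undefined at zero coverage")
    return 100.0 * meth_a / cov_a - 100.0 * meth_b / cov_b


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p elementwise)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise CfMethError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dml(
    a: PoolMethylome, b: PoolMethylome, params: DiffMethParams | None = None
) -> pd.DataFrame:
    """Full per-base DML call of pool ``a`` (case) against ``b`` (control).

    Pipeline: drop excluded chromosomes -> destrand (if enabled and strand
    information is present) -> unite at min coverage -> Fisher exact +
    DMV + BH q per locus -> keep loci with |DMV| >= dmv_threshold and
    p <= p_threshold (and q <= q_threshold when set).

    Returns a DataFrame with one row per called DML; the attribute
    ``df.attrs["n_tested"]`` records how many united loci were tested.
    """
    params = params or DiffMethParams()
    a = a.drop_chromosomes(params.exclude_chromosomes)
    b = b.drop_chromosomes(params.exclude_chromosomes)
    logger.info(
        "excluded chromosomes %s; %d/%d loci remain in %s/%s",
        sorted(params.exclude_chromosomes), len(a), len(b), a.label, b.label,
    )
    if params.destrand:
        if a.strand_known:
            a = destrand_merge(a)
        if b.strand_known:
            b = destrand_merge(b)
    united = unite_pools(a, b, params)
    if united.empty:
        out = pd.DataFrame(
            columns=UNITED_COLUMNS + ["pct_a", "pct_b", "dmv", "p_value", "q_value", "direction"]
        )
        out.attrs["n_tested"] = 0
        return out
    cov_a = united["meth_a"] + united["unmeth_a"]
    cov_b = united["meth_b"] + united["unmeth_b"]
    united = united.assign(
        pct_a=100.0 * united["meth_a"] / cov_a,
        pct_b=100.0 * united["meth_b"] / cov_b,
    )
    united["dmv"] = united["pct_a"] - united["pct_b"]
    united["p_value"] = fisher_exact_many(
        united["meth_a"].to_numpy(), united["unmeth_a"].to_numpy(),
        united["meth_b"].to_numpy(), united["unmeth_b"].to_numpy(),
    )
    united["q_value"] = bh_qvalues(united["p_value"].to_numpy())
    keep = (united["dmv"].abs() >= params.dmv_threshold) & (
        united["p_value"] <= params.p_threshold
    )
    if params.q_threshold is not None:
        keep &= united["q_value"] <= params.q_threshold
    called = united[keep].copy()
    called["direction"] = np.where(called["dmv"] > 0, "hyper", "hypo")
    called = called.reset_index(drop=True)
    called.attrs["n_tested"] = len(united)
    logger.info(
        "call_dml %s vs %s: %d tested, %d called (|DMV| >= %g, p <= %g%s)",
        a.label, b.label, len(united), len(called), params.dmv_threshold,
        params.p_threshold,
        f", q <= {params.q_threshold}" if params.q_threshold is not None else "",
    )
    return called


def direction_summary(records: pd.DataFrame) -> dict[str, float]:
    """Hyper/hypo counts and percentages over a called DML set."""
    n = len(records)
    n_hyper = int((records["direction"] == "hyper").sum()) if n else 0
    n_hypo = n - n_hyper
    return {
        "n_dml": n,
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "pct_hyper": 100.0 * n_hyper / n if n else float("nan"),
        "pct_hypo": 100.0 * n_hypo / n if n else float("nan"),
    }
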