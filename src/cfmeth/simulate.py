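"""Synthetic pooled plasma methylomes with planted ground truth.

The generator emulates the statistical structure a pooled-WGBS differential
methylation analysis assumes:

* a bimodal per-CpG methylation landscape — background loci near fully
  methylated (Beta with mean ~0.85), CpG-island loci near unmethylated
  (Beta with mean ~0.05);
* a tunable *global hypomethylation shift* subtracted from background
  probabilities in one pool (islands stay low), mimicking the genome-wide
  hypomethylation of tumour-derived cfDNA;
* *planted focal hypermethylation* in a chosen subset of islands of that
  same pool, mimicking focal CpG-island hypermethylation hotspots;
* per-pool depth-of-coverage models (negative binomial) and beta-binomial
  read counts, because a pool of 40 individuals is overdispersed relative
  to a single binomial (``overdispersion_rho = 0`` recovers binomial).

All pools share one per-locus *landscape* of true baseline methylation
proportions, drawn once per study: two pools simulated from identical
parameters then satisfy the two-group null exactly at every locus, which is
what calibration checks of the downstream Fisher test require.  Pool-level
modifications (shift, planting, count noise) are applied on top.

Both strands of each CpG dyad are emitted (same underlying proportion,
independent coverage draws) so that destranding is exercised downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AnnotationTrack, CfMethError, GenomicInterval, PoolMethylome
from . import io as _io

__all__ = [
    "SimGenomeModel", "SimPoolParams", "SimulationTruth",
    "make_genome", "place_cpgs", "draw_landscape", "simulate_pool",
    "simulate_study", "StudyData", "default_pool_params",
    "emit_truth", "load_truth",
]

# Concentration (alpha+beta) of the Beta used to redraw proportions inside
# planted islands; sd ~ 0.04 at level 0.9.
_PLANT_CONCENTRATION = 50.0


@dataclass
class SimGenomeModel:
    """Genome skeleton for the simulation: chromosomes, islands, CpG density."""

    chromosomes: list[tuple[str, int]]
    islands: list[GenomicInterval] = field(default_factory=list)
    cpg_spacing_mean: float = 130.0
    island_cpg_density_multiplier: float = 5.0

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise CfMethError(f"chromosome {name!r} has non-positive length")
        for iv in self.islands:
            if iv.chrom not in lengths or iv.end > lengths[iv.chrom]:
                raise CfMethError(
                    f"island {iv.name} [{iv.chrom}:{iv.start}-{iv.end}) exceeds "
                    "chromosome bounds"
                )
        if self.island_cpg_density_multiplier < 1:
            raise CfMethError("island_cpg_density_multiplier must be >= 1")
        if self.cpg_spacing_mean <= 2:
            raise CfMethError("cpg_spacing_mean must exceed a dyad width (2 bp)")


@dataclass
class SimPoolParams:
    """Per-pool generative parameters.

    depth_mean
        mean per-cytosine read coverage (each strand drawn independently).
    depth_dispersion
        negative-binomial size parameter k; variance = mu + mu^2/k.
    background_beta / island_beta
        (alpha, beta) of the baseline methylation-proportion Beta outside /
        inside CpG islands.
    global_hypo_shift
        proportion subtracted from background (non-island) methylation
        probabilities, in [0, 1); models genome-wide hypomethylation.
    overdispersion_rho
        intra-pool beta-binomial correlation in [0, 1); 0 means binomial.
    """

    label: str
    depth_mean: float = 10.0
    depth_dispersion: float = 8.0
    background_beta: tuple[float, float] = (6.8, 1.2)
    island_beta: tuple[float, float] = (0.75, 14.25)
    global_hypo_shift: float = 0.0
    overdispersion_rho: float = 0.02

    def __post_init__(self) -> None:
        if self.depth_mean <= 0:
            raise CfMethError("depth_mean must be > 0")
        if self.depth_dispersion <= 0:
            raise CfMethError("depth_dispersion must be > 0")
        for pair in (self.background_beta, self.island_beta):
            if pair[0] <= 0 or pair[1] <= 0:
                raise CfMethError("Beta parameters must be > 0")
        if not 0 <= self.global_hypo_shift < 1:
            raise CfMethError("global_hypo_shift must lie in [0, 1)")
        if not 0 <= self.overdispersion_rho < 1:
            raise CfMethError("overdispersion_rho must lie in [0, 1)")


@dataclass
class SimulationTruth:
    """Planted ground truth for recovery scoring, JSON round-trippable."""

    planted_hotspot_islands: list[GenomicInterval]
    planted_hyper_level: float
    affected_pool_label: str
    seed: int
    pool_params: list[SimPoolParams] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "planted_hotspot_islands": [asdict(iv) for iv in self.planted_hotspot_islands],
            "planted_hyper_level": self.planted_hyper_level,
            "affected_pool_label": self.affected_pool_label,
            "seed": int(self.seed),
            "pool_params": [asdict(p) for p in self.pool_params],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        return cls(
            planted_hotspot_islands=[
                GenomicInterval(**iv) for iv in d["planted_hotspot_islands"]
            ],
            planted_hyper_level=d["planted_hyper_level"],
            affected_pool_label=d["affected_pool_label"],
            seed=int(d["seed"]),
            pool_params=[
                SimPoolParams(
                    **{
                        **p,
                        "background_beta": tuple(p["background_beta"]),
                        "island_beta": tuple(p["island_beta"]),
                    }
                )
                for p in d.get("pool_params", [])
            ],
        )


def emit_truth(truth: SimulationTruth, path: str | Path) -> None:
    _io.write_summary_json(truth.to_dict(), path)


def load_truth(path: str | Path) -> SimulationTruth:
    return SimulationTruth.from_dict(_io.read_summary_json(path))


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def make_genome(
    seed: int = 0,
    chrom_name: str = "chr1",
    chrom_length: int = 2_000_000,
    n_islands: int = 200,
    island_length: int = 600,
    cpg_spacing_mean: float = 130.0,
    island_cpg_density_multiplier: float = 5.0,
    n_genes: int = 100,
    gene_body_length: int = 8_000,
) -> tuple[SimGenomeModel, dict[str, AnnotationTrack]]:
    """Build a desk-scale genome model and matching annotation tracks.

    Islands are placed one per equal-width slot (jittered within the slot)
    so they never overlap.  Every other island is promoter-associated: a
    gene TSS is placed at its start, producing TSS1500 / UTR5 / Exon1 /
    GeneBody intervals that overlap island and background loci the way
    promoter CpG islands do in real genomes.
    """
    rng = _substream(seed, 0xC0)
    slot = chrom_length // n_islands
    if slot <= island_length:
        raise CfMethError("chromosome too short for the requested island count")
    islands = []
    for i in range(n_islands):
        offset = int(rng.integers(0, slot - island_length))
        start = i * slot + offset
        islands.append(GenomicInterval(chrom_name, start, start + island_length, f"island_{i:04d}"))

    genome = SimGenomeModel(
        chromosomes=[(chrom_name, chrom_length)],
        islands=islands,
        cpg_spacing_mean=cpg_spacing_mean,
        island_cpg_density_multiplier=island_cpg_density_multiplier,
    )

    # Genes: half anchored at island starts (promoter islands), half at
    # random background positions.
    tss1500, utr5, exon1, bodies = [], [], [], []
    island_idx = rng.choice(n_islands, size=min(n_genes // 2, n_islands), replace=False)
    tss_positions = [islands[i].start for i in sorted(island_idx)]
    n_bg = n_genes - len(tss_positions)
    tss_positions += sorted(
        int(p) for p in rng.integers(2000, chrom_length - gene_body_length, size=n_bg)
    )
    for g, tss in enumerate(sorted(tss_positions)):
        name = f"gene_{g:04d}"
        tss1500.append(GenomicInterval(chrom_name, max(0, tss - 1500), max(1, tss), name))
        utr5.append(GenomicInterval(chrom_name, tss, tss + 300, name))
        exon1.append(GenomicInterval(chrom_name, tss + 300, tss + 600, name))
        bodies.append(
            GenomicInterval(chrom_name, tss, min(chrom_length, tss + gene_body_length), name)
        )

    tracks = {
        "CPGI": AnnotationTrack("CPGI", islands),
        "TSS1500": AnnotationTrack("TSS1500", tss1500),
        "UTR5": AnnotationTrack("UTR5", utr5),
        "Exon1": AnnotationTrack("Exon1", exon1),
        "GeneBody": AnnotationTrack("GeneBody", bodies),
    }
    return genome, tracks


def _island_arrays(genome: SimGenomeModel, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    ivs = sorted(
        (iv for iv in genome.islands if iv.chrom == chrom), key=lambda iv: iv.start
    )
    starts = np.array([iv.start for iv in ivs], dtype=np.int64)
    ends = np.array([iv.end for iv in ivs], dtype=np.int64)
    return starts, ends


def island_membership(cpgs: pd.DataFrame, genome: SimGenomeModel) -> np.ndarray:
    """Boolean array: does each dyad's C position fall inside an island."""
    out = np.zeros(len(cpgs), dtype=bool)
    for chrom, idx in cpgs.groupby("chrom", sort=False).groups.items():
        starts, ends = _island_arrays(genome, str(chrom))
        if len(starts) == 0:
            continue
        pos0 = cpgs.loc[idx, "pos"].to_numpy() - 1  # 0-based
        k = np.searchsorted(starts, pos0, side="right") - 1
        hit = (k >= 0) & (pos0 < ends[np.clip(k, 0, None)])
        out[cpgs.index.get_indexer(idx)] = hit
    return out


def place_cpgs(genome: SimGenomeModel, seed: int = 0) -> pd.DataFrame:
    """Draw CpG dyad positions along every chromosome.

    A Poisson process with mean spacing ``cpg_spacing_mean`` outside islands
    and ``cpg_spacing_mean / multiplier`` inside; returns a frame with
    columns ``chrom`` and ``pos`` (1-based position of the plus-strand C;
    the dyad occupies pos and pos+1).  Deterministic given the seed.
    """
    rng = _substream(seed, 0xC9)
    frames = []
    for chrom, length in genome.chromosomes:
        if length < genome.cpg_spacing_mean:
            raise CfMethError(
                f"chromosome {chrom!r} (length {length}) shorter than one "
                f"CpG spacing unit ({genome.cpg_spacing_mean})"
            )
        starts, ends = _island_arrays(genome, chrom)
        # Segment boundaries (0-based): alternating gap / island.
        bounds = [0]
        for s, e in zip(starts, ends):
            bounds += [int(s), int(e)]
        bounds.append(length)
        positions = []
        for i in range(len(bounds) - 1):
            seg_start, seg_end = bounds[i], bounds[i + 1]
            if seg_end - seg_start < 2:
                continue
            inside = i % 2 == 1  # odd segments are islands
            spacing = genome.cpg_spacing_mean
            if inside:
                spacing /= genome.island_cpg_density_multiplier
            n = rng.poisson((seg_end - seg_start) / spacing)
            if n == 0:
                continue
            pos = np.unique(rng.integers(seg_start + 1, seg_end, size=n))
            positions.append(pos)
        if not positions:
            continue
        pos = np.concatenate(positions)
        pos.sort()
        # Dyads occupy two bases; drop positions clashing with the previous dyad.
        keep = np.ones(len(pos), dtype=bool)
        keep[1:] = np.diff(pos) >= 2
        pos = pos[keep]
        pos = pos[pos <= length - 1]
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    if not frames:
        raise CfMethError("no CpGs placed; genome too sparse")
    return pd.concat(frames, ignore_index=True)


def draw_landscape(
    cpgs: pd.DataFrame,
    genome: SimGenomeModel,
    background_beta: tuple[float, float] = (6.8, 1.2),
    island_beta: tuple[float, float] = (0.75, 14.25),
    seed: int = 0,
) -> np.ndarray:
    """Per-dyad baseline methylation proportions (shared across pools)."""
    rng = _substream(seed, 0x1A)
    in_island = island_membership(cpgs, genome)
    p = np.empty(len(cpgs))
    p[~in_island] = rng.beta(*background_beta, size=int((~in_island).sum()))
    p[in_island] = rng.beta(*island_beta, size=int(in_island.sum()))
    return p


def _beta_binomial(
    rng: np.random.Generator, cov: np.ndarray, p: np.ndarray, rho: float
) -> np.ndarray:
    if rho == 0:
        return rng.binomial(cov, p)
    pc = np.clip(p, 1e-9, 1 - 1e-9)
    scale = (1 - rho) / rho
    q = rng.beta(pc * scale, (1 - pc) * scale)
    return rng.binomial(cov, q)


def simulate_pool(
    cpgs: pd.DataFrame,
    genome: SimGenomeModel,
    params: SimPoolParams,
    truth: SimulationTruth | None = None,
    seed: int = 0,
    landscape: np.ndarray | None = None,
) -> PoolMethylome:
    """Simulate one pool's per-cytosine count table.

    ``landscape`` is the shared per-dyad baseline proportion vector; if not
    given, a pool-private one is drawn from this pool's Beta parameters.
    The global hypomethylation shift applies to background (non-island)
    loci only; if this pool is the affected pool of ``truth``, proportions
    inside planted islands are redrawn centred at the planted level.
    """
    rng = _substream(seed, 0x90, hash(params.label) & 0x7FFFFFFF)
    if landscape is None:
        landscape = draw_landscape(
            cpgs, genome, params.background_beta, params.island_beta, seed
        )
    if len(landscape) != len(cpgs):
        raise CfMethError("landscape length does not match CpG count")
    in_island = island_membership(cpgs, genome)
    p = landscape.copy()
    p[~in_island] = np.clip(p[~in_island] - params.global_hypo_shift, 0.0, 1.0)

    if truth is not None and params.label == truth.affected_pool_label:
        genome_islands = {(iv.chrom, iv.start, iv.end) for iv in genome.islands}
        planted = np.zeros(len(cpgs), dtype=bool)
        pos0 = cpgs["pos"].to_numpy() - 1
        chroms = cpgs["chrom"].to_numpy()
        for iv in truth.planted_hotspot_islands:
            if (iv.chrom, iv.start, iv.end) not in genome_islands:
                raise CfMethError(
                    f"planted island {iv.name} [{iv.chrom}:{iv.start}-{iv.end}) "
                    "is not an island of the genome model"
                )
            planted |= (chroms == iv.chrom) & (pos0 >= iv.start) & (pos0 < iv.end)
        lvl = truth.planted_hyper_level
        a = lvl * _PLANT_CONCENTRATION
        b = (1 - lvl) * _PLANT_CONCENTRATION
        # Planted proportions are part of the pool's biology, not of one
        # measurement: derive them from the truth seed so that re-measuring
        # the same pool (e.g. on a second platform) sees the same state.
        rng_plant = _substream(truth.seed, 0xA7, hash(params.label) & 0x7FFFFFFF)
        p[planted] = rng_plant.beta(a, b, size=int(planted.sum()))

    nb_p = params.depth_dispersion / (params.depth_dispersion + params.depth_mean)
    frames = []
    for strand, offset in (("+", 0), ("-", 1)):
        cov = rng.negative_binomial(params.depth_dispersion, nb_p, size=len(cpgs))
        meth = np.zeros(len(cpgs), dtype=np.int64)
        nz = cov > 0
        meth[nz] = _beta_binomial(rng, cov[nz], p[nz], params.overdispersion_rho)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": cpgs["chrom"],
                    "pos": cpgs["pos"] + offset,
                    "strand": strand,
                    "meth": meth,
                    "unmeth": cov - meth,
                }
            )
        )
    return PoolMethylome(params.label, pd.concat(frames, ignore_index=True))


def default_pool_params(
    depths: Sequence[float] = (7.4, 9.6, 16.9),
    shift: float = 0.15,
    rho: float = 0.02,
    labels: Sequence[str] = ("H", "DFS", "MBC"),
    affected: str = "MBC",
) -> list[SimPoolParams]:
    """The three-pool study design: healthy, disease-free survivor, and a
    metastatic-cancer analogue carrying the global hypomethylation shift."""
    return [
        SimPoolParams(
            label=lab,
            depth_mean=d,
            global_hypo_shift=shift if lab == affected else 0.0,
            overdispersion_rho=rho,
        )
        for lab, d in zip(labels, depths)
    ]


@dataclass
class StudyData:
    """Everything one simulated study produces."""

    cpgs: pd.DataFrame
    landscape: np.ndarray
    pools: dict[str, PoolMethylome]
    truth: SimulationTruth


def simulate_study(
    genome: SimGenomeModel,
    pool_params: Sequence[SimPoolParams],
    seed: int = 0,
    n_planted: int = 10,
    planted_hyper_level: float = 0.9,
    affected: str = "MBC",
) -> StudyData:
    """Simulate a full multi-pool study with planted hotspots.

    Returns the dyad table, the shared landscape, one methylome per pool,
    and the truth manifest.  All randomness derives from ``seed``; the
    landscape is drawn once and shared by every pool.
    """
    cpgs = place_cpgs(genome, seed)
    base = next((p for p in pool_params if p.label != affected), pool_params[0])
    landscape = draw_landscape(
        cpgs, genome, base.background_beta, base.island_beta, seed
    )
    rng = _substream(seed, 0x7E)
    if n_planted > len(genome.islands):
        raise CfMethError("more planted hotspots requested than islands exist")
    idx = sorted(rng.choice(len(genome.islands), size=n_planted, replace=False))
    truth = SimulationTruth(
        planted_hotspot_islands=[genome.islands[i] for i in idx],
        planted_hyper_level=planted_hyper_level,
        affected_pool_label=affected,
        seed=int(seed),
        pool_params=list(pool_params),
    )
    pools = {
        p.label: simulate_pool(cpgs, genome, p, truth, seed, landscape)
        for p in pool_params
    }
    return StudyData(cpgs=cpgs, landscape=landscape, pools=pools, truth=truth)
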