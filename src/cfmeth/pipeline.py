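"""End-to-end orchestration: simulate (or load) -> similarity -> differential
methylation -> context annotation -> hotspot calling -> concordance.

A run is a pure function of its validated configuration and seed: rerunning
with the same config and seed reproduces every output table byte for byte.
The manifest therefore records only deterministic content (parameters,
seeds, per-stage record counts, artifact checksums); wall-clock timings go
to the log.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from time import perf_counter
from typing import Any, Mapping

import pandas as pd
import yaml

from . import io as _io
from .annotate import annotate_dml, summarize_contexts
from .concordance import concordance_stats, pair_platforms, per_group_test
from .core import AnnotationTrack, CfMethError, ConfigError, PoolMethylome
from .diffmeth import DiffMethParams, call_dml, direction_summary
from .hotspots import HotspotParams, call_hotspots, intersect_calls, score_recovery
from .similarity import similarity_report
from .simulate import (
    SimPoolParams,
    StudyData,
    default_pool_params,
    emit_truth,
    make_genome,
    simulate_pool,
    simulate_study,
)
from .version import __version__

logger = logging.getLogger(__name__)

#: comparisons run by the full pipeline, as (case, control) labels
DEFAULT_COMPARISONS = (("MBC", "H"), ("MBC", "DFS"), ("H", "DFS"))


@dataclass
class SimulationConfig:
    chrom_name: str = "chr1"
    chrom_length: int = 2_000_000
    n_islands: int = 200
    island_length: int = 600
    cpg_spacing_mean: float = 130.0
    island_cpg_density_multiplier: float = 5.0
    n_genes: int = 100
    depths: tuple[float, float, float] = (7.4, 9.6, 16.9)
    global_hypo_shift: float = 0.15
    overdispersion_rho: float = 0.02
    n_planted: int = 10
    planted_hyper_level: float = 0.9
    affected_pool: str = "MBC"
    #: platform-2 (deep targeted) depth multiplier for the concordance stage
    platform2_depth: float = 2500.0
    n_validation_amplicons: int = 4


@dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    seed: int = 0
    outdir: Path = Path("cfmeth_out")
    pools: dict[str, Path] = field(default_factory=dict)     # label -> counts file
    tracks: dict[str, Path] = field(default_factory=dict)    # category -> BED
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    diff: DiffMethParams = field(default_factory=DiffMethParams)
    hotspots: HotspotParams = field(default_factory=HotspotParams)
    comparisons: tuple = DEFAULT_COMPARISONS


def validate_config(raw: Mapping[str, Any] | str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a mapping or a YAML file.

    Defaults follow the standard pooled-WGBS thresholds (coverage 5,
    DMV 20, P 0.05, hotspot rule 8 loci at DMV >= 50).  Errors name the
    offending key; referenced files must exist.
    """
    if isinstance(raw, (str, Path)):
        with open(raw) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration must be a mapping")

    known = {"seed", "outdir", "pools", "tracks", "simulation", "diff", "hotspots"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")

    def build(cls, block: Mapping[str, Any], name: str):
        try:
            return cls(**dict(block))
        except TypeError as exc:
            raise ConfigError(f"{name}: {exc}") from None
        except CfMethError as exc:
            raise ConfigError(f"{name}: {exc}") from None

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        raise ConfigError(f"seed: must be a non-negative integer, got {seed!r}")

    sim_block = dict(raw.get("simulation") or {})
    if "depths" in sim_block:
        sim_block["depths"] = tuple(sim_block["depths"])
    cfg = PipelineConfig(
        seed=seed,
        outdir=Path(raw.get("outdir", "cfmeth_out")),
        pools={k: Path(v) for k, v in (raw.get("pools") or {}).items()},
        tracks={k: Path(v) for k, v in (raw.get("tracks") or {}).items()},
        simulation=build(SimulationConfig, sim_block, "simulation"),
        diff=build(DiffMethParams, raw.get("diff") or {}, "diff"),
        hotspots=build(HotspotParams, raw.get("hotspots") or {}, "hotspots"),
    )
    for label, path in {**cfg.pools, **cfg.tracks}.items():
        if not path.exists():
            raise ConfigError(f"{label}: file not found: {path}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: PipelineConfig):
    """Either load pools/tracks from files or simulate the study."""
    if cfg.pools:
        if not cfg.tracks:
            raise ConfigError("file-based runs require annotation tracks (at least CPGI)")
        pools = {}
        for label, path in cfg.pools.items():
            reader = (
                _io.read_coverage_file
                if path.suffix in (".cov", ".coverage")
                else _io.read_cytosine_report
            )
            pools[label] = reader(path, label=label)
        tracks = {
            cat: _io.read_bed_track(path, cat) for cat, path in cfg.tracks.items()
        }
        _check_namespaces(pools, tracks)
        return None, None, pools, tracks, None

    s = cfg.simulation
    genome, tracks = make_genome(
        seed=cfg.seed,
        chrom_name=s.chrom_name,
        chrom_length=s.chrom_length,
        n_islands=s.n_islands,
        island_length=s.island_length,
        cpg_spacing_mean=s.cpg_spacing_mean,
        island_cpg_density_multiplier=s.island_cpg_density_multiplier,
        n_genes=s.n_genes,
    )
    params = default_pool_params(
        depths=s.depths, shift=s.global_hypo_shift, rho=s.overdispersion_rho,
        affected=s.affected_pool,
    )
    study = simulate_study(
        genome, params, seed=cfg.seed, n_planted=s.n_planted,
        planted_hyper_level=s.planted_hyper_level, affected=s.affected_pool,
    )
    return genome, study, study.pools, tracks, study.truth


def _check_namespaces(pools, tracks) -> None:
    pool_chroms = set().union(*(p.chromosomes() for p in pools.values()))
    track_chroms = set().union(*(t.chromosomes() for t in tracks.values()))
    if pool_chroms and track_chroms and not pool_chroms & track_chroms:
        raise ConfigError(
            f"chromosome namespaces disjoint between pools ({sorted(pool_chroms)[:3]}...) "
            f"and tracks ({sorted(track_chroms)[:3]}...); no silent renaming is applied"
        )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage, write all artifacts, return the run manifest."""
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "diff": {**asdict(cfg.diff),
                     "exclude_chromosomes": sorted(cfg.diff.exclude_chromosomes)},
            "hotspots": asdict(cfg.hotspots),
            "simulation": None if cfg.pools else asdict(cfg.simulation),
        },
        "stages": {},
        "artifacts": {},
    }
    artifacts: dict[str, Path] = {}

    def record(stage: str, t0: float, **counts) -> None:
        manifest["stages"][stage] = counts
        logger.info("stage %s done in %.2fs: %s", stage, perf_counter() - t0, counts)

    # --- inputs -----------------------------------------------------------
    t0 = perf_counter()
    genome, study, pools, tracks, truth = _load_inputs(cfg)
    if study is not None:
        for label, pool in pools.items():
            p = out / f"{label}.CpG_report.txt"
            _io.write_cytosine_report(pool, p)
            artifacts[f"pool_{label}"] = p
        _io.write_bed_track(tracks["CPGI"], out / "islands.bed")
        artifacts["islands"] = out / "islands.bed"
        emit_truth(truth, out / "truth.json")
        artifacts["truth"] = out / "truth.json"
    record(
        "inputs", t0,
        n_pools=len(pools), n_loci_per_pool={k: len(v) for k, v in pools.items()},
        simulated=study is not None,
    )

    # --- similarity -------------------------------------------------------
    t0 = perf_counter()
    sim_report = similarity_report(
        [pools[label] for label in sorted(pools)],
        min_coverage=cfg.diff.min_coverage_per_group,
    )
    _io.write_summary_json(sim_report, out / "similarity.json")
    artifacts["similarity"] = out / "similarity.json"
    record("similarity", t0, n_common_loci=sim_report["n_common_loci"])

    # --- differential methylation + annotation ----------------------------
    comparisons = [
        (case, ctrl) for case, ctrl in cfg.comparisons if case in pools and ctrl in pools
    ]
    dml_tables: dict[str, pd.DataFrame] = {}
    context_summaries: dict[str, dict] = {}
    for case, ctrl in comparisons:
        t0 = perf_counter()
        name = f"{case}_vs_{ctrl}"
        records = call_dml(pools[case], pools[ctrl], cfg.diff)
        records = annotate_dml(records, tracks) if len(records) else records.assign(contexts="")
        dml_tables[name] = records
        path = out / f"dml_{name}.tsv"
        _io.write_dml_table(records, path, comparison=name, seed=cfg.seed)
        artifacts[f"dml_{name}"] = path
        context_summaries[name] = summarize_contexts(records) if len(records) else {}
        record(
            f"diff_{name}", t0,
            n_tested=records.attrs.get("n_tested", 0),
            n_dml=len(records),
            direction=direction_summary(records) if len(records) else None,
        )
    _io.write_summary_json(context_summaries, out / "context_summaries.json")
    artifacts["context_summaries"] = out / "context_summaries.json"

    # --- hotspot calling --------------------------------------------------
    t0 = perf_counter()
    cpgi = tracks.get("CPGI")
    if cpgi is None:
        raise ConfigError("hotspot calling requires a CPGI track")
    affected = cfg.simulation.affected_pool if truth is not None else comparisons[0][0]
    hotspot_calls = {}
    for case, ctrl in comparisons:
        if case != affected:
            continue
        name = f"{case}_vs_{ctrl}"
        calls = call_hotspots(dml_tables[name], cpgi, cfg.hotspots)
        hotspot_calls[name] = calls
        path = out / f"hotspots_{name}.bed"
        _io.write_hotspot_bed(calls, path, comparison=name)
        artifacts[f"hotspots_{name}"] = path
    consensus = None
    if len(hotspot_calls) >= 2:
        names = sorted(hotspot_calls)
        consensus = intersect_calls(hotspot_calls[names[0]], hotspot_calls[names[1]])
        path = out / "hotspots_consensus.bed"
        _io.write_hotspot_bed(consensus, path, comparison="consensus")
        artifacts["hotspots_consensus"] = path
    recovery = None
    if truth is not None and hotspot_calls:
        primary = consensus if consensus is not None else next(iter(hotspot_calls.values()))
        recovery = score_recovery(primary, truth)
        _io.write_summary_json(recovery, out / "hotspot_recovery.json")
        artifacts["hotspot_recovery"] = out / "hotspot_recovery.json"
    record(
        "hotspots", t0,
        n_calls={k: len(v) for k, v in hotspot_calls.items()},
        n_consensus=None if consensus is None else len(consensus),
        recovery=recovery,
    )

    # --- concordance (simulation mode: deep second platform) --------------
    if study is not None and truth is not None and truth.planted_hotspot_islands:
        t0 = perf_counter()
        s = cfg.simulation
        amplicons = truth.planted_hotspot_islands[: s.n_validation_amplicons]
        deep_seed = cfg.seed + 10_007
        pairs = []
        for label, pool in pools.items():
            base = next(p for p in truth.pool_params if p.label == label)
            deep = simulate_pool(
                study.cpgs, genome,
                SimPoolParams(
                    label=label, depth_mean=s.platform2_depth,
                    depth_dispersion=base.depth_dispersion,
                    background_beta=base.background_beta,
                    island_beta=base.island_beta,
                    global_hypo_shift=base.global_hypo_shift,
                    overdispersion_rho=base.overdispersion_rho,
                ),
                truth, deep_seed, study.landscape,
            )
            pairs.append(pair_platforms(pool, deep, amplicons, pool_label=label))
        all_pairs = pd.concat(pairs, ignore_index=True)
        stats = concordance_stats(all_pairs)
        ctrl_label = next(
            (ctrl for case, ctrl in comparisons if case == affected), comparisons[0][1]
        )
        amplicon_tests = per_group_test(pools[affected], pools[ctrl_label], amplicons)
        stats["amplicon_tests"] = amplicon_tests.round(12).to_dict(orient="records")
        _io.write_summary_json(stats, out / "concordance.json")
        artifacts["concordance"] = out / "concordance.json"
        all_pairs.to_csv(out / "paired_measurements.tsv", sep="\t", index=False,
                         float_format="%.10g")
        artifacts["paired_measurements"] = out / "paired_measurements.tsv"
        record(
            "concordance", t0,
            n_pairs=len(all_pairs), pearson_r=stats["pearson_r"],
            r_squared=stats["r_squared"],
        )

    manifest["artifacts"] = {
        key: {"path": str(path.relative_to(out)), "sha256": _sha256(path)}
        for key, path in sorted(artifacts.items())
    }
    _io.write_summary_json(manifest, out / "manifest.json")
    return manifest
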