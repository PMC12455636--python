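"""End-to-end orchestration: simulate -> demultiplex -> call -> quantify.

A single YAML config drives a reproducible run. One global seed expands
deterministically into per-stage seeds, so any stage can be rerun in
isolation; every filtering step logs its attrition, which is the audit trail
of the analysis. Outputs per run: the fixture copies, pooled FASTQ + truth
table, assignment TSV, per-pool GFF3 and calls, abundance/top-N/gate-profile
tables, and a per-pool summary TSV that is byte-identical across reruns of
the same config.
"""

from __future__ import annotations

import difflib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import calling, demux, fixtures, parts, quantify, simulate

log = logging.getLogger("sortscreen")


class ConfigError(ValueError):
    pass


@dataclass
class GateConfig:
    t_low: float = 2.7
    t_mid: float = 3.2
    t_high: float = 4.2


@dataclass
class ErrorConfig:
    sub_rate: float = 0.03
    ins_rate: float = 0.02
    del_rate: float = 0.03
    truncation_prob: float = 0.0
    chimera_prob: float = 0.0


@dataclass
class SimulateConfig:
    orf_libraries: list[str] = field(default_factory=lambda: list(fixtures.SEQUENCED_LIBRARIES))
    n_cells: int = 20_000
    reads_per_pool: int = 500
    sigma: float = 0.3
    gates: GateConfig = field(default_factory=GateConfig)
    errors: ErrorConfig = field(default_factory=ErrorConfig)
    display_mode: str = "display"


@dataclass
class DemuxConfig:
    max_dist: int = 4
    window: int = 150
    min_len: int = 2000
    marker_part: str = "CBM"
    marker_min_identity: float = 0.8


@dataclass
class CallConfig:
    min_identity: float = 0.8
    min_coverage: float = 0.8


@dataclass
class QuantifyConfig:
    top: int = 5
    min_full_reads: int = 1000


@dataclass
class PathsConfig:
    parts_fasta: str = ""
    parts_manifest: str = ""
    barcodes: str = ""


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run_out"
    fixture_seed: int = fixtures.FIXTURE_SEED
    paths: PathsConfig = field(default_factory=PathsConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    demux: DemuxConfig = field(default_factory=DemuxConfig)
    call: CallConfig = field(default_factory=CallConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)

    def validate(self) -> None:
        if self.demux.max_dist < 0:
            raise ConfigError("demux.max_dist must be >= 0")
        if self.demux.min_len < 0:
            raise ConfigError("demux.min_len must be >= 0")
        for name in ("min_identity", "min_coverage"):
            v = getattr(self.call, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"call.{name} must lie in (0, 1], got {v}")
        if not (self.simulate.gates.t_low < self.simulate.gates.t_mid < self.simulate.gates.t_high):
            raise ConfigError("gate thresholds must be strictly increasing")
        if self.simulate.reads_per_pool < 1 or self.simulate.n_cells < 1:
            raise ConfigError("reads_per_pool and n_cells must be >= 1")
        for p in (self.paths.parts_fasta, self.paths.parts_manifest, self.paths.barcodes):
            if p and not Path(p).exists():
                raise ConfigError(f"configured path does not exist: {p}")


_NESTED = {
    "paths": PathsConfig,
    "simulate": SimulateConfig,
    "demux": DemuxConfig,
    "call": CallConfig,
    "quantify": QuantifyConfig,
    "gates": GateConfig,
    "errors": ErrorConfig,
}


def _build(cls, data: Mapping[str, Any], context: str):
    known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown key {context}{key!r}{suggestion}")
        if key in _NESTED and isinstance(value, Mapping):
            kwargs[key] = _build(_NESTED[key], value, f"{context}{key}.")
        else:
            kwargs[key] = value
    return cls(**kwargs)


def validate_config(path_or_dict: str | Path | Mapping[str, Any]) -> RunConfig:
    """Parse and strictly validate a run config; defaults are filled in and
    unknown keys are rejected with a closest-match suggestion."""
    if isinstance(path_or_dict, Mapping):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    config = _build(RunConfig, raw, "")
    config.validate()
    return config


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Expand the global seed into independent per-stage seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns the output manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config_used.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    stage = "setup"
    try:
        # --- fixtures / references -----------------------------------------
        if config.paths.parts_fasta:
            registry = parts.load_registry(config.paths.parts_fasta, config.paths.parts_manifest)
            barcodes = pd.read_csv(config.paths.barcodes, sep="\t", dtype=str)
        else:
            fix = fixtures.write_fixtures(out / "fixtures", seed=config.fixture_seed)
            registry = parts.load_registry(fix["parts_fasta"], fix["parts_manifest"])
            barcodes = pd.read_csv(fix["barcodes"], sep="\t", dtype=str)
        marker = registry[config.demux.marker_part].sequence

        stage = "simulate"
        seeds = _stage_seeds(config.seed, 4)
        reads, truth_designs = _simulate_stage(config, registry, barcodes, seeds[0], out)

        stage = "demux"
        assignments = demux.demultiplex(reads, barcodes, config.demux.max_dist, config.demux.window)
        n_assigned = sum(a.status == demux.ASSIGNED for a in assignments)
        log.info("demux: %d/%d reads assigned", n_assigned, len(reads))
        assignments = demux.length_filter(assignments, reads, config.demux.min_len)
        n_len = sum(a.status == demux.ASSIGNED for a in assignments)
        log.info("length filter (>=%d nt): %d kept", config.demux.min_len, n_len)
        oriented, assignments = demux.orient_reads(
            reads, assignments, marker, config.demux.marker_min_identity
        )
        log.info("orientation: %d oriented", len(oriented))
        demux.assignments_to_frame(assignments).to_csv(out / "assignments.tsv", sep="\t", index=False)

        stage = "call"
        hits_by_read, calls = calling.call_reads(
            oriented, registry, config.call.min_identity, config.call.min_coverage
        )
        calling.emit_gff(hits_by_read, out / "annotations.gff3")
        calling.calls_to_frame(calls).to_csv(out / "calls.tsv", sep="\t", index=False)
        n_full = sum(c.call_status == calling.FULL for c in calls)
        log.info("calling: %d/%d full calls", n_full, len(calls))

        stage = "quantify"
        manifest = _quantify_stage(config, registry, assignments, calls, reads, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["config"] = str(out / "config_used.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _simulate_stage(config, registry, barcodes, seed, out):
    promoters = registry.by_role("promoter")
    sps = registry.by_role("sp_flag")
    fusion = registry.by_role("fusion_4a")[0]
    cassette_id = (
        "cassette_display" if config.simulate.display_mode == "display" else "cassette_secrete"
    )
    cassette = registry[cassette_id]
    gates = simulate.GateModel(
        config.simulate.gates.t_low, config.simulate.gates.t_mid, config.simulate.gates.t_high
    )
    errors = simulate.ErrorModel(**asdict(config.simulate.errors))

    sub_seeds = _stage_seeds(seed, 2 * len(config.simulate.orf_libraries) + 1)
    all_reads: list[simulate.ReadRecord] = []
    all_designs: dict[str, list[parts.ConstructDesign]] = {}
    for i, orf in enumerate(config.simulate.orf_libraries):
        cds = registry[orf]
        designs = parts.enumerate_design_space(
            promoters, sps, cds, fusion, cassette, mode=config.simulate.display_mode
        )
        all_designs[orf] = designs
        model = simulate.assign_fluorescence(designs, seed=sub_seeds[-1], sigma=config.simulate.sigma)
        composition = {d.genotype_key: 1.0 / len(designs) for d in designs}
        pools = simulate.sort_cells(model, gates, composition, config.simulate.n_cells,
                                    seed=sub_seeds[2 * i])
        lib_barcodes = barcodes[
            (barcodes["role"] == "rev") | (barcodes["pool"] == orf)
        ]
        reads = simulate.simulate_reads(
            pools, designs, lib_barcodes, errors, config.simulate.reads_per_pool,
            seed=sub_seeds[2 * i + 1], orf_pool=orf,
        )
        all_reads.extend(reads)
        log.info("simulate: %s -> %d reads", orf, len(reads))

    simulate.write_fastq(all_reads, out / "reads.fastq")
    simulate.write_truth(all_reads, out / "truth.tsv")
    return all_reads, all_designs


def _quantify_stage(config, registry, assignments, calls, reads, out):
    promoter_order = [p.part_id for p in registry.by_role("promoter")]
    sp_order = [p.part_id for p in registry.by_role("sp_flag")]
    call_by_read = {c.read_id: c for c in calls}
    assigned = [a for a in assignments if a.status == demux.ASSIGNED]

    matrices_dir = out / "matrices"
    matrices_dir.mkdir(exist_ok=True)
    summary_rows = []
    matrices: dict[tuple[str, str], quantify.AbundanceMatrix] = {}
    # reads demoted by the length/orientation filters keep their pool labels,
    # so per-pool attrition at every stage is recoverable from final statuses
    ever_assigned = [
        a for a in assignments
        if a.orf_pool and a.status in (demux.ASSIGNED, "too_short", "no_marker", "chimeric")
    ]
    pools = sorted({(a.orf_pool, a.gate_pool) for a in ever_assigned})
    for pool in pools:
        in_pool = [a for a in ever_assigned if (a.orf_pool, a.gate_pool) == pool]
        n_assigned = len(in_pool)
        n_len = sum(a.status != "too_short" for a in in_pool)
        pool_reads = [a.read_id for a in in_pool if a.status == demux.ASSIGNED]
        pool_calls = [call_by_read[r] for r in pool_reads if r in call_by_read]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # depth warnings surface via log instead
            matrix = quantify.count_genotypes(
                pool_calls, pool, promoter_order, sp_order,
                min_full_reads=config.quantify.min_full_reads,
            )
        if matrix.n_full_reads < config.quantify.min_full_reads:
            log.warning("pool %s: %d full reads below floor %d",
                        pool, matrix.n_full_reads, config.quantify.min_full_reads)
        matrices[pool] = matrix
        quantify.export_heatmap_table(matrix, matrices_dir / f"{pool[0]}_{pool[1]}.tsv")
        top = quantify.top_n(matrix, config.quantify.top) if matrix.n_full_reads else []
        top_label = f"{top[0][0][0]}__{top[0][0][1]}" if top else ""
        summary_rows.append(
            {
                "orf_pool": pool[0],
                "gate_pool": pool[1],
                "assigned": n_assigned,
                "length_passed": n_len,
                "oriented": len(pool_calls),
                "full_calls": matrix.n_full_reads,
                "top_genotype": top_label,
                "top_fraction": round(top[0][1], 6) if top else 0.0,
            }
        )

    profiles_dir = out / "profiles"
    profiles_dir.mkdir(exist_ok=True)
    orf_pools = sorted({p[0] for p in matrices})
    for orf in orf_pools:
        gate_ms = {g: m for (o, g), m in matrices.items() if o == orf}
        if set(gate_ms) == set(quantify.GATE_WEIGHTS):
            profile = quantify.enrichment_across_gates(gate_ms)
            profile.to_csv(profiles_dir / f"{orf}.tsv", sep="\t", index=False)

    summary = pd.DataFrame(summary_rows)
    summary.insert(0, "reads_in", len(reads))
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    return {
        "reads": str(out / "reads.fastq"),
        "truth": str(out / "truth.tsv"),
        "assignments": str(out / "assignments.tsv"),
        "calls": str(out / "calls.tsv"),
        "gff": str(out / "annotations.gff3"),
        "summary": str(out / "summary.tsv"),
        "matrices": sorted(str(p) for p in matrices_dir.glob("*.tsv")),
        "profiles": sorted(str(p) for p in profiles_dir.glob("*.tsv")),
    }
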