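"""End-to-end runs: configuration schema, seeding, logging, reports.

A run is described by a single TOML/JSON config validated against a strict
schema (unknown keys are errors). One global seed is expanded into
independent per-stage seeds through ``numpy.random.SeedSequence(seed,
spawn_key=(stage,))``, so stages rerun standalone reproduce the pipeline
exactly and the whole run is bit-deterministic.

Stage order: simulate → map (to the lysogen) → quantify → excise → map (to
the prophage-free reference) → staircase fit → detection. A stage failure
marks the report and skips downstream stages.
"""
from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from . import induction, lateral, mapping, mlva, synthetic

logger = logging.getLogger(__name__)

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    tomllib = None


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class HostConfig(_Strict):
    id: str = "host"
    length_bp: int = 450_000
    gc_fraction: float = synthetic.DEFAULT_GC
    circular: bool = False


class ProphageConfig(_Strict):
    id: str
    length_bp: int
    attb_pos: int
    orientation: Literal["+", "-"] = "-"
    pac_offset_bp: int = 0
    packaging_mode: Literal["excised_circle", "headful_in_situ"] = "excised_circle"
    induction_weight: float = 1.0
    in_situ_prob: float = 0.0
    max_headfuls: int = 1
    continuation_prob: float = 0.0

    def to_spec(self) -> synthetic.ProphageSpec:
        return synthetic.ProphageSpec(**self.model_dump())


class SimulateConfig(_Strict):
    host: HostConfig = HostConfig()
    prophages: list[ProphageConfig] = []
    att_site_seq: str = synthetic.DEFAULT_ATT_SITE
    n_molecules: int = 10_000
    host_contamination_frac: Optional[float] = None
    host_read_share: Optional[float] = None  # alternative: target READ share
    host_fragment_len: int = 5000

    @model_validator(mode="after")
    def _one_contamination_spec(self) -> "SimulateConfig":
        if self.host_contamination_frac is not None and self.host_read_share is not None:
            raise ValueError(
                "set host_contamination_frac or host_read_share, not both"
            )
        if self.host_contamination_frac is None and self.host_read_share is None:
            self.host_contamination_frac = 0.02
        return self


class ReadsConfig(_Strict):
    read_len: int = 100
    n_reads: int = 50_000
    error_rate: float = 0.001


class MapperConfig(_Strict):
    k: int = 21
    max_mismatch: int = 2


class QuantifyConfig(_Strict):
    fold_threshold: float = induction.DEFAULT_FOLD_THRESHOLD
    background_margin_bp: int = induction.DEFAULT_BACKGROUND_MARGIN_BP


class StaircaseConfig(_Strict):
    target_prophage: Optional[str] = None  # default: the only in-situ-capable one
    flank_bp: int = 195_000
    min_segment_bp: int = 5000
    penalty_frac: float = 0.02
    background_factor: float = 1.5
    min_steps: int = 2
    min_asymmetry: float = 3.0
    pac_motif: str = lateral.DEFAULT_PAC_MOTIF
    motif_window_bp: int = 2000


class RunConfig(_Strict):
    seed: int = 0
    simulate: SimulateConfig = SimulateConfig()
    reads: ReadsConfig = ReadsConfig()
    mapper: MapperConfig = MapperConfig()
    quantify: QuantifyConfig = QuantifyConfig()
    staircase: StaircaseConfig = StaircaseConfig()
    mlva_panel: Optional[str] = None  # path to a VNTR panel TSV


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".toml":
        data = tomllib.loads(text)
    elif path.suffix == ".json":
        data = json.loads(text)
    else:
        raise ValueError(f"config must be .toml or .json, got {path.suffix}")
    return RunConfig.model_validate(data)


def bundled_config(name: str) -> RunConfig:
    """Load one of the configs shipped with the package (lateral, null,
    induction_two_phage, induction_five_phage)."""
    from importlib.resources import files

    res = files("lysovir") / "configs" / f"{name}.toml"
    if not res.is_file():
        raise KeyError(f"no bundled config named {name!r}")
    return RunConfig.model_validate(tomllib.loads(res.read_text()))


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Per-stage seed derivation (documented, stable)."""
    stages = ["host", "lysogen", "virions", "reads"]
    return np.random.SeedSequence(seed, spawn_key=(stages.index(stage),))


def _seed_int(seed: int, stage: str) -> int:
    return int(stage_seed(seed, stage).generate_state(1)[0] % (2**31))


def resolve_contamination(cfg: RunConfig, specs: list[synthetic.ProphageSpec]) -> float:
    if cfg.simulate.host_contamination_frac is not None:
        return cfg.simulate.host_contamination_frac
    return synthetic.host_fraction_for_read_share(
        specs,
        cfg.simulate.host_read_share,
        cfg.simulate.host_fragment_len,
        cfg.reads.read_len,
    )


def simulate_reads(cfg: RunConfig, seed: int | None = None):
    """Run just the simulation stage; returns (specs, lysogen, reads)."""
    seed = cfg.seed if seed is None else seed
    specs = [p.to_spec() for p in cfg.simulate.prophages]
    host = synthetic.generate_host(
        cfg.simulate.host.length_bp,
        cfg.simulate.host.gc_fraction,
        _seed_int(seed, "host"),
        id=cfg.simulate.host.id,
        circular=cfg.simulate.host.circular,
    )
    lysogen = synthetic.build_lysogen(
        host, specs, cfg.simulate.att_site_seq, _seed_int(seed, "lysogen")
    )
    molecules = synthetic.simulate_virions(
        lysogen,
        specs,
        cfg.simulate.n_molecules,
        resolve_contamination(cfg, specs),
        cfg.simulate.host_fragment_len,
        _seed_int(seed, "virions"),
    )
    reads = synthetic.molecules_to_reads(
        molecules,
        lysogen,
        cfg.reads.read_len,
        cfg.reads.n_reads,
        cfg.reads.error_rate,
        _seed_int(seed, "reads"),
    )
    return specs, lysogen, reads


def run_lateral_analysis(cfg: RunConfig, seed: int | None = None):
    """simulate → excise the target prophage → map reads to the
    prophage-free reference → coverage → staircase fit.

    Returns (fit, truth) where truth echoes the simulated pac geometry.
    """
    specs, lysogen, reads = simulate_reads(cfg, seed)
    target = cfg.staircase.target_prophage
    if target is None:
        in_situ = [s for s in specs if s.packaging_mode == synthetic.HEADFUL_IN_SITU]
        if not in_situ:
            raise ValueError("no in-situ-capable prophage to analyse")
        target = in_situ[0].id
    spec = next(s for s in specs if s.id == target)
    excised, attb = lateral.excise_reference(lysogen, target)
    alns = mapping.map_reads(reads, excised, cfg.mapper.k, cfg.mapper.max_mismatch)
    cov = mapping.coverage_from_alignments(alns, excised)
    fit = lateral.fit_staircase(
        cov,
        attb,
        cfg.staircase.flank_bp,
        lateral.StaircaseParams(
            min_segment_bp=cfg.staircase.min_segment_bp,
            penalty_frac=cfg.staircase.penalty_frac,
            background_factor=cfg.staircase.background_factor,
        ),
    )
    truth = {
        "pac_offset_bp": spec.pac_offset_bp,
        "first_headful_chromosomal_bp": spec.length_bp - spec.pac_offset_bp,
        "length_bp": spec.length_bp,
        "max_headfuls": spec.max_headfuls,
        "continuation_prob": spec.continuation_prob,
        "side": "left" if spec.orientation == "-" else "right",
    }
    return fit, truth


class RunReport(dict):
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self, indent=2, default=str))


def run_pipeline(cfg: RunConfig, out_dir: str | Path, seed: int | None = None) -> RunReport:
    """Execute simulate → map → quantify → lt-detect and aggregate a report.

    ``seed`` overrides the config seed when given.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed
    report = RunReport(
        config=json.loads(cfg.model_dump_json()),
        seed=seed,
        stages={},
        timings={},
    )

    def _fail(stage: str, exc: Exception) -> RunReport:
        logger.error("stage %s failed: %s", stage, exc)
        report["stages"][stage] = {"status": "failed", "error": str(exc)}
        report.to_json(out / "report.json")
        return report

    # --- simulate -----------------------------------------------------
    t0 = time.time()
    try:
        specs = [p.to_spec() for p in cfg.simulate.prophages]
        host = synthetic.generate_host(
            cfg.simulate.host.length_bp,
            cfg.simulate.host.gc_fraction,
            _seed_int(seed, "host"),
            id=cfg.simulate.host.id,
            circular=cfg.simulate.host.circular,
        )
        lysogen = synthetic.build_lysogen(
            host, specs, cfg.simulate.att_site_seq, _seed_int(seed, "lysogen")
        )
        contamination = resolve_contamination(cfg, specs)
        molecules = synthetic.simulate_virions(
            lysogen,
            specs,
            cfg.simulate.n_molecules,
            contamination,
            cfg.simulate.host_fragment_len,
            _seed_int(seed, "virions"),
        )
        reads = synthetic.molecules_to_reads(
            molecules,
            lysogen,
            cfg.reads.read_len,
            cfg.reads.n_reads,
            cfg.reads.error_rate,
            _seed_int(seed, "reads"),
        )
        synthetic.write_fasta(lysogen.genome, out / "lysogen.fasta")
        synthetic.write_fasta(lysogen.excised_host, out / "host.fasta")
        synthetic.write_placements_bed(lysogen, out / "prophages.bed")
        reads.to_fastq(out / "reads.fastq")
        reads.write_truth(out / "truth.tsv")
        synthetic.write_truth_json(
            specs,
            lysogen,
            {
                "seed": seed,
                "n_molecules": cfg.simulate.n_molecules,
                "host_contamination_frac": contamination,
                "host_fragment_len": cfg.simulate.host_fragment_len,
                "read_len": cfg.reads.read_len,
                "n_reads": cfg.reads.n_reads,
                "error_rate": cfg.reads.error_rate,
            },
            out / "truth.json",
        )
        report["stages"]["simulate"] = {
            "status": "ok",
            "n_molecules": len(molecules),
            "n_reads": len(reads),
            "host_contamination_frac": contamination,
            "lysogen_length": len(lysogen.genome),
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        return _fail("simulate", exc)
    report["timings"]["simulate"] = round(time.time() - t0, 2)

    # --- map to lysogen + quantify ------------------------------------
    t0 = time.time()
    try:
        alns = mapping.map_reads(
            reads, lysogen.genome, cfg.mapper.k, cfg.mapper.max_mismatch
        )
        stats = mapping.mapping_stats(alns)
        cov = mapping.coverage_from_alignments(alns, lysogen.genome)
        cov.write_bedgraph(out / "coverage_lysogen.bedgraph")
        intervals = [
            induction.ProphageInterval(pid, lysogen.genome.id, attl, attr)
            for pid, attl, attr in lysogen.placements
        ]
        profile = induction.quantify_induction(
            alns,
            intervals,
            lysogen.genome,
            background_margin_bp=cfg.quantify.background_margin_bp,
            coverage=cov,
        )
        induction.call_activated(profile, intervals, cfg.quantify.fold_threshold)
        profile.to_json(out / "induction.json")
        profile.to_tsv(out / "induction.tsv")
        report["stages"]["quantify"] = {
            "status": "ok",
            "mapping": stats,
            "fractions_of_mapped": profile.fractions,
            "activated": profile.activated,
            "background_depth": profile.background_depth,
        }
    except Exception as exc:  # noqa: BLE001
        return _fail("quantify", exc)
    report["timings"]["quantify"] = round(time.time() - t0, 2)

    # --- lateral transduction -----------------------------------------
    t0 = time.time()
    try:
        target = cfg.staircase.target_prophage
        if target is None:
            in_situ = [s for s in specs if s.packaging_mode == synthetic.HEADFUL_IN_SITU]
            target = in_situ[0].id if in_situ else None
        if target is None:
            report["stages"]["lateral"] = {
                "status": "skipped",
                "reason": "no in-situ-capable prophage and no explicit target",
            }
        else:
            excised, attb = lateral.excise_reference(lysogen, target)
            alns2 = mapping.map_reads(
                reads, excised, cfg.mapper.k, cfg.mapper.max_mismatch
            )
            cov2 = mapping.coverage_from_alignments(alns2, excised)
            cov2.write_bedgraph(out / "coverage_excised.bedgraph")
            fit = lateral.fit_staircase(
                cov2,
                attb,
                cfg.staircase.flank_bp,
                lateral.StaircaseParams(
                    min_segment_bp=cfg.staircase.min_segment_bp,
                    penalty_frac=cfg.staircase.penalty_frac,
                    background_factor=cfg.staircase.background_factor,
                ),
            )
            positive, det_report = lateral.detect_lateral_transduction(
                fit, cfg.staircase.min_steps, cfg.staircase.min_asymmetry
            )
            fit.to_json(out / "staircase.json")
            fit.steps_to_tsv(out / "staircase_steps.tsv")
            (out / "lt_detection.json").write_text(json.dumps(det_report, indent=2))
            motif_hits = []
            if positive and fit.side != "none" and not np.isnan(fit.pac_offset_bp):
                # inferred pac position on the lysogen: pac_offset inside the
                # prophage from the chromosome-proximal end on the staircase side
                attl, attr = lysogen.placement(target)
                pac_pos = (
                    attl + int(fit.pac_offset_bp)
                    if fit.side == "left"
                    else attr - int(fit.pac_offset_bp)
                )
                motif_hits = lateral.scan_pac_motif(
                    lysogen.genome.sequence,
                    pac_pos,
                    cfg.staircase.motif_window_bp,
                    cfg.staircase.pac_motif,
                )
            report["stages"]["lateral"] = {
                "status": "ok",
                "target_prophage": target,
                "detected": positive,
                "side": fit.side,
                "n_steps": fit.n_steps,
                "first_step_bp": fit.first_step_bp,
                "period_bp": fit.period_bp,
                "pac_offset_bp": fit.pac_offset_bp,
                "asymmetry": fit.asymmetry,
                "decay_ratios": fit.decay_ratios,
                "n_motif_hits_near_pac": len(motif_hits),
            }
    except Exception as exc:  # noqa: BLE001
        return _fail("lateral", exc)
    report["timings"]["lateral"] = round(time.time() - t0, 2)

    report.to_json(out / "report.json")
    return report
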