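"""Orchestration: simulate -> trim -> quantify -> switch -> de -> interact.

Each stage reads only files emitted by earlier stages, so a run is fully
reproducible from its config; identical config + seed produces identical
result tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .arm_analysis import (
    ArmCountTable,
    SwitchParams,
    call_arm_switches,
    profile_omega,
    quantify_arms,
    write_switch_calls,
)
from .diff_expr import DEParams, screen_contrast, write_contrast_results
from .interaction import (
    DuplexParams,
    scan_pairs,
    screen_interactions,
    write_interaction_calls,
)
from .io_formats import (
    read_count_matrix,
    read_fasta_sequences,
    read_hairpin_annotation,
    read_sample_sheet,
)
from .read_processing import ReadFilterParams, process_reads, read_fastq, write_fastq
from .synthetic_data import SimConfig, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class StageReport:
    name: str
    outputs: list[str]
    record_counts: dict[str, int]
    wall_seconds: float


@dataclass
class RunReport:
    version: str
    seed: int
    config: dict
    stages: list[StageReport] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "seed": self.seed,
                    "config": self.config,
                    "stages": [vars(s) for s in self.stages],
                },
                fh,
                indent=1,
            )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


_SIM_KEYS = set(SimConfig.__dataclass_fields__)


def _validate_config(config: dict) -> None:
    known_sections = {"sim", "filter", "switch", "de", "duplex", "contrast"}
    unknown = set(config) - known_sections
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    bad_sim = set(config.get("sim", {})) - _SIM_KEYS
    if bad_sim:
        raise ValueError(f"unknown sim keys: {sorted(bad_sim)}")
    # dataclass constructors validate values
    _build_params(config)


def _build_params(config: dict):
    sim = config.get("sim", {})
    sim = {**sim}
    for key in ("accessions", "tissues", "time_points_h"):
        if key in sim:
            sim[key] = tuple(sim[key])
    sim_cfg = SimConfig(**sim)
    filt = ReadFilterParams(adapter3p=sim_cfg.adapter3p, **config.get("filter", {}))
    switch = SwitchParams(**config.get("switch", {}))
    de = DEParams(**config.get("de", {}))
    duplex = DuplexParams(**config.get("duplex", {}))
    return sim_cfg, filt, switch, de, duplex


def run_all(config: dict | str | Path, out_dir: str | Path) -> RunReport:
    """Execute every stage on a synthetic dataset; returns the run report."""
    if not isinstance(config, dict):
        config = load_config(config)
    _validate_config(config)
    sim_cfg, filt_params, switch_params, de_params, duplex_params = _build_params(config)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, seed=sim_cfg.seed, config=config)

    def stage(name: str):
        logger.info("stage %s", name)
        return time.perf_counter()

    # 1. simulate ------------------------------------------------------------
    t0 = stage("simulate")
    sim_dir = out / "sim"
    generate_dataset(sim_cfg, sim_dir)
    samples = read_sample_sheet(sim_dir / "samples.tsv")
    report.stages.append(StageReport(
        "simulate", [str(sim_dir)], {"samples": len(samples)},
        time.perf_counter() - t0))

    # 2. trim + QC -----------------------------------------------------------
    t0 = stage("trim")
    trimmed_dir = out / "trimmed"
    trimmed_dir.mkdir(exist_ok=True)
    kept_by_sample = {}
    library_sizes = {}
    n_in = n_kept = 0
    for s in samples:
        reads = list(read_fastq(sim_dir / "reads" / f"{s.sample_id}.fastq"))
        kept, tally = process_reads(reads, filt_params)
        write_fastq(kept, trimmed_dir / f"{s.sample_id}.fastq")
        kept_by_sample[s.sample_id] = kept
        library_sizes[s.sample_id] = len(kept)
        n_in += len(reads)
        n_kept += len(kept)
    report.stages.append(StageReport(
        "trim", [str(trimmed_dir)], {"reads_in": n_in, "reads_kept": n_kept},
        time.perf_counter() - t0))

    # 3. quantify ------------------------------------------------------------
    t0 = stage("quantify")
    loci, skipped = read_hairpin_annotation(sim_dir / "hairpins.fa",
                                            sim_dir / "arms.gff3")
    arm_counts = quantify_arms(kept_by_sample, loci)
    arm_counts.to_tsv(out / "armcounts.tsv")
    report.stages.append(StageReport(
        "quantify", [str(out / "armcounts.tsv")],
        {"hairpins": len(loci), "skipped": len(skipped)},
        time.perf_counter() - t0))

    # 4. switch --------------------------------------------------------------
    t0 = stage("switch")
    profiles = profile_omega(arm_counts, switch_params)
    switches = call_arm_switches(profiles, samples, switch_params)
    write_switch_calls(switches, out / "switches.tsv")
    report.stages.append(StageReport(
        "switch", [str(out / "switches.tsv")], {"calls": len(switches)},
        time.perf_counter() - t0))

    # 5. differential expression ----------------------------------------------
    t0 = stage("de")
    mirna_mat = read_count_matrix(sim_dir / "counts_mirna.tsv")
    lncrna_mat = read_count_matrix(sim_dir / "abund_lncrna.tsv")
    contrast = config.get("contrast")
    if contrast is None:
        acc, tis = sim_cfg.accessions[0], sim_cfg.tissues[0]
        contrast = {
            "a": [acc, tis, sim_cfg.time_points_h[0]],
            "b": [acc, tis, sim_cfg.time_points_h[-1]],
        }
    cond_a = tuple(contrast["a"])
    cond_b = tuple(contrast["b"])
    label_a = "{},{},{:g}".format(*cond_a)
    label_b = "{},{},{:g}".format(*cond_b)
    group_a = [s.sample_id for s in samples
               if (s.accession, s.tissue, float(s.time_h)) == (cond_a[0], cond_a[1], float(cond_a[2]))]
    group_b = [s.sample_id for s in samples
               if (s.accession, s.tissue, float(s.time_h)) == (cond_b[0], cond_b[1], float(cond_b[2]))]
    mirna_de = screen_contrast(mirna_mat, group_a, group_b, de_params,
                               label_a, label_b)
    lnc_params = DEParams(min_cpm=0.0, min_abs_log2fc=de_params.min_abs_log2fc,
                          max_fdr=de_params.max_fdr,
                          pseudocount=de_params.pseudocount,
                          strict_inequalities=de_params.strict_inequalities)
    lncrna_de = screen_contrast(lncrna_mat, group_a, group_b, lnc_params,
                                label_a, label_b)
    write_contrast_results(mirna_de, out / "de_mirna.tsv")
    write_contrast_results(lncrna_de, out / "de_lncrna.tsv")
    report.stages.append(StageReport(
        "de", [str(out / "de_mirna.tsv"), str(out / "de_lncrna.tsv")],
        {"mirna_features": len(mirna_de), "lncrna_features": len(lncrna_de)},
        time.perf_counter() - t0))

    # 6. interactions ----------------------------------------------------------
    t0 = stage("interact")
    matures = read_fasta_sequences(sim_dir / "matures.fa")
    lncrnas = read_fasta_sequences(sim_dir / "lncrna.fa")
    sites = scan_pairs(matures, lncrnas, duplex_params)
    calls = screen_interactions(mirna_de, lncrna_de, sites)
    write_interaction_calls(calls, out / "interactions.tsv")
    report.stages.append(StageReport(
        "interact", [str(out / "interactions.tsv")],
        {"sites": len(sites), "calls": len(calls)},
        time.perf_counter() - t0))

    for s in report.stages:
        for o in s.outputs:
            p = Path(o)
            if not p.exists():
                raise RuntimeError(f"stage {s.name}: declared output {o} missing")
    report.to_json(out / "run_report.json")
    return report
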