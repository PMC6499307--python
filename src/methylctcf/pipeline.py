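"""End-to-end orchestration: simulate -> analyze -> report.

``run_pipeline`` executes the whole desk-scale analysis on a synthetic
epigenome and writes every intermediate in its standard text format together
with a provenance record (parameters, seed, package version).  Re-running
with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__, io
from .ctcf_sites import consensus_sites, scan_motifs, site_cpg_composition
from .intervals import IntervalSet
from .methylome import call_dmrs, smooth_methylation
from .nucleosomes import differential_occupancy, estimate_nrl, occupancy_track
from .profiles import anchor_profile, estimate_profile_periodicity, normalize_to_common
from .stats import build_predictor_table, expression_linkage, fold_enrichment, roc_auc
from .synthetic import SimulationResult, SyntheticConfig, simulate_all
from .trap import TrapParams, affinity_profile, load_ctcf_motif


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    trap: TrapParams = field(default_factory=TrapParams)
    dmr_window: int = 1000
    dmr_step: int = 100
    dmr_delta: float = 0.10
    occupancy_window: int = 100
    log2_threshold: float = 1.0
    profile_flank: int = 2000

    def __post_init__(self) -> None:
        if self.seed != self.synthetic.seed:
            self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)


@dataclass
class PipelineResult:
    sim: SimulationResult
    site_calls: list
    motif_sites: list
    dmrs: list
    occupancy_regions: list
    nrl: object
    predictor_table: pd.DataFrame
    aucs: dict[str, float]
    linkage: pd.DataFrame
    composition: dict
    summary: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    os.makedirs(config.outdir, exist_ok=True)
    t0 = time.time()
    stage = "simulate"
    try:
        sim = simulate_all(config.synthetic)
        _write_simulation(sim, config.outdir)

        stage = "affinity"
        motif = load_ctcf_motif()
        tracks = {
            chrom: affinity_profile(seq, motif, config.trap, chrom=chrom)
            for chrom, seq in sim.bundle.sequences.items()
        }

        stage = "methylome"
        dmrs = call_dmrs(
            sim.meth_wt, sim.meth_dko,
            window=config.dmr_window, step=config.dmr_step, delta=config.dmr_delta,
            chrom_lengths=sim.bundle.chrom_lengths,
        )
        io.write_intervals(IntervalSet([d.interval for d in dmrs]),
                           os.path.join(config.outdir, "dmrs.bed"))
        smoothed = smooth_methylation(sim.meth_wt, chrom_lengths=sim.bundle.chrom_lengths)
        io.write_bedgraph(smoothed, os.path.join(config.outdir, "meth_wt_smoothed.bedGraph"))

        stage = "nucleosomes"
        chrom_lengths = sim.bundle.chrom_lengths
        occ_wt = occupancy_track(
            [sim.fragments[("WT", r)] for r in range(config.synthetic.replicates_per_condition)],
            chrom_lengths,
        )
        occ_dko = occupancy_track(
            [sim.fragments[("DKO", r)] for r in range(config.synthetic.replicates_per_condition)],
            chrom_lengths,
        )
        occ_regions = differential_occupancy(
            occ_wt, occ_dko, window=config.occupancy_window,
            log2_threshold=config.log2_threshold,
        )
        dyads = np.concatenate(
            [sim.fragments[("WT", r)].dyads()["pos"].to_numpy()
             for r in range(config.synthetic.replicates_per_condition)]
        )
        nrl = estimate_nrl(dyads)

        stage = "sites"
        n_rep = config.synthetic.replicates_per_condition
        site_calls = consensus_sites(
            [sim.peaks[("WT", r)] for r in range(n_rep)],
            [sim.peaks[("DKO", r)] for r in range(n_rep)],
        )
        motif_sites = scan_motifs(
            [s for s in site_calls if s.category in ("common", "lost")],
            sim.bundle.sequences, motif,
        )
        io.write_intervals(
            IntervalSet([s.interval for s in motif_sites]),
            os.path.join(config.outdir, "motif_sites.bed"),
        )
        composition = site_cpg_composition(motif_sites, sim.bundle.sequences)

        stage = "profiles"
        lost_anchors = IntervalSet([s.interval for s in site_calls if s.category == "lost"])
        periodicity = None
        if len(lost_anchors):
            prof = anchor_profile(
                list(tracks.values())[0], lost_anchors, config.profile_flank,
                signal_label="affinity", anchor_label="lost sites",
            )
            try:
                periodicity = estimate_profile_periodicity(prof)
            except ValueError:
                periodicity = None

        stage = "stats"
        table = build_predictor_table(
            motif_sites, occ_wt, occ_dko, sim.meth_wt, sim.bundle.sequences
        )
        aucs = {}
        for col, direction in [
            ("flank_cpg_density", "less"),
            ("motif_score", "less"),
            ("delta_nuc_occupancy", "greater"),
            ("methylation_level", "greater"),
        ]:
            try:
                aucs[col], _ = roc_auc(table[col].to_numpy(), table["label"].to_numpy(), direction)
            except ValueError:
                aucs[col] = float("nan")
        linkage = expression_linkage(
            sim.transcripts, sim.tads, sim.loops,
            IntervalSet([s.interval for s in site_calls if s.category == "lost"]),
        )
        linkage.to_csv(os.path.join(config.outdir, "expression_linkage.tsv"),
                       sep="\t", index=False)
        island_enrich = fold_enrichment(
            IntervalSet([s.interval for s in motif_sites if s.category == "common"]),
            sim.bundle.islands,
            genome_size=sum(chrom_lengths.values()),
            query_label="common motifs", feature_label="CpG islands",
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    summary = {
        "n_common": sum(1 for s in site_calls if s.category == "common"),
        "n_lost": sum(1 for s in site_calls if s.category == "lost"),
        "n_gained": sum(1 for s in site_calls if s.category == "gained"),
        "n_dmrs": len(dmrs),
        "n_occupancy_gained": sum(1 for r in occ_regions if r.direction == "gained"),
        "n_occupancy_lost": sum(1 for r in occ_regions if r.direction == "lost"),
        "nrl_bp": nrl.nrl,
        "affinity_periodicity_bp": periodicity.nrl if periodicity and periodicity.periodic else None,
        "auc": aucs,
        "common_motif_island_fold_enrichment": island_enrich.fold,
        "runtime_s": round(time.time() - t0, 2),
    }
    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": _jsonable(dataclasses.asdict(config)),
        "summary": _jsonable(summary),
    }
    with open(os.path.join(config.outdir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=1)
    return PipelineResult(
        sim, site_calls, motif_sites, dmrs, occ_regions, nrl,
        table, aucs, linkage, composition, summary,
    )


def _write_simulation(sim: SimulationResult, outdir: str) -> None:
    io.write_fasta(sim.bundle.sequences, os.path.join(outdir, "genome.fa"))
    io.write_intervals(sim.bundle.islands, os.path.join(outdir, "islands.bed"), bed6=False)
    io.write_methylation(sim.meth_wt, os.path.join(outdir, "meth_wt.tsv"))
    io.write_methylation(sim.meth_dko, os.path.join(outdir, "meth_dko.tsv"))
    for (cond, r), frags in sim.fragments.items():
        io.write_fragments(frags, os.path.join(outdir, f"fragments_{cond}_{r}.bed"))
    for (cond, r), peaks in sim.peaks.items():
        io.write_intervals(peaks, os.path.join(outdir, f"peaks_{cond}_{r}.bed"), bed6=False)
    io.write_transcripts(sim.transcripts, os.path.join(outdir, "transcripts.tsv"))
    io.write_intervals(sim.tads, os.path.join(outdir, "tads.bed"), bed6=False)
    io.write_intervals(sim.loops, os.path.join(outdir, "loop_anchors.bed"), bed6=False)
    with open(os.path.join(outdir, "truth_manifest.json"), "w") as fh:
        fh.write(sim.manifest.to_json())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
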