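"""End-to-end orchestration: simulate/ingest -> call-genotypes -> map ->
haploscan -> synteny/project, with a reproducible run manifest."""
from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as fio
from . import linkage, synthdata, synteny
from .haplotype_scan import delineate_block
from .progeny_test import Thresholds, classify_population

log = logging.getLogger("d2finemap")
if not log.handlers:  # stderr, per-stage record counts
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

from . import __version__ as _version


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, input checksums, stage counts."""

    tool_version: str
    config: dict
    seed: int | None
    input_checksums: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    stages_skipped: list = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True) + "\n",
            encoding="utf-8")


def run_pipeline(config: dict, outdir) -> RunManifest:
    """Run every stage whose inputs are present; skipped stages are recorded.

    ``config`` keys (all optional unless a stage needs them):

    * ``seed`` — master seed for simulation stages
    * ``simulate`` — SimConfig-like mapping (``n_f2``, ``markers`` as
      ``[{name, mode}]``, ``distances_cm``, ``trait_position_cm``, ...)
    * ``genotype_table`` — path to a genotype TSV (alternative to simulate)
    * ``heights_table`` / ``family_summaries`` — phenotype input paths
    * ``thresholds`` — decision-rule overrides
    * ``flank_loci`` — two locus names for the recombinant screen
    * ``haplotype_matrix`` — path; ``max_exceptions``, ``break_run``
    * ``anchor_table`` — path; ``gap_unit_bp``, ``score_min``, ``emax``,
      ``max_hits``
    * ``project`` — ``{marker_1: [name, chrom, pos], marker_2: [...],
      annotation: path}``
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed")
    manifest = RunManifest(_version, config, seed)
    for key in ("genotype_table", "heights_table", "family_summaries",
                "haplotype_matrix", "anchor_table"):
        if config.get(key):
            manifest.input_checksums[key] = fio.sha256_file(config[key])

    # -- stage 1: simulate or ingest genotypes ------------------------------
    table = None
    truth = None
    if config.get("genotype_table"):
        table = fio.read_genotype_table(config["genotype_table"])
        log.info("ingest: %d plants, %d loci", len(table.plants),
                 len(table.loci))
    elif config.get("simulate"):
        sim = dict(config["simulate"])
        markers = [synthdata.MarkerDef(**m) for m in sim.pop("markers")]
        sc = synthdata.SimConfig(markers=markers, seed=seed or 0, **sim)
        table, truth = synthdata.simulate_f2(sc)
        fio.write_genotype_table(table, outdir / "genotypes.tsv")
        fio.write_trait_truth(truth, outdir / "trait_truth.tsv")
        log.info("simulate: %d plants, %d loci", len(table.plants),
                 len(table.loci))
    else:
        manifest.stages_skipped.append("genotypes")
    if table is not None:
        n0 = len(table.plants)
        table = table.drop_nonparental()
        if len(table.plants) < n0:
            log.info("removed %d plants with nonparental alleles",
                     n0 - len(table.plants))
        manifest.stage_counts["plants"] = len(table.plants)
        manifest.stage_counts["loci"] = len(table.loci)

    # -- stage 2: progeny-test genotype calls -------------------------------
    calls = None
    thresholds = Thresholds(**config.get("thresholds", {}))
    if config.get("heights_table") or config.get("family_summaries"):
        if config.get("heights_table"):
            families = fio.read_heights_table(config["heights_table"])
        else:
            families = fio.read_family_summaries(config["family_summaries"])
        calls = classify_population(families, thresholds)
        fio.write_trait_calls(calls.calls, outdir / "trait_calls.tsv")
        manifest.stage_counts["trait_calls"] = dict(calls.tally)
        log.info("call-genotypes: %s", calls.tally)
    else:
        manifest.stages_skipped.append("call-genotypes")

    # -- stage 3: linkage ----------------------------------------------------
    if table is not None and config.get("flank_loci"):
        a, b = config["flank_loci"]
        screen = linkage.find_recombinants(table, a, b)
        est = linkage.map_distance(screen.total_recombinant_chromosomes,
                                   screen.n_plants_screened)
        log.info("map: %d informative plants (%d excluded for missing "
                 "calls), %.1f cM", screen.n_informative,
                 len(screen.excluded_missing), est.cm)
        cmap = linkage.cluster_markers(table, screen.informative_plants,
                                       anchor_loci=(a, b))
        report = {
            "flank_loci": [a, b],
            "n_informative": screen.n_informative,
            "n_excluded_missing": len(screen.excluded_missing),
            "recombinant_chromosomes": screen.total_recombinant_chromosomes,
            "distance_cm": round(est.cm, 3),
            "distance_se_cm": round(est.se_cm, 3),
            "single_recombinant_assumption":
                "per-plant chromosome counts in informative_plants.tsv",
            "clusters": [c.loci for c in cmap.clusters],
            "adjacent_events_min_max": cmap.adjacent_events,
            "unplaced_loci": cmap.unplaced,
        }
        pd.DataFrame({
            "plant_id": screen.informative_plants,
            "recombinant_chromosomes":
                screen.recombinant_chromosomes.values,
        }).to_csv(outdir / "informative_plants.tsv", sep="\t", index=False)
        if calls is not None:
            mapping = calls.as_mapping()
            resolved = {p: c for p, c in mapping.items()
                        if p in screen.informative_plants}
            if any(c in linkage.TRAIT_TO_COUNT for c in resolved.values()):
                placement = linkage.place_trait(cmap, resolved)
                pvals = {c.f2_id: c.p_value_3to1 for c in calls.calls
                         if c.p_value_3to1 is not None}
                flags = linkage.flag_double_recombinants(cmap, resolved,
                                                         pvals)
                report["trait_host_cluster"] = \
                    cmap.clusters[placement.host_cluster].loci
                report["trait_total_events"] = placement.total_events
                report["double_recombinant_flags"] = [
                    {"f2_id": f.f2_id, "observed": f.observed_call,
                     "suggested": f.suggested_call,
                     "p_value_3to1": f.p_value_3to1} for f in flags]
                log.info("map: trait placed with %d extra events, %d "
                         "double-recombinant flags",
                         placement.total_events, len(flags))
        (outdir / "linkage_report.json").write_text(
            json.dumps(report, indent=2) + "\n", encoding="utf-8")
        manifest.stage_counts["informative_plants"] = screen.n_informative
        manifest.stage_counts["marker_clusters"] = len(cmap.clusters)
    else:
        manifest.stages_skipped.append("map")

    # -- stage 4: haplotype scan ---------------------------------------------
    if config.get("haplotype_matrix"):
        matrix = fio.read_haplotype_matrix(config["haplotype_matrix"])
        result = delineate_block(matrix,
                                 max_exceptions=config.get("max_exceptions", 1),
                                 break_run=config.get("break_run", 1))
        fio.write_locus_verdicts(result, outdir / "locus_verdicts.tsv")
        block_report = {
            "block_loci": result.block_loci,
            "distal_boundary": result.distal_boundary,
            "proximal_boundary": result.proximal_boundary,
            "n_discriminating": result.n_discriminating,
            "n_exceptions": result.n_exceptions,
        }
        (outdir / "haplotype_block.json").write_text(
            json.dumps(block_report, indent=2) + "\n", encoding="utf-8")
        manifest.stage_counts["block_loci"] = len(result.block_loci)
        log.info("haploscan: block of %d loci, proximal boundary %s",
                 len(result.block_loci), result.proximal_boundary)
    else:
        manifest.stages_skipped.append("haploscan")

    # -- stage 5: synteny / projection ---------------------------------------
    if config.get("anchor_table"):
        raw = fio.read_anchor_table(config["anchor_table"])
        anchors = synteny.filter_anchors(raw, config.get("emax", 1e-5),
                                         config.get("max_hits", 4))
        blocks = synteny.chain_blocks(anchors,
                                      config.get("gap_unit_bp", 10000.0),
                                      config.get("score_min", 300.0))
        fio.write_blocks_table(blocks, outdir / "synteny_blocks.tsv")
        dot = synteny.dotplot_data(anchors, blocks)
        dot.to_csv(outdir / "dotplot.tsv", sep="\t", index=False)
        calls_r = synteny.detect_rearrangements(blocks)
        pd.DataFrame([{"kind": c.kind, "block_index": c.block_index,
                       "breakpoint_a_left": str(c.breakpoint_a_left),
                       "breakpoint_a_right": str(c.breakpoint_a_right),
                       "breakpoint_b_left": str(c.breakpoint_b_left),
                       "breakpoint_b_right": str(c.breakpoint_b_right)}
                      for c in calls_r]).to_csv(
            outdir / "rearrangements.tsv", sep="\t", index=False)
        manifest.stage_counts["synteny_blocks"] = len(blocks)
        manifest.stage_counts["rearrangements"] = len(calls_r)
        log.info("synteny: %d anchors -> %d blocks, %d rearrangement calls",
                 len(anchors), len(blocks), len(calls_r))
    else:
        manifest.stages_skipped.append("synteny")

    if config.get("project"):
        proj = config["project"]
        annotation = (fio.read_annotation(proj["annotation"])
                      if proj.get("annotation") else None)
        interval = synteny.project_interval(tuple(proj["marker_1"]),
                                            tuple(proj["marker_2"]),
                                            annotation)
        fio.write_bed(interval, outdir / "candidate_interval.bed")
        (outdir / "candidate_interval.json").write_text(json.dumps({
            "chromosome": interval.chromosome,
            "start_bp": interval.start_bp, "end_bp": interval.end_bp,
            "length_bp": interval.length_bp,
            "markers": [interval.marker_distal, interval.marker_proximal],
            "n_genes": len(interval.genes), "genes": interval.genes,
        }, indent=2) + "\n", encoding="utf-8")
        manifest.stage_counts["interval_length_bp"] = interval.length_bp
        log.info("project: %d bp interval, %d genes",
                 interval.length_bp, len(interval.genes))
    else:
        manifest.stages_skipped.append("project")

    manifest.write(outdir / "manifest.json")
    return manifest
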