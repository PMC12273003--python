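"""End-to-end orchestration of the synthetic study.

Stages run in dependency order: simulate -> call -> annotate -> conserve ->
translate -> correlate.  Every run writes a manifest carrying the seed and a
configuration hash, and reruns with the same configuration are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import annotate, conserve, io, psicall, ribo, stats, synthdata
from .synthdata import SimConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "call", "annotate", "conserve", "translate", "correlate")


@dataclass
class PipelineConfig:
    """Thresholds and study conditions for a full run."""

    sim: SimConfig = field(default_factory=SimConfig)
    min_depth: int = 20
    min_deletion_reads: int = 5
    min_gap_ratio: float = 0.02
    q_cutoff: float = 0.05
    min_tpm: float = 1.0
    psite_offset: int = ribo.DEFAULT_PSITE_OFFSET
    metagene_bins: int = 30
    conservation_window: int = 50
    lifetime_groups: int = 4
    te_groups: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.q_cutoff <= 1):
            raise ValueError("q_cutoff must be in (0, 1]")
        if self.min_depth < 1 or self.min_deletion_reads < 0:
            raise ValueError("bad depth thresholds")
        if not (0 <= self.min_gap_ratio <= 1):
            raise ValueError("min_gap_ratio outside [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        data = io.load_yaml(path)
        sim_data = data.pop("sim", {})
        if seed is not None:
            sim_data["seed"] = seed
        sim = SimConfig(**sim_data)
        return cls(sim=sim, **data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["sim"].pop("calibration", None)
        return out


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    stages: Sequence[str] = STAGES,
) -> dict:
    """Execute the requested stages; returns a result bundle keyed by stage.

    ``outdir`` (optional) receives one subdirectory of TSV tables per stage
    plus ``manifest.json`` with the seed, configuration hash and per-stage
    record counts.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    out_path = Path(outdir) if outdir is not None else None
    results: dict = {}
    counts: dict[str, int] = {}
    sim = config.sim
    tissues = sim.tissue_names()

    def _stage_dir(name: str) -> Path | None:
        if out_path is None:
            return None
        d = out_path / name
        d.mkdir(parents=True, exist_ok=True)
        return d

    # ---- simulate --------------------------------------------------------
    bundle = synthdata.simulate_all(sim)
    results["simulate"] = bundle
    counts["simulate"] = len(bundle.truth)
    if "simulate" in stages and (d := _stage_dir("simulate")):
        io.write_fasta(bundle.sequences, d / "transcripts.fasta")
        io.write_annotation(bundle.models, d / "annotation.tsv")
        io.write_table(bundle.truth, d / "truth_sites.tsv")
        io.write_matrix(bundle.summed_truth, d / "truth_summed_fraction.tsv")
        io.write_matrix(bundle.codon_dwell, d / "truth_codon_dwell.tsv")
        io.write_table(bundle.trna_set.table, d / "trna_models.tsv")
        io.write_table(bundle.trna_set.sites, d / "trna_sites.tsv")
        io.write_table(
            bundle.lifetimes.rename_axis("transcript_id").reset_index(),
            d / "lifetimes.tsv",
        )
        for (tissue, rep), pileup in bundle.pileups.items():
            io.write_pileup(pileup, d / f"pileup_{tissue}_rep{rep}.tsv")
        io.dump_yaml(config.to_dict(), d / "config.yaml")

    if not any(s in stages for s in STAGES[1:]):
        _write_manifest(out_path, config, counts)
        return results

    # ---- call ------------------------------------------------------------
    site_tables: dict[str, pd.DataFrame] = {}
    for tissue in tissues:
        reps = [bundle.pileups[(tissue, r)] for r in range(sim.n_replicates)]
        combined = psicall.combine_replicates(reps)
        site_tables[tissue] = psicall.call_sites(
            combined,
            bundle.sequences,
            sim.curve,
            min_depth=config.min_depth,
            min_deletion_reads=config.min_deletion_reads,
            min_gap_ratio=config.min_gap_ratio,
            q_cutoff=config.q_cutoff,
            tissue=tissue,
        )
    all_sites = pd.concat(site_tables.values(), ignore_index=True)
    site_matrix = annotate.build_site_matrix(site_tables)
    results["call"] = {"site_tables": site_tables, "site_matrix": site_matrix,
                       "all_sites": all_sites}
    counts["call"] = len(all_sites)
    if "call" in stages and (d := _stage_dir("call")):
        for tissue, table in site_tables.items():
            io.write_sites(table, d / f"sites_{tissue}.tsv")
            io.write_bed(table, d / f"sites_{tissue}.bed")
        io.write_matrix(site_matrix, d / "site_matrix.tsv")
        io.write_table(psicall.motif_summary(all_sites, 3), d / "motif3_summary.tsv")

    # ---- annotate --------------------------------------------------------
    region_labels = annotate.assign_regions(all_sites, bundle.models)
    annotated = all_sites.assign(region=region_labels)
    metagene = annotate.metagene_profile(
        all_sites, bundle.models, config.metagene_bins
    )
    density = annotate.region_density(all_sites, bundle.models)
    sharing, sharing_counts = annotate.classify_tissue_sharing(site_matrix)
    seedling_sites = site_tables[tissues[0]]
    summed_called = annotate.summed_fraction_per_transcript(seedling_sites)
    results["annotate"] = {
        "annotated_sites": annotated,
        "metagene": metagene,
        "region_density": density,
        "sharing": sharing,
        "sharing_counts": sharing_counts,
        "summed_fraction": summed_called,
    }
    counts["annotate"] = len(annotated)
    if "annotate" in stages and (d := _stage_dir("annotate")):
        io.write_table(annotated, d / "annotated_sites.tsv")
        io.write_table(metagene, d / "metagene_profile.tsv")
        io.write_table(density, d / "region_density.tsv")
        io.write_table(
            sharing.rename_axis("site").reset_index(), d / "tissue_sharing.tsv"
        )
        io.write_table(
            summed_called.rename_axis("transcript_id").reset_index(),
            d / "summed_fraction_seedling.tsv",
        )

    # ---- conserve --------------------------------------------------------
    ortho = synthdata.make_orthologue_fixture(seed=sim.seed)
    class_rows = []
    for gid, group in ortho.truth.groupby("gene_a"):
        classified = conserve.classify_conservation(
            ortho.seqs_a[gid], ortho.partners[gid], group["pos"].tolist()
        )
        classified.insert(0, "gene_a", gid)
        class_rows.append(classified)
    classes = pd.concat(class_rows, ignore_index=True).merge(
        ortho.truth, left_on=["gene_a", "pos"], right_on=["gene_a", "pos"]
    )
    cons_fix = synthdata.make_conservation_fixture(seed=sim.seed)
    profile = conserve.conservation_score(
        cons_fix.msa, window=config.conservation_window
    )
    r_cons, p_cons = conserve.density_conservation_correlation(
        profile, cons_fix.site_positions, window=config.conservation_window
    )
    results["conserve"] = {
        "classes": classes,
        "profile": profile,
        "density_correlation": (r_cons, p_cons),
    }
    counts["conserve"] = len(classes)
    if "conserve" in stages and (d := _stage_dir("conserve")):
        io.write_table(classes, d / "site_classes.tsv")
        io.write_bedgraph(profile.scaled, "synthetic_rRNA", d / "conservation.bedgraph")
        io.write_table(
            pd.DataFrame({"r": [r_cons], "p": [p_cons]}),
            d / "density_conservation.tsv",
        )

    # ---- translate -------------------------------------------------------
    lengths = pd.Series({t: m.length for t, m in bundle.models.items()})
    te_matrix = {}
    e_codon = {}
    rna_tpms = {}
    for tissue in tissues:
        rna_tpm = ribo.compute_tpm(bundle.rna_counts[tissue], lengths)
        ribo_counts = pd.Series(
            {tid: cov.sum() for tid, cov in bundle.coverage[tissue].items()}
        )
        ribo_tpm = ribo.compute_tpm(ribo_counts, lengths)
        te_matrix[tissue] = ribo.transcript_te(ribo_tpm, rna_tpm, config.min_tpm)
        dwell = ribo.codon_dwell(
            bundle.coverage[tissue], bundle.models, bundle.sequences, rna_tpm
        )
        e_codon[tissue] = ribo.codon_te(dwell)
        rna_tpms[tissue] = rna_tpm
    te_matrix = pd.DataFrame(te_matrix)
    e_codon = pd.DataFrame(e_codon)
    results["translate"] = {
        "te_matrix": te_matrix,
        "e_codon": e_codon,
        "rna_tpm": pd.DataFrame(rna_tpms),
    }
    counts["translate"] = len(te_matrix)
    if "translate" in stages and (d := _stage_dir("translate")):
        io.write_matrix(te_matrix, d / "e_transcript.tsv")
        io.write_matrix(e_codon, d / "e_codon.tsv")
        io.write_matrix(results["translate"]["rna_tpm"], d / "rna_tpm.tsv")

    # ---- correlate -------------------------------------------------------
    site_te = stats.site_te_correlation(site_matrix, te_matrix)
    trna_records = stats.trna_region_te_correlation(
        bundle.trna_set.sites, bundle.trna_set.decode, e_codon
    )
    region_or = {
        region: stats.sign_odds_ratio(group["r"])
        for region, group in trna_records.groupby("region")
    }
    try:
        lifetime = stats.lifetime_group_analysis(
            summed_called, bundle.lifetimes, k=config.lifetime_groups
        )
        te_groups = stats.te_group_analysis(
            summed_called, te_matrix[tissues[0]], k=config.te_groups
        )
    except ValueError as err:  # too few modified transcripts to form groups
        logger.warning("group analyses skipped: %s", err)
        lifetime = te_groups = None
    results["correlate"] = {
        "site_te": site_te,
        "trna_records": trna_records,
        "region_or": region_or,
        "lifetime": lifetime,
        "te_groups": te_groups,
    }
    counts["correlate"] = len(site_te.records)
    if "correlate" in stages and (d := _stage_dir("correlate")):
        io.write_table(site_te.records, d / "site_te_correlations.tsv")
        io.write_table(
            site_te.site_median.rename_axis("site").reset_index(),
            d / "site_median_r.tsv",
        )
        io.write_table(trna_records, d / "trna_te_correlations.tsv")
        io.write_table(
            pd.DataFrame(
                [
                    {"region": region, "n_positive": s.n_positive,
                     "n_negative": s.n_negative, "odds_ratio": s.odds_ratio,
                     "p": s.p_value}
                    for region, s in sorted(region_or.items())
                ]
            ),
            d / "trna_region_odds_ratio.tsv",
        )
        if lifetime is not None:
            io.write_table(lifetime.groups, d / "lifetime_groups.tsv")
            io.write_table(lifetime.contrasts, d / "lifetime_contrasts.tsv")
        if te_groups is not None:
            io.write_table(te_groups.groups, d / "te_groups.tsv")
            io.write_table(te_groups.contrasts, d / "te_contrasts.tsv")

    _write_manifest(out_path, config, counts)
    return results


def _write_manifest(
    out_path: Path | None, config: PipelineConfig, counts: dict[str, int]
) -> None:
    if out_path is None:
        return
    out_path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.sim.seed,
        "config_hash": io.config_hash(config.to_dict()),
        "stage_counts": counts,
    }
    (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2))
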