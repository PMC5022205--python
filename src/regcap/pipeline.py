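"""End-to-end orchestration of the simulate/design/annotate/motif/ase stages.

``run_pipeline`` executes the enabled stages in dependency order on a
synthetic dataset generated from the master seed, writes each stage's
outputs as plain-text files under the output directory, and records a
manifest (stage list, output digests, seed, package version, resolved
configuration).  Outputs carry no timestamps, so reruns with an identical
configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SMOKE_SIM, PipelineConfig
from .enrichment import (SnpHitSet, capture_fraction, empirical_panel_enrichment)
from .intervals import write_chrom_sizes
from .motifs import bonferroni_alpha, impact_proportion_test, scan_variants, write_meme
from .panel import bin_and_normalize, design_panel, design_report
from .simulate import (AfSpectrumConfig, AseEffectConfig, PeakConfig,
                       make_genome, make_informative_pwm, make_transcripts,
                       simulate_ase, simulate_dhs_experiments,
                       simulate_motif_variants, simulate_variants, substream,
                       write_bedgraph, write_fasta)
from .variants import (annotate_coding_effect, assign_dhs_sharing,
                       classify_frequency, qc_filter, sharing_level_enrichment,
                       summary_table, transcripts_to_bed12, write_vcf)
from .ase import (adjusted_ai_proportions, annotate_records, count_dose_response,
                  pool_by_transcript, residual_variance_explained,
                  stratify_homozygous, vicinity_variant_counts)


class PipelineError(RuntimeError):
    pass


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir, seed: int | None = None) -> dict:
    """Run the enabled stages; returns the manifest dict (also written as
    ``manifest.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    sim_cfg = {**SMOKE_SIM, **config.sim}
    manifest: dict = {"version": __version__, "seed": int(seed), "stages": []}
    outputs: dict[str, list[str]] = {}

    def record(stage: str, *paths: Path) -> None:
        outputs.setdefault(stage, []).extend(str(p.name) for p in paths)

    enabled = list(config.stages)
    state: dict = {}

    # ---- simulate -------------------------------------------------------
    if "simulate" in enabled:
        chrom_sizes = dict(sim_cfg["chrom_sizes"])
        genome = make_genome(seed, chrom_sizes)
        cell_types = list(sim_cfg["cell_types"])
        rng = substream(seed, "pipeline-peaks")
        n_shared, n_spec = sim_cfg["n_peaks_shared"], sim_cfg["n_peaks_specific"]
        sharing_counts = [len(cell_types)] * n_shared + \
            list(rng.integers(1, len(cell_types), size=n_spec))
        dhs = simulate_dhs_experiments(
            chrom_sizes, cell_types, dict(sim_cfg["replicates"]),
            PeakConfig(sharing_counts=sharing_counts,
                       peak_reads=sim_cfg["peak_reads"]),
            depth=sim_cfg["dhs_depth"], seed=seed, bin_size=config.bin_size)
        write_fasta(genome, out / "genome.fa")
        write_chrom_sizes(chrom_sizes, out / "genome.chrom.sizes")
        for sample_id, counts in dhs.counts.items():
            write_bedgraph(counts, dhs.grid, out / f"{sample_id}.bedGraph")
        dhs.truth.to_json(out / "truth_dhs.json")
        record("simulate", out / "genome.fa", out / "genome.chrom.sizes",
               out / "truth_dhs.json",
               *[out / f"{s}.bedGraph" for s in dhs.counts])
        state.update(genome=genome, dhs=dhs, chrom_sizes=chrom_sizes)

    # ---- design ---------------------------------------------------------
    if "design" in enabled:
        dhs = state.get("dhs")
        if dhs is None:
            raise PipelineError("design stage requires the simulate stage")
        tracks: dict[str, list] = {}
        for sample_id, counts in dhs.counts.items():
            ct = dhs.cell_type_of[sample_id]
            tracks.setdefault(ct, []).append(
                bin_and_normalize(counts, dhs.grid, sample_id=sample_id,
                                  cell_type=ct))
        panel = design_panel(
            tracks, dhs.grid, n_top=sim_cfg["n_top"],
            block_size=sim_cfg["block_size"],
            min_overlap=config.min_block_overlap,
            exome_min_frac=config.exome_min_frac)
        panel.to_bed(out / "panel.bed")
        design_report(panel).to_csv(out / "design_report.tsv", sep="\t", index=False)
        record("design", out / "panel.bed", out / "design_report.tsv")
        state["panel"] = panel

    # ---- enrich ---------------------------------------------------------
    if "enrich" in enabled:
        panel = state.get("panel")
        if panel is None:
            raise PipelineError("enrich stage requires the design stage")
        rng = substream(seed, "pipeline-hits")
        grid = panel.grid
        n_hits = sim_cfg["n_hits"]
        in_frac = sim_cfg["hit_in_panel_fraction"]
        panel_bins = panel.bins
        off_bins = np.setdiff1d(np.arange(grid.n_bins), panel_bins)
        snps = {}
        for i in range(n_hits):
            b = int(rng.choice(panel_bins if rng.random() < in_frac else off_bins))
            chrom, s, e = grid.bin_interval(b)
            snps[f"hit{i}"] = (chrom, int(rng.integers(s, e)))
        hits = SnpHitSet(label="synthetic-hits", snps=snps)
        frac, n_cap, _ = capture_fraction(hits, panel)
        res = empirical_panel_enrichment(
            hits, panel, universe=np.arange(grid.n_bins),
            iterations=sim_cfg["iterations"], seed=int(substream(seed, "null").integers(2**31)))
        pd.DataFrame([{
            "hit_set": hits.label, "n_hits": len(hits), "captured": n_cap,
            "capture_fraction": frac, "fold_enrichment": res.fold_enrichment,
            "empirical_p": res.p_value,
        }]).to_csv(out / "enrichment_report.tsv", sep="\t", index=False)
        record("enrich", out / "enrichment_report.tsv")

    # ---- annotate -------------------------------------------------------
    if "annotate" in enabled:
        panel = state.get("panel")
        genome = state.get("genome")
        if panel is None or genome is None:
            raise PipelineError("annotate stage requires simulate and design")
        sim = simulate_variants(
            panel,
            AfSpectrumConfig(common_density=sim_cfg["common_density"],
                             rare_novel_density=sim_cfg["rare_novel_density"]),
            enrichment_fold=sim_cfg["enrichment_fold"],
            n_samples=sim_cfg["n_samples"], seed=seed, genome=genome)
        write_vcf(sim.sites, sim.calls, out / "variants.vcf",
                  chrom_sizes=state["chrom_sizes"])
        sim.freq_ref.to_csv(out / "frequency_reference.tsv", sep="\t", index=False)
        qc = qc_filter(sim.sites, sim.calls, dp_min=config.dp_min,
                       gq_min=config.gq_min, mq_min=config.mq_min,
                       ab_range=(config.ab_low, config.ab_high))
        sites = classify_frequency(qc.sites, sim.freq_ref, sim.known_sites,
                                   maf_threshold=config.maf_threshold)
        transcripts = make_transcripts(state["chrom_sizes"],
                                       sim_cfg["n_genes"], seed)
        transcripts_to_bed12(transcripts, out / "transcripts.bed")
        sites = annotate_coding_effect(sites, transcripts, genome)
        sites = assign_dhs_sharing(sites, panel)
        sites.to_csv(out / "annotated_variants.tsv", sep="\t", index=False)
        summary_table(sites, qc.calls).to_csv(out / "variant_summary.tsv",
                                              sep="\t", index=False)
        try:
            enr = sharing_level_enrichment(sites)
            pd.DataFrame({"level": enr.levels, "fold": enr.folds}).assign(
                slope=enr.slope, p_value=enr.p_value, fold_span=enr.fold_span
            ).to_csv(out / "sharing_enrichment.tsv", sep="\t", index=False)
            record("annotate", out / "sharing_enrichment.tsv")
        except Exception:
            pass
        record("annotate", out / "variants.vcf", out / "frequency_reference.tsv",
               out / "transcripts.bed", out / "annotated_variants.tsv",
               out / "variant_summary.tsv")
        state.update(sites=sites, transcripts=transcripts)

    # ---- motif ----------------------------------------------------------
    if "motif" in enabled:
        genome = state.get("genome")
        if genome is None:
            raise PipelineError("motif stage requires the simulate stage")
        pwms = [make_informative_pwm(f"TF{i + 1}", sim_cfg["pwm_width"],
                                     seed=seed + i)
                for i in range(sim_cfg["n_pwms"])]
        write_meme(pwms, out / "motifs.meme")
        mutated, mvars, mtruth = simulate_motif_variants(
            pwms, genome, sim_cfg["n_create"], sim_cfg["n_disrupt"],
            sim_cfg["n_neutral"], seed=seed, flank=config.flank)
        alpha = bonferroni_alpha(config.family_alpha, len(mvars))
        scanned = scan_variants(mvars, mutated, pwms, alpha=alpha,
                                flank=config.flank)
        scanned.drop(columns=["true_pwm"]).to_csv(
            out / "motif_impacts.tsv", sep="\t", index=False)
        mtruth.to_json(out / "truth_motifs.json")
        record("motif", out / "motifs.meme", out / "motif_impacts.tsv",
               out / "truth_motifs.json")

    # ---- ase ------------------------------------------------------------
    if "ase" in enabled:
        rec, geno, atruth = simulate_ase(
            AseEffectConfig(n_transcripts=sim_cfg["n_transcripts"],
                            n_affected=sim_cfg["n_affected"],
                            log2_effect=sim_cfg["log2_effect"],
                            carrier_fraction=sim_cfg["carrier_fraction"]),
            overdispersion=sim_cfg["overdispersion"],
            n_individuals=sim_cfg["n_individuals"], seed=seed)
        rec.to_csv(out / "allele_counts.tsv", sep="\t", index=False)
        geno.to_csv(out / "esnp_genotypes.tsv", sep="\t", index=False)
        ann = annotate_records(rec)
        per = pool_by_transcript(ann)
        # vicinity counts: affected transcripts have a planted rare variant
        affected = {e[0] for e in atruth.planted_cis_effects}
        per["n_rare_novel"] = [1 if t in affected else 0 for t in per["transcript"]]
        per["n_common"] = 1
        per["n_rare"] = per["n_rare_novel"]
        per["n_novel"] = 0
        props = adjusted_ai_proportions(per)
        props.to_csv(out / "ai_proportions.tsv", sep="\t", index=False)
        dose = count_dose_response(per, max_count=1)
        dose.to_csv(out / "dose_response.tsv", sep="\t", index=False)
        hom = stratify_homozygous(ann, geno)
        hom_per = pool_by_transcript(hom)
        hom_per["n_rare_novel"] = [1 if t in affected else 0
                                   for t in hom_per["transcript"]]
        r2 = residual_variance_explained(hom_per) if len(hom_per) >= 10 else None
        atruth.to_json(out / "truth_ase.json")
        with open(out / "ase_report.json", "w") as fh:
            json.dump({"n_transcripts": int(len(per)),
                       "n_ai": int((per["ai_class"] == "ai").sum()),
                       "residual_r2": r2}, fh, indent=1, sort_keys=True)
        record("ase", out / "allele_counts.tsv", out / "esnp_genotypes.tsv",
               out / "ai_proportions.tsv", out / "dose_response.tsv",
               out / "ase_report.json", out / "truth_ase.json")

    # ---- manifest -------------------------------------------------------
    resolved = out / "config.resolved.yaml"
    cfg = PipelineConfig.from_dict({**config.to_dict(), "seed": int(seed)})
    cfg.to_yaml(resolved)
    for stage in enabled:
        manifest["stages"].append({
            "name": stage,
            "outputs": {name: _digest(out / name)
                        for name in sorted(set(outputs.get(stage, [])))},
        })
    manifest["config"] = resolved.name
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
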