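"""End-to-end orchestration of the annotation + conservation study on
synthetic data.

``run_demo`` generates a full synthetic study, writes every input to disk,
reads it back through :mod:`cisreg.io` (the pipeline never bypasses its own
readers), runs QC, element classification, super-enhancer calling,
cross-species conservation, chromatin-state overlay, expression linkage and
CRC construction, and writes all artifacts plus a machine-readable run
manifest.  Identical seeds give byte-identical output trees.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from . import io as gio
from . import simulate
from .annotate import (AnnotationConfig, call_broad_domains, classify_elements,
                       rank_top_enhancers)
from .conservation import (LiftOverConfig, classify_conservation,
                           cluster_state_matrix, conservation_fractions,
                           distance_to_nearest_gene,
                           ks_compare_with_random_control,
                           overlay_chromatin_states)
from .core import Element, GenomicInterval
from .crc import build_crc, candidate_tfs, compare_crcs
from .expression import (apply_de_thresholds, compare_groups,
                         link_elements_to_genes, quantile_normalize,
                         tss_flank_intensity)
from .qc import (CoverageTrack, bin_track, peak_qc, replicate_correlation,
                 standardize_elements)
from .superenhancer import RoseConfig, assign_genes, call_superenhancers, \
    score_regions, stitch

__all__ = ["run_demo"]

_CRC_SCAN_THRESHOLD = 12.0  # bits; planted 10-mers score ~19.6


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_regions_tsv(regions, path) -> None:
    rows = []
    for r in regions:
        rows.append(
            dict(
                region_id=r.region_id,
                chrom=r.interval.chrom,
                start=r.interval.start,
                end=r.interval.end,
                n_constituents=len(r.constituents),
                signal=round(r.signal, 6) if r.signal is not None else "",
                rank=r.rank,
                is_super=int(r.is_super),
                constituents=",".join(r.constituent_ids),
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run_demo(seed: int, outdir, config: Optional[simulate.SyntheticConfig] = None
             ) -> Dict[str, object]:
    """Run the full synthetic study; returns a summary dict (also written
    to ``manifest.json``)."""
    outdir = Path(outdir)
    cfg = config or simulate.SyntheticConfig(seed=seed)
    counts: Dict[str, object] = {}

    # ------------------------------------------------------------------ inputs
    ref = simulate.generate_reference(cfg)
    peaks = simulate.generate_peaks_and_coverage(cfg, ref)
    inputs = outdir / "inputs"
    ref.write(inputs)
    peaks.write(inputs)

    # read everything back through the I/O layer
    chrom_sizes = gio.read_chrom_sizes(inputs / "genome.chrom.sizes")
    expression = gio.read_expression(inputs / "expression.tsv")
    mean_tpm = expression.mean(axis=1)
    tss = gio.read_tss(inputs / "genes.gtf", expression=mean_tpm.to_dict())
    k4_raw = gio.read_peaks(inputs / "h3k4me3.narrowPeak", "H3K4me3")
    k27_raw = gio.read_peaks(inputs / "h3k27ac.narrowPeak", "H3K27ac")
    tracks = {
        name: CoverageTrack.from_bedgraph(
            inputs / f"{name}.bedGraph", chrom_sizes, cfg.bin_size
        )
        for name in ("k4_ip", "k4_input", "k27_ip", "k27_input")
    }

    # --------------------------------------------------------------------- QC
    qc_dir = outdir / "qc"
    qc_dir.mkdir(parents=True, exist_ok=True)
    rep_r = {}
    for mark, (rep_a, rep_b) in peaks.replicates.items():
        rep_r[mark] = replicate_correlation(bin_track(rep_a), bin_track(rep_b))
    pd.DataFrame(
        [{"mark": m, "pearson_r": round(r, 6)} for m, r in sorted(rep_r.items())]
    ).to_csv(qc_dir / "replicate_correlation.tsv", sep="\t", index=False)

    k4_passed, k4_report = peak_qc(k4_raw, "narrow", tracks["k4_ip"], tracks["k4_input"])
    k27_passed, k27_report = peak_qc(k27_raw, "narrow", tracks["k27_ip"], tracks["k27_input"])
    k4_report.to_csv(qc_dir / "h3k4me3_peak_qc.tsv", sep="\t", index=False)
    k27_report.to_csv(qc_dir / "h3k27ac_peak_qc.tsv", sep="\t", index=False)
    counts["peaks"] = {
        "h3k4me3_raw": len(k4_raw),
        "h3k4me3_passed": len(k4_passed),
        "h3k27ac_raw": len(k27_raw),
        "h3k27ac_passed": len(k27_passed),
    }

    # ------------------------------------------------------------- annotation
    ann_cfg = AnnotationConfig()
    result = classify_elements(k4_passed, k27_passed, tss, ann_cfg, chrom_sizes)
    broad = call_broad_domains(k4_passed, tss, ann_cfg, chrom_sizes)
    el_dir = outdir / "elements"
    el_dir.mkdir(parents=True, exist_ok=True)
    gio.write_elements(result.promoters, el_dir / "promoters.bed")
    gio.write_elements(result.active_promoters, el_dir / "active_promoters.bed")
    gio.write_elements(result.poised_promoters, el_dir / "poised_promoters.bed")
    gio.write_elements(result.enhancers, el_dir / "enhancers.bed")
    gio.write_elements(broad, el_dir / "broad_domains.bed")
    class_counts = result.counts()
    class_counts["broad_domain"] = len(broad)
    pd.DataFrame([class_counts]).to_csv(
        el_dir / "class_counts.tsv", sep="\t", index=False
    )
    counts["elements"] = class_counts
    top_enh = rank_top_enhancers(result.enhancers, n=3000)
    gio.write_elements(top_enh, el_dir / "top_enhancers.bed")

    # --------------------------------------------------------- super-enhancers
    se_dir = outdir / "superenhancer"
    se_dir.mkdir(parents=True, exist_ok=True)
    rose_cfg = RoseConfig()
    regions = stitch(result.enhancers, rose_cfg)
    regions = score_regions(regions, tracks["k27_ip"], tracks["k27_input"])
    ranked, elbow = call_superenhancers(regions)
    _write_regions_tsv(ranked, se_dir / "stitched_regions.tsv")
    pd.DataFrame(
        {
            "rank": [r.rank for r in ranked],
            "signal": [round(r.signal, 6) for r in ranked],
            "is_super": [int(r.is_super) for r in ranked],
        }
    ).to_csv(se_dir / "hockey_plot.tsv", sep="\t", index=False)
    supers = [r for r in ranked if r.is_super]
    se_gene_map = assign_genes(supers, tss, rose_cfg.assign_mode)
    typical = [r for r in ranked if not r.is_super]
    typical_gene_map = assign_genes(typical, tss, rose_cfg.assign_mode)
    pd.DataFrame(
        [
            {"region_id": rid, "genes": ",".join(genes)}
            for rid, genes in sorted(se_gene_map.items())
        ]
    ).to_csv(se_dir / "superenhancer_genes.tsv", sep="\t", index=False)
    counts["superenhancer"] = {
        "stitched_regions": len(regions),
        "super_enhancers": len(supers),
        "elbow_cutoff_signal": None if elbow.degenerate else round(elbow.cutoff_signal, 6),
    }

    # ------------------------------------------- standardization + second QC
    std_enh = standardize_elements(result.enhancers, chrom_sizes,
                                   ann_cfg.standard_width_bp)
    std_prom = standardize_elements(result.promoters, chrom_sizes,
                                    ann_cfg.standard_width_bp)
    second_pass: List[Element] = []
    for el in std_enh:
        rpm_ip = tracks["k27_ip"].rpm(el.interval)
        rpm_input = tracks["k27_input"].rpm(el.interval)
        el.rpm_ip, el.rpm_input = rpm_ip, rpm_input
        if rpm_ip >= 2 * rpm_input and rpm_ip - rpm_input > 1:
            second_pass.append(el)
    counts["standardized"] = {
        "enhancers_2kb": len(std_enh),
        "enhancers_second_pass": len(second_pass),
    }

    # ------------------------------------------------------------ conservation
    cons_dir = outdir / "conservation"
    cons_dir.mkdir(parents=True, exist_ok=True)
    source_elements = second_pass + std_prom
    pair = simulate.generate_chain_pair(cfg, ref, source_elements=source_elements)
    pair.write(inputs / "pair")
    chains = gio.read_chain(inputs / "pair" / "source_to_target.chain")
    target_elements = gio.read_elements(inputs / "pair" / "target_elements.bed")
    lift_cfg = LiftOverConfig()
    calls = classify_conservation(source_elements, chains, target_elements, lift_cfg)
    pd.DataFrame(
        [
            dict(
                element_id=c.element_id,
                element_class=c.element_class,
                status=c.status,
                target=("" if c.target is None
                        else f"{c.target.chrom}:{c.target.start}-{c.target.end}"),
                matches=",".join(c.matched_target_ids),
                reason=c.reason,
            )
            for c in calls
        ]
    ).to_csv(cons_dir / "conservation_calls.tsv", sep="\t", index=False)

    enh_ids = {e.element_id for e in second_pass}
    enh_calls = [c for c in calls if c.element_id in enh_ids]
    fractions = conservation_fractions(enh_calls)
    truth = pair.truth.set_index("element_id")["status"]
    agree = float(
        np.mean([truth.get(c.element_id) == c.status for c in calls])
    )
    counts["conservation"] = {
        "n_elements": len(calls),
        "enhancer_fractions": {k: round(v, 4) for k, v in fractions.items()},
        "truth_agreement": round(agree, 4),
    }

    # distances + KS against random control
    by_id = {e.element_id: e for e in source_elements}
    funct_el = [by_id[c.element_id] for c in enh_calls if c.status == "functional"]
    seq_el = [by_id[c.element_id] for c in enh_calls if c.status == "sequence_only"]
    ks_summary = None
    if funct_el and seq_el:
        d_f = distance_to_nearest_gene(funct_el, tss)
        d_s = distance_to_nearest_gene(seq_el, tss)
        pool = distance_to_nearest_gene(second_pass, tss)
        draw_size = min(4000, max(1, len(pool) // 2))
        ks = ks_compare_with_random_control(d_f, d_s, pool, n_draws=100,
                                            draw_size=draw_size, seed=cfg.seed)
        ks_summary = {
            "ks_statistic": round(ks["ks_statistic"], 6),
            "pvalue": float(ks["pvalue"]),
            "median_functional": float(np.median(d_f)),
            "median_sequence_only": float(np.median(d_s)),
            "control_median_range": [
                float(ks["control_medians"].min()),
                float(ks["control_medians"].max()),
            ],
            "draw_size": draw_size,
        }
        pd.DataFrame([ks_summary]).to_csv(
            cons_dir / "distance_ks.tsv", sep="\t", index=False
        )
    counts["distance_ks"] = ks_summary

    # chromatin-state overlay of sequence-only conserved enhancers
    seq_mapped = [
        (c.element_id, c.target) for c in enh_calls if c.status == "sequence_only"
    ]
    overlay_summary = None
    if seq_mapped:
        segments, category_map, _ = simulate.generate_state_segments(cfg, seq_mapped)
        gio.write_state_bed(segments, inputs / "pair" / "target_states.bed")
        gio.write_category_map(category_map, inputs / "pair" / "state_categories.tsv")
        segments = gio.read_state_bed(inputs / "pair" / "target_states.bed")
        category_map = gio.read_category_map(inputs / "pair" / "state_categories.tsv")
        overlay = overlay_chromatin_states(seq_mapped, segments, category_map)
        overlay.matrix.to_csv(cons_dir / "state_matrix.tsv", sep="\t")
        k = min(100, len(overlay.matrix), len(overlay.matrix.drop_duplicates()))
        clusters = cluster_state_matrix(overlay.matrix, k=k, seed=cfg.seed)
        clusters.to_csv(cons_dir / "state_clusters.tsv", sep="\t")
        overlay_summary = {
            "n_sequence_only": len(seq_mapped),
            "n_regulatory": overlay.n_regulatory,
            "regulatory_fraction": round(overlay.regulatory_fraction, 4),
            "tissue_counts": overlay.tissue_counts,
            "k_clusters": k,
        }
    counts["state_overlay"] = overlay_summary

    # -------------------------------------------------------------- expression
    expr_dir = outdir / "expression"
    expr_dir.mkdir(parents=True, exist_ok=True)
    orthology = gio.read_orthology(inputs / "pair" / "orthology.tsv")
    de_stats, _ = simulate.generate_de_stats(cfg, list(expression.index))
    # cross-species matrix on one2one orthologs, then quantile normalization
    target_tpm = mean_tpm / np.power(2.0, de_stats["log2_fold"])
    xspecies = pd.DataFrame(
        {"source_liver": mean_tpm, "target_liver": target_tpm}
    ).loc[list(orthology)]
    qn = quantile_normalize(xspecies)
    qn.round(6).to_csv(expr_dir / "expression_quantile_normalized.tsv", sep="\t")
    de_table, de_counts = apply_de_thresholds(de_stats, compute_fdr=True)
    de_table.round(6).to_csv(expr_dir / "de_genes.tsv", sep="\t")
    counts["differential_expression"] = de_counts

    # group comparisons (planted directions: all "greater")
    def _group_tpms(gene_ids) -> List[float]:
        return [float(mean_tpm[g]) for g in gene_ids if g in mean_tpm.index]

    active_genes = sorted(set(link_elements_to_genes(result.active_promoters, tss).values()))
    poised_genes = sorted(set(link_elements_to_genes(result.poised_promoters, tss).values()) )
    poised_genes = [g for g in poised_genes if g not in set(active_genes)]
    se_genes = sorted({g for genes in se_gene_map.values() for g in genes})
    typ_genes = sorted({g for genes in typical_gene_map.values() for g in genes}
                       - set(se_genes))
    broad_genes = sorted(set(link_elements_to_genes(broad, tss).values()))
    typical_prom_genes = sorted(
        set(link_elements_to_genes(result.promoters, tss).values()) - set(broad_genes)
    )
    comparisons = {}
    for name, (ga, gb) in {
        "active_vs_poised_promoter": (active_genes, poised_genes),
        "se_vs_typical_enhancer": (se_genes, typ_genes),
        "broad_vs_typical_h3k4me3": (broad_genes, typical_prom_genes),
    }.items():
        a, b = _group_tpms(ga), _group_tpms(gb)
        if a and b:
            stat, p = compare_groups(np.log1p(a), np.log1p(b), alternative="greater")
            comparisons[name] = {
                "n_a": len(a), "n_b": len(b),
                "median_a": float(np.median(a)), "median_b": float(np.median(b)),
                "statistic": stat, "pvalue": p,
            }
    pd.DataFrame(comparisons).T.to_csv(expr_dir / "group_comparisons.tsv", sep="\t")
    counts["group_comparisons"] = {
        k: {"pvalue": v["pvalue"], "n_a": v["n_a"], "n_b": v["n_b"]}
        for k, v in comparisons.items()
    }

    # TSS-flank histone intensity of DE genes
    up = de_table.index[de_table["direction"] == "up_in_A"]
    down = de_table.index[de_table["direction"] == "down_in_A"]
    flank = tss_flank_intensity(tss, tracks["k27_ip"], flank_bp=1000)
    counts["tss_flank_rpm"] = {
        "up_mean": round(float(np.mean([flank[g] for g in up])), 4) if len(up) else None,
        "down_mean": round(float(np.mean([flank[g] for g in down])), 4) if len(down) else None,
    }

    # --------------------------------------------------------------------- CRC
    crc_dir = outdir / "crc"
    crc_dir.mkdir(parents=True, exist_ok=True)
    sequences = gio.read_fasta(inputs / "genome.fa")
    tf_list = sorted(ref.se_target_genes)
    candidates = candidate_tfs(se_gene_map, tf_list, mean_tpm.to_dict(), min_tpm=1.0)
    pwms, kmers = simulate.generate_pwm_set(cfg, candidates)
    gio.write_meme_pwms({tf: pwms[tf].matrix for tf in candidates},
                        inputs / "tf_motifs.meme")
    read_pwms_raw, background = gio.read_meme_pwms(inputs / "tf_motifs.meme")
    from .crc import PWM
    read_pwms = {tf: PWM(tf, mat) for tf, mat in read_pwms_raw.items()}

    # constituent sequences per candidate, with every candidate's motif
    # planted in the first constituent (a fully interconnected circuitry)
    region_by_gene: Dict[str, object] = {}
    for r in supers:
        for g in se_gene_map.get(r.region_id, []):
            region_by_gene.setdefault(g, r)
    constituent_seqs: Dict[str, List[str]] = {}
    for tf in candidates:
        region = region_by_gene[tf]
        seqs = [
            sequences[e.interval.chrom][e.interval.start : e.interval.end]
            for e in region.constituents
        ]
        planted = seqs[0]
        for i, other in enumerate(candidates):
            planted = simulate.plant_motif(planted, kmers[other], [15 * i])
        constituent_seqs[tf] = [planted] + seqs[1:]
    gio.write_fasta(
        {f"{tf}_const{i}": s for tf, ss in constituent_seqs.items()
         for i, s in enumerate(ss)},
        crc_dir / "constituents.fa",
    )
    graph = build_crc(candidates, constituent_seqs, read_pwms,
                      background=background, threshold=_CRC_SCAN_THRESHOLD)
    pd.DataFrame(sorted(graph.edges), columns=["tf_from", "tf_to"]).to_csv(
        crc_dir / "edges.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"clique": ",".join(c), "size": len(c)} for c in graph.cliques]
    ).to_csv(crc_dir / "cliques.tsv", sep="\t", index=False)

    # three-way comparison: two further species with a designed shared core
    pig_tfs = sorted(graph.clique_members())
    shared_core = sorted(tf_list)[:10]
    species_sets = {
        "pig": pig_tfs,
        "human": shared_core + [f"HS_TF{i:02d}" for i in range(8)],
        "cattle": shared_core + [f"BT_TF{i:02d}" for i in range(6)],
    }
    crc_cmp = compare_crcs(species_sets)
    with open(crc_dir / "species_comparison.json", "w") as fh:
        json.dump(crc_cmp, fh, indent=2, sort_keys=True, default=_json_default)
    counts["crc"] = {
        "candidates": len(candidates),
        "auto_regulated": len(graph.nodes),
        "largest_clique": max((len(c) for c in graph.cliques), default=0),
        "shared_all_species": len(crc_cmp["shared_all"]),
    }

    # ----------------------------------------------------------------- manifest
    manifest = {
        "tool": "cisreg",
        "version": __version__,
        "seed": seed,
        "config": asdict(cfg),
        "parameters": {
            "narrow_pvalue_cutoff": 0.01,
            "broad_pvalue_cutoff": 0.1,
            "enrichment": "rpm_ip >= 2*rpm_input and rpm_ip - rpm_input > 1",
            "tss_window": [ann_cfg.upstream_bp, ann_cfg.downstream_bp],
            "broad_min_width_bp": ann_cfg.broad_min_width_bp,
            "standard_width_bp": ann_cfg.standard_width_bp,
            "stitch_bp": rose_cfg.stitch_bp,
            "liftover_min_match": lift_cfg.min_match,
            "de_thresholds": "|log2FC|>=2, p<0.001, FDR<0.01",
            "crc_scan_threshold_bits": _CRC_SCAN_THRESHOLD,
        },
        "replicate_correlation": {m: round(r, 6) for m, r in rep_r.items()},
        "counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
    return manifest
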