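"""Synthetic-study generator: determinism, planted structure, sizing."""

import numpy as np
import pytest

import cisreg.io as gio
from cisreg.conservation import map_interval
from cisreg.core import GenomicInterval
from cisreg.simulate import (SizingError, SyntheticConfig, generate_chain_pair,
                             generate_de_stats, generate_peaks_and_coverage,
                             generate_pwm_set, generate_reference, plant_motif)

SMALL = dict(n_chroms=2, chrom_len=1_500_000, n_genes=60,
             n_h3k4me3_peaks=60, n_h3k27ac_peaks=90, n_se_loci=6)


class TestConfig:
    def test_fraction_sum_validated(self):
        with pytest.raises(ValueError):
            SyntheticConfig(frac_functional=0.6, frac_sequence_only=0.6)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(noise_sd=-0.1)


class TestReference:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        for sub in ("a", "b"):
            cfg = SyntheticConfig(seed=1, **SMALL)
            ref = generate_reference(cfg)
            generate_peaks_and_coverage(cfg, ref)
            ref.write(tmp_path / sub)
        for name in ("genome.fa", "genes.gtf", "expression.tsv",
                     "genome.chrom.sizes"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_zero_genes_empty_annotation_and_expression(self):
        ref = generate_reference(SyntheticConfig(seed=1, n_genes=0))
        assert len(ref.genes) == 0
        assert len(ref.expression) == 0

    def test_gene_count_bounds_and_strand_consistency(self):
        cfg = SyntheticConfig(seed=2, n_chroms=2, chrom_len=1_000_000,
                              n_genes=50)
        ref = generate_reference(cfg)
        assert len(ref.genes) == 50
        tss = ref.tss_records()
        assert len(tss) == 50
        for t, row in zip(tss, ref.genes.itertuples()):
            assert 0 <= t.pos < cfg.chrom_len
            assert t.pos == (row.start if row.strand == "+" else row.end - 1)
        # non-overlapping genes per chromosome
        for _, sub in ref.genes.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"].values[1:] >= sub["end"].values[:-1]).all()

    def test_chrom_too_short_raises_sizing_error(self):
        with pytest.raises(SizingError):
            generate_reference(SyntheticConfig(seed=1, chrom_len=100_000,
                                               n_genes=50, n_chroms=1))

    def test_expression_non_negative(self):
        ref = generate_reference(SyntheticConfig(seed=3, **SMALL))
        assert (ref.expression.to_numpy() >= 0).all()


class TestPeaksAndCoverage:
    def test_zero_noise_rpm_identity(self):
        cfg = SyntheticConfig(seed=4, noise_sd=0.0, **SMALL)
        ref = generate_reference(cfg, with_sequence=False)
        peaks = generate_peaks_and_coverage(cfg, ref)
        for pk in peaks.h3k27ac:
            got = peaks.tracks["k27_ip"].rpm(pk.interval)
            assert got == pytest.approx(pk.rpm_ip, rel=1e-9)
            got_in = peaks.tracks["k27_input"].rpm(pk.interval)
            assert got_in == pytest.approx(pk.rpm_input, rel=1e-9)

    def test_heavy_tail_top_stitched_signal_dominates_median(self):
        cfg = SyntheticConfig(seed=5, se_tail_exponent=1.2, **SMALL)
        ref = generate_reference(cfg, with_sequence=False)
        peaks = generate_peaks_and_coverage(cfg, ref)
        from cisreg.annotate import AnnotationConfig, classify_elements
        from cisreg.superenhancer import score_regions, stitch

        res = classify_elements(peaks.h3k4me3, peaks.h3k27ac,
                                ref.tss_records(), AnnotationConfig(),
                                ref.chrom_sizes)
        regions = score_regions(stitch(res.enhancers),
                                peaks.tracks["k27_ip"],
                                peaks.tracks["k27_input"])
        signals = np.array([r.signal for r in regions])
        assert signals.max() >= 10 * np.median(signals)

    def test_all_h3k4me3_at_tss_leaves_no_distal_placements(self):
        cfg = SyntheticConfig(seed=6, frac_k4_at_tss=1.0, **SMALL)
        ref = generate_reference(cfg, with_sequence=False)
        peaks = generate_peaks_and_coverage(cfg, ref)
        from cisreg.annotate import AnnotationConfig, tss_window

        windows = [tss_window(t) for t in ref.tss_records()]
        for pk in peaks.h3k4me3:
            assert any(pk.interval.overlaps(w) for w in windows)

    def test_planted_se_genes_recorded_and_boosted(self):
        cfg = SyntheticConfig(seed=7, **SMALL)
        ref = generate_reference(cfg, with_sequence=False)
        generate_peaks_and_coverage(cfg, ref)
        assert len(ref.se_target_genes) == cfg.n_se_loci
        boosted = ref.expression.loc[ref.se_target_genes].mean(axis=1)
        assert (boosted >= 2.0 * 2 ** cfg.de_effect_log2 * 0.9).all()

    def test_round_trips_through_io(self, tmp_path):
        cfg = SyntheticConfig(seed=8, **SMALL)
        ref = generate_reference(cfg, with_sequence=False)
        peaks = generate_peaks_and_coverage(cfg, ref)
        peaks.write(tmp_path)
        back = gio.read_peaks(tmp_path / "h3k27ac.narrowPeak", "H3K27ac")
        assert len(back) == len(peaks.h3k27ac)
        assert [p.interval for p in back] == [p.interval for p in peaks.h3k27ac]
        from cisreg.qc import CoverageTrack

        track = CoverageTrack.from_bedgraph(tmp_path / "k27_ip.bedGraph",
                                            ref.chrom_sizes, cfg.bin_size)
        orig = peaks.tracks["k27_ip"]
        for chrom in ref.chrom_sizes:
            np.testing.assert_allclose(track.density[chrom],
                                       orig.density[chrom], rtol=1e-6)


class TestChainPair:
    def test_identity_configuration_maps_everything_unchanged(self):
        cfg = SyntheticConfig(seed=9, chain_coverage=1.0,
                              chain_with_indels=False, **SMALL)
        ref = generate_reference(cfg, with_sequence=False)
        elements = [
            gio_el for gio_el in (
                _mk(i, s) for i, s in enumerate(range(10_000, 900_000, 50_000))
            )
        ]
        pair = generate_chain_pair(cfg, ref, source_elements=elements)
        for el in elements:
            res = map_interval(el.interval, pair.chains)
            assert res.mapped
            assert (res.target.start, res.target.end) == \
                (el.interval.start, el.interval.end)

    def test_reverse_strand_chain_present_and_reflects(self):
        cfg = SyntheticConfig(seed=10, **SMALL)
        ref = generate_reference(cfg, with_sequence=False)
        pair = generate_chain_pair(cfg, ref)
        strands = {c.t_strand for c in pair.chains}
        assert "-" in strands
        rev = next(c for c in pair.chains if c.t_strand == "-")
        from conftest import per_base_target_positions

        iv = GenomicInterval(rev.s_chrom, rev.s_start + 500,
                             rev.s_start + 1_500)
        res = map_interval(iv, [rev])
        oracle = per_base_target_positions(iv, rev)
        assert res.mapped
        assert res.target.start == min(oracle.values())
        assert res.target.end == max(oracle.values()) + 1

    def test_functional_targets_overlap_mapped_sources(self):
        cfg = SyntheticConfig(seed=11, **SMALL)
        ref = generate_reference(cfg, with_sequence=False)
        pair = generate_chain_pair(cfg, ref)
        targets_by_id = {t.element_id: t for t in pair.target_elements}
        truth = pair.truth.set_index("element_id")["status"]
        for el in pair.source_elements:
            if truth[el.element_id] != "functional":
                continue
            res = map_interval(el.interval, pair.chains)
            tgt = targets_by_id[f"tgt_{el.element_id.split('_')[1]}"
                                if el.element_id.startswith("src_")
                                else f"tgt_{el.element_id}"]
            assert res.mapped and res.target.overlaps(tgt.interval)


class TestDEStats:
    def test_planted_de_set_recovered_by_thresholds(self):
        from cisreg.expression import apply_de_thresholds

        cfg = SyntheticConfig(seed=12, **SMALL)
        genes = [f"G{i:04d}" for i in range(200)]
        stats, truth = generate_de_stats(cfg, genes)
        table, counts = apply_de_thresholds(stats, compute_fdr=True)
        assert set(table.index[table["direction"] == "up_in_A"]) == truth["up"]
        assert set(table.index[table["direction"] == "down_in_A"]) == truth["down"]
        assert counts["up_in_A"] == len(truth["up"])


class TestPWMSet:
    def test_rows_sum_to_one_and_seeded_determinism(self, tmp_path):
        cfg = SyntheticConfig(seed=13)
        pwms1, kmers1 = generate_pwm_set(cfg, ["TFA", "TFB"])
        pwms2, kmers2 = generate_pwm_set(cfg, ["TFA", "TFB"])
        assert kmers1 == kmers2
        for tf in pwms1:
            np.testing.assert_allclose(pwms1[tf].matrix.sum(axis=1), 1.0,
                                       atol=1e-9)
            np.testing.assert_array_equal(pwms1[tf].matrix, pwms2[tf].matrix)
        for sub in ("x", "y"):
            gio.write_meme_pwms({t: p.matrix for t, p in pwms1.items()},
                                tmp_path / f"{sub}.meme")
        assert (tmp_path / "x.meme").read_bytes() == \
            (tmp_path / "y.meme").read_bytes()

    def test_planted_occurrences_retrievable_by_string_match(self):
        cfg = SyntheticConfig(seed=14)
        pwms, kmers = generate_pwm_set(cfg, ["TFA"])
        seq = plant_motif("A" * 200, kmers["TFA"], [30, 100])
        assert seq[30:40] == kmers["TFA"]
        assert seq.count(kmers["TFA"]) >= 2

    def test_empty_tf_names_rejected(self):
        with pytest.raises(ValueError):
            generate_pwm_set(SyntheticConfig(seed=1), [])

    def test_plant_outside_sequence_rejected(self):
        with pytest.raises(ValueError):
            plant_motif("ACGT", "ACGTACGT", [2])


def _mk(i, start):
    from conftest import make_element

    return make_element(start=start, end=start + 2_000,
                        element_id=f"e{i:03d}")
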