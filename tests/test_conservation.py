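"""Chain mapping, conservation classification, distances, state overlay."""

import numpy as np
import pandas as pd
import pytest

from cisreg.conservation import (LiftOverConfig, classify_conservation,
                                 cluster_state_matrix, conservation_fractions,
                                 distance_to_nearest_gene,
                                 ks_compare_with_random_control, map_interval,
                                 overlay_chromatin_states)
from cisreg.core import ChainAlignment, GenomicInterval, StateSegment, TSSRecord

from conftest import (identity_chain, make_element, per_base_target_positions,
                      random_chains)


class TestMapInterval:
    def test_identity_chain_maps_to_same_coordinates(self):
        chain = identity_chain(size=50_000)
        res = map_interval(GenomicInterval("chr1", 1_000, 3_000), [chain])
        assert res.mapped
        assert (res.target.start, res.target.end) == (1_000, 3_000)
        assert res.fraction == 1.0

    def test_min_match_boundary(self):
        # 2000 bp element, exactly 500 bp inside the single aligned block
        chain = ChainAlignment(1, 100.0, "chr1", 100_000, 0, 500, "chr2",
                               100_000, "+", 0, 500, [(500, 0, 0)])
        iv = GenomicInterval("chr1", 0, 2_000)
        assert map_interval(iv, [chain], LiftOverConfig(min_match=0.2)).mapped
        res = map_interval(iv, [chain], LiftOverConfig(min_match=0.3))
        assert not res.mapped
        assert "below_min_match" in res.reason

    def test_reverse_strand_reflection(self):
        # block source [100, 400) <-> target reverse-strand [50, 350)
        chain = ChainAlignment(1, 100.0, "chr1", 10_000, 100, 400, "chr2",
                               5_000, "-", 50, 350, [(300, 0, 0)])
        iv = GenomicInterval("chr1", 150, 250)
        res = map_interval(iv, [chain])
        oracle = per_base_target_positions(iv, chain)
        assert res.mapped
        assert res.target.start == min(oracle.values())
        assert res.target.end == max(oracle.values()) + 1
        assert res.target.width == iv.width  # fully inside one block

    def test_split_across_chains_rejected_by_default(self):
        left = ChainAlignment(1, 1.0, "chr1", 10_000, 0, 1_000, "chr2",
                              10_000, "+", 0, 1_000, [(1_000, 0, 0)])
        right = ChainAlignment(2, 1.0, "chr1", 10_000, 1_000, 2_000, "chr3",
                               10_000, "+", 0, 1_000, [(1_000, 0, 0)])
        iv = GenomicInterval("chr1", 0, 2_000)
        res = map_interval(iv, [left, right])
        assert not res.mapped and res.reason == "split_across_chains"
        res = map_interval(iv, [left, right], LiftOverConfig(allow_multiple=True))
        assert res.mapped

    def test_agrees_with_per_base_oracle_on_random_chains(self):
        rng = np.random.default_rng(20)
        chains = random_chains(rng)
        cfg = LiftOverConfig(min_match=0.2)
        for _ in range(200):
            s = int(rng.integers(0, 19_000))
            iv = GenomicInterval("chr1", s, s + int(rng.integers(50, 1_000)))
            res = map_interval(iv, chains, cfg)
            per_chain = {
                ch.chain_id: per_base_target_positions(iv, ch) for ch in chains
            }
            qualifying = {
                cid: pos for cid, pos in per_chain.items()
                if len(pos) / iv.width >= cfg.min_match
            }
            if not qualifying:
                assert not res.mapped
            elif len(qualifying) > 1:
                assert not res.mapped and res.reason == "split_across_chains"
            else:
                (cid, pos), = qualifying.items()
                assert res.mapped and res.chain_id == cid
                assert res.mapped_bases == len(pos)
                assert res.target.start == min(pos.values())
                assert res.target.end == max(pos.values()) + 1


class TestClassifyConservation:
    def _chain(self):
        return identity_chain(size=1_000_000)

    def test_one_bp_overlap_same_class_is_functional(self):
        el = make_element(start=10_000, end=12_000, element_id="e")
        tgt = make_element(start=11_999, end=14_000, element_id="t")
        (call,) = classify_conservation([el], [self._chain()], [tgt])
        assert call.status == "functional"
        assert call.matched_target_ids == ("t",)

    def test_class_mismatch_is_sequence_only(self):
        el = make_element(start=10_000, end=12_000, element_id="e")
        tgt = make_element(start=10_000, end=12_000, element_id="t",
                           element_class="promoter")
        with pytest.warns(UserWarning, match="absent"):
            (call,) = classify_conservation([el], [self._chain()], [tgt])
        assert call.status == "sequence_only"

    def test_statuses_partition_elements(self):
        rng = np.random.default_rng(21)
        chains = random_chains(rng)
        els = [make_element(start=int(s), end=int(s) + 500,
                            element_id=f"e{i}")
               for i, s in enumerate(rng.integers(0, 19_000, 100))]
        tgts = [make_element(chrom="tchr1", start=int(s), end=int(s) + 500,
                             element_id=f"t{i}")
                for i, s in enumerate(rng.integers(0, 5_000, 20))]
        calls = classify_conservation(els, chains, tgts)
        fractions = conservation_fractions(calls)
        assert sum(fractions.values()) == pytest.approx(1.0)
        assert len(calls) == len(els)

    def test_planted_fraction_recovery(self):
        """Slot-built genome pair: recovered fractions match the planted
        frac_functional / frac_sequence_only within 3 binomial SD."""
        from cisreg.simulate import SyntheticConfig, generate_chain_pair, \
            generate_reference

        cfg = SyntheticConfig(seed=2, n_chroms=2, chrom_len=12_000_000,
                              n_h3k27ac_peaks=2_000, n_genes=0,
                              frac_functional=0.30, frac_sequence_only=0.55)
        ref = generate_reference(cfg, with_sequence=False)
        pair = generate_chain_pair(cfg, ref)
        calls = classify_conservation(pair.source_elements, pair.chains,
                                      pair.target_elements)
        fr = conservation_fractions(calls)
        n = len(calls)
        for planted, key in ((0.30, "functional"), (0.55, "sequence_only")):
            sd = np.sqrt(planted * (1 - planted) / n)
            assert abs(fr[key] - planted) < 3 * sd
        truth = pair.truth.set_index("element_id")["status"]
        assert all(truth[c.element_id] == c.status for c in calls)


class TestDistances:
    TSS = [TSSRecord("g1", "chr1", 50_000, "+", 1.0),
           TSSRecord("g2", "chr1", 90_000, "+", 1.0)]

    def test_element_centered_on_tss_is_zero(self):
        el = make_element(start=49_000, end=51_000)
        assert distance_to_nearest_gene([el], self.TSS)[0] == 0

    def test_midpoint_five_kb_away(self):
        el = make_element(start=54_000, end=56_000)
        assert distance_to_nearest_gene([el], self.TSS)[0] == 5_000

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(22)
        tss = [TSSRecord(f"g{i}", "chr1", int(p), "+", 1.0)
               for i, p in enumerate(rng.integers(0, 900_000, 60))]
        els = [make_element(start=int(s), end=int(s) + 2_000,
                            element_id=f"e{i}")
               for i, s in enumerate(rng.integers(0, 890_000, 80))]
        got = distance_to_nearest_gene(els, tss)
        for el, d in zip(els, got):
            oracle = min(abs(t.pos - el.interval.midpoint) for t in tss)
            assert d == oracle


class TestKSControl:
    def test_identical_samples(self):
        x = np.arange(100.0)
        res = ks_compare_with_random_control(x, x, x, n_draws=3, draw_size=10)
        assert res["ks_statistic"] == 0.0
        assert res["pvalue"] == pytest.approx(1.0)

    def test_statistic_equals_ecdf_sup_difference(self):
        rng = np.random.default_rng(23)
        a = rng.normal(0, 1, 400)
        b = rng.normal(0.5, 1, 300)
        res = ks_compare_with_random_control(a, b, np.concatenate([a, b]),
                                             n_draws=2, draw_size=50)
        grid = np.sort(np.concatenate([a, b]))
        ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
        ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
        assert res["ks_statistic"] == pytest.approx(
            np.abs(ecdf_a - ecdf_b).max(), rel=1e-12
        )

    def test_fixed_seed_reproducible_draws(self):
        pool = np.arange(1_000.0)
        r1 = ks_compare_with_random_control(pool[:10], pool[10:20], pool,
                                            n_draws=5, draw_size=100, seed=9)
        r2 = ks_compare_with_random_control(pool[:10], pool[10:20], pool,
                                            n_draws=5, draw_size=100, seed=9)
        for d1, d2 in zip(r1["control_draws"], r2["control_draws"]):
            np.testing.assert_array_equal(d1, d2)

    def test_draw_size_exceeding_pool_rejected(self):
        with pytest.raises(ValueError):
            ks_compare_with_random_control([1.0], [2.0], np.arange(5.0),
                                           draw_size=10)

    def test_planted_proximity_rejected_by_ks(self):
        """Functional enhancers planted nearer genes: KS rejects and the
        random control band sits between the two groups."""
        rng = np.random.default_rng(24)
        d_funct = rng.exponential(3_000, 500)
        d_seq = rng.exponential(12_000, 500)
        pool = np.concatenate([d_funct, d_seq])
        res = ks_compare_with_random_control(d_funct, d_seq, pool,
                                             n_draws=100, draw_size=400,
                                             seed=1)
        assert res["pvalue"] < 0.01
        med = res["control_medians"]
        assert np.median(d_funct) < med.min() and med.max() < np.median(d_seq)


class TestOverlay:
    CATEGORIES = {"EnhA": "active_enhancer", "EnhWk": "weak_enhancer",
                  "DNase": "primary_DNase", "Quies": "other"}

    def test_active_enhancer_in_one_tissue_counts_regulatory(self):
        iv = GenomicInterval("chr1", 1_000, 3_000)
        segs = [StateSegment(GenomicInterval("chr1", 0, 5_000), "EnhA", "kidney"),
                StateSegment(GenomicInterval("chr1", 0, 5_000), "Quies", "heart")]
        overlay = overlay_chromatin_states([("e1", iv)], segs, self.CATEGORIES)
        assert overlay.n_regulatory == 1
        assert overlay.matrix.loc["e1", "kidney"] == "active_enhancer"

    def test_quiescent_everywhere_not_regulatory(self):
        iv = GenomicInterval("chr1", 1_000, 3_000)
        segs = [StateSegment(GenomicInterval("chr1", 0, 5_000), "Quies", t)
                for t in ("kidney", "heart")]
        overlay = overlay_chromatin_states([("e1", iv)], segs, self.CATEGORIES)
        assert overlay.n_regulatory == 0

    def test_largest_overlap_wins(self):
        iv = GenomicInterval("chr1", 0, 1_000)
        segs = [StateSegment(GenomicInterval("chr1", 0, 600), "EnhA", "kidney"),
                StateSegment(GenomicInterval("chr1", 600, 1_000), "Quies",
                             "kidney")]
        overlay = overlay_chromatin_states([("e1", iv)], segs, self.CATEGORIES)
        assert overlay.matrix.loc["e1", "kidney"] == "active_enhancer"

    def test_uncovered_tissue_is_other(self):
        iv = GenomicInterval("chr1", 10_000, 12_000)
        segs = [StateSegment(GenomicInterval("chr1", 0, 600), "EnhA", "kidney")]
        overlay = overlay_chromatin_states([("e1", iv)], segs, self.CATEGORIES)
        assert overlay.matrix.loc["e1", "kidney"] == "other"

    def test_planted_regulatory_fraction_recovered(self):
        """Disjoint elements with a planted regulatory fraction: the overlay
        recovers it within 3 binomial SD."""
        from cisreg.simulate import SyntheticConfig, generate_state_segments

        cfg = SyntheticConfig(seed=3, frac_seqonly_regulatory=0.78)
        elements = [(f"e{i}", GenomicInterval("tchr1", i * 10_000, i * 10_000 + 2_000))
                    for i in range(800)]
        segments, cat_map, truth = generate_state_segments(cfg, elements)
        overlay = overlay_chromatin_states(elements, segments, cat_map)
        assert overlay.n_regulatory == int(truth["regulatory"].sum())
        sd = np.sqrt(0.78 * 0.22 / 800)
        assert abs(overlay.regulatory_fraction - 0.78) < 3 * sd


class TestClusterStateMatrix:
    def _matrix(self, labels, tissues=("kidney", "heart")):
        return pd.DataFrame(labels, columns=list(tissues))

    def test_two_separated_blobs(self):
        rows = [["active_enhancer", "active_enhancer"]] * 30 + \
               [["other", "other"]] * 30
        matrix = self._matrix(rows)
        matrix.index = [f"e{i}" for i in range(60)]
        clusters = cluster_state_matrix(matrix, k=2, seed=0)
        assert clusters.iloc[:30].nunique() == 1
        assert clusters.iloc[30:].nunique() == 1
        assert clusters.iloc[0] != clusters.iloc[-1]

    def test_k_equals_n_each_own_cluster(self):
        rows = [["active_enhancer", "other"], ["other", "active_enhancer"],
                ["weak_enhancer", "other"]]
        clusters = cluster_state_matrix(self._matrix(rows), k=3, seed=0)
        assert clusters.nunique() == 3

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            cluster_state_matrix(self._matrix([["other", "other"]]), k=5)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(25)
        cats = np.array(["active_enhancer", "weak_enhancer", "other"])
        rows = cats[rng.integers(0, 3, size=(50, 4))]
        matrix = pd.DataFrame(rows, columns=list("abcd"))
        c1 = cluster_state_matrix(matrix, k=5, seed=42)
        c2 = cluster_state_matrix(matrix, k=5, seed=42)
        pd.testing.assert_series_equal(c1, c2)
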