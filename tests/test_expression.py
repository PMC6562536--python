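"""Quantile normalization, DE thresholds, linkage, rank-sum comparisons."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from cisreg.core import TSSRecord
from cisreg.expression import (DEThresholds, apply_de_thresholds,
                               compare_groups, link_elements_to_genes,
                               quantile_normalize, tss_flank_intensity)
from cisreg.qc import CoverageTrack

from conftest import make_element


class TestQuantileNormalize:
    def test_hand_computed_two_columns(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        # per-rank means: (1+4)/2, (2+5)/2, (3+6)/2
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)

    def test_ties_get_mean_of_tied_reference_values(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        ref = np.sort(m.to_numpy(), axis=0).mean(axis=1)
        assert out["a"][0] == out["a"][1] == pytest.approx(ref[:2].mean())

    def test_idempotent(self):
        rng = np.random.default_rng(30)
        m = pd.DataFrame(rng.lognormal(1, 1, size=(50, 3)),
                         columns=list("abc"))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy())

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_sorted_columns_identical_after_normalization(self, data):
        # tie-free columns: with within-column ties the tie-averaging rule
        # deliberately trades the exact sorted-vector identity for rank
        # symmetry, so the defining property is asserted on distinct values
        n = data.draw(st.integers(2, 25))
        cols = {
            name: data.draw(st.lists(st.floats(0, 1e6), min_size=n,
                                     max_size=n, unique=True))
            for name in "abc"
        }
        m = pd.DataFrame(cols, dtype=float)
        out = quantile_normalize(m).to_numpy()
        ranked = np.sort(out, axis=0)
        np.testing.assert_allclose(ranked[:, 1], ranked[:, 0], atol=1e-9)
        np.testing.assert_allclose(ranked[:, 2], ranked[:, 0], atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame())


class TestDEThresholds:
    def _stats(self, rows):
        return pd.DataFrame(rows, columns=["log2_fold", "pvalue", "fdr"],
                            index=[f"g{i}" for i in range(len(rows))])

    def test_boundary_inclusive_fold_strict_p_and_fdr(self):
        df, counts = apply_de_thresholds(
            self._stats([
                (2.0, 5e-4, 0.005),    # DE: fold boundary is inclusive
                (1.99, 1e-9, 1e-9),    # ns: fold below threshold
                (2.5, 0.001, 1e-9),    # ns: p must be strictly < 0.001
                (-2.5, 1e-5, 0.01),    # ns: fdr must be strictly < 0.01
                (-2.5, 1e-5, 0.005),   # DE down
            ])
        )
        assert counts == {"up_in_A": 1, "down_in_A": 1, "ns": 3}
        assert df.loc["g0", "direction"] == "up_in_A"
        assert df.loc["g4", "direction"] == "down_in_A"

    def test_hand_counted_toy_table(self):
        rng = np.random.default_rng(31)
        rows = []
        for i in range(10):
            de = i < 3
            rows.append((
                (2.5 if i % 2 else -2.5) if de else rng.normal(0, 0.3),
                1e-6 if de else 0.5,
                1e-4 if de else 0.9,
            ))
        _, counts = apply_de_thresholds(self._stats(rows))
        assert counts["up_in_A"] + counts["down_in_A"] == 3
        assert sum(counts.values()) == 10

    def test_missing_fdr_without_bh_rejected(self):
        stats = pd.DataFrame({"log2_fold": [2.5], "pvalue": [1e-6]})
        with pytest.raises(ValueError, match="fdr"):
            apply_de_thresholds(stats)

    def test_bh_fdr_computed_when_requested(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(32)
        pvals = np.concatenate([10.0 ** -rng.uniform(5, 9, 5),
                                rng.uniform(0.01, 1, 45)])
        stats = pd.DataFrame({
            "log2_fold": np.where(np.arange(50) < 5, 3.0, 0.1),
            "pvalue": pvals,
        }, index=[f"g{i}" for i in range(50)])
        df, counts = apply_de_thresholds(stats, compute_fdr=True)
        np.testing.assert_allclose(
            df["fdr"], multipletests(pvals, method="fdr_bh")[1]
        )
        assert counts["up_in_A"] == 5


class TestTssFlank:
    def test_zero_coverage(self):
        track = CoverageTrack.zeros({"chr1": 100_000}, 10, 1e6)
        tss = [TSSRecord("g1", "chr1", 50_000, "+", 1.0)]
        assert tss_flank_intensity(tss, track)["g1"] == 0.0

    def test_uniform_track_identical_for_interior_genes(self):
        track = CoverageTrack.zeros({"chr1": 100_000}, 10, 1e6)
        track.density["chr1"][:] = 0.01
        tss = [TSSRecord(f"g{i}", "chr1", p, "+", 1.0)
               for i, p in enumerate((20_000, 50_000, 80_000))]
        vals = tss_flank_intensity(tss, track)
        assert len(set(round(v, 9) for v in vals.values())) == 1

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(33)
        track = CoverageTrack.zeros({"chr1": 50_000}, 10, 1e6)
        track.density["chr1"][:] = rng.random(5_000) * 0.01
        per_base = np.repeat(track.density["chr1"], 10)
        tss = [TSSRecord(f"g{i}", "chr1", int(p), "+", 1.0)
               for i, p in enumerate(rng.integers(2_000, 48_000, 20))]
        vals = tss_flank_intensity(tss, track, flank_bp=1000)
        for t in tss:
            oracle = 1e6 * per_base[t.pos - 1000 : t.pos + 1000].sum() / 1e6
            assert vals[t.gene_id] == pytest.approx(oracle, rel=1e-9)


class TestLinkage:
    def test_overlapping_tss_assigned(self):
        tss = [TSSRecord("g1", "chr1", 10_500, "+", 1.0),
               TSSRecord("g2", "chr1", 90_000, "+", 1.0)]
        el = make_element(start=10_000, end=11_000, element_id="e")
        assert link_elements_to_genes([el], tss)["e"] == "g1"

    def test_equidistant_tie_lexicographic(self):
        tss = [TSSRecord("gB", "chr1", 9_000, "+", 1.0),
               TSSRecord("gA", "chr1", 11_000, "+", 1.0)]
        el = make_element(start=9_500, end=10_500, element_id="e")  # mid 10_000
        assert link_elements_to_genes([el], tss)["e"] == "gA"

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(34)
        tss = [TSSRecord(f"g{i}", "chr1", int(p), "+", 1.0)
               for i, p in enumerate(rng.integers(0, 500_000, 50))]
        els = [make_element(start=int(s), end=int(s) + 1_000,
                            element_id=f"e{i}")
               for i, s in enumerate(rng.integers(0, 499_000, 60))]
        got = link_elements_to_genes(els, tss)
        for el in els:
            mid = el.interval.midpoint
            oracle = min(tss, key=lambda t: (abs(t.pos - mid), t.gene_id))
            assert got[el.element_id] == oracle.gene_id


def enumeration_rank_sum_p(a, b, alternative):
    """Exact Wilcoxon rank-sum p by enumerating all rank assignments."""
    pooled = np.concatenate([a, b])
    n = len(a)
    ranks = rankdata(pooled)
    obs_u = (sum(1.0 for x in a for y in b if x > y)
             + 0.5 * sum(1.0 for x in a for y in b if x == y))
    us = np.array([
        ranks[list(idx)].sum() - n * (n + 1) / 2
        for idx in combinations(range(len(pooled)), n)
    ])
    ge, le = np.mean(us >= obs_u), np.mean(us <= obs_u)
    if alternative == "greater":
        return ge
    if alternative == "less":
        return le
    return min(1.0, 2 * min(ge, le))


class TestCompareGroups:
    def test_small_example_exact_one_sided(self):
        # {1,2} vs {3,4}: 1 of C(4,2)=6 rank assignments is as extreme
        _, p = compare_groups([1, 2], [3, 4], alternative="less")
        assert p == pytest.approx(1 / 6)

    def test_identical_groups_two_sided_p_one(self):
        _, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_matches_full_enumeration_up_to_6x6(self):
        rng = np.random.default_rng(35)
        for n in range(1, 7):
            for m in range(n, 7):
                a = rng.normal(size=n)
                b = rng.normal(size=m) + 0.7
                for alt in ("two-sided", "less", "greater"):
                    _, p = compare_groups(a, b, alternative=alt)
                    oracle = enumeration_rank_sum_p(a, b, alt)
                    assert p == pytest.approx(oracle, rel=1e-9)

    def test_exact_and_asymptotic_agree_on_large_shifted_normals(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(36)
        a = rng.normal(0.3, 1, size=8)
        b = rng.normal(0, 1, size=100)
        exact = mannwhitneyu(a, b, alternative="greater", method="exact").pvalue
        approx = mannwhitneyu(a, b, alternative="greater",
                              method="asymptotic", use_continuity=False).pvalue
        assert approx == pytest.approx(exact, rel=0.10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])

    def test_planted_shift_detected_in_direction(self):
        rng = np.random.default_rng(37)
        high = rng.normal(4, 1, 40)   # e.g. SE-linked gene expression
        low = rng.normal(2, 1, 120)
        _, p = compare_groups(high, low, alternative="greater")
        assert p < 0.01
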