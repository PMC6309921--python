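"""Normalised region quantification, imputation contract, CRI,
mark ratios, binned correlation and rank tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnctx.annotation import TranscriptionUnit
from lnctx.quantify import (
    binned_correlation,
    chromatin_retention_index,
    class_window,
    compare_groups,
    cri_table,
    filter_and_impute,
    ip_minus_input_value,
    mark_ratio,
    normalize_quant,
    region_basecount,
)
from lnctx.signal import StrandedSignalTrack


class TestRegionBasecount:
    def test_uniform(self, make_track):
        trk = make_track([("chrA", "+", 1000 + i, 2.0) for i in range(100)])
        assert region_basecount(trk, "chrA", 1000, 1100, "+") == 200

    def test_empty_track(self, make_track):
        assert region_basecount(make_track(), "chrA", 0, 5000, "+") == 0

    def test_unknown_chromosome(self, make_track):
        with pytest.raises(KeyError):
            region_basecount(make_track(), "chrZ", 0, 10, "+")

    def test_matches_naive_oracle_on_random_regions(self, chrom_sizes, rng):
        trk = StrandedSignalTrack(chrom_sizes, library_size=int(1e8))
        pos = rng.integers(0, 100_000, size=5000)
        np.add.at(trk.array("chrA", "+"), pos, 1.0)
        dense = np.zeros(100_000)
        np.add.at(dense, pos, 1.0)
        for _ in range(50):
            s = int(rng.integers(0, 99_000))
            e = s + int(rng.integers(1, 1000))
            assert region_basecount(trk, "chrA", s, e, "+") == dense[s:e].sum()

    def test_strand_modes(self, make_track):
        trk = make_track([("chrA", "+", 10, 3.0), ("chrA", "-", 10, 5.0)])
        assert region_basecount(trk, "chrA", 0, 20, "+", "sense") == 3
        assert region_basecount(trk, "chrA", 0, 20, "+", "antisense") == 5
        assert region_basecount(trk, "chrA", 0, 20, "+", "both") == 8


class TestNormalizeQuant:
    def test_reference_example(self):
        q = normalize_quant(100, int(1e8), 1000)
        assert q.value == pytest.approx(0.1)
        assert q.log2_value == pytest.approx(np.log2(0.1), abs=1e-4)

    def test_zero_count_defers_log(self):
        q = normalize_quant(0, int(1e8), 1000)
        assert q.value == 0 and np.isnan(q.log2_value) and not q.imputed

    @given(
        count=st.floats(0, 1e6),
        lib=st.integers(1_000, 2_000_000_000),
        length=st.integers(1, 1_000_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_formula_reevaluation(self, count, lib, length):
        q = normalize_quant(count, lib, length)
        assert q.value == pytest.approx(count * (1e8 / lib) / length)

    @given(count=st.floats(1, 1e5), scale=st.integers(2, 100))
    @settings(max_examples=50, deadline=None)
    def test_scaling_invariance(self, count, scale):
        a = normalize_quant(count, 1_000_000, 500)
        b = normalize_quant(count * scale, 1_000_000 * scale, 500)
        assert b.value == pytest.approx(a.value, rel=1e-12)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            normalize_quant(1, 100, 0)


class TestIpMinusInputImputation:
    def test_equal_signals_give_zero(self):
        assert ip_minus_input_value(10, 10, 1000, 1000, 100) == 0

    def test_twofold_ip(self):
        # ip normalised to 2x input over 1 kb
        v = ip_minus_input_value(20, 10, 1_000_000, 1_000_000, 1000)
        assert v == pytest.approx((20 - 10) * 100 / 1000)

    def test_min_half_rule(self):
        # region 3 is kept by its positive value in the other sample;
        # its non-positive s1 entry becomes min(2.0, 0.5)/2 = 0.25
        table = pd.DataFrame({"s1": [2.0, 0.5, -1.0], "s2": [1.0, 1.0, 1.0]})
        out, mask = filter_and_impute(table)
        assert out["s1"].tolist() == [2.0, 0.5, 0.25]
        assert mask["s1"].tolist() == [False, False, True]

    def test_all_nonpositive_rows_dropped_then_no_nonpositive_remains(self, rng):
        table = pd.DataFrame(
            {
                "a": rng.normal(0.2, 1.0, size=200),
                "b": rng.normal(0.2, 1.0, size=200),
            }
        )
        out, mask = filter_and_impute(table)
        dropped = ((table <= 0).all(axis=1)).sum()
        assert len(out) == len(table) - dropped
        assert (out > 0).all().all()
        n_nonpos_pre = int((table.loc[out.index] <= 0).sum().sum())
        assert int(mask.sum().sum()) == n_nonpos_pre

    def test_empty_after_filter_raises(self):
        with pytest.raises(ValueError):
            filter_and_impute(pd.DataFrame({"s": [-1.0, 0.0]}))


def tu(gene_id="g", biotype="PROMPT", start=10_000, end=11_000, strand="+"):
    return TranscriptionUnit(gene_id, biotype, "chrA", start, end, strand,
                             ((start, end),))


class TestClassWindow:
    def test_prompt_plus(self):
        assert class_window(tu(strand="+"), "PROMPT") == (10_000, 13_000)

    def test_prompt_minus_mirrors(self):
        t = tu(strand="-")  # tss = 11_000
        assert class_window(t, "PROMPT") == (8_000, 11_000)

    def test_erna_center_window(self):
        t = tu(start=49_000, end=51_000)
        assert class_window(t, "eRNA") == (48_000, 52_000)

    def test_cri_window(self):
        assert class_window(tu(strand="+"), "CRI_PROMPT") == (10_000, 15_000)

    def test_span_classes_and_unknown(self):
        t = tu(biotype="lincRNA")
        assert class_window(t, "lincRNA") == (10_000, 11_000)
        with pytest.raises(ValueError):
            class_window(t, "exotic")


class TestCri:
    def quant(self, value, sample="chromatin"):
        from lnctx.quantify import RegionQuant

        return RegionQuant("chrA", 0, 5000, "+", sample, value * 5000, 1.0,
                           5000, value, np.log2(value) if value > 0 else np.nan)

    def test_equal_values_zero(self):
        assert chromatin_retention_index(self.quant(2.0), self.quant(2.0)).cri == 0

    def test_fourfold_gives_two(self):
        rec = chromatin_retention_index(self.quant(4.0), self.quant(1.0))
        assert rec.cri == pytest.approx(2.0)

    def test_antisymmetry(self):
        a, b = self.quant(3.7), self.quant(0.9)
        assert chromatin_retention_index(a, b).cri == pytest.approx(
            -chromatin_retention_index(b, a).cri
        )

    def test_mismatched_regions_rejected(self):
        from lnctx.quantify import RegionQuant

        other = RegionQuant("chrA", 1, 5001, "+", "", 1, 1, 5000, 1.0, 0.0)
        with pytest.raises(ValueError):
            chromatin_retention_index(self.quant(1.0), other)

    def test_cri_table_pseudovalue(self):
        chrom = pd.Series({"p1": 4.0, "p2": 2.0, "p3": 0.0})
        nuc = pd.Series({"p1": 1.0, "p2": 2.0, "p3": 1.0})
        df = cri_table(chrom, nuc)
        # zero chromatin -> half the smallest positive chromatin value (1.0)
        assert df.loc["p3", "chromatin"] == 1.0
        assert df.loc["p3", "imputed"]
        assert df.loc["p1", "cri"] == pytest.approx(2.0)


class TestMarkRatio:
    def test_equal_is_zero(self):
        assert mark_ratio(5.0, 5.0) == 0

    def test_eightfold_is_three(self):
        assert mark_ratio(8.0, 1.0) == pytest.approx(3.0)

    def test_polii_normalisation(self):
        assert mark_ratio(4.0, 1.0, polii_value=2.0) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mark_ratio(1.0, 0.0)


class TestBinnedCorrelation:
    def fill(self, trk, values, chrom="chrA"):
        for i, v in enumerate(values):
            trk.array(chrom, "+")[i * 10_000 : (i + 1) * 10_000] = v / 10_000

    def make(self, chrom_sizes, values, label):
        trk = StrandedSignalTrack(chrom_sizes, library_size=int(1e8), label=label)
        self.fill(trk, values)
        return trk

    def test_self_correlation_is_one(self, chrom_sizes, rng):
        vals = rng.random(10)
        t = self.make(chrom_sizes, vals, "a")
        mat = binned_correlation([t, t])
        assert mat.iloc[0, 1] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, chrom_sizes, rng):
        vals = rng.random(10) + 0.1
        a = self.make(chrom_sizes, vals, "a")
        b = self.make(chrom_sizes, vals**2, "b")
        assert binned_correlation([a, b]).iloc[0, 1] == pytest.approx(1.0)

    def test_planted_anticorrelation(self, chrom_sizes, rng):
        # complementary occupancy: active-mark bins vs silenced-mark bins
        active = rng.permutation(np.concatenate([np.ones(5) * 100, np.ones(5)]))
        silenced = active.max() + 1 - active
        a = self.make(chrom_sizes, active, "H3K36me3")
        b = self.make(chrom_sizes, silenced, "H3K27me3")
        assert binned_correlation([a, b]).iloc[0, 1] < -0.8

    def test_needs_two_tracks(self, chrom_sizes):
        with pytest.raises(ValueError):
            binned_correlation([self.make(chrom_sizes, [1.0], "a")])


class TestCompareGroups:
    def test_identical_groups_nonsignificant(self):
        _, p = compare_groups([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.5

    def test_full_separation(self):
        _, p = compare_groups(list(range(1, 11)), list(range(101, 111)))
        assert p < 0.001

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3], [1, 2, 3, 4], paired=True)

    def test_degenerate_all_tied(self):
        with pytest.raises(ValueError):
            compare_groups([1, 1, 1], [1, 1, 1])

    def test_type_one_error_under_null(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            a, b = rng.normal(size=(2, 20))
            _, p = compare_groups(a, b)
            rejections += p < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)
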