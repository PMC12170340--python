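"""Stranded signal container, bedGraph I/O and normalization operations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polkinetics.errors import InputError, ParseError
from polkinetics.signal import (
    StrandedBaseSignal,
    correct_antisense,
    count_region,
    estimate_antisense_ratio,
    filter_expressed,
    mask_signal,
    size_factors,
    spikein_factors,
)


def _random_signal(rng, chrom="chr1", strand="+", n=30, span=500):
    sig = StrandedBaseSignal()
    pos = 0
    starts, ends, values = [], [], []
    for _ in range(n):
        pos += int(rng.integers(0, 10))
        width = int(rng.integers(1, 12))
        starts.append(pos)
        ends.append(pos + width)
        values.append(float(rng.integers(0, 20)))
        pos += width
    sig.add_intervals(chrom, strand, starts, ends, values)
    return sig, list(zip(starts, ends, values))


def _brute_force_count(intervals, qs, qe):
    total = 0.0
    for s, e, v in intervals:
        for base in range(s, e):
            if qs <= base < qe:
                total += v
    return total


class TestContainer:
    def test_single_line_mass(self, tmp_path):
        plus = tmp_path / "p.bedgraph"
        minus = tmp_path / "m.bedgraph"
        plus.write_text("chr1\t0\t10\t2.5\n")
        minus.write_text("")
        sig = StrandedBaseSignal.read_bedgraph_pair(plus, minus)
        assert sig.count("chr1", "+", 0, 10) == pytest.approx(25.0)
        assert sig.total_mass() == pytest.approx(25.0)

    def test_roundtrip_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        sig, _ = _random_signal(rng)
        sig.add_array("chr1", "-", 100, rng.random(50))
        sig.write_bedgraph_pair(tmp_path / "p.bg", tmp_path / "m.bg")
        back = StrandedBaseSignal.read_bedgraph_pair(tmp_path / "p.bg", tmp_path / "m.bg")
        for strand in "+-":
            a = sig.runs("chr1", strand)
            b = back.runs("chr1", strand)
            for x, y in zip(a, b):
                np.testing.assert_array_equal(x, y)

    def test_overlap_rejected(self, tmp_path):
        plus = tmp_path / "p.bedgraph"
        minus = tmp_path / "m.bedgraph"
        plus.write_text("chr1\t0\t10\t1\nchr1\t5\t15\t1\n")
        minus.write_text("")
        with pytest.raises(ParseError, match="overlap"):
            StrandedBaseSignal.read_bedgraph_pair(plus, minus)

    @pytest.mark.parametrize(
        "line, msg",
        [("chr1\t0\t10\t-1\n", "negative"),
         ("chr1\t10\t5\t1\n", "end must exceed"),
         ("chr1\t0\tx\t1\n", "malformed"),
         ("chr1\t0\t10\n", "4 columns")],
    )
    def test_parse_errors_carry_line(self, tmp_path, line, msg):
        plus = tmp_path / "p.bedgraph"
        minus = tmp_path / "m.bedgraph"
        plus.write_text(line)
        minus.write_text("")
        with pytest.raises(ParseError, match=msg):
            StrandedBaseSignal.read_bedgraph_pair(plus, minus)


class TestCountRegion:
    def test_constant_slice(self):
        sig = StrandedBaseSignal()
        sig.add_intervals("chr1", "+", [0], [100], [2.0])
        assert count_region(sig, "chr1", "+", 10, 20) == pytest.approx(20.0)

    def test_empty_signal_and_unknown_chrom(self):
        sig = StrandedBaseSignal()
        assert count_region(sig, "chrX", "+", 0, 10) == 0.0
        with pytest.raises(InputError):
            count_region(sig, "chrX", "+", 0, 10, unknown_chrom="error")

    def test_matches_per_base_oracle_and_additivity(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            sig, intervals = _random_signal(rng)
            qs = int(rng.integers(0, 400))
            qe = qs + int(rng.integers(1, 120))
            mid = qs + (qe - qs) // 2
            expected = _brute_force_count(intervals, qs, qe)
            got = sig.count("chr1", "+", qs, qe)
            assert got == pytest.approx(expected)
            assert sig.count("chr1", "+", qs, mid) + sig.count(
                "chr1", "+", mid, qe
            ) == pytest.approx(got)

    def test_dense_matches_count(self):
        rng = np.random.default_rng(3)
        sig, _ = _random_signal(rng)
        dense = sig.dense("chr1", "+", 50, 250)
        assert dense.sum() == pytest.approx(sig.count("chr1", "+", 50, 250))

    def test_mask_keeps_only_regions(self):
        sig = StrandedBaseSignal()
        sig.add_intervals("chr1", "+", [0, 200], [100, 300], [1.0, 2.0])
        masked = mask_signal(sig, [("chr1", 50, 250), ("chr1", 240, 260)])
        assert masked.count("chr1", "+", 0, 50) == 0.0
        assert masked.count("chr1", "+", 50, 100) == pytest.approx(50.0)
        assert masked.count("chr1", "+", 200, 260) == pytest.approx(120.0)
        assert masked.count("chr1", "+", 260, 300) == 0.0


class TestAntisense:
    def test_known_mixture_recovered(self):
        # true (100, 0) observed through mixing at c = 0.1 is (100, 10)
        s, a = correct_antisense(100.0, 10.0, 0.1)
        assert s == pytest.approx(100.0)
        assert a == pytest.approx(0.0, abs=1e-9)

    def test_identity_and_symmetric_fixed_point(self):
        assert correct_antisense(7.0, 3.0, 0.0) == (7.0, 3.0)
        s, a = correct_antisense(50 * 1.4, 50 * 1.4, 0.4)
        assert s == pytest.approx(50.0) and a == pytest.approx(50.0)

    def test_invalid_ratio(self):
        with pytest.raises(InputError):
            correct_antisense(1.0, 1.0, 1.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        s=st.floats(0, 1e6),
        a=st.floats(0, 1e6),
        c=st.floats(0, 0.9),
    )
    def test_mixing_then_correction_is_identity(self, s, a, c):
        obs_s = s + c * a
        obs_a = a + c * s
        rs, ra = correct_antisense(obs_s, obs_a, c)
        assert rs == pytest.approx(s, rel=1e-9, abs=1e-6)
        assert ra == pytest.approx(a, rel=1e-9, abs=1e-6)

    def test_ratio_estimate_exact_on_leaky_signal(self):
        sig = StrandedBaseSignal()
        sig.add_intervals("chr1", "+", [0], [1000], [200.0])
        sig.add_intervals("chr1", "-", [0], [1000], [20.0])
        c = estimate_antisense_ratio(sig, [("chr1", "+", 0, 1000)], min_coverage=100)
        assert c == pytest.approx(0.1)

    def test_leak_free_sample_gives_zero(self):
        sig = StrandedBaseSignal()
        sig.add_intervals("chr1", "+", [0], [1000], [150.0])
        assert estimate_antisense_ratio(sig, [("chr1", "+", 0, 1000)]) == 0.0

    def test_no_qualifying_positions_errors(self):
        sig = StrandedBaseSignal()
        sig.add_intervals("chr1", "+", [0], [1000], [5.0])
        with pytest.raises(InputError, match="min_coverage"):
            estimate_antisense_ratio(sig, [("chr1", "+", 0, 1000)], min_coverage=100)

    def test_poisson_estimate_close_at_depth(self):
        rng = np.random.default_rng(5)
        lam = 500.0
        sig = StrandedBaseSignal()
        sig.add_array("chr1", "+", 0, rng.poisson(lam, 20000).astype(float))
        sig.add_array("chr1", "-", 0, rng.poisson(0.1 * lam, 20000).astype(float))
        c = estimate_antisense_ratio(sig, [("chr1", "+", 0, 20000)], min_coverage=100)
        assert abs(c - 0.1) < 0.005


class TestSizeFactors:
    def test_identical_columns_are_one(self):
        counts = pd.DataFrame({"a": [5, 10, 3], "b": [5, 10, 3], "c": [5, 10, 3]})
        np.testing.assert_allclose(size_factors(counts), 1.0)

    def test_two_sample_closed_form(self):
        counts = pd.DataFrame({"a": [10.0, 40.0, 7.0], "b": [20.0, 80.0, 14.0]})
        f = size_factors(counts)
        np.testing.assert_allclose(f.values, [1 / np.sqrt(2), np.sqrt(2)])

    def test_gene_order_invariance_and_scaling(self):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.integers(1, 500, (60, 4)).astype(float),
                              columns=list("abcd"))
        f1 = size_factors(counts)
        f2 = size_factors(counts.sample(frac=1, random_state=0))
        np.testing.assert_allclose(f1, f2)
        scaled = counts.copy()
        scaled["b"] *= 3.0
        f3 = size_factors(scaled)
        # scaling one sample scales its factor by c relative to the others
        np.testing.assert_allclose(
            (f3["b"] / f3["a"]), 3.0 * (f1["b"] / f1["a"]), rtol=1e-12
        )

    def test_agrees_with_reference_implementation(self):
        from pydeseq2.preprocessing import deseq2_norm

        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.integers(1, 1000, (50, 4)).astype(float))
        ours = size_factors(counts).to_numpy()
        _, ref = deseq2_norm(counts.T)  # reference expects samples x genes
        ref = np.asarray(ref, dtype=float).ravel()
        ref = ref / np.exp(np.mean(np.log(ref)))  # match geomean-1 convention
        np.testing.assert_allclose(ours, ref, rtol=1e-8)

    def test_no_all_positive_gene_errors(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(InputError):
            size_factors(counts)


class TestSpikeins:
    def test_reference_ratio(self):
        f = spikein_factors(pd.Series({"s1": 100.0, "s2": 200.0}))
        assert f["s1"] == 1.0 and f["s2"] == 0.5

    def test_equal_totals_all_one(self):
        f = spikein_factors(pd.Series({"a": 70.0, "b": 70.0, "c": 70.0}))
        np.testing.assert_allclose(f, 1.0)

    def test_zero_total_errors(self):
        with pytest.raises(InputError):
            spikein_factors(pd.Series({"a": 0.0, "b": 1.0}))


class TestExpressedFilter:
    @pytest.mark.parametrize(
        "reads, kept",
        [(25.0, True),   # 12.5 rpk on a 2 kb gene
         (15.0, False),  # 7.5 rpk at every time point
         (20.0, True)],  # boundary: 10 rpk counts as expressed
    )
    def test_rpk_threshold(self, reads, kept):
        counts = pd.DataFrame({"t0": [reads], "t1": [reads]}, index=["g"])
        lengths = pd.Series({"g": 2000})
        assert ("g" in filter_expressed(counts, lengths, min_rpk=10)) is kept

    def test_any_timepoint_suffices(self):
        counts = pd.DataFrame({"t0": [2.0], "t1": [30.0]}, index=["g"])
        assert "g" in filter_expressed(counts, pd.Series({"g": 2000}), 10)
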