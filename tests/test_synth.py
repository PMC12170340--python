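"""Forward-model contracts of the synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest

from polkinetics.errors import InvalidConfigError
from polkinetics.pause import detect_pause_site
from polkinetics.synth import (
    LN2,
    SimConfig,
    simulate_annotation,
    simulate_chipnexus_timecourse,
    simulate_mnetseq,
    simulate_truth,
    simulate_ttseq,
)


def _truth(n=40, seed=1, **kw):
    return simulate_truth(SimConfig(n_genes=n, seed=seed, **kw))


class TestConfig:
    def test_empty_cohort_invalid(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(n_genes=0)

    @pytest.mark.parametrize(
        "kw",
        [dict(tt_depth=0), dict(noise="gauss"), dict(antisense_ratio=0.6),
         dict(inhibition_times_min=(6.0, 30.0)), dict(calibration="bogus")],
    )
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(InvalidConfigError):
            SimConfig(**kw)


class TestTruth:
    def test_deterministic_given_seed(self):
        a = _truth(seed=7).df
        b = _truth(seed=7).df
        pd.testing.assert_frame_equal(a, b)

    def test_self_consistency_identities(self):
        truth = _truth(60, noise="poisson")
        truth.validate()  # p0*ln2/t½ == r and I == r(1-f) to 1e-12

    def test_class_trajectories_have_stated_structure(self):
        truth = _truth(400, seed=3)
        df = truth.df
        pre_b = df[df.temporal_class == "pre-B"]
        assert ((pre_b["I_96"] < pre_b["I_0"]) & (pre_b["f_96"] > pre_b["f_0"])).all()
        imac1 = df[df.temporal_class == "iMac-I"]
        assert (imac1["r_96"] > imac1["r_0"]).all()
        np.testing.assert_allclose(imac1["f_96"], imac1["f_0"])
        imac2 = df[df.temporal_class == "iMac-II"]
        assert ((imac2["f_96"] < imac2["f_0"]) & (imac2["r_96"] > imac2["r_0"])).all()
        assert (imac2["thalf_96"] < imac2["thalf_0"]).all()
        stable = df[df.temporal_class == "stable"]
        np.testing.assert_allclose(stable["I_96"], stable["I_0"])

    def test_geometry_invariants(self):
        truth = _truth(50, seed=9)
        for gid in truth.gene_ids:
            exons = truth.exons(gid)
            assert all(e > s for s, e in exons)
            assert all(exons[i][1] <= exons[i + 1][0] for i in range(len(exons) - 1))
            row = truth.df.loc[gid]
            assert 0 <= row.pause_offset < 250


class TestAnnotationForwardModel:
    def test_conflict_construction(self):
        truth = _truth(100, seed=2, conflict_fraction=0.3)
        _, tpm = simulate_annotation(truth)
        conflicted = truth.df[truth.df.conflict].index
        for gid in conflicted[:10]:
            sub = tpm[tpm.gene_id == gid]
            tps = [c for c in tpm.columns if c.endswith("h")]
            shares = sub[tps].div(sub[tps].sum(axis=0), axis=1)
            # each of the two isoforms dominates somewhere
            assert ((shares > 0.7).any(axis=1)).sum() == 2

    def test_nonconflict_majors_selectable_count(self):
        from polkinetics.annotation import select_major_isoforms

        truth = _truth(100, seed=2, conflict_fraction=0.2)
        transcripts, tpm = simulate_annotation(truth)
        models = select_major_isoforms(tpm, {t.transcript_id: t for t in transcripts})
        n_conflict = int(truth.df.conflict.sum())
        assert len(models) == 100 - n_conflict
        assert set(models) == set(truth.df.index[~truth.df.conflict])


class TestTTseqForwardModel:
    def test_noiseless_exonic_coverage_equals_I(self):
        cfg = SimConfig(n_genes=12, seed=4, noise="none", antisense_ratio=0.0)
        truth = simulate_truth(cfg)
        sig = simulate_ttseq(truth, cfg)[(0, 1)]
        for gid in truth.gene_ids[:5]:
            row = truth.df.loc[gid]
            exonic = sum(e - s for s, e in truth.exons(gid))
            total = sum(
                sig.count(row.chrom, row.strand, s, e) for s, e in truth.exons(gid)
            )
            assert total == pytest.approx(row["I_0"] * exonic, rel=1e-12)

    def test_zero_antisense_ratio_means_silent_antisense(self):
        cfg = SimConfig(n_genes=8, seed=4, noise="none", antisense_ratio=0.0)
        truth = simulate_truth(cfg)
        sig = simulate_ttseq(truth, cfg)[(0, 1)]
        for gid in truth.gene_ids:
            row = truth.df.loc[gid]
            anti = "-" if row.strand == "+" else "+"
            assert sig.count(row.chrom, anti, row.span_start, row.span_end) == 0.0

    def test_antisense_leak_is_mirrored_fraction(self):
        cfg = SimConfig(n_genes=8, seed=4, noise="none", antisense_ratio=0.2)
        truth = simulate_truth(cfg)
        sig = simulate_ttseq(truth, cfg)[(0, 1)]
        row = truth.df.iloc[0]
        anti = "-" if row.strand == "+" else "+"
        s = sig.count(row.chrom, row.strand, row.span_start, row.span_end)
        a = sig.count(row.chrom, anti, row.span_start, row.span_end)
        assert a == pytest.approx(0.2 * s, rel=1e-12)

    def test_poisson_mean_matches_rate(self):
        cfg = SimConfig(n_genes=1, seed=6, noise="poisson", tt_depth=50,
                        antisense_ratio=0.0, class_proportions={"stable": 1.0})
        truth = simulate_truth(cfg)
        sig = simulate_ttseq(truth, cfg)[(0, 1)]
        row = truth.df.iloc[0]
        s, e = truth.exons(row.gene_id)[-1]
        lam = cfg.tt_depth * row["I_0"]
        mean = sig.count(row.chrom, row.strand, s, e) / (e - s)
        se = np.sqrt(lam / (e - s))
        assert abs(mean - lam) < 3 * se


class TestMnetForwardModel:
    def test_detectable_genes_pass_rule_and_offset_exact(self):
        cfg = SimConfig(n_genes=30, seed=8, noise="none", undetectable_fraction=0.3)
        truth = simulate_truth(cfg)
        sig = simulate_mnetseq(truth, cfg)[(0, 1)]
        for gid in truth.gene_ids:
            row = truth.df.loc[gid]
            if row.strand == "+":
                window = sig.dense(row.chrom, "+", row.tss, row.tss + 250)
            else:
                window = sig.dense(row.chrom, "-", row.tss - 250, row.tss)[::-1]
            off = detect_pause_site(window)
            if row.detectable:
                assert off == row.pause_offset
            else:
                assert off is None

    def test_zero_halfwidth_concentrates_mass(self):
        cfg = SimConfig(n_genes=5, seed=8, noise="none", peak_halfwidth=0,
                        body_density=0.0, undetectable_fraction=0.0)
        truth = simulate_truth(cfg)
        sig = simulate_mnetseq(truth, cfg)[(0, 1)]
        row = truth.df.iloc[0]
        center = (row.tss + row.pause_offset if row.strand == "+"
                  else row.tss - row.pause_offset - 1)
        at_peak = sig.count(row.chrom, row.strand, center, center + 1)
        total = sig.count(row.chrom, row.strand, row.span_start, row.span_end)
        assert at_peak == pytest.approx(total) == pytest.approx(row["p0_0"])


class TestNexusForwardModel:
    def test_halflife_time_ratio_is_two(self):
        cfg = SimConfig(n_genes=6, seed=10, noise="none")
        truth = simulate_truth(cfg)
        row = truth.df.iloc[0]
        tau = float(row["thalf_0"])
        cfg2 = SimConfig(n_genes=6, seed=10, noise="none",
                         inhibition_times_min=(0.0, tau))
        signals, _, _ = simulate_chipnexus_timecourse(truth, cfg2)
        lo, hi = sorted([row.span_start, row.span_end])
        dmso = signals[(0, "DMSO", tau, 1)].count(row.chrom, row.strand, lo, hi)
        trp = signals[(0, "TRP", tau, 1)].count(row.chrom, row.strand, lo, hi)
        assert dmso / trp == pytest.approx(2.0, rel=1e-12)

    def test_unit_mode_spike_factors_are_one(self):
        cfg = SimConfig(n_genes=4, seed=10, noise="none")
        truth = simulate_truth(cfg)
        _, totals, factors = simulate_chipnexus_timecourse(truth, cfg)
        np.testing.assert_allclose(factors, 1.0)
        assert totals.nunique() == 1

    def test_arbitrary_mode_records_true_factors(self):
        from polkinetics.signal import spikein_factors

        cfg = SimConfig(n_genes=4, seed=10, noise="none", calibration="arbitrary")
        truth = simulate_truth(cfg)
        _, totals, factors = simulate_chipnexus_timecourse(truth, cfg)
        est = spikein_factors(totals)
        np.testing.assert_allclose(est, factors, rtol=1e-12)


def test_full_generator_determinism(tmp_path):
    from polkinetics.synth import simulate_cohort, write_cohort

    cfg = SimConfig(n_genes=10, seed=7, noise="poisson")
    a_dir, b_dir = tmp_path / "a", tmp_path / "b"
    write_cohort(simulate_cohort(cfg), a_dir)
    write_cohort(simulate_cohort(SimConfig(n_genes=10, seed=7, noise="poisson")), b_dir)
    files = sorted(p.relative_to(a_dir) for p in a_dir.rglob("*") if p.is_file())
    assert files
    for rel in files:
        assert (a_dir / rel).read_bytes() == (b_dir / rel).read_bytes()
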