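"""Instrument selection, outlier removal and the GLS combiner."""

import numpy as np
import pytest
from scipy import stats

from methmr.gsmr import (
    GsmrConfig,
    InstrumentSet,
    bidirectional,
    fit,
    heidi_outlier_filter,
    select_instruments,
)
from methmr.sumstats_io import QtlProbeSet
from methmr.synthetic import simulate_instrument_dataset

from conftest import make_record, random_panel


def make_instrument_set(ratios, ratio_ses, b_exp=0.5, se_exp=1e-6, R=None):
    """InstrumentSet with per-SNP Wald ratios ~ ratios and variances ~ ratio_ses^2.

    A near-noiseless exposure makes the delta-method variance collapse to
    (se_out/b_exp)^2, so ratio SEs can be dialed in exactly.
    """
    snps = []
    for i, (r, s) in enumerate(zip(ratios, ratio_ses)):
        exp = make_record(snp_id=f"rs{i+1}", beta=b_exp, se=se_exp, bp=1000 * (i + 1))
        out = make_record(snp_id=f"rs{i+1}", beta=r * b_exp, se=s * b_exp,
                          bp=1000 * (i + 1))
        snps.append((exp, out))
    m = len(ratios)
    return InstrumentSet(exposure_id="exp", outcome_id="out", snps=snps,
                         ld_corr=np.eye(m) if R is None else np.asarray(R))


class TestSelectInstruments:
    def test_exposure_threshold_applied(self):
        rng = np.random.default_rng(0)
        panel = random_panel(rng, m=2, chrom=["1", "2"],
                             bp=[1000, 1000])
        exp = QtlProbeSet("cg1", "1", 1000, "", [
            make_record(snp_id="rs1", beta=0.4, se=0.05, chrom="1", bp=1000),
            make_record(snp_id="rs2", beta=0.15, se=0.028, chrom="2", bp=1000),
        ])
        assert exp.records[0].p < 5e-8 < exp.records[1].p
        out = [make_record(snp_id="rs1", beta=0.1, se=0.02, chrom="1", bp=1000),
               make_record(snp_id="rs2", beta=0.1, se=0.02, chrom="2", bp=1000)]
        inst = select_instruments(exp, out, panel)
        assert [s[0].snp_id for s in inst.snps] == ["rs1"]
        assert ("rs2", "exposure-not-significant") in inst.dropped

    def test_ld_pair_clumped_to_lower_p(self):
        rng = np.random.default_rng(1)
        base = rng.binomial(2, 0.4, size=300)
        flip = rng.random(300) < 0.2
        other = np.where(flip, rng.binomial(2, 0.4, size=300), base)
        from conftest import make_panel
        panel = make_panel(np.column_stack([base, other]), bp=[1000, 2000])
        assert panel.r2("rs1", "rs2") > 0.2
        exp = QtlProbeSet("cg1", "1", 1000, "", [
            make_record(snp_id="rs1", beta=0.5, se=0.05, bp=1000),
            make_record(snp_id="rs2", beta=0.4, se=0.05, bp=2000),
        ])
        out = [make_record(snp_id=s, beta=0.1, se=0.02, bp=b)
               for s, b in [("rs1", 1000), ("rs2", 2000)]]
        inst = select_instruments(exp, out, panel)
        assert [s[0].snp_id for s in inst.snps] == ["rs1"]
        assert ("rs2", "clumped") in inst.dropped

    def test_missing_outcome_record_dropped(self):
        rng = np.random.default_rng(2)
        panel = random_panel(rng, m=2, chrom=["1", "2"])
        exp = QtlProbeSet("cg1", "1", 1000, "", [
            make_record(snp_id="rs1", beta=0.5, se=0.05, chrom="1", bp=1000),
            make_record(snp_id="rs2", beta=0.5, se=0.05, chrom="2", bp=2000),
        ])
        out = [make_record(snp_id="rs1", beta=0.1, se=0.02, chrom="1", bp=1000)]
        inst = select_instruments(exp, out, panel)
        assert [s[0].snp_id for s in inst.snps] == ["rs1"]
        assert ("rs2", "no-outcome-record") in inst.dropped


class TestOutlierFilter:
    def test_identical_ratios_nothing_removed(self):
        inst = make_instrument_set([0.3] * 6, [0.05] * 6)
        out = heidi_outlier_filter(inst)
        assert out.n_instruments == 6

    def test_two_instruments_skips_filter(self, caplog):
        inst = make_instrument_set([0.3, 3.0], [0.01, 0.01])
        with caplog.at_level("WARNING", logger="methmr.gsmr"):
            out = heidi_outlier_filter(inst)
        assert out.n_instruments == 2
        assert any("skipped" in m for m in caplog.messages)

    def test_planted_outlier_removed(self):
        ratios = [0.3] * 9 + [3.0]
        inst = make_instrument_set(ratios, [0.05] * 10)
        out = heidi_outlier_filter(inst)
        assert [s[0].snp_id for s in out.snps] == [f"rs{i+1}" for i in range(9)]
        assert ("rs10", "heidi-outlier") in out.dropped

    def test_simulated_planted_outlier(self):
        cfg = GsmrConfig()
        removed = clean = 0
        for seed in range(25):
            probe, out, panel = simulate_instrument_dataset(
                seed, n_instruments=10, outlier_index=9)
            inst = select_instruments(probe, out, panel, cfg)
            filt = heidi_outlier_filter(inst, cfg)
            rem = {x[0] for x in filt.dropped if x[1] == "heidi-outlier"}
            removed += "rs10" in rem
            clean += not (rem - {"rs10"})
        assert removed >= 23
        assert clean >= 20


class TestFit:
    def test_single_instrument_delta_method(self):
        inst = make_instrument_set([0.3], [0.05])
        snps = [(make_record(beta=0.5, se=0.05),
                 make_record(beta=0.15, se=0.02))]
        inst = InstrumentSet("exp", "out", snps, np.eye(1))
        res = fit(inst)
        assert res.b_xy == pytest.approx(0.30)
        expected_se = np.sqrt((0.02 / 0.5) ** 2 + (0.15 * 0.05 / 0.25) ** 2)
        assert res.se_xy == pytest.approx(expected_se, rel=1e-12)
        assert expected_se == pytest.approx(0.05, rel=1e-9)

    def test_equal_ratios_recovered_exactly(self):
        inst = make_instrument_set([0.7] * 5, [0.02, 0.05, 0.1, 0.2, 0.03])
        res = fit(inst)
        assert res.b_xy == pytest.approx(0.7, rel=1e-12)

    def test_diagonal_v_equals_ivw_oracle(self):
        rng = np.random.default_rng(3)
        ratios = rng.normal(0.3, 0.2, size=12)
        ses = rng.uniform(0.02, 0.3, size=12)
        inst = make_instrument_set(list(ratios), list(ses))
        res = fit(inst)
        b, var = inst.ratios()
        w = 1.0 / var
        ivw = float(np.sum(w * b) / np.sum(w))
        ivw_se = float(np.sqrt(1.0 / np.sum(w)))
        assert res.b_xy == pytest.approx(ivw, rel=1e-10)
        assert res.se_xy == pytest.approx(ivw_se, rel=1e-10)

    def test_invariant_to_instrument_order_and_allele_flip(self):
        rng = np.random.default_rng(4)
        m = 6
        ratios = rng.normal(0.3, 0.1, size=m)
        ses = rng.uniform(0.02, 0.2, size=m)
        A = rng.normal(size=(m, m))
        R = np.corrcoef(A @ A.T)
        inst = make_instrument_set(list(ratios), list(ses), R=R)
        res = fit(inst)
        perm = rng.permutation(m)
        inst2 = InstrumentSet("exp", "out", [inst.snps[i] for i in perm],
                              inst.ld_corr[np.ix_(perm, perm)])
        res2 = fit(inst2)
        assert res2.b_xy == pytest.approx(res.b_xy, rel=1e-9)
        assert res2.se_xy == pytest.approx(res.se_xy, rel=1e-9)
        # flip the counted allele of instrument 0 in both studies: betas and
        # the corresponding LD row change sign, the causal estimate does not
        import dataclasses
        e0, o0 = inst.snps[0]
        flipped = [(dataclasses.replace(e0, beta=-e0.beta),
                    dataclasses.replace(o0, beta=-o0.beta))] + inst.snps[1:]
        R3 = R.copy()
        R3[0, :] *= -1
        R3[:, 0] *= -1
        res3 = fit(InstrumentSet("exp", "out", flipped, R3))
        assert res3.b_xy == pytest.approx(res.b_xy, rel=1e-9)
        assert res3.se_xy == pytest.approx(res.se_xy, rel=1e-9)

    def test_adding_concordant_instrument_never_hurts_precision(self):
        base = make_instrument_set([0.4] * 4, [0.05, 0.1, 0.2, 0.08])
        bigger = make_instrument_set([0.4] * 5, [0.05, 0.1, 0.2, 0.08, 0.5])
        assert fit(bigger).se_xy <= fit(base).se_xy + 1e-15

    def test_empty_set_not_testable(self):
        res = fit(InstrumentSet("exp", "out", [], np.zeros((0, 0))))
        assert not res.testable
        assert res.reason == "no-instruments"

    def test_type_one_error_under_null(self):
        """b_xy = 0, 10 independent valid instruments, 5000 replicates."""
        rng = np.random.default_rng(11)
        reps, m = 5000, 10
        b_exp = 0.5 + 0.2 * rng.random(m)
        se_exp = np.full(m, 0.02)
        se_out = np.full(m, 0.02)
        rejected = 0
        for _ in range(reps):
            bh_exp = b_exp + se_exp * rng.standard_normal(m)
            bh_out = se_out * rng.standard_normal(m)
            ratios = bh_out / bh_exp
            var = se_out**2 / bh_exp**2 + bh_out**2 * se_exp**2 / bh_exp**4
            w = 1.0 / var
            b = np.sum(w * ratios) / np.sum(w)
            z = b * np.sqrt(np.sum(w))
            if 2 * stats.norm.sf(abs(z)) < 0.05:
                rejected += 1
        assert 0.035 <= rejected / reps <= 0.065


class TestBidirectional:
    def test_forward_causation_reverse_clean(self):
        fwd_sig = rev_ok_count = 0
        for seed in range(10):
            probe, out, panel = simulate_instrument_dataset(seed, n_instruments=8)
            outcome_probe = QtlProbeSet("trait", "", -1, "", list(out))
            fwd, rev, rev_ok = bidirectional(probe, out, panel)
            fwd_sig += fwd.testable and fwd.p_xy < 5e-8
            rev_ok_count += rev_ok
        assert fwd_sig >= 9
        assert rev_ok_count >= 9

    def test_untestable_reverse_counts_as_ok(self):
        rng = np.random.default_rng(5)
        panel = random_panel(rng, m=3, chrom=["1", "2", "3"])
        exp = QtlProbeSet("cg1", "1", 1000, "", [
            make_record(snp_id="rs1", beta=0.5, se=0.05, chrom="1", bp=1000)])
        # outcome has no genome-wide-significant SNP anywhere
        out = [make_record(snp_id=f"rs{i+1}", beta=0.01, se=0.02, chrom=c, bp=1000)
               for i, c in enumerate(["1", "2", "3"])]
        fwd, rev, rev_ok = bidirectional(exp, out, panel)
        assert not rev.testable
        assert rev_ok
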