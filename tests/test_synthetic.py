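"""Generator internal consistency: LD structure, summary statistics,
ground-truth manifest, determinism and cross-cohort independence."""

import json

import numpy as np
import pytest
from scipy import stats

from methmr.sumstats_io import read_gmt, read_gwas_ma, read_qtl_table
from methmr.synthetic import (
    ScenarioSpec,
    build_layout,
    emit_study,
    regress_columns,
    simulate_genotypes,
    simulate_heidi_dataset,
    simulate_individuals,
    simulate_instrument_dataset,
    simulate_panel,
    summarize,
)


@pytest.fixture(scope="module")
def tiny_spec():
    return ScenarioSpec(
        seed=7, n_ref=300, n_mqtl_disc=500, n_mqtl_repl=500, n_eqtl=500,
        n_gwas=2000, n_mediation=1, n_pleiotropy=1, n_linkage=1,
        n_reverse=1, n_null=2, causal_genes_per_trait=1,
        decoy_genes_per_trait=1, background_blocks_per_trait=2, n_traits=2,
    )


class TestPanelStructure:
    def test_block_ld_decays_and_blocks_are_independent(self):
        spec = ScenarioSpec(seed=3, n_ref=500)
        layout = build_layout(spec)
        panel = simulate_panel(spec, layout)
        blk = layout.blocks[0]
        ids = layout.snp_ids[blk.snp_slice]
        R = panel.corr_matrix(ids)
        lag1 = np.array([R[i, i + 1] ** 2 for i in range(len(ids) - 1)])
        lag12 = np.array([R[i, i + 12] ** 2 for i in range(len(ids) - 12)])
        assert np.median(lag1) > np.median(lag12) + 0.1
        # cross-block r2 at sampling-noise level
        other = layout.snp_ids[layout.blocks[1].snp_slice]
        cross = [panel.r2(ids[i], other[i]) for i in range(0, 25, 5)]
        assert np.median(cross) < 0.02

    def test_null_correlation_level(self):
        """With rho=0 the mean off-diagonal r2 is ~1/n (null expectation)."""
        spec = ScenarioSpec(seed=5, n_ref=500, rho_cpg_block=0.0,
                            rho_gene_block=0.0, rho_background_block=0.0,
                            rho_linkage_block=0.0)
        layout = build_layout(spec)
        panel = simulate_panel(spec, layout)
        blk = layout.blocks[0]
        ids = layout.snp_ids[blk.snp_slice]
        R = panel.corr_matrix(ids)
        off = R[np.triu_indices(len(ids), 1)] ** 2
        assert np.mean(off) == pytest.approx(1 / spec.n_ref, rel=0.5)

    def test_linkage_block_r2_near_half(self):
        spec = ScenarioSpec(seed=9)
        layout = build_layout(spec)
        panel = simulate_panel(spec, layout)
        vals = []
        for info in layout.cpgs:
            if info.topology != "linkage":
                continue
            blk = layout.blocks[info.block]
            a = layout.snp_ids[blk.snp_slice.start]
            b = layout.snp_ids[blk.snp_slice.start + 12]
            vals.append(panel.r2(a, b))
        assert 0.3 < np.median(vals) < 0.7


class TestSummarize:
    def test_exact_linear_phenotype(self):
        rng = np.random.default_rng(0)
        from methmr.synthetic import _mini_layout
        mafs = np.array([0.3, 0.4])
        layout = _mini_layout(["rs1", "rs2"], ["1", "1"], [100, 200], mafs)
        G = rng.binomial(2, mafs[None, :], size=(500, 2)).astype(np.int8)
        y = 2.0 * G[:, 0].astype(float)
        recs = summarize(G, y, layout)
        assert recs[0].beta == pytest.approx(2.0, abs=1e-5)
        assert recs[0].p < 1e-100

    def test_beta_se_p_consistency(self):
        rng = np.random.default_rng(1)
        G = rng.binomial(2, 0.3, size=(200, 50)).astype(np.int8)
        y = rng.standard_normal(200)
        beta, se, p, keep = regress_columns(G, y[:, None])
        t = beta[keep, 0] / se[keep, 0]
        expected = 2 * stats.t.sf(np.abs(t), df=198)
        np.testing.assert_allclose(p[keep, 0], expected, rtol=1e-10)

    def test_permuted_phenotype_p_uniform(self):
        rng = np.random.default_rng(2)
        G = rng.binomial(2, rng.uniform(0.1, 0.5, 1000)[None, :],
                         size=(400, 1000)).astype(np.int8)
        y = rng.standard_normal(400)
        _, _, p, keep = regress_columns(G, y[:, None])
        ks = stats.kstest(p[keep, 0], "uniform")
        assert ks.pvalue > 0.01

    def test_monomorphic_snp_skipped(self, caplog):
        from methmr.synthetic import _mini_layout
        mafs = np.array([0.3, 0.4])
        layout = _mini_layout(["rs1", "rs2"], ["1", "1"], [100, 200], mafs)
        G = np.column_stack([np.ones(100), np.random.default_rng(3).binomial(2, .4, 100)]).astype(np.int8)
        with caplog.at_level("WARNING", logger="methmr.synthetic"):
            recs = summarize(G, np.random.default_rng(4).standard_normal(100), layout)
        assert [r.snp_id for r in recs] == ["rs2"]
        assert any("monomorphic" in m for m in caplog.messages)

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="n >= 30"):
            regress_columns(np.zeros((10, 2), dtype=np.int8), np.zeros((10, 1)))

    def test_per_snp_effect_recovery(self):
        """Estimated per-allele beta within 2 SE of the planted effect."""
        hits = total = 0
        for seed in range(40):
            probe, _, _ = simulate_instrument_dataset(
                seed, n_instruments=3, n_exposure=2000, n_outcome=100)
            h2 = 0.005
            for rec in probe.records:
                sd_g = np.sqrt(2 * rec.freq * (1 - rec.freq))
                true_beta = np.sqrt(h2) / sd_g
                hits += abs(rec.beta - true_beta) <= 2 * rec.se
                total += 1
        assert hits / total >= 0.93


class TestPhenotypes:
    def test_all_effects_zero_trait_variance_is_noise(self):
        spec = ScenarioSpec(
            seed=13, n_mediation=0, n_pleiotropy=0, n_linkage=0, n_reverse=0,
            n_null=4, causal_genes_per_trait=0, decoy_genes_per_trait=1,
            background_blocks_per_trait=1, background_h2=0.0,
            trait_noise_var=0.5, n_gwas=20000,
        )
        layout = build_layout(spec)
        rng = np.random.default_rng(0)
        G = simulate_genotypes(layout, 20000, rng)
        ph = simulate_individuals(layout, G, rng)
        for t in layout.traits():
            assert np.var(ph["trait"][t]) == pytest.approx(0.5, rel=0.05)

    def test_linkage_cpg_has_no_trait_path(self):
        """In the generating model a linkage CpG never enters the trait."""
        spec = ScenarioSpec(seed=1)
        layout = build_layout(spec)
        for info in layout.cpgs:
            if info.topology == "linkage":
                assert info.gene is None
                assert set(info.causal_local).isdisjoint(info.trait_local)

    def test_mediation_path_product_recovered(self, study_bundle,
                                              pipeline_records):
        """Discovery MR estimate matches b_cpg_gene * b_gene_trait within 2 SE."""
        spec = study_bundle.spec
        truth = {tuple(p) for p in study_bundle.manifest["true_pairs"]}
        checked = 0
        for rec in pipeline_records:
            if (rec.cpg_id, rec.trait_id) not in truth or not rec.final_pass:
                continue
            g = study_bundle.manifest["cpgs"][rec.cpg_id]["gene"]
            b_gt = study_bundle.manifest["genes"][g]["b_gene_trait"]
            implied = spec.b_cpg_gene * b_gt
            assert abs(rec.discovery.b_xy - implied) <= 2.5 * rec.discovery.se_xy
            checked += 1
        assert checked >= 3


class TestEmitStudy:
    def test_same_seed_byte_identical(self, tiny_spec, tmp_path):
        emit_study(tiny_spec, tmp_path / "a")
        emit_study(tiny_spec, tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_refuses_nonempty_outdir(self, tiny_spec, tmp_path):
        d = tmp_path / "x"
        d.mkdir()
        (d / "junk").write_text("hi")
        with pytest.raises(FileExistsError):
            emit_study(tiny_spec, d)
        emit_study(tiny_spec, d, force=True)

    def test_manifest_counts_and_roundtrip(self, tiny_spec, tmp_path):
        out = tmp_path / "s"
        bundle = emit_study(tiny_spec, out)
        manifest = json.loads((out / "manifest.json").read_text())
        counts = manifest["topology_counts"]
        from collections import Counter
        seen = Counter(info["topology"] for info in manifest["cpgs"].values())
        assert seen == Counter({k: v for k, v in counts.items() if v})

        mqtl = read_qtl_table(out / "mqtl_discovery.tsv")
        assert len(mqtl) == tiny_spec.n_cpgs
        by_probe = {p.probe_id: p for p in mqtl}
        for ps in bundle.mqtl_disc:
            assert len(by_probe[ps.probe_id].records) == len(ps.records)
        for trait in [f"trait{t}" for t in range(tiny_spec.n_traits)]:
            back = read_gwas_ma(out / f"gwas_{trait}.ma",
                                snp_map=bundle.panel.snp_map())
            assert len(back) == len(bundle.gwas[trait])
        sets = read_gmt(out / "gene_sets.gmt")
        assert len(sets) == 2 * tiny_spec.n_traits

    def test_cross_cohort_noise_independent(self, study_bundle):
        """Null-CpG trans betas are uncorrelated between the two mQTL cohorts."""
        nulls = [c for c, info in study_bundle.manifest["cpgs"].items()
                 if info["topology"] == "null"]
        disc = study_bundle.mqtl_disc_by_probe()
        repl = study_bundle.mqtl_repl_by_probe()
        xs, ys = [], []
        for cpg in nulls:
            d = disc[cpg]
            cis_chrom = d.probe_chrom
            rep_by = repl[cpg].by_snp()
            for rec in d.records:
                if rec.chrom == cis_chrom and abs(rec.bp - d.probe_bp) < 50_000:
                    continue  # cis records share true signal; skip
                if rec.snp_id in rep_by:
                    xs.append(rec.beta)
                    ys.append(rep_by[rec.snp_id].beta)
        assert len(xs) > 200
        r = np.corrcoef(xs, ys)[0, 1]
        assert abs(r) < 0.1


class TestFocusedGenerators:
    def test_heidi_scenarios_have_declared_architecture(self):
        probe, gwas, panel = simulate_heidi_dataset("pleiotropy", 0)
        top = probe.top_snp()
        assert top.snp_id == "rs1"  # the shared causal variant
        g = {r.snp_id: r for r in gwas}
        assert abs(g["rs1"].z) > 4
        probe2, gwas2, panel2 = simulate_heidi_dataset("linkage", 0)
        g2 = {r.snp_id: r for r in gwas2}
        assert abs(g2["rs13"].z) > abs(g2["rs1"].z)
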