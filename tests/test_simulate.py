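"""Synthetic panels, QTN effect calibration, scenarios, pedigree gene-drop."""

import json

import numpy as np
import pytest

from fasteblmm.io import read_plink
from fasteblmm.kinship import build_kinship
from fasteblmm.simulate import (PedigreeDesign, ScenarioConfig,
                                calibrate_qtn_effects, export_experiment,
                                select_qtn_columns, simulate_genotypes,
                                simulate_pedigree, simulate_scenario)


class TestSimulateGenotypes:
    def test_determinism(self):
        g1, m1 = simulate_genotypes(20, 30, seed=7)
        g2, m2 = simulate_genotypes(20, 30, seed=7)
        np.testing.assert_array_equal(g1.codes, g2.codes)
        assert list(m1.positions) == list(m2.positions)

    def test_empirical_maf(self):
        g, _ = simulate_genotypes(10_000, 6, maf_sampler=0.30, seed=3)
        maf = 1.0 - g.codes.mean(axis=0) / 2.0
        assert np.abs(maf - 0.30).max() < 0.02
        assert abs(maf.mean() - 0.30) < 0.01

    def test_hwe_proportions_at_half(self):
        g, _ = simulate_genotypes(20_000, 2, maf_sampler=0.5, seed=11)
        fracs = [(g.codes == c).mean() for c in (0, 1, 2)]
        np.testing.assert_allclose(fracs, [0.25, 0.5, 0.25], atol=0.02)

    def test_map_layout(self):
        _, mm = simulate_genotypes(5, 10, seed=1, n_chromosomes=2,
                                   spacing_bp=1000)
        assert list(mm.chromosomes) == ["1"] * 5 + ["2"] * 5
        assert list(mm.positions[:5]) == [1000, 2000, 3000, 4000, 5000]


class TestCalibration:
    def test_scenario1_total_variance(self):
        beta, V = calibrate_qtn_effects(ScenarioConfig())
        assert V == pytest.approx(10 / 0.55, abs=1e-10)

    def test_qtn4_effect(self):
        beta, V = calibrate_qtn_effects(ScenarioConfig())
        assert beta[3] == pytest.approx(
            np.sqrt(0.15 * (10 / 0.55) / (2 * 0.3 * 0.7)), abs=1e-10)
        assert beta[3] == pytest.approx(2.5482, abs=1e-3)

    def test_scenario2_polygenic_share(self):
        # sigma_g2 = 2 on top of residual 10 and QTN h2 sum 0.45 implies a
        # polygenic heritability of 0.092
        _, V = calibrate_qtn_effects(ScenarioConfig(), scenario=2)
        assert V == pytest.approx(12 / 0.55, abs=1e-10)
        assert 2.0 / V == pytest.approx(0.092, abs=5e-4)

    def test_scenario3_epistatic_share(self):
        _, V = calibrate_qtn_effects(ScenarioConfig(), scenario=3)
        assert 1.25 / V == pytest.approx(0.05, abs=1e-10)

    def test_zero_heritability(self):
        cfg = ScenarioConfig(qtn_h2=(0.0,) * 6)
        beta, V = calibrate_qtn_effects(cfg)
        assert V == 10.0
        np.testing.assert_array_equal(beta, np.zeros(6))

    def test_infeasible_shares(self):
        with pytest.raises(ValueError, match="sum to < 1"):
            ScenarioConfig(qtn_h2=(0.5, 0.3, 0.2, 0.1, 0.05, 0.05))


class TestScenario:
    def cfg(self, n=300, m=400, **kw):
        return ScenarioConfig(n_individuals=n, n_snps=m, **kw)

    def test_null_model_moments(self):
        cfg = self.cfg()
        cfg = ScenarioConfig(n_individuals=2000, n_snps=50,
                             qtn_h2=(0.0,) * 6)
        g, mm = simulate_genotypes(cfg.n_individuals, cfg.n_snps, seed=5, spacing_bp=200_000)
        y, truth = simulate_scenario(cfg, g, mm, 1, seed=5)
        assert y.values.mean() == pytest.approx(10.0, abs=0.3)
        assert y.values.var() == pytest.approx(10.0, rel=0.15)

    def test_qtn_selection_unlinked_near_target_maf(self):
        cfg = self.cfg()
        g, mm = simulate_genotypes(300, 400, seed=2, spacing_bp=200_000)
        idx = select_qtn_columns(g, mm, cfg)
        assert len(idx) == 6 and len(set(idx)) == 6
        maf = 1.0 - g.codes[:, idx].mean(axis=0) / 2.0
        assert np.abs(maf - 0.30).max() < 0.05
        chrom, pos = mm.chromosomes, mm.positions
        for i in idx:
            for j in idx:
                if i < j and chrom[i] == chrom[j]:
                    assert abs(int(pos[i]) - int(pos[j])) >= cfg.min_qtn_separation_bp

    def test_variance_bookkeeping_scenario1(self):
        # across replicates, var(y) tracks the calibrated V and QTN4's share
        # tracks its target heritability
        cfg = self.cfg(n=400, m=300)
        rng = np.random.default_rng(17)
        _, V = calibrate_qtn_effects(cfg)
        tot, share = [], []
        for _ in range(150):
            g, mm = simulate_genotypes(400, 300, rng=rng, spacing_bp=200_000)
            y, truth = simulate_scenario(cfg, g, mm, 1, rng=rng)
            z4 = g.codes[:, truth.qtn_indices[3]].astype(float)
            tot.append(y.values.var())
            share.append((z4 * truth.qtn_effects[3]).var() / y.values.var())
        assert np.mean(tot) == pytest.approx(V, rel=0.04)
        assert np.mean(share) == pytest.approx(0.15, abs=0.02)

    def test_scenario2_adds_polygenic_variance(self):
        cfg = self.cfg(n=300, m=200, qtn_h2=(0.0,) * 6)
        g, mm = simulate_genotypes(300, 200, seed=9, spacing_bp=200_000)
        kf = build_kinship(g)
        rng = np.random.default_rng(4)
        v1 = np.var([simulate_scenario(cfg, g, mm, 1, rng=rng)[0].values
                     for _ in range(40)], axis=0).mean()
        v2 = np.var([simulate_scenario(cfg, g, mm, 2, rng=rng, kinship=kf)[0].values
                     for _ in range(40)], axis=0).mean()
        # polygenic term inflates per-individual variance by ~ diag(K)*2
        assert v2 > v1 + 0.5

    def test_scenario3_epistatic_terms(self):
        cfg = self.cfg(n=500, m=100)
        g, mm = simulate_genotypes(500, 100, seed=21, spacing_bp=200_000)
        y, truth = simulate_scenario(cfg, g, mm, 3, seed=21)
        assert len(truth.epi_pairs) == 3
        Z = g.complete_codes()
        for (a, b), eff in zip(truth.epi_pairs, truth.epi_effects):
            assert a not in truth.qtn_indices and b not in truth.qtn_indices
            c = (Z[:, a] - Z[:, a].mean()) * (Z[:, b] - Z[:, b].mean())
            assert (c * eff).var() == pytest.approx(1.25, rel=1e-6)

    def test_determinism(self):
        cfg = self.cfg(n=50, m=60)
        g, mm = simulate_genotypes(50, 60, seed=3, spacing_bp=200_000)
        y1, t1 = simulate_scenario(cfg, g, mm, 1, seed=99)
        y2, t2 = simulate_scenario(cfg, g, mm, 1, seed=99)
        np.testing.assert_array_equal(y1.values, y2.values)
        np.testing.assert_array_equal(t1.qtn_indices, t2.qtn_indices)


class TestPedigree:
    def reduced(self, **kw):
        base = dict(founders=8, males_per_gen=4, females_per_gen=40,
                    mates_per_male=11, chromosomes=2, snps_per_chrom=50,
                    chrom_length_bp=2_500_000, qtl_count=6)
        base.update(kw)
        return PedigreeDesign(**base)

    def test_default_counts(self):
        d = PedigreeDesign()
        assert d.total_individuals == 4100
        assert d.total_snps == 10_000

    def test_reduced_structure(self):
        res = simulate_pedigree(self.reduced(), seed=5)
        d = self.reduced()
        assert res.genotypes.n == d.total_individuals
        ped = res.pedigree
        assert (ped["generation"].value_counts().sort_index()
                == [8, 44, 44, 44, 44]).all()
        # analysis set: females of G1..G3
        sel = ped.iloc[res.analysis_indices]
        assert set(sel["generation"]) == {1, 2, 3}
        assert (sel["sex"] == "F").all()
        assert len(sel) == 3 * 40

    def test_parentage_valid(self):
        res = simulate_pedigree(self.reduced(), seed=8)
        ped = res.pedigree
        sex = ped["sex"].to_numpy()
        gen = ped["generation"].to_numpy()
        for _, row in ped[ped["generation"] > 0].iterrows():
            s, d_, g_ = int(row["sire"]), int(row["dam"]), int(row["generation"])
            assert sex[s] == "M" and gen[s] == g_ - 1
            assert sex[d_] == "F" and gen[d_] == g_ - 1
        assert (ped.loc[ped["generation"] == 0, "sire"] == -1).all()

    def test_mendelian_consistency(self):
        # both parents homozygous pins the offspring genotype
        res = simulate_pedigree(self.reduced(), seed=13)
        codes = np.asarray(res.genotypes.codes)
        ped = res.pedigree
        checked = 0
        for _, row in ped[ped["generation"] > 0].head(30).iterrows():
            i = int(ped.index[ped["id"] == row["id"]][0])
            s, d_ = int(row["sire"]), int(row["dam"])
            both_hom = (codes[s] % 2 == 0) & (codes[d_] % 2 == 0)
            expect = codes[s] // 2 + codes[d_] // 2
            np.testing.assert_array_equal(codes[i][both_hom], expect[both_hom])
            checked += both_hom.sum()
        assert checked > 0

    def test_qtl_positions_even(self):
        res = simulate_pedigree(self.reduced(), seed=2)
        assert len(res.qtl_indices) == 6
        assert (res.qtl_indices % 2 == 0).all()

    def test_realized_heritability(self):
        res = simulate_pedigree(self.reduced(females_per_gen=150), seed=4)
        d = self.reduced(females_per_gen=150)
        sel = res.analysis_indices
        G = res.genotypes.codes[:, res.qtl_indices].astype(float) @ res.qtl_effects
        for t, h2 in enumerate(d.trait_h2):
            num = G[sel, t].var()
            den = res.phenotypes[t].values[sel].var()
            assert num / den == pytest.approx(h2, abs=0.07)

    def test_zero_effects_zero_heritability(self):
        res = simulate_pedigree(self.reduced(), seed=6)
        res.qtl_effects[:] = 0.0
        G = res.genotypes.codes[:, res.qtl_indices].astype(float) @ res.qtl_effects
        assert np.allclose(G, 0.0)

    def test_determinism(self):
        r1 = simulate_pedigree(self.reduced(), seed=3)
        r2 = simulate_pedigree(self.reduced(), seed=3)
        np.testing.assert_array_equal(r1.genotypes.codes, r2.genotypes.codes)
        np.testing.assert_array_equal(r1.qtl_indices, r2.qtl_indices)
        np.testing.assert_array_equal(r1.phenotypes[0].values,
                                      r2.phenotypes[0].values)


class TestExport:
    def test_round_trip_and_truth(self, tmp_path):
        cfg = ScenarioConfig(n_individuals=30, n_snps=40)
        g, mm = simulate_genotypes(30, 40, seed=12, spacing_bp=200_000)
        y, truth = simulate_scenario(cfg, g, mm, 1, seed=12)
        out = tmp_path / "exp"
        export_experiment(g, mm, [y], {"config": cfg, "truth": truth}, out)
        g2, mm2 = read_plink(out / "genotypes.bed", out / "genotypes.bim",
                             out / "genotypes.fam")
        np.testing.assert_array_equal(g2.codes, g.codes)
        with open(out / "truth.json") as fh:
            tr = json.load(fh)
        assert tr["truth"]["qtn_indices"] == truth.qtn_indices.tolist()
        # same seed reproduces the simulation recorded in the truth file
        y2, _ = simulate_scenario(cfg, g, mm, 1, seed=tr["truth"]["seed"])
        np.testing.assert_array_equal(y2.values, y.values)

    def test_collision_without_force(self, tmp_path):
        cfg = ScenarioConfig(n_individuals=20, n_snps=30)
        g, mm = simulate_genotypes(20, 30, seed=1, spacing_bp=400_000)
        y, truth = simulate_scenario(cfg, g, mm, 1, seed=1)
        out = tmp_path / "exp"
        export_experiment(g, mm, [y], {}, out)
        with pytest.raises(FileExistsError):
            export_experiment(g, mm, [y], {}, out)
        export_experiment(g, mm, [y], {}, out, force=True)
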