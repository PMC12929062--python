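import numpy as np
import pandas as pd
import pytest

from rhizogwas import association as assoc
from rhizogwas import kinship_mlm as km
from rhizogwas import ld_qtl
from rhizogwas import phenotypes as ph
from rhizogwas import prediction as pr
from rhizogwas import synthetic_data as sd


class TestConfigValidation:
    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(n_markers=0)

    def test_block_longer_than_chromosome_rejected(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(ld_block_len=20_000_000)

    def test_h2_range_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(h2_range=(0.5, 1.0))

    def test_more_hub_targets_than_genes_rejected(self, small_panel):
        cfg, G = small_panel
        from dataclasses import replace
        bad = replace(cfg, n_genes=10, hub_n_targets=50)
        with pytest.raises(ValueError):
            sd.simulate_expression(G, bad, seed=0)

    def test_negative_ionome_weight_rejected(self, structured_grm):
        cfg = sd.SimulationConfig()
        with pytest.raises(ValueError):
            sd.simulate_ionome({"WGS": structured_grm.K}, {"WGS": -1.0}, cfg, seed=0)


class TestDeterminism:
    def test_generators_are_pure_functions_of_seed(self, small_panel):
        cfg, _ = small_panel
        G1 = sd.simulate_genotypes(cfg, seed=5)
        G2 = sd.simulate_genotypes(cfg, seed=5)
        np.testing.assert_array_equal(G1.codes, G2.codes)
        c1, m1, t1 = sd.simulate_asv_counts(G1, cfg, seed=6)
        c2, m2, t2 = sd.simulate_asv_counts(G2, cfg, seed=6)
        pd.testing.assert_frame_equal(c1, c2)
        e1, _ = sd.simulate_expression(G1, cfg, seed=7)
        e2, _ = sd.simulate_expression(G2, cfg, seed=7)
        np.testing.assert_array_equal(e1.values, e2.values)

    def test_different_seed_changes_output(self, small_panel):
        cfg, _ = small_panel
        G1 = sd.simulate_genotypes(cfg, seed=5)
        G2 = sd.simulate_genotypes(cfg, seed=6)
        assert not np.array_equal(G1.codes, G2.codes)


class TestGenotypes:
    def test_markers_pass_maf_filter_by_construction(self, small_panel):
        _, G = small_panel
        freq = G.allele_freq()
        assert np.all(np.minimum(freq, 1 - freq) >= 0.05)
        # and the GWAS filter keeps everything
        assert assoc.filter_markers(G).n_markers == G.n_markers

    def test_block_structure_dominates_ld(self):
        """Panmictic mosaic: mean within-block r^2 exceeds 5x between-block."""
        cfg = sd.panmictic_config(n_genotypes=150, n_markers=400,
                                  ld_block_len=10_000,
                                  chromosomes=(("A01", 2_000_000),))
        G = sd.simulate_genotypes(cfg, seed=9)
        block = (G.map["pos"].to_numpy() - 1) // cfg.ld_block_len
        C = np.corrcoef(G.codes.T) ** 2
        iu = np.triu_indices(G.n_markers, 1)
        same = block[iu[0]] == block[iu[1]]
        assert np.nanmean(C[iu][same]) > 5 * np.nanmean(C[iu][~same])

    def test_structured_panel_has_group_kinship(self, structured_panel):
        _, G = structured_panel
        K = km.vanraden_grm(G).K
        off = K[np.triu_indices(G.n_samples, 1)]
        # ancestral groups: strongly bimodal relatedness
        assert off.max() > 0.5 and np.median(off) < 0.2


class TestFieldTrial:
    def test_pure_genetic_signal_is_constant_within_genotype(self):
        cfg = sd.SimulationConfig(n_genotypes=20, sigma_rep2=0.0, sigma_block2=0.0)
        gv = pd.Series(np.arange(20.0), index=[f"G{i:03d}" for i in range(20)])
        plot = sd.simulate_field_trial(gv, cfg, sigma_e2=0.0, seed=1)
        spread = plot.records.groupby("genotype")["value"].std()
        assert spread.max() < 1e-12

    def test_single_replicate_h2_denominator(self):
        vc = ph.VarianceComponents(1.0, 0.0, 0.0, 1.0, 0.0, 1)
        assert ph.estimate_h2(vc) == pytest.approx(0.5)

    def test_configured_h2_recovered(self):
        """Plot trials at target H2 = 0.4 give estimates near 0.4 on average."""
        cfg = sd.SimulationConfig(n_genotypes=150)
        h2s = []
        for s in range(12):
            rng = np.random.default_rng(70 + s)
            target = 0.4
            sigma_g2 = target / (1 - target) * 1.0 / cfg.n_reps
            gv = pd.Series(rng.normal(0, np.sqrt(sigma_g2), 150),
                           index=[f"G{i:03d}" for i in range(150)])
            plot = sd.simulate_field_trial(gv, cfg, sigma_e2=1.0, seed=700 + s)
            h2s.append(ph.estimate_h2(ph.fit_plot_lmm(plot, "E1")))
        assert np.mean(h2s) == pytest.approx(0.4, abs=0.08)


class TestAsvCounts:
    def test_null_asv_yields_no_gwas_hits(self):
        """ASVs with zero target heritability produce no FDR hits in >= 95%
        of runs."""
        cfg = sd.panmictic_config(n_genotypes=120, n_markers=250, n_asvs=40,
                                  frac_heritable_asvs=0.0,
                                  chromosomes=(("A01", 5_000_000),))
        clean = 0
        n_runs = 10
        for run in range(n_runs):
            G = sd.simulate_genotypes(cfg, seed=40 + run)
            counts, meta, truth = sd.simulate_asv_counts(G, cfg, seed=140 + run)
            la = ph.normalize_asv_abundance(counts)
            j = 0  # any ASV; all are null
            plot = pd.DataFrame({
                "genotype": meta["genotype"].to_numpy(), "environment": "E1",
                "replicate": meta["replicate"].to_numpy(),
                "block": meta["block"].to_numpy(), "value": la.values[:, j],
            })
            blues = ph.compute_blues(plot, "E1")
            K = km.vanraden_grm(G)
            res = assoc.run_association_study(
                assoc.StudySpec(mode="gwas"), pd.DataFrame({"a": blues}), G, K
            )
            clean += int(not res["a"]["significant"].any())
        assert clean >= 0.95 * n_runs - 1e-9

    def test_causal_snp_leads_detected_qtl(self):
        """H2 = 0.5 single-causal ASVs: the causal SNP leads a QTL in >= 80%
        of runs."""
        cfg = sd.panmictic_config(n_genotypes=150, n_markers=250, n_asvs=30,
                                  frac_heritable_asvs=1.0, h2_range=(0.5, 0.5),
                                  n_causal_per_asv=1,
                                  chromosomes=(("A01", 5_000_000),))
        hits = 0
        n_runs = 15
        for run in range(n_runs):
            G = sd.simulate_genotypes(cfg, seed=60 + run)
            counts, meta, truth = sd.simulate_asv_counts(G, cfg, seed=160 + run)
            la = ph.normalize_asv_abundance(counts)
            asv = la.feature_ids[0]
            causal = truth.set_index("asv").loc[asv, "causal_markers"]
            plot = pd.DataFrame({
                "genotype": meta["genotype"].to_numpy(), "environment": "E1",
                "replicate": meta["replicate"].to_numpy(),
                "block": meta["block"].to_numpy(), "value": la.values[:, 0],
            })
            blues = ph.compute_blues(plot, "E1")
            K = km.vanraden_grm(G)
            res = assoc.run_association_study(
                assoc.StudySpec(mode="gwas"), pd.DataFrame({asv: blues}), G, K
            )
            sig = res[asv][res[asv]["significant"]][["feature_id", "p"]]
            if len(sig) == 0:
                continue
            qtls = ld_qtl.build_qtl_regions(G, sig)
            hits += any(q.lead_snp == causal for q in qtls)
        assert hits >= 0.8 * n_runs - 1e-9

    def test_zero_library_rejected_downstream(self, small_panel):
        cfg, G = small_panel
        counts, _, _ = sd.simulate_asv_counts(G, cfg, seed=3)
        counts.iloc[0, :] = 0
        with pytest.raises(ValueError):
            ph.normalize_asv_abundance(counts)


class TestExpression:
    def test_cis_gene_classified_local(self, small_panel):
        """A strong cis gene's eQTL is local by the 50-kb rule."""
        cfg, G = small_panel
        from dataclasses import replace
        cfg2 = replace(cfg, n_genes=60, cis_fraction=1.0, cis_effect=2.0,
                       hub_n_targets=0)
        expr, truth = sd.simulate_expression(G, cfg2, seed=21)
        K = km.vanraden_grm(G)
        vals = np.column_stack([ph.qqnorm_transform(expr.values[:, j])
                                for j in range(expr.values.shape[1])])
        from rhizogwas.io_formats import FeatureMatrix
        qq = FeatureMatrix(expr.ids, expr.feature_ids, vals, "expression",
                           expr.coordinates)
        res = assoc.run_association_study(
            assoc.StudySpec(mode="egwas", adjust="holm"), qq.to_frame(), G, K
        )
        scans = {g: t[t["significant"]][["feature_id", "p"]]
                 for g, t in res.items()}
        rec = ld_qtl.eqtl_records_from_scans(G, scans, expr.coordinates)
        assert len(rec) > 0
        local_frac = (rec["class"] == "local").mean()
        assert local_frac > 0.8

    def test_no_hub_no_hotspot(self, small_panel):
        cfg, G = small_panel
        from dataclasses import replace
        cfg2 = replace(cfg, n_genes=40, hub_n_targets=10, hub_effect=0.0, cis_fraction=0.0)
        expr, truth = sd.simulate_expression(G, cfg2, seed=31)
        # with neither cis nor hub effects, expression is pure noise
        assert not truth["hub_target"].any() or cfg2.hub_effect == 0.0
        corr = np.corrcoef(expr.values.T[:10])
        off = corr[np.triu_indices(10, 1)]
        assert np.abs(off).max() < 0.5


class TestIonome:
    def test_noiseless_single_kernel_is_predictable(self):
        # low-rank kernel: noiseless genetic values on held-out genotypes are
        # fully determined by the training block, so accuracy approaches 1
        rng = np.random.default_rng(11)
        ids = [f"G{i:03d}" for i in range(175)]
        Kfeat = km.feature_kinship(pd.DataFrame(rng.normal(size=(175, 25)),
                                                index=ids))
        cfg = sd.SimulationConfig(n_traits=1, trait_residual_var=1e-12)
        traits, truth = sd.simulate_ionome({"Gene": Kfeat.K}, {"Gene": 1.0},
                                           cfg, seed=11)
        y = traits.iloc[:, 0].to_numpy()
        res = pr.kernel_cv_predict(y, pr.PredictionScenario(("Gene",)),
                                   {"Gene": Kfeat}, repeats=5, seed=2)
        assert res.mean_r >= 0.95

    def test_zero_weights_give_no_accuracy(self, structured_grm):
        cfg = sd.SimulationConfig(n_traits=1, trait_residual_var=1.0)
        traits, truth = sd.simulate_ionome({"WGS": structured_grm.K},
                                           {"WGS": 0.0}, cfg, seed=12)
        y = traits.iloc[:, 0].to_numpy()
        res = pr.kernel_cv_predict(y, pr.PredictionScenario(("WGS",)),
                                   {"WGS": structured_grm}, repeats=20, seed=3)
        assert abs(res.mean_r) <= 0.15

    def test_realized_fractions_recorded(self, structured_grm):
        cfg = sd.SimulationConfig(n_traits=3)
        _, truth = sd.simulate_ionome({"WGS": structured_grm.K},
                                      {"WGS": 0.5}, cfg, seed=13)
        assert {"frac_WGS", "frac_resid"}.issubset(truth.columns)
        assert ((truth["frac_WGS"] >= 0) & (truth["frac_WGS"] <= 1)).all()
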