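"""Generator reproducibility, marginal recovery, and component behavior."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import metbc
from metbc.synth import (ChipModel, Esr1Model, HOTSPOT_CATEGORIES, RateSpec,
                         null_config)


class TestConfig:
    def test_planted_headline_rates(self, paper_config):
        esr1 = paper_config.esr1_model
        assert esr1.rate.by_group["local"] == pytest.approx(0.022)
        assert esr1.rate.by_site_er[("liver", "positive")] == pytest.approx(0.44)
        assert esr1.base_mixture["D538G"] == pytest.approx(0.332)
        assert esr1.base_mixture["Y537S"] == pytest.approx(0.214)
        ctcf = paper_config.rates[("CTCF", "short_variant")]
        assert ctcf.by_group["metastasis"] == pytest.approx(0.020)
        assert ctcf.by_group["local"] == pytest.approx(0.009)
        cdkn1b = paper_config.rates[("CDKN1B", "amplification")]
        assert cdkn1b.by_group["local"] == pytest.approx(0.036)
        assert cdkn1b.by_group["metastasis"] == pytest.approx(0.013)

    def test_group_sizes(self, paper_config):
        assert (paper_config.n_local + paper_config.n_lymph
                + paper_config.n_met) == 10903
        assert paper_config.n_ambiguous == 713

    def test_probabilities_validate(self, paper_config):
        paper_config.validate()
        for p in paper_config.er_pos_by_site.values():
            assert 0.0 <= p <= 1.0
        assert abs(sum(paper_config.esr1_model.base_mixture.values()) - 1) < 1e-9

    def test_invalid_config_rejected_before_sampling(self, paper_config):
        bad = replace(paper_config, site_freqs={"liver": 0.5})
        with pytest.raises(ValueError, match="sum to 1"):
            metbc.simulate_cohort(bad, 0)
        bad2 = replace(paper_config, n_met=-1)
        with pytest.raises(ValueError, match="nonnegative"):
            metbc.simulate_cohort(bad2, 0)

    def test_panel_size(self, paper_config):
        assert len(paper_config.panel) == 287
        assert len(set(paper_config.panel)) == 287


class TestReproducibility:
    def test_identical_seed_identical_tables(self, paper_config):
        config = replace(paper_config, n_local=150, n_lymph=40, n_met=150,
                         n_ambiguous=20)
        c1, t1 = metbc.simulate_cohort(config, seed=5)
        c2, t2 = metbc.simulate_cohort(config, seed=5)
        pd.testing.assert_frame_equal(c1.samples, c2.samples)
        pd.testing.assert_frame_equal(c1.alterations, c2.alterations)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self, paper_config):
        config = replace(paper_config, n_local=150, n_lymph=0, n_met=150,
                         n_ambiguous=0)
        c1, _ = metbc.simulate_cohort(config, seed=5)
        c2, _ = metbc.simulate_cohort(config, seed=6)
        assert not c1.alterations.equals(c2.alterations)


class TestMarginalRecovery:
    def test_configured_marginals_recovered(self, small_cohort):
        """Site frequencies and subtype proportions land within 4 SE."""
        cohort, truth, config = small_cohort
        met = truth[truth["group"] == "metastasis"]
        n = len(met)
        for site, f in config.site_freqs.items():
            obs = (met["site"] == site).mean()
            se = np.sqrt(f * (1 - f) / n)
            assert abs(obs - f) < 4 * se + 1e-9, site
        # local ER+ proportion
        loc = truth[truth["group"] == "local"]
        f = config.er_pos_local
        se = np.sqrt(f * (1 - f) / len(loc))
        assert abs((loc["true_er"] == "positive").mean() - f) < 4 * se

    def test_planted_gene_rate_recovered(self, paper_config):
        """A 10% planted rate is recovered within 4 binomial SE."""
        rates = {("TP53", "short_variant"): RateSpec(0.10)}
        config = replace(null_config(n_genes=5, n_local=20000, n_met=0),
                         rates=rates)
        cohort, truth = metbc.simulate_cohort(config, seed=3)
        alts = cohort.alterations
        carriers = alts[(alts.gene == "TP53")
                        & (alts.alteration_class == "short_variant")
                        ]["sample_id"].nunique()
        obs = carriers / config.n_local
        se = np.sqrt(0.1 * 0.9 / config.n_local)
        assert abs(obs - 0.10) < 4 * se

    def test_null_config_no_group_difference(self):
        """All-equal rates: met-vs-local prevalence differs < 4 binomial SE."""
        config = null_config(n_genes=8, n_local=8000, n_met=8000, gene_rate=0.08)
        cohort, truth = metbc.simulate_cohort(config, seed=9)
        fm = metbc.build_feature_matrix(cohort, granularity="gene")
        met = truth["group"].eq("metastasis").to_numpy()
        for gene in [g for g in config.panel if not g.startswith("SYN")][:8]:
            col = fm.X[f"{gene}_mut"].to_numpy()
            diff = col[met].mean() - col[~met].mean()
            se = np.sqrt(2 * 0.08 * 0.92 / 8000)
            assert abs(diff) < 4 * se, gene

    def test_truth_completeness(self, small_cohort):
        cohort, truth, _ = small_cohort
        assert len(truth) == cohort.n_samples
        assert set(truth["sample_id"]) == set(cohort.samples["sample_id"])


class TestEsr1Simulation:
    def test_single_category_mixture(self, paper_config):
        m = paper_config.esr1_model
        only = Esr1Model(m.rate,
                         {k: (1.0 if k == "D538G" else 0.0)
                          for k in HOTSPOT_CATEGORIES},
                         {}, {},
                         {k: (1.0 if k == "D538G" else 0.0)
                          for k in HOTSPOT_CATEGORIES},
                         multi_mutation_prob=0.0)
        rng = np.random.default_rng(0)
        events = metbc.simulate_esr1_variants(rng, only, n=200)
        assert all(e["category"] == "D538G" for e in events)

    def test_default_mixture_fractions(self, paper_config):
        rng = np.random.default_rng(1)
        events = metbc.simulate_esr1_variants(rng, paper_config.esr1_model,
                                              n=10000)
        cats = pd.Series([e["category"] for e in events])
        for cat, f in [("D538G", 0.332), ("Y537S", 0.214)]:
            se = np.sqrt(f * (1 - f) / len(cats))
            assert abs((cats == cat).mean() - f) < 3 * se

    def test_multi_mutation_fraction(self, paper_config):
        rng = np.random.default_rng(2)
        events = metbc.simulate_esr1_variants(rng, paper_config.esr1_model,
                                              n=20000)
        per = pd.Series([e["carrier"] for e in events]).value_counts()
        f = 0.089
        se = np.sqrt(f * (1 - f) / 20000)
        assert abs((per >= 2).mean() - f) < 3 * se

    def test_degenerate_mixture_error(self, paper_config):
        m = paper_config.esr1_model
        bad = Esr1Model(m.rate, {k: 0.5 for k in HOTSPOT_CATEGORIES},
                        {}, {}, m.local_mixture)
        with pytest.raises(ValueError, match="sum to 1"):
            metbc.GeneratorConfig(esr1_model=bad).validate()


class TestChipSimulation:
    def test_vaf_in_unit_interval(self):
        rng = np.random.default_rng(0)
        model = ChipModel()
        vafs = [metbc.simulate_chip_vaf(a, model, rng)
                for a in rng.integers(25, 90, 500)]
        assert all(0.0 <= v <= 1.0 for v in vafs)

    def test_constant_mean_model_flat(self):
        rng = np.random.default_rng(1)
        model = ChipModel(vaf_slope_per_year=0.0)
        v40 = np.array([metbc.simulate_chip_vaf(40, model, rng) for _ in range(800)])
        v80 = np.array([metbc.simulate_chip_vaf(80, model, rng) for _ in range(800)])
        se = np.sqrt(v40.var() / 800 + v80.var() / 800)
        assert abs(v40.mean() - v80.mean()) < 3 * se

    def test_default_model_slope_negative(self):
        from scipy import stats
        rng = np.random.default_rng(2)
        ages, vafs = [], []
        model = ChipModel()
        for decade in range(30, 90, 10):
            for _ in range(1000):
                ages.append(decade)
                vafs.append(metbc.simulate_chip_vaf(decade, model, rng))
        assert stats.linregress(ages, vafs).slope < 0


class TestReports:
    def test_positive_plain_contains_keyword(self, paper_config):
        rng = np.random.default_rng(0)
        text = metbc.simulate_pathology_report("positive", rng, template_id=0,
                                               with_boilerplate=False)
        assert "ER" in text and "detect" in text

    def test_negative_negated_template(self, paper_config):
        rng = np.random.default_rng(0)
        text = metbc.simulate_pathology_report("negative", rng, template_id=0)
        assert "not detected" in text

    def test_empty_template_set_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="empty"):
            metbc.simulate_pathology_report(
                "positive", rng, templates={"positive": [], "negative": []})


class TestTissueCohorts:
    def test_lung_triplet_cooccurrence(self, paper_config):
        lung = metbc.simulate_tissue_cohort("lung", 2000, paper_config, seed=4)
        fm = metbc.build_feature_matrix(lung, granularity="gene")
        kras = fm.X["KRAS_mut"].to_numpy()
        keap1 = fm.X["KEAP1_mut"].to_numpy()
        # planted latent factor makes the triplet positively correlated
        assert np.corrcoef(kras, keap1)[0, 1] > 0.1

    def test_unknown_tissue_error(self, paper_config):
        with pytest.raises(ValueError, match="profile"):
            metbc.simulate_tissue_cohort("kidney", 10, paper_config, seed=0)
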