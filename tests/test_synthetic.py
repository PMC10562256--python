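"""Synthetic cohort generator: determinism, sampling oracles, truth plumbing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from haqtl.quant import quantify_activity
from haqtl.synthetic import (
    ConfigurationError,
    SimConfig,
    simulate_activity,
    simulate_cohort,
    simulate_expression,
    simulate_fragments,
    simulate_genotypes,
    simulate_gwas,
)


class TestSimulateGenotypes:
    def test_same_seed_identical(self):
        g1 = simulate_genotypes(50, 100, seed=7)
        g2 = simulate_genotypes(50, 100, seed=7)
        assert np.array_equal(g1.dosages, g2.dosages)

    def test_dosages_in_0_1_2(self):
        g = simulate_genotypes(100, 200, seed=1)
        assert set(np.unique(g.dosages)) <= {0.0, 1.0, 2.0}

    def test_no_ld_adjacent_variants_uncorrelated(self):
        # under independence the mean |corr| of adjacent pairs is O(1/sqrt(n))
        g = simulate_genotypes(2000, 200, ld_rho=0.0, seed=3)
        D = g.dosages
        cors = [
            abs(np.corrcoef(D[i], D[i + 1])[0, 1]) for i in range(D.shape[0] - 1)
        ]
        assert np.mean(cors) < 0.05

    def test_ld_rho_induces_adjacent_correlation(self):
        g = simulate_genotypes(2000, 200, ld_rho=0.9, ld_block_size=10, seed=3)
        D = g.dosages
        within = [
            np.corrcoef(D[i], D[i + 1])[0, 1]
            for i in range(D.shape[0] - 1)
            if (i % 10) != 9  # skip block boundaries
        ]
        assert np.mean(within) > 0.5

    def test_fixed_maf_half_mean_dosage_one(self):
        n = 5000
        g = simulate_genotypes(n, 50, maf_range=(0.5, 0.5), seed=9)
        se = np.sqrt(2 * 0.5 * 0.5 / n)  # binomial(2, 0.5) mean oracle
        assert np.all(np.abs(g.dosages.mean(axis=1) - 1.0) < 3 * se * 3)
        assert abs(g.dosages.mean() - 1.0) < 3 * se

    def test_empirical_maf_within_sampling_error_of_bounds(self):
        g = simulate_genotypes(3000, 300, maf_range=(0.2, 0.4), seed=5)
        se = np.sqrt(0.2 * 0.8 / (2 * 3000))
        assert g.maf().min() > 0.2 - 3 * se

    def test_invalid_sizes_error(self):
        with pytest.raises(ConfigurationError):
            simulate_genotypes(1, 10)
        with pytest.raises(ConfigurationError):
            simulate_genotypes(10, 10, maf_range=(0.0, 0.5))


class TestSimulateActivity:
    def _config(self, **kw):
        defaults = dict(
            n_individuals_per_tissue={"t1": 100},
            n_variants=100,
            n_ares=10,
            n_genes=5,
            seed=2,
        )
        defaults.update(kw)
        return SimConfig(**defaults)

    def test_noiseless_slope_recovers_beta(self):
        cfg = self._config(noise_sd=1e-12, covariate_count=0, haqtl_effect_sd=0.8)
        g = {"t1": simulate_genotypes(100, 100, seed=2)}
        act, _, ares, truth = simulate_activity(g, cfg)
        row = truth.true_haqtl.iloc[0]
        y = act["t1"].loc[row["are_id"]].to_numpy()
        x = g["t1"].to_frame().loc[row["variant_id"]].to_numpy()
        slope = stats.linregress(x, y).slope
        assert slope == pytest.approx(row["beta"], abs=1e-6)

    def test_zero_effect_sd_plants_nothing(self):
        cfg = self._config(haqtl_effect_sd=0.0)
        g = {"t1": simulate_genotypes(100, 100, seed=2)}
        _, _, _, truth = simulate_activity(g, cfg)
        assert len(truth.true_haqtl) == 0

    def test_full_sharing_copies_every_effect_with_same_sign(self):
        t = ["t1", "t2"]
        sm = pd.DataFrame(np.ones((2, 2)), index=t, columns=t)
        cfg = self._config(
            n_individuals_per_tissue={"t1": 50, "t2": 50}, sharing_matrix=sm
        )
        g = {
            "t1": simulate_genotypes(50, 100, seed=2),
            "t2": simulate_genotypes(50, 100, seed=3),
        }
        _, _, _, truth = simulate_activity(g, cfg)
        th = truth.true_haqtl
        per_are = th.groupby("are_id")
        for _, grp in per_are:
            assert set(grp["tissue"]) == {"t1", "t2"}
            assert grp["beta"].nunique() == 1  # identical effect, same sign
        assert truth.true_sharing[("t1", "t2")] == 1.0

    def test_missing_tissue_genotypes_error(self):
        cfg = self._config(n_individuals_per_tissue={"t1": 50, "t2": 50})
        with pytest.raises(ConfigurationError, match="t2"):
            simulate_activity({"t1": simulate_genotypes(50, 100, seed=2)}, cfg)


class TestSimulateExpression:
    def _setup(self, frac, seed=4):
        cfg = SimConfig(
            n_individuals_per_tissue={"t1": 200},
            n_variants=150,
            n_ares=20,
            n_genes=10,
            frac_shared_causal=frac,
            noise_sd=1.0,
            eqtl_effect_sd=1.0,
            seed=seed,
        )
        g = {"t1": simulate_genotypes(200, 150, seed=seed)}
        _, _, _, truth = simulate_activity(g, cfg)
        expr, genes, truth = simulate_expression(g, cfg, truth)
        return cfg, g, expr, genes, truth

    def test_frac_one_links_every_designated_pair(self):
        _, _, _, _, truth = self._setup(1.0)
        n_genes_with_eqtl = truth.true_eqtl["gene_id"].nunique()
        assert len(truth.true_links) == n_genes_with_eqtl

    def test_frac_zero_no_links(self):
        _, _, _, _, truth = self._setup(0.0)
        assert truth.true_links == []

    def test_planted_eqtl_beta_recovered_by_ols(self):
        # OLS sampling-distribution oracle: slope - beta ~ N(0, se) with
        # se = noise_sd / sqrt(n var(g)); standardized errors stay small
        _, g, expr, _, truth = self._setup(0.5, seed=8)
        zs = []
        for r in truth.true_eqtl.itertuples():
            y = expr[r.tissue].loc[r.gene_id].to_numpy()
            x = g[r.tissue].to_frame().loc[r.variant_id].to_numpy()
            if np.var(x) == 0:
                continue
            se = 1.0 / np.sqrt(len(x) * np.var(x))
            zs.append((stats.linregress(x, y).slope - r.beta) / se)
        assert len(zs) >= 5
        assert np.mean(np.abs(zs)) < 2.0
        assert np.max(np.abs(zs)) < 5.0
        assert abs(np.mean(zs)) < 3.0 / np.sqrt(len(zs))  # unbiased


class TestSimulateFragments:
    def _ares(self):
        return pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [1000, 5000],
             "end": [1500, 5600], "are_id": ["a1", "a2"], "center": [1250, 5300]}
        )

    def test_zero_activity_zero_fragments(self):
        frags = simulate_fragments(
            pd.Series({"a1": 0.0, "a2": 1.0}), self._ares(), seed=1
        )
        ares = self._ares()
        inside_a1 = (frags["start"] < 1500) & (frags["end"] > 1000)
        assert not inside_a1.any()

    def test_same_seed_identical(self):
        a = pd.Series({"a1": 1.0, "a2": 2.0})
        f1 = simulate_fragments(a, self._ares(), seed=3)
        f2 = simulate_fragments(a, self._ares(), seed=3)
        pd.testing.assert_frame_equal(f1, f2)

    def test_quantify_roundtrip_matches_poisson_oracle(self):
        # E[quantified] = depth * activity; Poisson SE over replicates
        ares = self._ares()
        a = pd.Series({"a1": 0.8, "a2": 1.6})
        depth, reps = 10.0, 500
        got = {"a1": [], "a2": []}
        for i in range(reps):
            frags = simulate_fragments(a, ares, mean_depth=depth, seed=i)
            if not len(frags):
                q = pd.DataFrame(0.0, index=ares["are_id"], columns=["s0"])
            else:
                q = quantify_activity(frags, ares)
            for k in got:
                got[k].append(q.loc[k, "s0"] if "s0" in q.columns else 0.0)
        for k, expected in (("a1", 8.0), ("a2", 16.0)):
            lam = expected * (ares.set_index("are_id").loc[k, "end"]
                              - ares.set_index("are_id").loc[k, "start"]) / 200
            # variance of the per-replicate estimate: Poisson counts scaled
            per_frag = expected / lam
            se = np.sqrt(lam) * per_frag / np.sqrt(reps)
            assert abs(np.mean(got[k]) - expected) < 3 * se

    def test_negative_depth_error(self):
        with pytest.raises(ConfigurationError):
            simulate_fragments(pd.Series({"a1": 1.0}), self._ares(), mean_depth=-1)


class TestSimulateGwas:
    def _truth_and_genotypes(self, seed=6):
        cfg = SimConfig(
            n_individuals_per_tissue={"t1": 300},
            n_variants=200,
            n_ares=20,
            n_genes=5,
            seed=seed,
        )
        g = simulate_genotypes(300, 200, seed=seed)
        _, _, _, truth = simulate_activity({"t1": g}, cfg)
        return g, truth

    def test_deterministic_given_seed(self):
        g, truth = self._truth_and_genotypes()
        t1 = simulate_gwas(g, truth, seed=5)
        t2 = simulate_gwas(g, truth, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_strong_causal_z_gives_genome_wide_significance(self):
        g, truth = self._truth_and_genotypes()
        tab = simulate_gwas(g, truth, shared_fraction=1.0, causal_z=12, seed=5)
        causal = tab[tab["gwas_causal"]]
        assert len(causal) and (causal["p"] < 5e-8).all()

    def test_se_follows_allele_frequency_formula(self):
        g, truth = self._truth_and_genotypes()
        n = 10_000
        tab = simulate_gwas(g, truth, n_gwas=n, seed=5)
        f = g.allele_freqs
        maf = np.minimum(f, 1 - f)
        assert np.allclose(tab["se"], 1 / np.sqrt(2 * maf * (1 - maf) * n))

    def test_too_small_n_error(self):
        g, truth = self._truth_and_genotypes()
        with pytest.raises(ConfigurationError):
            simulate_gwas(g, truth, n_gwas=1)


class TestCohortConsistency:
    def test_truth_ids_resolve(self, small_cohort):
        c = small_cohort
        vids = set(c.genotypes["t1"].variant_ids)
        assert set(c.truth.true_haqtl["variant_id"]) <= vids
        assert set(c.truth.true_haqtl["are_id"]) <= set(c.ares["are_id"])
        assert set(c.truth.true_eqtl["gene_id"]) <= set(c.genes["gene_id"])
        for are, gene in c.truth.true_links:
            h = c.truth.true_haqtl[c.truth.true_haqtl["are_id"] == are]
            e = c.truth.true_eqtl[c.truth.true_eqtl["gene_id"] == gene]
            assert set(h["variant_id"]) & set(e["variant_id"])

    def test_planted_sharing_matches_sharing_matrix(self):
        # with >= 500 planted effects the realized sharing sits inside the
        # binomial 95% CI around the configured probability
        t = ["t1", "t2"]
        sm = pd.DataFrame([[1.0, 0.3], [0.3, 1.0]], index=t, columns=t)
        cfg = SimConfig(
            n_individuals_per_tissue={"t1": 10, "t2": 10},
            n_variants=600,
            n_ares=1000,
            n_genes=5,
            sharing_matrix=sm,
            seed=13,
        )
        g = {
            "t1": simulate_genotypes(10, 600, seed=1),
            "t2": simulate_genotypes(10, 600, seed=2),
        }
        _, _, _, truth = simulate_activity(g, cfg)
        realized = truth.true_sharing[("t1", "t2")]
        p = 0.3
        se = np.sqrt(p * (1 - p) / 1000)
        assert abs(realized - p) < 1.96 * se * 2  # conservative band

    def test_cohort_determinism(self):
        cfg = dict(
            n_individuals_per_tissue={"t1": 30},
            n_variants=80,
            n_ares=10,
            n_genes=4,
            seed=21,
        )
        c1 = simulate_cohort(SimConfig(**cfg))
        c2 = simulate_cohort(SimConfig(**cfg))
        pd.testing.assert_frame_equal(c1.activity["t1"], c2.activity["t1"])
        pd.testing.assert_frame_equal(c1.gwas, c2.gwas)
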