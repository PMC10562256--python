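"""Cis-QTL mapping: residualization, nominal scan, permutation empirical p."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from haqtl.qtl import (
    call_gares,
    empirical_p,
    map_qtls,
    nominal_scan,
    residualize,
)
from haqtl.synthetic import GenotypeMatrix, simulate_genotypes


def _geno(n_ind=100, n_var=50, seed=0, **kw):
    return simulate_genotypes(n_ind, n_var, seed=seed, **kw)


class TestResidualize:
    def test_orthogonal_covariate_leaves_centered_phenotype(self, rng):
        n = 60
        y = rng.standard_normal(n)
        cov = rng.standard_normal(n)
        cov -= cov.mean()
        y_orth = y - y.mean()
        y_orth -= (y_orth @ cov) / (cov @ cov) * cov  # orthogonalize exactly
        pheno = pd.DataFrame([y_orth], index=["f1"],
                             columns=[f"s{i}" for i in range(n)])
        covs = pd.DataFrame({"c1": cov}, index=pheno.columns)
        resid, _ = residualize(pheno, covs)
        assert np.allclose(resid.loc["f1"], y_orth - y_orth.mean(), atol=1e-10)

    def test_phenotype_equal_to_covariate_vanishes(self, rng):
        n = 40
        c = rng.standard_normal(n)
        pheno = pd.DataFrame([c], index=["f1"], columns=[f"s{i}" for i in range(n)])
        covs = pd.DataFrame({"c1": c}, index=pheno.columns)
        resid, _ = residualize(pheno, covs)
        assert np.linalg.norm(resid.loc["f1"]) < 1e-8

    def test_matches_normal_equations_on_random_design(self, rng):
        n, p = 50, 5
        Y = rng.standard_normal((3, n))  # 3 features
        C = rng.standard_normal((n, p))
        pheno = pd.DataFrame(Y, index=["a", "b", "c"],
                             columns=[f"s{i}" for i in range(n)])
        covs = pd.DataFrame(C, index=pheno.columns,
                            columns=[f"c{j}" for j in range(p)])
        resid, n_removed = residualize(pheno, covs)
        D = np.hstack([np.ones((n, 1)), C])
        beta = np.linalg.solve(D.T @ D, D.T @ Y.T)
        expected = Y.T - D @ beta
        expected -= expected.mean(axis=0)
        assert np.allclose(resid.to_numpy().T, expected, atol=1e-10)
        assert n_removed == p

    def test_residuals_orthogonal_to_design(self, rng):
        n = 80
        pheno = pd.DataFrame(rng.standard_normal((10, n)),
                             columns=[f"s{i}" for i in range(n)])
        covs = pd.DataFrame(rng.standard_normal((n, 3)), index=pheno.columns,
                            columns=list("abc"))
        resid, _ = residualize(pheno, covs, n_latent_factors=2)
        assert np.abs(covs.to_numpy().T @ resid.to_numpy().T).max() < 1e-8

    def test_collinear_design_names_columns(self, rng):
        n = 30
        c = rng.standard_normal(n)
        covs = pd.DataFrame({"c1": c, "c2": 2 * c},
                            index=[f"s{i}" for i in range(n)])
        pheno = pd.DataFrame(rng.standard_normal((2, n)), columns=covs.index)
        with pytest.raises(ValueError, match="collinear.*c"):
            residualize(pheno, covs)


class TestNominalScan:
    def test_phenotype_equal_to_dosage_beta_one(self):
        g = _geno(200, 50, seed=1)
        center = int(g.positions[25])
        y = g.dosages[25].copy()
        res = nominal_scan("f", center, y, g)
        hit = res[res["variant_id"] == g.variant_ids[25]].iloc[0]
        assert hit["beta"] == pytest.approx(1.0, abs=1e-10)
        assert hit["p_nominal"] < 1e-12

    def test_maf_boundary_exclusion(self):
        # construct dosages with exact empirical MAF 0.049 and 0.05
        n = 1000
        d = np.zeros((2, n))
        d[0, :98] = 1.0  # maf 0.049
        d[1, :100] = 1.0  # maf 0.05
        g = GenotypeMatrix(
            dosages=d, variant_ids=["v_low", "v_ok"], chrom="chr1",
            positions=np.array([1000, 2000]),
            individual_ids=[f"i{k}" for k in range(n)],
            allele_freqs=np.array([0.049, 0.05]),
        )
        y = np.random.default_rng(0).standard_normal(n)
        res = nominal_scan("f", 1500, y, g, maf_min=0.05)
        assert list(res["variant_id"]) == ["v_ok"]

    def test_t_statistic_matches_closed_form(self, rng):
        g = _geno(80, 20, seed=2)
        y = rng.standard_normal(80)
        res = nominal_scan("f", int(g.positions[10]), y, g, window_bp=10**9,
                           maf_min=0.0)
        for r in res.itertuples():
            x = g.dosages[g.variant_ids.index(r.variant_id)]
            slope, intercept, rv, pv, se = stats.linregress(x, y)
            assert r.beta == pytest.approx(slope, abs=1e-10)
            assert r.t_stat == pytest.approx(slope / se, abs=1e-8)
            assert r.p_nominal == pytest.approx(pv, rel=1e-8)

    def test_variants_outside_window_excluded(self):
        g = _geno(50, 50, seed=3)
        res = nominal_scan("f", int(g.positions[0]), np.random.default_rng(0)
                           .standard_normal(50), g, window_bp=1000)
        assert (res["distance_to_center"].abs() <= 1000).all()

    def test_empty_window_returns_empty(self):
        g = _geno(50, 10, seed=4)
        res = nominal_scan("f", 10**9, np.zeros(50) + np.arange(50), g)
        assert len(res) == 0


class TestEmpiricalP:
    def test_single_variant_shapes_near_uniform(self):
        # the minimum of one uniform p-value is uniform -> Beta(1, 1)
        n = 300
        d = np.zeros((1, n))
        rng = np.random.default_rng(5)
        d[0] = rng.integers(0, 3, n).astype(float)
        g = GenotypeMatrix(
            dosages=d, variant_ids=["v0"], chrom="chr1",
            positions=np.array([5000]),
            individual_ids=[f"i{k}" for k in range(n)],
            allele_freqs=np.array([0.5]),
        )
        y = rng.standard_normal(n)
        lr = empirical_p("f", 5000, y, g, n_permutations=2000, seed=1)
        assert lr.beta_shape1 == pytest.approx(1.0, rel=0.2)
        assert lr.beta_shape2 == pytest.approx(1.0, rel=0.2)
        assert lr.p_empirical == pytest.approx(lr.lead["p_nominal"], rel=0.2)

    def test_identical_seed_identical_result(self):
        g = _geno(60, 30, seed=6)
        y = np.random.default_rng(1).standard_normal(60)
        l1 = empirical_p("f", int(g.positions[15]), y, g, 200, seed=3)
        l2 = empirical_p("f", int(g.positions[15]), y, g, 200, seed=3)
        assert l1.p_empirical == l2.p_empirical
        assert l1.beta_shape1 == l2.beta_shape1

    def test_constant_phenotype_error(self):
        g = _geno(50, 10, seed=7)
        with pytest.raises(ValueError, match="constant"):
            empirical_p("f", int(g.positions[5]), np.ones(50), g, 100, seed=0)

    def test_beta_approximation_tracks_direct_estimate(self):
        g = _geno(100, 40, seed=8)
        rng = np.random.default_rng(2)
        diffs = []
        for i in range(10):
            y = rng.standard_normal(100)
            lr = empirical_p("f", int(g.positions[20]), y, g, 2000, seed=i)
            diffs.append(abs(lr.p_empirical - lr.p_empirical_direct))
        assert np.median(diffs) < 0.02


class TestCallGares:
    def _locus(self, p_emp, shapes=(1.0, 1.0)):
        from haqtl.qtl import LocusResult

        nominals = pd.DataFrame(
            {"feature_id": "f", "variant_id": ["v0", "v1"],
             "beta": [1.0, 0.5], "se": [0.1, 0.2], "t_stat": [10.0, 2.5],
             "p_nominal": [1e-6, 0.02], "distance_to_center": [10, 20],
             "maf": [0.3, 0.3]}
        )
        return LocusResult(
            feature_id="f", lead=nominals.iloc[0], n_variants_tested=2,
            beta_shape1=shapes[0], beta_shape2=shapes[1], p_empirical=p_emp,
            p_empirical_direct=p_emp,
            nominal_threshold=float(stats.beta.ppf(0.005, *shapes)),
            nominals=nominals,
        )

    def test_threshold_boundary(self):
        qset = call_gares([self._locus(0.004), ])
        assert qset.features == ["f"]
        qset = call_gares([self._locus(0.006)])
        assert qset.features == []

    def test_uniform_shapes_nominal_threshold_is_0005(self):
        lr = self._locus(0.004)
        assert lr.nominal_threshold == pytest.approx(0.005)

    def test_lead_always_in_qtl_list(self):
        qset = call_gares([self._locus(0.001)])
        assert "v0" in set(qset.qtls["f"]["variant_id"])


class TestPowerAndCalibration:
    def test_discovery_rate_monotone_in_effect_and_sample_size(self):
        # power grid: larger planted beta and larger n never hurt discovery
        rates = {}
        for n, beta in [(50, 0.4), (50, 0.9), (150, 0.9)]:
            g = _geno(n, 30, seed=10)
            rng = np.random.default_rng(n + int(beta * 10))
            hits = 0
            n_feat = 30
            for i in range(n_feat):
                v = 15
                y = beta * g.dosages[v] + rng.standard_normal(n)
                lr = empirical_p("f", int(g.positions[v]), y, g, 300, seed=i)
                hits += lr.p_empirical <= 0.005
            rates[(n, beta)] = hits / n_feat
        assert rates[(50, 0.4)] <= rates[(50, 0.9)] <= rates[(150, 0.9)]

    def test_map_qtls_runs_and_is_deterministic(self, small_cohort):
        c = small_cohort
        centers = pd.Series(c.ares["center"].to_numpy(), index=c.ares["are_id"])
        sub = c.activity["t1"].iloc[:8]
        loci1, q1 = map_qtls(sub, centers, c.genotypes["t1"],
                             c.covariates["t1"], 1, n_permutations=200, seed=4)
        loci2, q2 = map_qtls(sub, centers, c.genotypes["t1"],
                             c.covariates["t1"], 1, n_permutations=200, seed=4)
        assert q1.features == q2.features
        assert [l.p_empirical for l in loci1] == [l.p_empirical for l in loci2]
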