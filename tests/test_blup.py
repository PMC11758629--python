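import numpy as np
import pandas as pd
import pytest

from strdose.blup import (
    Pedigree,
    adjust_phenotypes,
    animal_model_blup,
    correlate_dosage,
    pedigree_a_matrix,
)
from strdose.genotypes import DosageMatrix
from strdose.gwas import VarianceComponents

from ._oracles import blup_gls_oracle, recursive_kinship


def ped_from_rows(rows):
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam"]))


def random_pedigree(rng, n_founders=10, n_later=30):
    rows = [(f"f{i}", None, None) for i in range(n_founders)]
    ids = [r[0] for r in rows]
    for i in range(n_later):
        s, d = rng.choice(len(ids), size=2, replace=False)
        rows.append((f"x{i}", ids[s], ids[d]))
        ids.append(f"x{i}")
    return ped_from_rows(rows)


class TestAMatrix:
    def test_unrelated_founders_identity(self):
        amat = pedigree_a_matrix(ped_from_rows([("a", None, None), ("b", None, None)]))
        np.testing.assert_allclose(amat.matrix, np.eye(2))

    def test_parent_offspring_and_full_sibs(self):
        ped = ped_from_rows(
            [("s", None, None), ("d", None, None), ("k1", "s", "d"), ("k2", "s", "d")]
        )
        A = pedigree_a_matrix(ped).to_frame()
        assert A.loc["s", "k1"] == pytest.approx(0.5)
        assert A.loc["k1", "k2"] == pytest.approx(0.5)
        assert A.loc["k1", "k1"] == pytest.approx(1.0)

    def test_full_sib_mating_inbreeding(self):
        ped = ped_from_rows(
            [("s", None, None), ("d", None, None), ("k1", "s", "d"), ("k2", "s", "d"),
             ("inbred", "k1", "k2")]
        )
        A = pedigree_a_matrix(ped).to_frame()
        assert A.loc["inbred", "inbred"] == pytest.approx(1.25)  # F = 0.25

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_recursive_kinship_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ped = random_pedigree(rng, n_founders=8, n_later=40)
        amat = pedigree_a_matrix(ped)
        expected = recursive_kinship(ped.records)
        np.testing.assert_allclose(amat.matrix, expected, atol=1e-12)

    def test_cycle_detection_names_individual(self):
        with pytest.raises(ValueError, match="cycle"):
            ped_from_rows([("a", "b", None), ("b", "a", None)])

    def test_unknown_parent_id_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ped_from_rows([("a", "ghost", None)])


def toy_pheno(rng, ped, h2=0.4, mu=20.0):
    amat = pedigree_a_matrix(ped)
    n = len(amat.ids)
    sa2, se2 = 8.0, 12.0
    a = np.linalg.cholesky(amat.matrix + 1e-10 * np.eye(n)) @ rng.standard_normal(n) * np.sqrt(sa2)
    sex = rng.choice(["M", "F"], size=n)
    ibw = rng.normal(5, 1, size=n)
    y = mu + (sex == "F") * 1.5 + 1.2 * ibw + a + rng.standard_normal(n) * np.sqrt(se2)
    return pd.DataFrame({"sex": sex, "ibw": ibw, "hbw": y}, index=pd.Index(amat.ids, name="id"))


class TestAnimalModelBlup:
    def test_matches_dense_gls_oracle(self, rng):
        ped = random_pedigree(rng, n_founders=6, n_later=20)
        pheno = toy_pheno(rng, ped)
        vc = VarianceComponents(8.0, 12.0, 0.0, True)
        fit = animal_model_blup(pheno, ped, varcomp=vc)
        amat = pedigree_a_matrix(ped)
        n = len(amat.ids)
        Z = np.eye(n)
        from strdose.blup import _eq2_design

        X, _ = _eq2_design(pheno.loc[amat.ids])
        y = pheno.loc[amat.ids, "hbw"].to_numpy()
        b_o, a_o = blup_gls_oracle(y, X, Z, amat.matrix, 8.0, 12.0)
        np.testing.assert_allclose(fit.b_hat.to_numpy(), b_o, rtol=1e-8)
        np.testing.assert_allclose(fit.a_hat.loc[amat.ids].to_numpy(), a_o, rtol=1e-7, atol=1e-9)

    def test_mme_solution_satisfies_decomposition(self, rng):
        ped = random_pedigree(rng, n_founders=5, n_later=15)
        pheno = toy_pheno(rng, ped)
        fit = animal_model_blup(pheno, ped, varcomp=VarianceComponents(5.0, 10.0, 0.0, True))
        # y = Xb + a + e must hold exactly for phenotyped individuals
        recon = fit.fitted_fixed + fit.a_hat.loc[fit.e_hat.index] + fit.e_hat
        np.testing.assert_allclose(recon.to_numpy(), pheno.loc[fit.e_hat.index, "hbw"].to_numpy(), rtol=1e-10)

    def test_unphenotyped_relatives_get_breeding_values(self, rng):
        ped = random_pedigree(rng, n_founders=6, n_later=12)
        pheno = toy_pheno(rng, ped).iloc[6:]  # founders unphenotyped
        fit = animal_model_blup(pheno, ped, varcomp=VarianceComponents(5.0, 10.0, 0.0, True))
        assert set(fit.a_hat.index) == set(pedigree_a_matrix(ped).ids)
        assert set(fit.e_hat.index) == set(pheno.index)

    def test_zero_genetic_variance_limit(self, rng):
        ped = random_pedigree(rng, n_founders=5, n_later=10)
        pheno = toy_pheno(rng, ped)
        fit = animal_model_blup(pheno, ped, varcomp=VarianceComponents(0.0, 10.0, 0.0, True))
        assert np.allclose(fit.a_hat, 0.0)
        y_star = adjust_phenotypes(fit)
        expected = pheno["hbw"] - fit.fitted_fixed
        np.testing.assert_allclose(y_star.loc[expected.index], expected, rtol=1e-10)

    def test_reml_recovers_breeding_values(self, small_cohort):
        fit = animal_model_blup(small_cohort.phenotypes, small_cohort.pedigree)
        truth = small_cohort.truth.breeding_values
        common = fit.e_hat.index
        r = np.corrcoef(fit.a_hat.loc[common], truth.loc[common])[0, 1]
        assert r > 0.5

    def test_singular_design_rejected(self, rng):
        ped = ped_from_rows([(f"i{k}", None, None) for k in range(8)])
        pheno = toy_pheno(rng, ped)
        pheno["ibw"] = 0.0  # IBW-within-sex columns both zero -> singular
        with pytest.raises(ValueError, match="singular"):
            animal_model_blup(pheno, ped, varcomp=VarianceComponents(1.0, 1.0, 0.0, True))

    def test_phenotyped_id_missing_from_pedigree(self, rng):
        ped = ped_from_rows([("a", None, None), ("b", None, None), ("c", None, None)])
        pheno = toy_pheno(rng, ped)
        pheno.index = ["a", "b", "zz"]
        with pytest.raises(ValueError, match="absent"):
            animal_model_blup(pheno, ped, varcomp=VarianceComponents(1.0, 1.0, 0.0, True))


class TestAdjustedPhenotypes:
    def test_sum_of_components(self):
        blup = type("B", (), {})()
        fit_ids = ["a", "b"]
        import strdose.blup as m

        res = m.BlupResult(
            b_hat=pd.Series([1.0], index=["intercept"]),
            a_hat=pd.Series({"a": 2.0, "b": -1.0}),
            e_hat=pd.Series({"a": -0.5, "b": 0.25}),
            fitted_fixed=pd.Series({"a": 1.0, "b": 1.0}),
            varcomp=VarianceComponents(1.0, 1.0, 0.0, True),
            design_columns=["intercept"],
        )
        y_star = adjust_phenotypes(res)
        assert y_star["a"] == pytest.approx(1.5)
        assert y_star["b"] == pytest.approx(-0.75)


class TestCorrelateDosage:
    def make_matrix(self, arr, samples):
        arr = np.asarray(arr, dtype=float)
        loci = pd.DataFrame(
            {"scaffold": "s1", "pos": np.arange(arr.shape[0]) + 1, "period": 2},
            index=pd.Index([f"L{i}" for i in range(arr.shape[0])], name="locus_id"),
        )
        return DosageMatrix(loci=loci, dosage=pd.DataFrame(arr, index=loci.index, columns=samples))

    def test_perfect_negative_correlation_passes(self):
        samples = list("abcd")
        dm = self.make_matrix([[0.0, 1.0, 2.0, 3.0]], samples)
        adj = pd.Series([3.0, 2.0, 1.0, 0.0], index=samples)
        rec = correlate_dosage(dm, adj).iloc[0]
        assert rec["r"] == pytest.approx(-1.0)
        assert rec["passes"]

    def test_perfect_linear_toy(self):
        samples = list("abcd")
        dm = self.make_matrix([[0.0, 1.0, 2.0, 3.0]], samples)
        adj = pd.Series([1.0, 3.0, 5.0, 7.0], index=samples)
        assert correlate_dosage(dm, adj).iloc[0]["r"] == pytest.approx(1.0)

    def test_independent_null_does_not_pass(self, rng):
        n = 300
        samples = [f"s{i}" for i in range(n)]
        dm = self.make_matrix(rng.integers(-2, 3, size=(1, n)).astype(float), samples)
        adj = pd.Series(rng.standard_normal(n), index=samples)
        rec = correlate_dosage(dm, adj).iloc[0]
        assert abs(rec["r"]) < 0.2 and not rec["passes"]

    def test_affine_transformation_flips_sign_only(self, rng):
        n = 50
        samples = [f"s{i}" for i in range(n)]
        s = rng.integers(-2, 3, size=n).astype(float)
        adj = pd.Series(rng.standard_normal(n) + s, index=samples)
        r1 = correlate_dosage(self.make_matrix(s[None, :], samples), adj).iloc[0]["r"]
        r2 = correlate_dosage(self.make_matrix((-2.0 * s + 3)[None, :], samples), adj).iloc[0]["r"]
        assert r2 == pytest.approx(-r1)

    def test_constant_dosage_degenerate(self):
        samples = list("abc")
        dm = self.make_matrix([[1.0, 1.0, 1.0]], samples)
        adj = pd.Series([1.0, 2.0, 3.0], index=samples)
        assert correlate_dosage(dm, adj).iloc[0]["degenerate"]

    def test_planted_causal_locus_outranks_null_loci(self, small_cohort):
        fit = animal_model_blup(small_cohort.phenotypes, small_cohort.pedigree)
        y_star = adjust_phenotypes(fit)
        tab = correlate_dosage(small_cohort.dosage, y_star)
        causal = small_cohort.truth.causal
        big = causal.index[causal["effect"].argmax()]
        null_mean = tab.drop(index=causal.index)["r"].abs().mean()
        assert abs(tab.loc[big, "r"]) > null_mean
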