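import itertools

import numpy as np
import pandas as pd
import pytest

from strdose.genotypes import (
    CallSet,
    DosageMatrix,
    StrCall,
    allele_frequencies,
    dosage_matrix,
    filter_calls,
    filter_loci,
    genotype_counts,
    hwe_test,
    locus_qc,
    pic,
    polymorphism_class,
)


def make_callset(rows, periods=None, samples=None):
    """rows: (locus, sample, bp1, bp2, q, flank, stutter)"""
    calls = pd.DataFrame(rows, columns=["locus_id", "sample_id", "bp1", "bp2", "posterior", "flank_frac", "stutter_frac"])
    locus_ids = calls["locus_id"].unique()
    periods = periods or {l: 2 for l in locus_ids}
    loci = pd.DataFrame(
        {"locus_id": locus_ids,
         "scaffold": ["s1"] * len(locus_ids),
         "pos": range(1, len(locus_ids) + 1),
         "period": [periods[l] for l in locus_ids]}
    )
    if samples is None:
        samples = sorted(calls["sample_id"].unique())
    return CallSet(calls=calls, loci=loci, samples=samples)


class TestDosageCoding:
    def test_bp_difference_to_relative_copies(self):
        cs = make_callset([("L1", "a", 4.0, 0.0, 0.99, 0, 0)])
        dm = dosage_matrix(cs)
        assert dm.allele1.loc["L1", "a"] == 2.0
        assert dm.dosage.loc["L1", "a"] == 2.0

    def test_reference_identical_call_has_zero_dosage(self):
        cs = make_callset([("L1", "a", 0.0, 0.0, 0.99, 0, 0)])
        assert dosage_matrix(cs).dosage.loc["L1", "a"] == 0.0

    def test_nonintegral_bp_difference_flagged_and_kept(self):
        cs = make_callset([("L1", "a", 3.0, 0.0, 0.99, 0, 0)])
        dm = dosage_matrix(cs)
        assert dm.dosage.loc["L1", "a"] == 1.5
        assert bool(dm.nonintegral.loc["L1", "a"])

    def test_allele_order_symmetry(self):
        cs1 = make_callset([("L1", "a", 4.0, -2.0, 0.99, 0, 0)])
        cs2 = make_callset([("L1", "a", -2.0, 4.0, 0.99, 0, 0)])
        assert dosage_matrix(cs1).dosage.equals(dosage_matrix(cs2).dosage)

    def test_strcall_validates_fractions(self):
        with pytest.raises(ValueError):
            StrCall("a", "L1", (0.0, 0.0), posterior=1.2, flank_indel_frac=0, stutter_frac=0)


class TestCallFilters:
    base = [
        ("L1", "a", 0.0, 0.0, 0.89, 0.0, 0.0),   # posterior below 0.90
        ("L1", "b", 0.0, 0.0, 0.95, 0.16, 0.0),  # flank indel fraction too high
        ("L1", "c", 0.0, 0.0, 0.95, 0.10, 0.10),  # passes
        ("L1", "d", 0.0, 0.0, 0.95, 0.0, 0.151),  # stutter fraction too high
    ]

    def test_three_conditions(self):
        kept = filter_calls(make_callset(self.base)).calls
        assert list(kept["sample_id"]) == ["c"]

    def test_boundary_values_survive(self):
        rows = [("L1", "a", 0.0, 0.0, 0.90, 0.15, 0.15)]
        assert len(filter_calls(make_callset(rows)).calls) == 1

    def test_idempotent(self):
        once = filter_calls(make_callset(self.base))
        twice = filter_calls(once)
        assert once.calls.equals(twice.calls)


class TestLocusFilters:
    def make_matrix(self, n_samples, observed, values=None):
        samples = [f"s{i:04d}" for i in range(n_samples)]
        rows = []
        for i in range(observed):
            v = values[i] if values is not None else float(i % 3)
            rows.append(("L1", samples[i], 2 * v, 0.0, 0.99, 0.0, 0.0))
        return dosage_matrix(make_callset(rows, samples=samples))

    def test_gwas_presence_strictly_above_threshold(self):
        dm = self.make_matrix(326, 65)  # 65/326 = 0.199
        with pytest.raises(ValueError, match="threshold"):
            filter_loci(dm, purpose="gwas")

    def test_grm_missing_rate_strictly_below(self):
        dm = self.make_matrix(100, 92)  # 8% missing
        assert len(filter_loci(dm, purpose="grm").locus_ids) == 1
        dm2 = self.make_matrix(100, 89)  # 11% missing: dropped
        with pytest.raises(ValueError):
            filter_loci(dm2, purpose="grm")

    def test_monomorphic_dropped(self):
        dm = self.make_matrix(10, 10, values=[1.0] * 10)
        with pytest.raises(ValueError):
            filter_loci(dm, purpose="gwas")

    def test_idempotent(self):
        dm = self.make_matrix(100, 95)
        once = filter_loci(dm, purpose="grm")
        twice = filter_loci(once, purpose="grm")
        assert once.dosage.equals(twice.dosage)


class TestPic:
    def test_known_values(self):
        assert pic({0.0: 1.0}) == pytest.approx(0.0)
        assert pic({0.0: 0.5, 1.0: 0.5}) == pytest.approx(0.375)
        assert pic(dict.fromkeys(range(4), 0.25)) == pytest.approx(0.703125)

    def test_bad_frequencies_error(self):
        with pytest.raises(ValueError):
            pic({0.0: 0.5, 1.0: 0.4})

    @pytest.mark.parametrize("k", [2, 3, 5, 10, 20])
    def test_equifrequent_bound(self, k):
        v = pic(dict.fromkeys(range(k), 1.0 / k))
        assert v <= 1.0 - 1.0 / k + 1e-12
        assert v > 1.0 - 1.0 / k - 0.3  # approaches the bound as k grows

    def test_relabeling_invariance(self, rng):
        p = rng.dirichlet(np.ones(5))
        base = pic(dict(zip(range(5), p)))
        shuffled = pic(dict(zip(rng.permutation(5), p)))
        assert base == pytest.approx(shuffled)

    def test_class_boundaries(self):
        assert polymorphism_class(0.0) == "low"
        assert polymorphism_class(0.375) == "medium"
        assert polymorphism_class(0.25) == "medium"
        assert polymorphism_class(0.5) == "medium"
        assert polymorphism_class(0.51) == "high"


class TestAlleleFrequencies:
    def test_small_example(self):
        cs = make_callset([
            ("L1", "a", 0.0, 0.0, 0.99, 0, 0),
            ("L1", "b", 0.0, 2.0, 0.99, 0, 0),
        ])
        freqs = allele_frequencies(dosage_matrix(cs), "L1")
        assert freqs == {0.0: 0.75, 1.0: 0.25}

    def test_homozygous_single_allele(self):
        cs = make_callset([("L1", "a", 4.0, 4.0, 0.99, 0, 0)])
        assert allele_frequencies(dosage_matrix(cs), "L1") == {2.0: 1.0}

    def test_matches_brute_force_tally(self, rng):
        rows = []
        tally = {}
        for i in range(60):
            a, b = rng.integers(-3, 4, size=2)
            rows.append(("L1", f"s{i}", 2.0 * a, 2.0 * b, 0.99, 0, 0))
            for v in (float(a), float(b)):
                tally[v] = tally.get(v, 0) + 1
        freqs = allele_frequencies(dosage_matrix(make_callset(rows)), "L1")
        for v, c in tally.items():
            assert freqs[v] == pytest.approx(c / 120)

    def test_fully_missing_locus_errors(self):
        cs = make_callset([("L1", "a", 0.0, 2.0, 0.99, 0, 0), ("L2", "a", 0.0, 0.0, 0.5, 0, 0)])
        dm = dosage_matrix(filter_calls(cs))
        with pytest.raises(ValueError):
            allele_frequencies(dm, "L2")


class TestHwe:
    def test_exact_hwe_table_gives_p_one(self):
        counts = {(0, 0): 25, (0, 1): 50, (1, 1): 25}
        res = hwe_test(counts, method="chisq")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_all_heterozygote_rejected_by_both_methods(self):
        counts = {(0, 1): 100}
        assert hwe_test(counts, method="chisq").p_value < 0.05
        assert hwe_test(counts, method="montecarlo", n_perm=2000, seed=1).p_value < 0.05

    def test_single_allele_degenerate(self):
        res = hwe_test({(0, 0): 50})
        assert res.degenerate and res.p_value == 1.0

    def test_biallelic_collapse_mode_runs(self):
        counts = {(0, 0): 30, (0, 1): 20, (1, 1): 5, (0, 2): 5, (2, 2): 1}
        res = hwe_test(counts, method="chisq_biallelic")
        assert 0 < res.p_value <= 1

    def test_montecarlo_matches_exhaustive_enumeration(self):
        # tiny 3-allele table: enumerate all 8! orderings of the allele pool
        counts = {(0, 1): 2, (1, 2): 1, (0, 0): 1}
        obs = hwe_test(counts, method="chisq")
        pool = [a for pair, c in counts.items() for a in pair * c]
        stats = []
        k = 3
        freq = np.bincount(pool, minlength=k) / len(pool)
        n = len(pool) // 2
        exp = np.zeros((k, k))
        for i in range(k):
            exp[i, i] = n * freq[i] ** 2
            for j in range(i + 1, k):
                exp[i, j] = 2 * n * freq[i] * freq[j]
        iu = np.triu_indices(k)
        for perm in itertools.permutations(pool):
            tab = np.zeros((k, k))
            for a, b in zip(perm[0::2], perm[1::2]):
                lo, hi = min(a, b), max(a, b)
                tab[lo, hi] += 1
            cells = np.where(exp[iu] > 0, (tab[iu] - exp[iu]) ** 2 / exp[iu], 0.0)
            stats.append(cells.sum())
        exact_p = np.mean(np.asarray(stats) >= obs.statistic - 1e-12)
        mc = hwe_test(counts, method="montecarlo", n_perm=20_000, seed=3)
        assert mc.p_value == pytest.approx(exact_p, abs=0.02)

    def test_type_one_error_near_nominal_under_hwe(self, rng):
        # genotypes drawn under HWE: empirical rejection at 5% within +-2 pp
        n_loci, n_ind = 400, 60
        rejections = 0
        for i in range(n_loci):
            freqs = rng.dirichlet([2.0, 2.0, 2.0])
            g = rng.choice(3, size=(n_ind, 2), p=freqs)
            counts = {}
            for a, b in g:
                key = (min(a, b), max(a, b))
                counts[key] = counts.get(key, 0) + 1
            p = hwe_test(counts, method="montecarlo", n_perm=1000, seed=i).p_value
            rejections += p < 0.05
        assert 0.03 <= rejections / n_loci <= 0.07


def test_locus_qc_table(small_cohort):
    dm = small_cohort.dosage.subset_loci(small_cohort.dosage.locus_ids[:20])
    qc = locus_qc(dm)
    assert set(qc.columns) >= {"presence_rate", "pic", "polymorphism_class"}
    assert ((qc["pic"] >= 0) & (qc["pic"] < 1)).all()
    assert (qc["presence_rate"] == 1.0).all()  # truth matrix has no missingness
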