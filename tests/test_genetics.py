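import itertools

import numpy as np
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from windowscape.genetics import (bray_curtis, default_rarefaction_g,
                                  deme_summaries, drop_loci, encode_alleles,
                                  filter_individuals, fis, fst_wc, pca_scores,
                                  rarefied_richness)

from conftest import make_table, random_genotype_table


class TestFilterIndividuals:
    def test_three_missing_removed(self):
        calls = [[(1, 2)] * 10, [(0, 0)] * 3 + [(1, 2)] * 7]
        t = make_table(calls)
        out = filter_individuals(t, max_missing_loci=2)
        assert out.individual_id == ["i0"]

    def test_exactly_two_missing_retained(self):
        calls = [[(0, 0)] * 2 + [(1, 2)] * 8]
        out = filter_individuals(make_table(calls), max_missing_loci=2)
        assert out.n_individuals == 1

    def test_fully_typed_unchanged(self, random_table):
        t = random_table
        full = filter_individuals(t, max_missing_loci=t.n_loci)
        assert full.individual_id == t.individual_id


class TestDropLoci:
    def test_drop_two_of_twelve(self):
        loci = [f"Mon{k:02d}" for k in range(12)]
        t = make_table([[(1, 1)] * 12], loci=loci)
        out = drop_loci(t, ["Mon00", "Mon05"])
        assert out.n_loci == 10

    def test_drop_empty_is_identity(self, toy_table):
        out = drop_loci(toy_table, [])
        assert out.loci == toy_table.loci
        np.testing.assert_array_equal(out.calls, toy_table.calls)

    def test_unknown_locus(self, toy_table):
        with pytest.raises(ValueError, match="unknown"):
            drop_loci(toy_table, ["MonXX"])


class TestEncodeAlleles:
    def test_homozygote_heterozygote(self, toy_table):
        am = encode_alleles(toy_table)
        # locus L0, alleles {120, 124}
        sl = am.locus_slices["L0"]
        np.testing.assert_array_equal(am.counts[0, sl], [2, 0])  # 120/120
        np.testing.assert_array_equal(am.counts[1, sl], [1, 1])  # 120/124

    def test_missing_masked(self, toy_table):
        am = encode_alleles(toy_table)
        assert am.missing[3, 1]
        assert not am.missing[3, 0]

    def test_row_sums_two_per_typed_locus(self, rng):
        t = random_genotype_table(rng, n=30, n_loci=6)
        am = encode_alleles(t)
        for locus in am.loci:
            sl = am.locus_slices[locus]
            j = am.loci.index(locus)
            sums = am.counts[:, sl].sum(axis=1)
            typed = ~am.missing[:, j]
            assert np.all(sums[typed] == 2)
            assert np.all(sums[~typed] == 0)

    def test_column_count_is_total_distinct_alleles(self, rng):
        t = random_genotype_table(rng, n=25, n_loci=4, missing_rate=0)
        am = encode_alleles(t)
        total = sum(len(np.unique(t.calls[:, j])) for j in range(t.n_loci))
        assert am.n_alleles == total


def bray_curtis_oracle(am, i, j):
    """Independent multiset-overlap oracle over loci typed in both."""
    num = den = 0.0
    for locus in am.loci:
        k = am.loci.index(locus)
        if am.missing[i, k] or am.missing[j, k]:
            continue
        sl = am.locus_slices[locus]
        x, y = am.counts[i, sl], am.counts[j, sl]
        num += np.minimum(x, y).sum()
        den += x.sum() + y.sum()
    return 1.0 - 2.0 * num / den


class TestBrayCurtis:
    def test_identical_genotypes_zero(self):
        t = make_table([[(1, 2), (3, 3)], [(1, 2), (3, 3)]])
        d = bray_curtis(encode_alleles(t))
        assert d[0, 1] == 0.0

    def test_disjoint_alleles_one(self):
        t = make_table([[(1, 1), (3, 3)], [(2, 2), (4, 4)]])
        assert bray_curtis(encode_alleles(t))[0, 1] == 1.0

    def test_single_locus_half(self):
        # x=(2,0), y=(1,1): d = 1 - 2*1/4 = 0.5
        t = make_table([[(120, 120)], [(120, 124)]])
        assert bray_curtis(encode_alleles(t))[0, 1] == pytest.approx(0.5)

    def test_matches_oracle_on_random_fixture(self, rng):
        t = random_genotype_table(rng, n=15, n_loci=6, missing_rate=0.15)
        am = encode_alleles(t)
        d = bray_curtis(am)
        for i, j in itertools.combinations(range(am.n_individuals), 2):
            assert d[i, j] == pytest.approx(bray_curtis_oracle(am, i, j), abs=1e-12)

    def test_matches_scipy_when_fully_typed(self, rng):
        t = random_genotype_table(rng, n=12, n_loci=5, missing_rate=0.0)
        am = encode_alleles(t)
        d = bray_curtis(am)
        for i, j in itertools.combinations(range(12), 2):
            expect = scipy_braycurtis(am.counts[i].astype(float),
                                      am.counts[j].astype(float))
            assert d[i, j] == pytest.approx(expect, abs=1e-12)

    def test_no_shared_locus_errors(self):
        t = make_table([[(1, 1), (0, 0)], [(0, 0), (2, 2)]])
        with pytest.raises(ValueError, match="share no typed locus"):
            bray_curtis(encode_alleles(t))
        d = bray_curtis(encode_alleles(t), on_no_shared="nan")
        assert np.isnan(d[0, 1])


class TestPCA:
    def test_duplicated_individuals_identical_scores(self):
        t = make_table([[(1, 2), (3, 4)], [(1, 2), (3, 4)], [(1, 1), (3, 3)],
                        [(2, 2), (4, 4)]])
        scores, _, _ = pca_scores(encode_alleles(t), n_axes=2)
        np.testing.assert_allclose(scores[0], scores[1], atol=1e-10)

    def test_eigenvalue_conservation(self, rng):
        t = random_genotype_table(rng, n=20, n_loci=5, missing_rate=0)
        am = encode_alleles(t)
        x = am.counts.astype(float)
        x -= x.mean(axis=0)
        total_var = (x ** 2).sum() / x.shape[0]
        _, eig, _ = pca_scores(am, n_axes=min(x.shape))
        assert eig.sum() == pytest.approx(total_var, rel=1e-10)

    def test_two_disjoint_clusters_separate_on_axis1(self):
        a = [[(1, 1), (3, 3)]] * 5
        b = [[(2, 2), (4, 4)]] * 5
        t = make_table(a + b)
        scores, _, _ = pca_scores(encode_alleles(t), n_axes=1)
        s = scores[:, 0]
        assert (s[:5] > 0).all() != (s[5:] > 0).all()
        assert max(s[:5].max(), -s[:5].min()) > 0
        assert np.sign(s[:5]).std() == 0 and np.sign(s[5:]).std() == 0

    def test_truncation_warning(self):
        t = make_table([[(1, 1)], [(2, 2)], [(1, 2)]])
        with pytest.warns(UserWarning, match="rank"):
            pca_scores(encode_alleles(t), n_axes=10)


def wc_theta_oracle(calls_a, calls_b):
    """Plain transliteration of the two-population theta estimator with
    explicit loops (independent of the production implementation)."""
    calls = {0: np.asarray(calls_a), 1: np.asarray(calls_b)}
    n = {k: len(v) for k, v in calls.items()}
    alleles = sorted({int(x) for v in calls.values() for x in v.reshape(-1)})
    r = 2
    nbar = (n[0] + n[1]) / 2
    nc = (r * nbar - (n[0] ** 2 + n[1] ** 2) / (r * nbar)) / (r - 1)
    num = den = 0.0
    for allele in alleles:
        p = {}
        h = {}
        for k, v in calls.items():
            p[k] = np.mean(v == allele)
            h[k] = np.mean([(x[0] == allele) != (x[1] == allele) for x in v])
        pbar = (n[0] * p[0] + n[1] * p[1]) / (r * nbar)
        s2 = (n[0] * (p[0] - pbar) ** 2 + n[1] * (p[1] - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n[0] * h[0] + n[1] * h[1]) / (r * nbar)
        a = nbar / nc * (s2 - 1 / (nbar - 1) *
                         (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestFst:
    def test_identical_frequencies_near_zero(self, rng):
        pool = np.array([1, 2])
        calls = rng.choice(pool, size=(300, 1, 2))
        t = make_table(calls, demes=["a"] * 150 + ["b"] * 150)
        assert abs(fst_wc(t, "a", "b")) < 0.02

    def test_fixed_alternate_alleles_one(self):
        calls = [[(1, 1)]] * 5 + [[(2, 2)]] * 5
        t = make_table(calls, demes=["a"] * 5 + ["b"] * 5)
        assert fst_wc(t, "a", "b") == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self):
        # 2 demes, 1 locus, tabulated genotype counts
        a = [(1, 1)] * 4 + [(1, 2)] * 3 + [(2, 2)] * 1
        b = [(1, 2)] * 2 + [(2, 2)] * 5 + [(1, 1)] * 1
        t = make_table([[g] for g in a + b],
                       demes=["a"] * len(a) + ["b"] * len(b))
        expect = wc_theta_oracle(a, b)
        assert fst_wc(t, "a", "b") == pytest.approx(expect, abs=1e-12)

    def test_symmetry_and_relabeling_invariance(self, rng):
        t = random_genotype_table(rng, n=30, n_loci=4, n_demes=2, missing_rate=0)
        v1 = fst_wc(t, "d0", "d1")
        assert fst_wc(t, "d1", "d0") == pytest.approx(v1, abs=1e-12)
        relabeled = make_table(t.calls + 1000, demes=t.deme_id)
        assert fst_wc(relabeled, "d0", "d1") == pytest.approx(v1, abs=1e-12)

    def test_monomorphic_nan(self):
        t = make_table([[(1, 1)]] * 6, demes=["a"] * 3 + ["b"] * 3)
        assert np.isnan(fst_wc(t, "a", "b"))


class TestFis:
    def test_all_heterozygous_minus_one(self):
        t = make_table([[(1, 2)]] * 10)
        assert fis(t) == pytest.approx(-1.0)

    def test_all_homozygous_plus_one(self):
        t = make_table([[(1, 1)]] * 5 + [[(2, 2)]] * 5)
        assert fis(t) == pytest.approx(1.0)

    def test_hwe_simulation_near_zero(self, rng):
        freqs = np.array([0.5, 0.3, 0.2])
        calls = rng.choice([1, 2, 3], p=freqs, size=(500, 4, 2))
        t = make_table(calls)
        assert abs(fis(t)) < 0.05

    def test_monomorphic_nan(self):
        t = make_table([[(1, 1)]] * 4)
        assert np.isnan(fis(t))


def rarefaction_oracle(gene_copies, g):
    """Exhaustive enumeration over all subsamples of size g."""
    total = 0
    count = 0
    for combo in itertools.combinations(range(len(gene_copies)), g):
        total += len({gene_copies[i] for i in combo})
        count += 1
    return total / count


class TestRarefiedRichness:
    def test_monomorphic_is_one(self):
        t = make_table([[(5, 5)]] * 4)
        for g in (1, 2, 4):
            assert rarefied_richness(t, "d0", g) == pytest.approx(1.0)

    def test_g1_is_one_even_polymorphic(self):
        t = make_table([[(1, 2)], [(3, 4)]])
        assert rarefied_richness(t, "d0", 1) == pytest.approx(1.0)

    def test_counts_2_2_g2_is_five_thirds(self):
        # N=4 copies, two alleles with 2 copies each
        t = make_table([[(1, 1)], [(2, 2)]])
        expect = rarefaction_oracle([1, 1, 2, 2], 2)
        assert expect == pytest.approx(5 / 3)
        assert rarefied_richness(t, "d0", 2) == pytest.approx(expect, abs=1e-12)

    def test_matches_enumeration_random(self, rng):
        calls = rng.choice([1, 2, 3], size=(4, 2, 2))
        t = make_table(calls)
        for g in (2, 3):
            per_locus = [rarefaction_oracle(list(t.calls[:, j].reshape(-1)), g)
                         for j in range(2)]
            assert rarefied_richness(t, "d0", g) == pytest.approx(
                np.mean(per_locus), abs=1e-10)

    def test_g_too_large_skips_with_warning(self):
        t = make_table([[(1, 2)]] * 2)
        with pytest.warns(UserWarning, match="skipped"):
            assert np.isnan(rarefied_richness(t, "d0", 5))


class TestDemeSummaries:
    def test_columns_and_sizes(self, rng):
        t = random_genotype_table(rng, n=20, n_demes=4, missing_rate=0)
        df = deme_summaries(t)
        assert list(df.columns) == ["deme_id", "n", "A", "AR", "Fis"]
        assert df["n"].sum() == 20
        assert (df["AR"] <= df["A"] + 1e-9).all()

    def test_default_g(self, rng):
        t = random_genotype_table(rng, n=20, n_demes=4)
        assert default_rarefaction_g(t) == 2 * 5
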