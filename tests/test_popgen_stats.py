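import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from hapaudit.haplotyping import Haplotype, build_count_table, collapse
from hapaudit.popgen_stats import (
    base_composition,
    chi_square_unique,
    compare_diversity,
    diversity_stats,
    haplotype_diversity,
    nucleotide_diversity,
    pairwise_diff_matrix,
    segregating_sites,
)
from hapaudit.io_formats import CountTable
from hapaudit.synthetic_data import SyntheticConfig, gen_haplotype_sequences

BB_COUNTS = [4, 4, 3, 1, 3, 2, 3, 1, 2, 1, 1, 2, 1, 1, 1, 1] + [1] * 8


def _hap_set(n, seed=0, L=40):
    seqs = gen_haplotype_sequences(n, SyntheticConfig(L=L, S=min(L - 1, n + 5), seed=seed))
    return [Haplotype(label=f"H{i}", seq=s, members=(f"H{i}",)) for i, s in enumerate(seqs)]


class TestHaplotypeDiversity:
    def test_bb_reference_values(self):
        h, v, ci = haplotype_diversity(BB_COUNTS)
        assert round(h, 3) == 0.968
        assert round(ci[0], 3) == 0.942 and round(ci[1], 3) == 0.993

    def test_sta_reference_value(self, table2):
        h, _, _ = haplotype_diversity(table2.column("STA"))
        assert round(h, 3) == 0.939

    def test_single_haplotype(self):
        h, v, ci = haplotype_diversity([5])
        assert h == 0 and v == 0 and ci == (0, 0)

    def test_two_singletons(self):
        h, _, _ = haplotype_diversity([1, 1])
        assert h == pytest.approx(1.0)

    def test_n_below_two_raises(self):
        with pytest.raises(ValueError):
            haplotype_diversity([1])

    @settings(max_examples=60, deadline=None)
    @given(counts=st.lists(st.integers(1, 12), min_size=1, max_size=15))
    def test_unbiasedness_identity(self, counts):
        """h equals 1 - sum c_i(c_i-1) / (n(n-1)), by pair counting."""
        n = sum(counts)
        if n < 2:
            return
        h, _, _ = haplotype_diversity(counts)
        same_pairs = sum(c * (c - 1) for c in counts)
        assert h == pytest.approx(1 - same_pairs / (n * (n - 1)), abs=1e-12)

    def test_ci_truncated_to_unit_interval(self):
        _, _, ci = haplotype_diversity([1, 1])  # tiny n, huge variance
        assert 0 <= ci[0] <= ci[1] <= 1


class TestPairwiseDiffMatrix:
    def test_simple(self):
        a = Haplotype("a", "ACGT", ("a",))
        b = Haplotype("b", "ACGA", ("b",))
        d = pairwise_diff_matrix([a, b])
        assert d.tolist() == [[0, 1], [1, 0]]

    def test_identical(self):
        a = Haplotype("a", "ACGT", ("a",))
        b = Haplotype("b", "ACGT", ("b",))
        assert pairwise_diff_matrix([a, b])[0, 1] == 0

    def test_pairwise_deletion(self):
        a = Haplotype("a", "ACNT", ("a",))
        b = Haplotype("b", "TC-A", ("b",))
        # column 0 differs; columns 2 (N) and 3-vs-gap? col3: T vs A both resolved
        assert pairwise_diff_matrix([a, b])[0, 1] == 2

    def test_against_position_oracle(self, rng):
        haps = _hap_set(20, seed=3, L=50)
        d = pairwise_diff_matrix(haps)
        for i in range(20):
            for j in range(20):
                oracle = sum(
                    x != y
                    for x, y in zip(haps[i].seq, haps[j].seq)
                    if x in "ACGT" and y in "ACGT"
                )
                assert d[i, j] == oracle
        assert (d == d.T).all() and not d.diagonal().any()


class TestNucleotideDiversity:
    def test_one_haplotype(self):
        with pytest.raises(ValueError):
            nucleotide_diversity([1], np.zeros((1, 1)), 10)
        pi, *_ = nucleotide_diversity([3], np.zeros((1, 1)), 10)
        assert pi == 0

    def test_two_individuals_one_diff(self):
        d = np.array([[0, 1], [1, 0]])
        pi, *_ = nucleotide_diversity([1, 1], d, 10)
        assert pi == pytest.approx(0.1)

    def test_brute_force_oracle(self):
        haps = _hap_set(12, seed=8, L=60)
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 6, size=12)
        d = pairwise_diff_matrix(haps)
        pi, *_ = nucleotide_diversity(counts, d, 60)
        # oracle: expand to individuals, average over all pairs, unbiased scale
        individuals = [i for i, c in enumerate(counts) for _ in range(c)]
        n = len(individuals)
        total = sum(
            d[individuals[i], individuals[j]]
            for i in range(n)
            for j in range(i + 1, n)
        )
        oracle = total / (n * (n - 1) / 2) / 60
        assert pi == pytest.approx(oracle, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            nucleotide_diversity([1, 1, 1], np.zeros((2, 2)), 10)

    def test_tajima_ci_matches_reference_width(self):
        # A per-site diversity of ~0.018 at n=39, L=435 must give the wide
        # total-variance interval of reports, (0.000, ~0.036) — not the
        # narrow +/-0.001 sampling-only band.  (0.018 is itself a rounded
        # printed value, so the upper bound is checked to 2e-3.)
        pi = 0.018
        n, L = 39, 435
        v = (n + 1) * pi / (3 * (n - 1) * L) + 2 * (n**2 + n + 3) * pi**2 / (
            9 * n * (n - 1)
        )
        lo, hi = max(0.0, pi - 1.96 * v**0.5), pi + 1.96 * v**0.5
        assert lo == 0.0
        assert hi == pytest.approx(0.036, abs=2e-3)


class TestSegregatingSites:
    def test_identical_and_single_column(self):
        with pytest.warns(UserWarning, match="single haplotype"):
            assert segregating_sites(_hap_set(1, seed=0)) == 0
        a = Haplotype("a", "AAA", ("a",))
        b = Haplotype("b", "AAT", ("b",))
        assert segregating_sites([a, b]) == 1

    def test_unresolved_ignored(self):
        a = Haplotype("a", "AAN", ("a",))
        b = Haplotype("b", "AAT", ("b",))
        assert segregating_sites([a, b]) == 0

    def test_generator_construction(self):
        haps = _hap_set(20, seed=5, L=100)
        assert segregating_sites(haps) == 25  # S = n + 5


class TestBaseComposition:
    def test_uniform(self):
        comp, gc = base_composition(["ACGT"])
        assert comp == {b: 25.0 for b in "ACGT"} and gc == 50.0

    def test_gc_only(self):
        _, gc = base_composition(["GGCC"])
        assert gc == 100.0

    def test_counting_oracle(self, rng):
        seqs = ["".join(rng.choice(list("ACGTN"), size=30)) for _ in range(10)]
        comp, gc = base_composition(seqs)
        joined = "".join(seqs)
        resolved = sum(joined.count(b) for b in "ACGT")
        for b in "ACGT":
            assert comp[b] == pytest.approx(100 * joined.count(b) / resolved)
        assert sum(comp.values()) == pytest.approx(100.0)


class TestChiSquareUnique:
    def test_table2_reference(self, table2):
        result = chi_square_unique(table2)
        assert result.observed.tolist() == [[8, 5, 6], [16, 16, 8]]
        assert round(result.statistic, 2) == 1.42
        assert result.df == 2
        assert round(result.p_value, 2) == 0.49

    def test_expected_margins_match_observed(self, table2):
        result = chi_square_unique(table2)
        assert np.allclose(result.expected.sum(0), result.observed.sum(0))
        assert np.allclose(result.expected.sum(1), result.observed.sum(1))

    def test_equal_proportions_gives_zero(self):
        table = CountTable(
            haplotype_ids=[f"h{i}" for i in range(4)],
            site_ids=["A", "B"],
            counts=np.array([[1, 0], [0, 1], [1, 1], [1, 1]]),
        )
        result = chi_square_unique(table)
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_pearson_formula_oracle(self):
        obs = np.array([[7, 3], [5, 9]])
        table = CountTable(
            haplotype_ids=[f"h{i}" for i in range(24)],
            site_ids=["A", "B"],
            counts=np.array(
                [[1, 0]] * 7 + [[0, 1]] * 3 + [[1, 1]] * 14
            ),
        )
        # the contingency table from this layout: unique (7,3), shared (14,14)
        result = chi_square_unique(table)
        o = result.observed.astype(float)
        rowsum, colsum, n = o.sum(1), o.sum(0), o.sum()
        expected = np.outer(rowsum, colsum) / n
        chi2 = ((o - expected) ** 2 / expected).sum()
        assert result.statistic == pytest.approx(chi2, abs=1e-12)

    def test_p_values_uniform_under_null(self):
        """Null-simulated 2x3 tables give ~uniform p-values (KS, alpha=0.01)."""
        from hapaudit.popgen_stats import pearson_chi2

        rng = np.random.default_rng(99)
        n_per_site, p_unique = 120, 0.4
        pvals = []
        for _ in range(2000):
            unique = rng.binomial(n_per_site, p_unique, size=3)
            obs = np.vstack([unique, n_per_site - unique])
            pvals.append(pearson_chi2(obs).p_value)
        ks = sstats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_single_site_rejected(self):
        table = CountTable(["h1"], ["A"], np.array([[3]]))
        with pytest.raises(ValueError):
            chi_square_unique(table)


class TestCompareDiversity:
    def test_equal_statistics(self):
        t, p = compare_diversity(0.5, 0.1, 0.5, 0.1, df=2)
        assert t == 0 and p == pytest.approx(1.0)

    def test_reference_p_from_t(self):
        # |t| = 4.467 with df=2 gives a two-tailed P near 0.047
        p = 2 * sstats.t.sf(4.467, 2)
        assert round(p, 3) == 0.047
        se = 0.01
        stat_diff = 4.467 * np.hypot(se, se)
        t, p2 = compare_diversity(0.06, se, 0.06 - stat_diff, se, df=2)
        assert t == pytest.approx(4.467)
        assert round(p2, 3) == 0.047

    def test_symmetry(self):
        a = compare_diversity(0.3, 0.05, 0.5, 0.02, df=4)
        b = compare_diversity(0.5, 0.02, 0.3, 0.05, df=4)
        assert a == b

    def test_zero_pooled_se(self):
        with pytest.raises(ValueError):
            compare_diversity(0.1, 0, 0.2, 0, df=2)


class TestDiversityStatsBundle:
    def test_composition_sums_and_bounds(self, table2):
        from hapaudit.synthetic_data import gen_haplotypes

        records, _ = gen_haplotypes(SyntheticConfig(seed=13), table2)
        haps = collapse(records)
        t = build_count_table(haps, {r.id: r.site for r in records})
        st_ = diversity_stats("BB", haps, t.column("BB"))
        assert st_.n == 39 and st_.k == 24
        assert 0 <= st_.h <= 1
        assert 0 <= st_.ci_h[0] <= st_.ci_h[1] <= 1
        assert st_.ci_pi[0] >= 0
        assert sum(st_.composition.values()) == pytest.approx(100.0)
        assert st_.s <= 435
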