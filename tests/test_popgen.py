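"""Diversity statistics, Hudson FST, and the panmixia permutation test."""

import numpy as np
import pytest

from landgraph import popgen
from landgraph.core import MISSING, DegenerateInputError

from conftest import enumeration_fst, make_dataset


class TestDiversity:
    def test_theta_pi_matches_pair_enumeration(self):
        # 4 haploids over 2 SNPs: pairwise diffs sum to 7 over 6 pairs, L=2
        ds = make_dataset([[0, 0], [0, 0], [0, 1], [1, 1]], ["X"] * 4, L=2)
        assert popgen.nucleotide_diversity(ds) == pytest.approx(7 / 12, abs=1e-12)

    def test_theta_pi_zero_without_variation(self):
        ds = make_dataset([[0, 0], [0, 0]], ["X", "X"])
        assert popgen.nucleotide_diversity(ds) == 0.0

    def test_single_allele_is_an_error(self):
        ds = make_dataset([[0, 1]], ["X"])
        with pytest.raises(DegenerateInputError):
            popgen.nucleotide_diversity(ds)

    def test_watterson_closed_form(self):
        # n=4 alleles, S=3 segregating sites, L=100: S/(a1·L), a1=1+1/2+1/3
        g = [[0, 0, 0], [0, 0, 1], [0, 1, 1], [1, 1, 0]]
        ds = make_dataset(g, ["X"] * 4, L=100)
        a1 = 1 + 1 / 2 + 1 / 3
        assert popgen.watterson_theta(ds) == pytest.approx(3 / (a1 * 100), abs=1e-12)

    def test_watterson_n2_is_s_over_l(self):
        ds = make_dataset([[0, 1], [1, 1]], ["X", "X"], L=7)
        assert popgen.watterson_theta(ds) == pytest.approx(1 / 7)

    def test_tajimas_d_matches_independent_transcription(self):
        g = np.array([[0, 0], [0, 0], [0, 1], [1, 1]])
        ds = make_dataset(g, ["X"] * 4, L=2)
        # independent transcription of the 1989 constants
        n, S = 4, 2
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        pi_total = 7 / 6
        expected = (pi_total - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
        assert popgen.tajimas_d(ds) == pytest.approx(expected, abs=1e-12)

    def test_tajimas_d_undefined_signalled(self):
        ds = make_dataset([[0], [0], [0], [0]], ["X"] * 4)
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(popgen.tajimas_d(ds))

    def test_statistics_invariant_to_reordering(self, rng):
        g = rng.integers(0, 2, size=(12, 30))
        ds = make_dataset(g, ["X"] * 12, L=60)
        perm_s = rng.permutation(12)
        perm_l = rng.permutation(30)
        ds2 = make_dataset(g[perm_s][:, perm_l], ["X"] * 12, L=60)
        assert popgen.nucleotide_diversity(ds2) == pytest.approx(
            popgen.nucleotide_diversity(ds), abs=1e-12
        )
        assert popgen.watterson_theta(ds2) == pytest.approx(
            popgen.watterson_theta(ds), abs=1e-12
        )
        assert popgen.tajimas_d(ds2) == pytest.approx(popgen.tajimas_d(ds), abs=1e-12)


class TestHudsonFst:
    def test_no_differentiation_near_zero(self):
        # identical 50/50 frequencies in both locales, large n
        g = [[0], [1]] * 200
        ds = make_dataset(g, ["A", "A"] * 100 + ["B", "B"] * 100)
        assert popgen.hudson_fst(ds, "A", "B") == pytest.approx(0.0, abs=0.01)
        assert popgen.hudson_fst(ds, "A", "B") < 0  # slightly negative, unclamped

    def test_fixed_difference_is_one(self):
        g = [[0]] * 5 + [[1]] * 5
        ds = make_dataset(g, ["A"] * 5 + ["B"] * 5)
        assert popgen.hudson_fst(ds, "A", "B") == pytest.approx(1.0)

    def test_textbook_frequencies(self):
        # n=10 haploids each, p=0.8 vs 0.2: 1 − 0.35556/0.68 ≈ 0.477
        g = [[1]] * 8 + [[0]] * 2 + [[1]] * 2 + [[0]] * 8
        ds = make_dataset(g, ["A"] * 10 + ["B"] * 10)
        assert popgen.hudson_fst(ds, "A", "B") == pytest.approx(
            1 - (2 * 0.8 * 0.2 * 10 / 9) / 0.68, abs=1e-12
        )

    def test_negative_values_not_clamped(self, rng):
        for _ in range(20):
            g = rng.integers(0, 2, size=(8, 15))
            ds = make_dataset(g, ["A"] * 4 + ["B"] * 4)
            try:
                f = popgen.hudson_fst(ds, "A", "B")
            except DegenerateInputError:
                continue
            if f < 0:
                return  # a negative estimate surfaced unclamped
        pytest.fail("no negative FST produced by random noise datasets")

    @pytest.mark.parametrize("ploidy", [1, 2])
    def test_matches_enumeration_oracle(self, rng, ploidy):
        """Exhaustive allele-pair enumeration agrees to 1e−12 (≤12 alleles)."""
        for rep in range(25):
            n_a = int(rng.integers(2, 12 // ploidy + 1))
            n_b = int(rng.integers(2, 12 // ploidy + 1))
            g = rng.integers(0, ploidy + 1, size=(n_a + n_b, 8))
            ds = make_dataset(g, ["A"] * n_a + ["B"] * n_b, ploidy=ploidy)
            try:
                got = popgen.hudson_fst(ds, "A", "B")
            except DegenerateInputError:
                continue
            want = enumeration_fst(g[:n_a], g[n_a:], ploidy)
            assert got == pytest.approx(want, abs=1e-12)

    def test_matrix_composes_per_pair_calls(self, rng):
        g = rng.integers(0, 2, size=(12, 25))
        ds = make_dataset(g, ["A"] * 4 + ["B"] * 4 + ["C"] * 4)
        matrix, _ = popgen.pairwise_fst_matrix(ds)
        for a, b in matrix.pairs():
            assert matrix.get(a, b) == pytest.approx(
                popgen.hudson_fst(ds, a, b), abs=1e-12
            )

    def test_fst_never_exceeds_one(self, rng):
        for _ in range(30):
            g = rng.integers(0, 2, size=(10, 12))
            ds = make_dataset(g, ["A"] * 5 + ["B"] * 5)
            try:
                assert popgen.hudson_fst(ds, "A", "B") <= 1.0
            except DegenerateInputError:
                pass

    def test_missing_data_pairwise_deletion(self):
        # locus 2 is missing in locale B entirely: only locus 1 contributes
        g = np.array([[1, 0], [1, 1], [0, MISSING], [0, MISSING]])
        ds = make_dataset(g, ["A", "A", "B", "B"])
        expected = popgen.hudson_fst(
            make_dataset(g[:, :1], ["A", "A", "B", "B"]), "A", "B"
        )
        assert popgen.hudson_fst(ds, "A", "B") == pytest.approx(expected)


class TestPanmixiaPermutation:
    def test_monomorphic_everywhere_gives_p_one(self):
        g = np.zeros((8, 4), dtype=int)
        g[:, 0] = [1, 0, 1, 0, 1, 0, 1, 0]  # one balanced locus so FST defined
        ds = make_dataset(g, ["A"] * 4 + ["B"] * 4)
        res = popgen.panmixia_permutation(ds, n_perm=99, seed=3)
        r = res.results[("A", "B")]
        assert r.observed <= 0.0 or np.isclose(r.observed, 0.0, atol=0.4)
        assert r.p_value > 0.2

    def test_fixed_difference_exact_enumeration(self):
        """Two locales of 6 haploids, fixed at 10 loci: P(null ≥ 1) = 2/C(12,6).

        The only label splits reproducing FST = 1 are the two that place all
        carriers together, so p should be far below 0.05 and near its exact
        lower bound.
        """
        g = np.vstack([np.zeros((6, 10), int), np.ones((6, 10), int)])
        ds = make_dataset(g, ["A"] * 6 + ["B"] * 6)
        res = popgen.panmixia_permutation(ds, n_perm=1000, seed=5)
        assert res.results[("A", "B")].observed == pytest.approx(1.0)
        assert res.results[("A", "B")].p_value <= 0.01

    def test_deterministic_under_fixed_seed(self, rng):
        g = rng.integers(0, 2, size=(12, 20))
        ds = make_dataset(g, ["A"] * 6 + ["B"] * 6)
        r1 = popgen.panmixia_permutation(ds, n_perm=50, seed=11)
        r2 = popgen.panmixia_permutation(ds, n_perm=50, seed=11)
        np.testing.assert_array_equal(
            r1.results[("A", "B")].null_values, r2.results[("A", "B")].null_values
        )
        assert r1.results[("A", "B")].p_value == r2.results[("A", "B")].p_value

    def test_bootstrap_mode_runs(self, rng):
        g = rng.integers(0, 2, size=(10, 15))
        ds = make_dataset(g, ["A"] * 5 + ["B"] * 5)
        res = popgen.panmixia_permutation(ds, n_perm=20, seed=1, bootstrap=True)
        assert res.results[("A", "B")].null_model == "pooled_bootstrap"
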