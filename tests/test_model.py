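"""Unit and property tests for the core maternal-selection recursion."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import matsel as ms
from matsel.model import hardy_weinberg_total

from conftest import constant_viability_recursion, mating_table_oracle, random_state


class TestCombinatorics:
    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 7), (3, 24), (4, 58), (5, 115)])
    def test_parameter_count(self, n, expected):
        assert ms.count_parameters(n) == expected

    @pytest.mark.parametrize("n,expected", [(1, 0), (2, 3), (3, 15)])
    def test_heterozygote_pair_count(self, n, expected):
        assert ms.heterozygote_pair_count(n) == expected

    def test_heterozygote_pair_count_matches_enumeration(self):
        """n(n-1)(2n-1)/2 equals a direct count of het-offspring pairs."""
        for n in range(1, 6):
            count = sum(
                1 for p in ms.enumerate_pairs(n) if not p.offspring.is_homozygote
            )
            assert count == ms.heterozygote_pair_count(n)

    @pytest.mark.parametrize("n", range(1, 9))
    def test_enumeration_length_and_uniqueness(self, n):
        pairs = ms.enumerate_pairs(n)
        assert len(pairs) == ms.count_parameters(n)
        assert len(set(pairs)) == len(pairs)
        for p in pairs:
            assert p.offspring.i <= p.offspring.j
            assert p.mother.i <= p.mother.j
            assert p.is_compatible

    def test_enumeration_by_independent_set_construction(self):
        """Enumeration equals the set of all compatible unordered combinations."""
        n = 4
        genos = [ms.Genotype(i, j) for i in range(n) for j in range(i, n)]
        expected = {
            (og, mg)
            for og, mg in itertools.product(genos, genos)
            if {mg.i, mg.j} & {og.i, og.j}
        }
        assert {(p.offspring, p.mother) for p in ms.enumerate_pairs(n)} == expected

    @pytest.mark.parametrize("bad_n", [0, -1])
    def test_invalid_n_rejected(self, bad_n):
        with pytest.raises(ValueError):
            ms.count_parameters(bad_n)
        with pytest.raises(ValueError):
            ms.heterozygote_pair_count(bad_n)


class TestGenotypesAndClasses:
    def test_genotype_canonicalization(self):
        assert ms.Genotype.of(3, 1) == ms.Genotype.of(1, 3) == ms.Genotype(1, 3)

    def test_incompatible_pair_rejected(self):
        with pytest.raises(ValueError):
            ms.OffspringMotherPair.of((0, 0), (1, 1))

    @pytest.mark.parametrize(
        "offspring,mother,expected",
        [
            ((0, 0), (0, 0), ms.PairClass.C_iiii),
            ((0, 0), (0, 2), ms.PairClass.C_iiij),
            ((0, 1), (1, 1), ms.PairClass.C_ijii),
            ((0, 1), (0, 1), ms.PairClass.C_ijij),
            ((0, 1), (0, 2), ms.PairClass.C_ijik),
            ((0, 1), (1, 2), ms.PairClass.C_ijik),
        ],
    )
    def test_classification(self, offspring, mother, expected):
        assert ms.classify_pair(ms.OffspringMotherPair.of(offspring, mother)) == expected

    @pytest.mark.parametrize("n", [1, 2, 3, 5])
    def test_class_sizes_partition_enumeration(self, n):
        """Class sizes follow the combinatorial counts and sum to C(n)."""
        from collections import Counter

        sizes = Counter(ms.classify_pair(p) for p in ms.enumerate_pairs(n))
        assert sizes[ms.PairClass.C_iiii] == n
        assert sizes[ms.PairClass.C_iiij] == n * (n - 1)
        assert sizes[ms.PairClass.C_ijii] == n * (n - 1)
        assert sizes[ms.PairClass.C_ijij] == n * (n - 1) // 2
        assert sizes[ms.PairClass.C_ijik] == n * (n - 1) * (n - 2)
        assert sum(sizes.values()) == ms.count_parameters(n)


class TestPopulationState:
    def test_allele_frequencies_examples(self):
        st1 = ms.PopulationState(np.array([[1.0]]))
        assert ms.allele_frequencies(st1) == pytest.approx([1.0])
        st2 = ms.PopulationState(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert ms.allele_frequencies(st2) == pytest.approx([0.5, 0.5])

    def test_hw_round_trip(self):
        g = np.random.default_rng(3)
        p = g.dirichlet(np.ones(4))
        state = ms.hardy_weinberg_state(p)
        assert np.abs(ms.allele_frequencies(state) - p).max() < 1e-12
        assert abs(state.total() - 1.0) < 1e-12

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError):
            ms.hardy_weinberg_state(np.array([0.6, 0.6]))
        with pytest.raises(ValueError):
            ms.hardy_weinberg_state(np.array([1.2, -0.2]))


class TestStep:
    def test_neutral_reaches_hw_in_one_generation(self):
        g = np.random.default_rng(11)
        state = random_state(3, g)
        p = state.allele_frequencies()
        nxt, wbar = ms.step(state, ms.FitnessSet.constant(3, 1.0))
        assert wbar == pytest.approx(1.0, abs=1e-12)
        assert np.abs(nxt.x - hardy_weinberg_total(p)).max() < 1e-12
        # and allele frequencies stay put forever after
        for _ in range(5):
            nxt, _ = ms.step(nxt, ms.FitnessSet.constant(3, 1.0))
            assert np.abs(nxt.allele_frequencies() - p).max() < 1e-12

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_step_matches_mating_table_oracle(self, n):
        g = np.random.default_rng(100 + n)
        for trial in range(25):
            fs = ms.random_fitness_set(n, ms.RngConfig(trial, (n,)))
            state = random_state(n, g)
            got, wbar = ms.step(state, fs)
            want, wbar_o = mating_table_oracle(state, fs)
            assert np.abs(got.x - want.x).max() < 1e-12
            assert wbar == pytest.approx(wbar_o, abs=1e-12)

    def test_mother_independent_reduces_to_constant_viability(self):
        """With w_ijkl = v_ij the trajectory equals the classical recursion."""
        v = np.array([[0.9, 0.5, 0.3], [0.5, 1.0, 0.8], [0.3, 0.8, 0.2]])
        fs = ms.FitnessSet.mother_independent(v)
        p = np.array([0.2, 0.5, 0.3])
        state = ms.hardy_weinberg_state(p)
        for _ in range(50):
            state, _ = ms.step(state, fs)
            p = constant_viability_recursion(p, v)
            # genotype frequencies are HW on the *post-selection* gametes only
            # after one extra round; allele frequencies agree each generation
            assert np.abs(state.allele_frequencies() - p).max() < 1e-12

    def test_overdominant_fixed_point(self):
        v = np.array([[0.4, 1.0], [1.0, 0.6]])
        fs = ms.FitnessSet.mother_independent(v)
        state = ms.hardy_weinberg_state([0.9, 0.1])
        for _ in range(3000):
            state, _ = ms.step(state, fs)
        p_hat = (1.0 - 0.6) / (2 * 1.0 - 0.4 - 0.6)
        assert state.allele_frequencies()[0] == pytest.approx(p_hat, abs=1e-9)

    def test_frequencies_sum_to_one_every_generation(self):
        g = np.random.default_rng(5)
        fs = ms.random_fitness_set(3, ms.RngConfig(5))
        state = random_state(3, g)
        for _ in range(200):
            state, _ = ms.step(state, fs)
            assert abs(state.total() - 1.0) < 1e-12
            assert np.all(state.x >= 0)

    def test_permutation_equivariance(self):
        """Relabeling alleles in state and fitness permutes the output identically."""
        g = np.random.default_rng(17)
        n = 4
        fs = ms.random_fitness_set(n, ms.RngConfig(17))
        state = random_state(n, g)
        perm = [2, 0, 3, 1]
        fs_p = fs.permute(perm)
        state_p = ms.PopulationState(state.x[np.ix_(perm, perm)])
        out, w1 = ms.step(state, fs)
        out_p, w2 = ms.step(state_p, fs_p)
        assert w1 == pytest.approx(w2, abs=1e-14)
        assert np.abs(out_p.x - out.x[np.ix_(perm, perm)]).max() < 1e-13

    def test_zero_mean_fitness_raises(self):
        fs = ms.FitnessSet.constant(2, 0.0)
        state = ms.hardy_weinberg_state([0.5, 0.5])
        with pytest.raises(ms.DegenerateStateError):
            ms.step(state, fs)

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValueError):
            ms.step(ms.hardy_weinberg_state([0.5, 0.5]), ms.FitnessSet.constant(3, 1.0))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(2, 4), st.integers(0, 10**6))
def test_step_preserves_simplex_property(n, seed):
    """Normalization invariant holds for arbitrary random instances."""
    g = np.random.default_rng(seed)
    fs = ms.random_fitness_set(n, g)
    state = random_state(n, g)
    nxt, wbar = ms.step(state, fs)
    assert wbar > 0
    assert abs(nxt.total() - 1.0) < 1e-12
    assert np.all(nxt.x >= 0)
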