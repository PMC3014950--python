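import numpy as np
import pytest
from scipy.stats import chisquare

from mitrans.align import as_alignment
from mitrans.seqio import NucleotideSequence
from mitrans.shannon import joint_frequencies, shannon_mi, single_letter_entropy
from mitrans.simulate import (
    EvolutionParams,
    QuartetSpec,
    counterexample_triple,
    evolve,
    random_sequence,
    rate_matrix,
    simulate_chain,
    simulate_pair,
    simulate_quartet,
)

from ._oracles import jc_expected_p


class TestRateMatrix:
    @pytest.mark.parametrize("model", ["JC", "K2P", "HKY"])
    def test_rows_sum_to_zero_and_unit_rate(self, model):
        q = rate_matrix(model, kappa=3.0)
        assert np.allclose(q.sum(axis=1), 0.0)
        assert -np.mean(np.diag(q)) == pytest.approx(1.0)

    def test_hky_stationarity(self):
        pi = np.array([0.4, 0.1, 0.1, 0.4])
        q = rate_matrix("HKY", kappa=2.0, base_freqs=pi)
        assert np.allclose(pi @ q, 0.0, atol=1e-12)


class TestEvolve:
    def test_zero_branch_identity(self):
        p = EvolutionParams(branch_length=0.0, seed=1)
        x = random_sequence(500, p, seq_id="x")
        assert evolve(x, p).letters == x.letters

    def test_seeded_determinism(self):
        p = EvolutionParams(model="K2P", branch_length=0.3, indel_rate=0.01, seed=42)
        a = simulate_pair(2000, p)
        b = simulate_pair(2000, p)
        assert a[0].letters == b[0].letters and a[1].letters == b[1].letters

    def test_long_branch_reaches_stationarity(self):
        p = EvolutionParams(model="JC", branch_length=50.0, seed=3)
        x, y = simulate_pair(100_000, p)
        match = sum(a == b for a, b in zip(x.letters, y.letters)) / len(x.letters)
        assert match == pytest.approx(0.25, abs=0.01)

    def test_jc_closed_form_p_distance(self):
        t = 0.2
        p = EvolutionParams(model="JC", branch_length=t, seed=9)
        x, y = simulate_pair(100_000, p)
        observed = sum(a != b for a, b in zip(x.letters, y.letters)) / len(x.letters)
        expected = jc_expected_p(t)
        se = np.sqrt(expected * (1 - expected) / 100_000)
        assert abs(observed - expected) < 3 * se

    def test_indels_change_length(self):
        p = EvolutionParams(branch_length=0.1, indel_rate=0.02, seed=8)
        x = random_sequence(2000, p, seq_id="x")
        rng = np.random.default_rng(8)
        y = evolve(x, p, rng)
        assert len(y.letters) != len(x.letters)

    def test_stationary_composition_uniform(self):
        """Long JC simulations keep a uniform base composition."""
        rejected = 0
        for seed in range(20):
            p = EvolutionParams(model="JC", branch_length=0.5, seed=seed)
            x, y = simulate_pair(100_000, p)
            counts = [y.letters.count(c) for c in "ACGT"]
            if chisquare(counts).pvalue < 0.01:
                rejected += 1
        assert rejected <= 2  # ~alpha=0.01: expect 0-1 rejections in 20

    def test_at_rich_bias_lowers_entropy_but_not_mi_decay(self):
        """Compositional bias reduces single-sequence entropy while
        substitution-driven MI decay persists (the insect-bias effect)."""
        entropies = []
        for at in (0.25, 0.35, 0.45):
            f = (at, 0.5 - at, 0.5 - at, at)
            p = EvolutionParams(model="HKY", branch_length=0.2, base_freqs=f, seed=21)
            x, y = simulate_pair(20_000, p)
            entropies.append(single_letter_entropy(x.letters))
            mi = shannon_mi(joint_frequencies(as_alignment(x, y))).bits
            assert mi > 0.5  # MI survives the bias
        assert entropies[0] > entropies[1] > entropies[2]
        assert entropies[2] < 2.0


class TestChainAndQuartet:
    def test_zero_branches_identical_chain(self):
        p = EvolutionParams(model="JC", seed=5)
        seqs = simulate_chain(300, [0.0, 0.0], p)
        assert seqs[0].letters == seqs[1].letters == seqs[2].letters

    def test_quartet_additive_matrix(self):
        spec = QuartetSpec((0.1, 0.2, 0.3, 0.4), 0.05)
        d = spec.additive_matrix()
        assert d[0, 1] == pytest.approx(0.3)
        assert d[0, 2] == pytest.approx(0.45)
        assert d[2, 3] == pytest.approx(0.7)
        assert np.allclose(d, d.T)

    def test_quartet_leaves_generated(self):
        spec = QuartetSpec((0.1, 0.1, 0.1, 0.1), 0.05,
                           EvolutionParams(model="K2P", seed=2), root_length=500)
        leaves = simulate_quartet(spec)
        assert [s.id for s in leaves] == ["a", "b", "c", "d"]
        assert all(len(s.letters) == 500 for s in leaves)


class TestCounterexample:
    def test_mi_structure(self):
        x, y, z = counterexample_triple(10_000, seed=4)
        def mi(a, b):
            return shannon_mi(joint_frequencies(as_alignment(a, b))).bits
        assert 0.9 <= mi(x, y) <= 1.05
        assert 0.9 <= mi(x, z) <= 1.05
        assert mi(y, z) < 0.01

    def test_deterministic(self):
        assert counterexample_triple(100, seed=1) == counterexample_triple(100, seed=1)

    def test_bit_semantics(self):
        # y conserves the weak/strong bit: A,T stay weak, C,G stay strong
        x, y, z = counterexample_triple(5000, seed=6)
        weak = set("AT")
        assert all((a in weak) == (b in weak) for a, b in zip(x.letters, y.letters))
        purine = set("AG")
        assert all((a in purine) == (c in purine) for a, c in zip(x.letters, z.letters))
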