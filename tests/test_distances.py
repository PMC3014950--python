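import math

import numpy as np
import pytest
from scipy.linalg import expm

from mitrans.align import as_alignment
from mitrans.distances import (
    distance_matrix,
    kimura1,
    kimura2,
    kimura_fractions,
    log_det,
    log_mi,
    ncd,
    nsd,
    p_distance,
    pair_distance,
    pc_p_distance,
    read_phylip,
    write_phylip,
)
from mitrans.kolmogorov import MIEstimate
from mitrans.shannon import JointFrequencyMatrix, joint_frequencies, marginal_entropies, shannon_mi
from mitrans.simulate import (
    EvolutionParams,
    rate_matrix,
    simulate_chain,
    simulate_pair,
)


def mk_mi(bits):
    return MIEstimate(bits=bits, method="align", codec="lzma")


def joint_from_pmat(pmat):
    f = pmat / 4.0
    return JointFrequencyMatrix("ACGT", f, 10_000)


class TestNormalizedDistances:
    @pytest.mark.parametrize("i,cx,cy,expected", [(0, 100, 100, 1.0), (100, 100, 100, 0.0), (50, 100, 100, 0.5)])
    def test_ncd_linear_form(self, i, cx, cy, expected):
        assert ncd(mk_mi(i), cx, cy).value == pytest.approx(expected)

    def test_ncd_clamped_and_logged(self):
        r = ncd(mk_mi(-50), 100, 100)
        assert r.value == 1.1 and "clamped" in r.note

    def test_ncd_zero_complexity_rejected(self):
        with pytest.raises(ValueError):
            ncd(mk_mi(1), 0, 10)

    @pytest.mark.parametrize("i,hx,hy,expected", [(2.0, 2.0, 2.0, 0.0), (0.0, 2.0, 2.0, 1.0), (1.0, 2.0, 2.0, 0.5)])
    def test_nsd(self, i, hx, hy, expected):
        assert nsd(i, hx, hy).value == pytest.approx(expected)

    def test_nsd_zero_entropy_rejected(self):
        with pytest.raises(ValueError, match="entropy"):
            nsd(0.5, 0.0, 1.0)

    @pytest.mark.parametrize("i,expected", [(2.0, 0.0), (0.5, 2.0)])
    def test_log_mi_values(self, i, expected):
        assert log_mi(i, 2.0, 2.0).value == pytest.approx(expected)

    def test_log_mi_infinite_at_nonpositive_mi(self):
        r = log_mi(0.0, 2.0, 2.0)
        assert math.isinf(r.value) and not r.finite


class TestLogDet:
    def test_identity_uniform_zero(self):
        j = JointFrequencyMatrix("ACGT", np.eye(4) * 0.25, 100)
        assert log_det(j).value == pytest.approx(0.0)

    def test_independent_uniform_infinite(self):
        j = JointFrequencyMatrix("ACGT", np.full((4, 4), 1 / 16), 100)
        assert math.isinf(log_det(j).value)

    def test_zero_marginal_rejected(self):
        f = np.zeros((4, 4))
        f[:3, :3] = np.eye(3) / 3
        with pytest.raises(ValueError, match="degenerate"):
            log_det(JointFrequencyMatrix("ACGT", f, 100))

    def test_k2p_simulation_matches_matrix_exponential_oracle(self):
        """Sampled log-det at t=0.2 agrees with the exact-probability value."""
        t = 0.2
        q = rate_matrix("K2P", kappa=2.0)
        exact = log_det(joint_from_pmat(expm(q * t))).value
        assert exact == pytest.approx(t, abs=1e-12)  # oracle: additivity of paralinear under K2P
        vals = []
        for rep in range(30):
            p = EvolutionParams(model="K2P", branch_length=t, seed=900 + rep)
            x, y = simulate_pair(10_000, p)
            vals.append(log_det(joint_frequencies(as_alignment(x, y))).value)
        se = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert abs(np.mean(vals) - exact) < 3 * se + 1e-4


class TestCountingDistances:
    def test_identical_zero(self):
        j = JointFrequencyMatrix("ACGT", np.eye(4) * 0.25, 100)
        assert p_distance(j).value == 0.0
        assert pc_p_distance(j).value == 0.0

    def test_half_sites_differ(self):
        f = np.eye(4) * 0.125
        f[0, 1] = f[1, 0] = f[2, 3] = f[3, 2] = 0.125
        j = JointFrequencyMatrix("ACGT", f, 100)
        assert p_distance(j).value == pytest.approx(0.5)
        assert pc_p_distance(j).value == pytest.approx(math.log(2))

    def test_p_equals_direct_column_count(self, rng):
        xs = "".join(rng.choice(list("ACGT"), 500))
        ys = "".join(rng.choice(list("ACGT"), 500))
        aln = as_alignment_pair(xs, ys)
        direct = sum(a != b for a, b in zip(xs, ys)) / 500
        assert p_distance(joint_frequencies(aln)).value == pytest.approx(direct)


def as_alignment_pair(xs, ys):
    from mitrans.align import PairwiseAlignment

    return PairwiseAlignment(xs, ys)


class TestKimura:
    def test_zero_fractions_zero_distance(self):
        from mitrans.distances import KimuraFractions

        assert kimura1(KimuraFractions(0.0, 0.0, 100)).value == 0.0

    def test_closed_form(self):
        from mitrans.distances import KimuraFractions

        expected = -0.5 * math.log(0.75 * math.sqrt(0.90))
        assert kimura1(KimuraFractions(0.1, 0.05, 100)).value == pytest.approx(expected)

    def test_domain_violation_gives_infinity_not_exception(self):
        from mitrans.distances import KimuraFractions

        r = kimura1(KimuraFractions(0.5, 0.3, 100))
        assert math.isinf(r.value) and not r.finite

    def test_k2p_simulation_recovers_branch_length(self):
        t, reps = 0.2, 50
        vals = []
        for rep in range(reps):
            p = EvolutionParams(model="K2P", branch_length=t, seed=3000 + rep)
            x, y = simulate_pair(10_000, p)
            vals.append(kimura1(kimura_fractions(joint_frequencies(as_alignment(x, y)))).value)
        se = np.std(vals, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(vals) - t) < 3 * se + 1e-4

    def test_kimura2_zero_when_independent(self):
        j = JointFrequencyMatrix("ACGT", np.full((4, 4), 1 / 16), 100)
        assert math.isinf(kimura2(j).value)  # coarse-grained MI = 0

    def test_kimura2_finite_and_positive_on_related_pair(self):
        q = rate_matrix("K2P", kappa=2.0)
        j = joint_from_pmat(expm(q * 0.2))
        v = kimura2(j).value
        assert 0 < v < math.inf


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        from mitrans.seqio import NucleotideSequence

        seqs = [NucleotideSequence(i, "ACGTACGTACGT") for i in "ab"]
        d, labels, notes = distance_matrix(seqs, "p")
        assert np.allclose(d, 0.0) and labels == ["a", "b"] and not notes

    def test_symmetric_zero_diagonal(self, rng):
        p = EvolutionParams(model="JC", branch_length=0.1, seed=11)
        seqs = simulate_chain(300, [0.1, 0.1, 0.1], p)
        d, _, _ = distance_matrix(seqs, "logdet")
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0.0)

    def test_length_filtered_pair_flagged_not_dropped(self):
        from mitrans.seqio import NucleotideSequence

        seqs = [
            NucleotideSequence("a", "ACGT" * 30),
            NucleotideSequence("b", "ACGT" * 10),
        ]
        d, _, notes = distance_matrix(seqs, "p")
        assert np.isnan(d[0, 1]) and notes[(0, 1)] == "length-filtered"


class TestMetricProperties:
    def test_nsd_triangle_inequality_on_substitution_triples(self):
        """Audit, not assert: count NSD triangle violations on Markov triples."""
        from mitrans.quartet import triangle_audit

        violations = 0
        for rep in range(40):
            p = EvolutionParams(model="JC", branch_length=0.25, seed=5000 + rep)
            seqs = simulate_chain(2000, [0.25, 0.25], p)
            d = np.zeros((3, 3))
            for i in range(3):
                for j in range(i + 1, 3):
                    aln = as_alignment(seqs[i], seqs[j])
                    jf = joint_frequencies(aln)
                    hx, hy = marginal_entropies(jf)
                    d[i, j] = d[j, i] = nsd(shannon_mi(jf).bits, hx, hy).value
            violations += len(triangle_audit(d))
        assert violations == 0  # none observed on substitution-only triples

    def test_nsd_and_ncd_saturate_at_one_not_infinity(self):
        p = EvolutionParams(model="JC", branch_length=8.0, seed=77)
        x, y = simulate_pair(8000, p)
        aln = as_alignment(x, y)
        jf = joint_frequencies(aln)
        hx, hy = marginal_entropies(jf)
        v = nsd(shannon_mi(jf).bits, hx, hy).value
        assert 0.95 < v <= 1.0 + 1e-9
        r = pair_distance(x, y, "ncd", aln=aln, estimator="align")
        assert 0.9 < r.value <= 1.1


class TestPhylipIO:
    def test_roundtrip(self, tmp_path, rng):
        d = rng.random((4, 4))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        labels = ["alpha", "beta", "gamma", "delta"]
        path = tmp_path / "m.phy"
        write_phylip(d, labels, path)
        d2, labels2 = read_phylip(path)
        assert labels2 == labels
        assert np.allclose(d, d2, atol=1e-6)
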