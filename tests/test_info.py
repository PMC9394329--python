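import itertools

import numpy as np
import pytest

from pyrpid import (TrivariateDistribution, canonical_gate, classical_measures,
                    local_mi, normalize_summary, random_distribution)


class TestGateMeasures:
    def test_independent_bits_carry_no_information(self):
        s = classical_measures(canonical_gate("indep"))
        assert s.h_y == pytest.approx(1.0, abs=1e-12)
        for f in ("jmi", "mi_b", "mi_a", "cmi_b", "cmi_a", "ii", "coi"):
            assert getattr(s, f) == pytest.approx(0.0, abs=1e-12)

    def test_xor_is_purely_conditional(self):
        s = classical_measures(canonical_gate("xor"))
        assert s.mi_b == pytest.approx(0.0, abs=1e-12)
        assert s.mi_a == pytest.approx(0.0, abs=1e-12)
        assert s.jmi == pytest.approx(1.0, abs=1e-12)
        assert s.cmi_b == pytest.approx(1.0, abs=1e-12)
        assert s.cmi_a == pytest.approx(1.0, abs=1e-12)
        assert s.ii == pytest.approx(1.0, abs=1e-12)
        assert s.coi == pytest.approx(-1.0, abs=1e-12)

    def test_redundant_gate_is_purely_marginal(self):
        s = classical_measures(canonical_gate("rdn"))
        assert s.mi_b == s.mi_a == pytest.approx(1.0, abs=1e-12)
        assert s.jmi == pytest.approx(1.0, abs=1e-12)
        assert s.cmi_b == pytest.approx(0.0, abs=1e-12)
        assert s.ii == pytest.approx(-1.0, abs=1e-12)


class TestIdentities:
    def test_chain_rule_and_interaction_identities(self, random_dists):
        for d in random_dists:
            s = classical_measures(d)
            assert s.jmi == pytest.approx(s.mi_b + s.cmi_a, abs=1e-10)
            assert s.jmi == pytest.approx(s.mi_a + s.cmi_b, abs=1e-10)
            assert s.ii == pytest.approx(s.jmi - s.mi_b - s.mi_a, abs=1e-12)
            assert s.coi == -s.ii
            assert min(s.h_y, s.jmi, s.mi_b, s.mi_a, s.cmi_b, s.cmi_a) >= -1e-12

    def test_measures_invariant_under_relabeling(self):
        d = random_distribution((3, 4, 2), seed=11)
        s = classical_measures(d)
        perm_y, perm_b, perm_a = (2, 0, 1), (3, 1, 0, 2), (1, 0)
        d2 = TrivariateDistribution(
            tuple(d.alphabet_y[i] for i in perm_y),
            tuple(d.alphabet_b[i] for i in perm_b),
            tuple(d.alphabet_a[i] for i in perm_a),
            d.pmf[np.ix_(perm_y, perm_b, perm_a)],
        )
        s2 = classical_measures(d2)
        for f in ("h_y", "jmi", "mi_b", "mi_a", "cmi_b", "cmi_a", "ii"):
            assert getattr(s2, f) == pytest.approx(getattr(s, f), abs=1e-12)


class TestLocalMI:
    def test_independent_pair_has_zero_local_mi_everywhere(self):
        p = np.outer([0.3, 0.7], [0.6, 0.4])
        for u, v in itertools.product(range(2), range(2)):
            assert local_mi(p, u, v) == pytest.approx(0.0, abs=1e-12)

    def test_xor_joint_realisations_each_carry_one_bit(self):
        # joint pmf of (y, (b,a)) for the xor gate
        p = np.zeros((2, 4))
        for i, (b, a) in enumerate(itertools.product(range(2), range(2))):
            p[b ^ a, i] = 0.25
        for i, (b, a) in enumerate(itertools.product(range(2), range(2))):
            assert local_mi(p, b ^ a, i) == pytest.approx(1.0, abs=1e-12)

    def test_direct_formula_example(self):
        # p(u) = 0.75, p(u|v) = 0.5  ->  log2(2/3)
        p = np.array([[0.5, 0.25], [0.0, 0.25]])
        assert local_mi(p, 0, 1) == pytest.approx(np.log2(2 / 3), abs=1e-12)

    def test_unsupported_realisation_rejected(self):
        p = np.array([[0.5, 0.5], [0.0, 0.0]])
        with pytest.raises(ValueError, match="zero probability"):
            local_mi(p, 1, 0)

    def test_average_local_mi_equals_mutual_information(self):
        d = random_distribution((3, 4, 2), seed=3)
        pyb = d.pmf.sum(axis=2)
        from pyrpid.info import mutual_information
        avg = sum(
            pyb[u, v] * local_mi(pyb, u, v)
            for u in range(3) for v in range(4) if pyb[u, v] > 0
        )
        assert avg == pytest.approx(mutual_information(pyb), abs=1e-10)


class TestNormalization:
    def test_normalized_complements_sum_to_one(self, random_dists):
        for d in random_dists:
            s = normalize_summary(classical_measures(d))
            assert s.normalized
            assert s.mi_b + s.cmi_a == pytest.approx(1.0, abs=1e-10)
            assert s.mi_a + s.cmi_b == pytest.approx(1.0, abs=1e-10)

    def test_percentage_complement(self):
        # a normalized basal MI of 61.2% forces a conditional apical MI of 38.8%
        d = random_distribution((3, 4, 4), seed=99)
        s = normalize_summary(classical_measures(d))
        assert 100 * s.cmi_a == pytest.approx(100 * (1 - s.mi_b), abs=1e-8)

    def test_zero_jmi_normalization_is_an_error(self, y_constant):
        with pytest.raises(ZeroDivisionError):
            normalize_summary(classical_measures(y_constant))
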