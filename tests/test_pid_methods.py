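"""Cross-method contracts: canonical values, consistency links, symmetries.

The AND-gate expectations are the published values of each measure's
original definition (recomputed by hand for the pointwise methods: the sx
redundancy follows from inclusion-exclusion over the union events, the pm
redundancy from the per-realisation minima of surprisals).
"""

import numpy as np
import pytest

from pyrpid import (METHODS, TrivariateDistribution, canonical_gate,
                    check_consistency, classical_measures, decompose,
                    normalize_pid, random_distribution, uia)
from pyrpid.pid import PIDResult, SolverInfo

ALL = sorted(METHODS)

#: published / hand-derived AND-gate decompositions (unq_b, unq_a, shd, syn)
AND_EXPECTED = {
    "broja": (0.0, 0.0, 0.311278, 0.5),
    "dep": (0.229574, 0.229574, 0.081704, 0.270426),
    "ccs": (0.207518, 0.207518, 0.103760, 0.292482),
    "pm": (-0.25, -0.25, 0.561278, 0.75),
    "sx": (0.188722, 0.188722, 0.122556, 0.311278),
}


class TestCanonicalGates:
    @pytest.mark.parametrize("method", ALL)
    def test_and_gate_reproduces_published_values(self, method, and_gate):
        r = decompose(and_gate, method)
        np.testing.assert_allclose(r.components, AND_EXPECTED[method], atol=2e-4)

    @pytest.mark.parametrize("method", ALL)
    def test_redundant_gate_is_pure_shared(self, method, rdn):
        r = decompose(rdn, method)
        np.testing.assert_allclose(r.components, (0, 0, 1, 0), atol=1e-6)

    @pytest.mark.parametrize("method", ["broja", "dep", "ccs"])
    def test_copy_gate_is_pure_unique(self, method, copy_b):
        r = decompose(copy_b, method)
        np.testing.assert_allclose(r.components, (1, 0, 0, 0), atol=1e-6)

    def test_copy_gate_pointwise_methods_hand_derived(self, copy_b):
        # pm: specificity minimum is always 1 bit, ambiguity minimum 0
        # (the informed input pins its value given y), so shd = 1 and the
        # remaining components follow from the consistency equations
        np.testing.assert_allclose(decompose(copy_b, "pm").components,
                                   (0.0, -1.0, 1.0, 1.0), atol=1e-9)
        # sx: every realisation contributes log2((2/3)/(1/2)) to the shared
        # term via its union event of probability 3/4
        shd = np.log2(4 / 3)
        np.testing.assert_allclose(decompose(copy_b, "sx").components,
                                   (1 - shd, -shd, shd, shd), atol=1e-9)

    @pytest.mark.parametrize("method", ALL)
    def test_xor_synergy_minus_shared_is_one_bit(self, method, xor):
        r = decompose(xor, method)
        assert r.syn - r.shd == pytest.approx(1.0, abs=1e-6)
        assert r.unq_b == pytest.approx(r.unq_a, abs=1e-6)

    @pytest.mark.parametrize("method", ALL)
    def test_independent_output_decomposes_to_zero(self, method):
        r = decompose(canonical_gate("indep"), method)
        np.testing.assert_allclose(r.components, 0.0, atol=1e-9)

    @pytest.mark.parametrize("method", ALL)
    def test_constant_output_decomposes_to_zero(self, method, y_constant):
        r = decompose(y_constant, method)
        np.testing.assert_allclose(r.components, 0.0, atol=1e-12)


class TestConsistencyLinks:
    @pytest.mark.parametrize("method", ALL)
    def test_defining_equations_on_random_systems(self, method, random_dists):
        for d in random_dists:
            s = classical_measures(d)
            r = decompose(d, method)
            report = check_consistency(r, s)
            assert report.ok, f"{method}: {report}"

    def test_uia_identical_across_methods(self, random_dists):
        for d in random_dists:
            values = [uia(decompose(d, m)) for m in ALL]
            assert max(values) - min(values) < 1e-6
            s = classical_measures(d)
            assert values[0] == pytest.approx(s.mi_b - s.mi_a, abs=1e-6)

    @pytest.mark.parametrize("method", ["broja", "dep"])
    def test_nonnegative_methods_stay_nonnegative(self, method, random_dists):
        for d in random_dists:
            r = decompose(d, method)
            assert min(r.components) >= -1e-8

    def test_perturbed_pid_is_flagged(self, and_gate):
        s = classical_measures(and_gate)
        r = decompose(and_gate, "broja")
        bad = PIDResult("broja", r.unq_b, r.unq_a, r.shd + 0.01, r.syn, r.jmi,
                        solver_info=SolverInfo())
        report = check_consistency(bad, s)
        assert set(report.flagged) == {"sum_residual", "mi_b_residual", "mi_a_residual"}
        assert report.mi_b_residual == pytest.approx(0.01, abs=1e-9)


class TestSymmetries:
    @pytest.mark.parametrize("method", ALL)
    def test_swapping_inputs_swaps_unique_components(self, method):
        d = random_distribution((3, 4, 2), seed=21)
        r = decompose(d, method)
        rs = decompose(d.swap_inputs(), method)
        assert rs.unq_b == pytest.approx(r.unq_a, abs=1e-6)
        assert rs.unq_a == pytest.approx(r.unq_b, abs=1e-6)
        assert rs.shd == pytest.approx(r.shd, abs=1e-6)
        assert rs.syn == pytest.approx(r.syn, abs=1e-6)

    @pytest.mark.parametrize("method", ALL)
    def test_relabeling_symbols_changes_nothing(self, method):
        d = random_distribution((3, 3, 3), seed=33)
        perm = (2, 0, 1)
        d2 = TrivariateDistribution(
            tuple(d.alphabet_y[i] for i in perm),
            tuple(d.alphabet_b[i] for i in perm),
            tuple(d.alphabet_a[i] for i in perm),
            d.pmf[np.ix_(perm, perm, perm)],
        )
        r, r2 = decompose(d, method), decompose(d2, method)
        np.testing.assert_allclose(r2.components, r.components, atol=1e-6)


class TestNormalization:
    def test_normalized_components_sum_to_one(self, random_dists):
        for d in random_dists[:10]:
            for m in ALL:
                r = normalize_pid(decompose(d, m))
                assert sum(r.components) == pytest.approx(1.0, abs=1e-6)
                assert r.normalized

    def test_components_are_not_clipped(self):
        # synthetic result with synergy above the joint mutual information
        r = PIDResult("pm", 0.1, -0.4, 0.8, 1.1, jmi=1.6)
        n = normalize_pid(r)
        assert n.syn > 0.65 and n.unq_a < 0
        assert sum(n.components) == pytest.approx(1.0, abs=1e-12)

    def test_zero_jmi_is_an_error(self, y_constant):
        with pytest.raises(ZeroDivisionError):
            normalize_pid(decompose(y_constant, "broja"))

    def test_unknown_method_rejected(self, xor):
        with pytest.raises(ValueError, match="unknown PID method"):
            decompose(xor, "imin")
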