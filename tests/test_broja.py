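"""The optimization PID against analytic values and an exhaustive oracle.

The oracle enumerates the marginal polytope of all-binary systems directly:
for fixed output value y the feasible set is a transportation polytope of
2x2 tables with one free parameter, so the whole polytope is a rectangle in
(t0, t1) and a fine grid plus one refinement pass bounds the optimum. The
oracle shares no code with the solver.
"""

import numpy as np
import pytest

from pyrpid import canonical_gate, classical_measures, pid_broja, random_distribution


def _jmi_bits(q):
    py = q.sum(axis=(1, 2))
    qba = q.sum(axis=0)
    total = 0.0
    for y in range(q.shape[0]):
        for b in range(q.shape[1]):
            for a in range(q.shape[2]):
                if q[y, b, a] > 0:
                    total += q[y, b, a] * np.log2(q[y, b, a] / (py[y] * qba[b, a]))
    return total


def grid_oracle_min_jmi(p, n=240):
    """Exhaustive fine-grid minimization of I_q(Y;B,A) for 2x2x2 systems."""
    assert p.shape == (2, 2, 2)
    tyb = p.sum(axis=2)
    tya = p.sum(axis=1)

    def bounds(y):
        r0, r1 = tyb[y]
        c0, _ = tya[y]
        return max(0.0, c0 - r1), min(r0, c0)

    def slice_of(y, t):
        r0, r1 = tyb[y]
        c0, c1 = tya[y]
        return np.array([[t, r0 - t], [c0 - t, r1 - (c0 - t)]])

    (lo0, hi0), (lo1, hi1) = bounds(0), bounds(1)

    def sweep(lo0_, hi0_, lo1_, hi1_, steps):
        t0s = np.linspace(lo0_, hi0_, steps) if hi0_ > lo0_ else np.array([lo0_])
        t1s = np.linspace(lo1_, hi1_, steps) if hi1_ > lo1_ else np.array([lo1_])
        best, arg = np.inf, (t0s[0], t1s[0])
        for t0 in t0s:
            for t1 in t1s:
                q = np.stack([slice_of(0, t0), slice_of(1, t1)])
                val = _jmi_bits(np.clip(q, 0, None))
                if val < best:
                    best, arg = val, (t0, t1)
        return best, arg

    best, (t0, t1) = sweep(lo0, hi0, lo1, hi1, n)
    # one refinement pass around the incumbent
    w0 = (hi0 - lo0) / n if hi0 > lo0 else 0.0
    w1 = (hi1 - lo1) / n if hi1 > lo1 else 0.0
    best2, _ = sweep(max(lo0, t0 - 2 * w0), min(hi0, t0 + 2 * w0),
                     max(lo1, t1 - 2 * w1), min(hi1, t1 + 2 * w1), 60)
    return min(best, best2)


class TestForcedGateValues:
    """Where marginal constraints plus nonnegativity force the decomposition."""

    @pytest.mark.parametrize("gate,expected", [
        ("xor", (0.0, 0.0, 0.0, 1.0)),
        ("copy_b", (1.0, 0.0, 0.0, 0.0)),
        ("rdn", (0.0, 0.0, 1.0, 0.0)),
    ])
    def test_gate(self, gate, expected):
        r = pid_broja(canonical_gate(gate))
        np.testing.assert_allclose(r.components, expected, atol=1e-6)
        assert r.solver_info.converged

    def test_constant_output_decomposes_to_zero(self, y_constant):
        r = pid_broja(y_constant)
        np.testing.assert_allclose(r.components, 0.0, atol=1e-12)


class TestAgainstOracle:
    def test_and_gate_matches_analytic_optimum(self, and_gate):
        # the minimum equals I(Y;B): shared 0.3113, synergy 0.5
        r = pid_broja(and_gate)
        s = classical_measures(and_gate)
        assert r.syn == pytest.approx(s.jmi - s.mi_b, abs=1e-6)
        assert r.shd == pytest.approx(s.mi_b, abs=1e-6)
        assert r.unq_b == pytest.approx(0.0, abs=1e-6)
        assert r.unq_a == pytest.approx(0.0, abs=1e-6)

    def test_and_gate_matches_grid_oracle(self, and_gate):
        r = pid_broja(and_gate)
        s = classical_measures(and_gate)
        oracle_syn = s.jmi - grid_oracle_min_jmi(and_gate.pmf)
        assert r.syn == pytest.approx(oracle_syn, abs=1e-3)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_binary_systems_match_grid_oracle(self, seed):
        d = random_distribution((2, 2, 2), seed=seed)
        r = pid_broja(d)
        s = classical_measures(d)
        oracle = grid_oracle_min_jmi(d.pmf)
        assert s.jmi - r.syn == pytest.approx(oracle, abs=1e-3)


class TestSolverContract:
    def test_solver_info_reports_gap(self):
        r = pid_broja(random_distribution((3, 3, 3), seed=0), tol=1e-9)
        assert r.solver_info.iterations > 0
        assert r.solver_info.residual < 1e-8
        assert r.solver_info.converged

    def test_nonnegative_components_on_random_systems(self, random_dists):
        for d in random_dists[:12]:
            r = pid_broja(d)
            assert min(r.components) >= -1e-8
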