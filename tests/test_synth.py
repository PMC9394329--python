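import numpy as np
import pytest

from pyrpid import (GridGenParams, NeuronGenParams, canonical_gate,
                    classical_measures, decompose, discretize_trials,
                    gen_ap_grid, gen_paired_trials, random_distribution)


class TestCanonicalGates:
    def test_xor_support(self, xor):
        assert xor.support_size == 4
        assert set(xor.as_dict().values()) == {0.25}

    def test_rdn_support(self, rdn):
        assert rdn.support_size == 2
        assert set(rdn.as_dict().values()) == {0.5}

    def test_and_interaction_information_matches_direct_evaluation(self, and_gate):
        s = classical_measures(and_gate)
        # direct: jmi = H(Y) (deterministic gate), mi_b = mi_a analytic
        h = -(0.25 * np.log2(0.25) + 0.75 * np.log2(0.75))
        mi = h - 0.5  # H(Y) - H(Y|B)
        assert s.ii == pytest.approx(h - 2 * mi, abs=1e-12)

    def test_unknown_gate_rejected(self):
        with pytest.raises(ValueError, match="unknown gate"):
            canonical_gate("nand")


class TestRandomDistribution:
    def test_same_seed_reproduces_identical_pmf(self):
        a = random_distribution((3, 4, 4), seed=7)
        b = random_distribution((3, 4, 4), seed=7)
        np.testing.assert_array_equal(a.pmf, b.pmf)
        assert a.support_size == 48

    def test_high_concentration_approaches_uniform(self):
        deviations = []
        for conc in (1.0, 1000.0):
            devs = [
                np.abs(random_distribution((2, 2, 2), conc, seed=s).pmf - 0.125).max()
                for s in range(40)
            ]
            deviations.append(np.mean(devs))
        assert deviations[1] < deviations[0] / 5

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            random_distribution((0, 2, 2))
        with pytest.raises(ValueError):
            random_distribution((2, 2, 2), concentration=0.0)


class TestPairedTrialGenerator:
    def test_amplitude_grids_matched_across_conditions(self):
        trials = gen_paired_trials(NeuronGenParams(n_units=2, seed=3))
        for unit in {t.unit_id for t in trials}:
            combos = {}
            for t in trials:
                if t.unit_id == unit:
                    combos.setdefault(t.condition, set()).add((t.basal_amp, t.apical_amp))
            assert combos["control"] == combos["treated"]

    def test_deterministic_given_seed(self):
        p = NeuronGenParams(n_units=1, seed=11)
        t1, t2 = gen_paired_trials(p), gen_paired_trials(p)
        assert len(t1) == len(t2)
        np.testing.assert_array_equal(t1[5].ap_times, t2[5].ap_times)
        np.testing.assert_array_equal(t1[5].basal_trace, t2[5].basal_trace)

    def test_zero_apical_gain_removes_apical_information(self):
        params = NeuronGenParams(n_units=1, apical_gain=0.0, seed=2,
                                 windows_per_trial=60)
        trials = [t for t in gen_paired_trials(params) if t.condition == "control"]
        dist = discretize_trials(trials)
        r = decompose(dist, "broja")
        assert abs(r.unq_a) < 0.05
        assert abs(r.syn) < 0.05

    def test_stronger_inhibition_widens_synergy_difference(self):
        # parameter recovery: the median within-unit synergy drop grows as
        # the inhibition factor departs from 1 (no inhibition)
        from pyrpid import build_paired_study, paired_differences
        meds = []
        for inhibition in (1.0, 0.3):
            params = NeuronGenParams(n_units=6, inhibition_factor=inhibition,
                                     seed=5, windows_per_trial=50)
            study = build_paired_study(gen_paired_trials(params), methods=("broja",))
            _, summary = paired_differences(study, "broja")
            meds.append(summary.loc["syn", "median"])
        assert abs(meds[0]) < abs(meds[1])

    def test_invalid_inhibition_rejected(self):
        with pytest.raises(ValueError):
            NeuronGenParams(inhibition_factor=1.5)


class TestGridGenerator:
    def test_structural_constraints(self):
        params = GridGenParams()
        grid = gen_ap_grid(params)
        # apical input alone never fires
        assert all(grid.count(0, a) == 0 for a in params.apical_levels)
        assert all(grid.count(params.basal_floor, a) == 0 for a in params.apical_levels)
        # basal-alone column: zero below the threshold, positive at and above
        for b in params.basal_levels:
            if b < params.basal_threshold_alone:
                assert grid.count(b, 0) == 0
            else:
                assert grid.count(b, 0) >= 1
        # counts graded and capped
        col = [grid.count(b, 0) for b in params.basal_levels]
        assert col == sorted(col)
        assert max(c for c in grid.counts.values()) <= params.max_ap

    def test_full_observation(self):
        grid = gen_ap_grid(GridGenParams())
        assert len(grid.observed) == 31 * 21

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            GridGenParams(basal_floor=200, basal_threshold_alone=100)
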