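"""Synthetic generators emulating the two study designs.

Two data sources are emulated so that every pipeline stage is testable
without external recordings:

* paired-condition trials from a two-compartment neuron model: graded basal
  (somatic) drive, saturating apical amplification that multiplies the
  basal response, and a treated condition in which an inhibition factor
  scales down the apical gain — the statistical signature of dendritic
  GABA-B inhibition;
* a deterministic action-potential count surface over a grid of basal and
  apical input counts, in which basal-alone input fires only above a
  threshold, apical-alone input never fires, and strong apical input
  lowers the basal threshold (apical amplification).

These are statistical emulations of the study designs, not biophysical
models; see docs/methods.md for what they do and do not reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import TrivariateDistribution
from .pipeline import APGrid, TrialRecord

__all__ = [
    "canonical_gate", "random_distribution",
    "NeuronGenParams", "gen_paired_trials",
    "GridGenParams", "gen_ap_grid",
]


# ---------------------------------------------------------------------------
# fixture distributions

_GATES = {}


def _gate(name):
    def deco(fn):
        _GATES[name] = fn
        return fn
    return deco


@_gate("xor")
def _xor():
    return {(b ^ a, b, a): 0.25 for b in (0, 1) for a in (0, 1)}


@_gate("and")
def _and():
    return {(b & a, b, a): 0.25 for b in (0, 1) for a in (0, 1)}


@_gate("or")
def _or():
    return {(b | a, b, a): 0.25 for b in (0, 1) for a in (0, 1)}


@_gate("copy_b")
def _copy_b():
    # Y = B with an independent, uninformative A
    return {(b, b, a): 0.25 for b in (0, 1) for a in (0, 1)}


_GATES["unq_b"] = _GATES["copy_b"]


@_gate("rdn")
def _rdn():
    # Y = B = A: fully redundant fair bit
    return {(v, v, v): 0.5 for v in (0, 1)}


@_gate("indep")
def _indep():
    return {(y, b, a): 0.125 for y in (0, 1) for b in (0, 1) for a in (0, 1)}


def canonical_gate(name: str) -> TrivariateDistribution:
    """Uniform-input logic-gate distributions used as PID test fixtures.

    Known names: ``xor, and, or, copy_b, unq_b, rdn, indep``.
    """
    try:
        cells = _GATES[name]()
    except KeyError:
        raise ValueError(f"unknown gate {name!r}; choose from {sorted(_GATES)}")
    ay = (0, 1)
    return TrivariateDistribution.from_dict(
        cells, alphabet_y=ay, alphabet_b=(0, 1), alphabet_a=(0, 1)
    )


def random_distribution(
    shape: tuple[int, int, int],
    concentration: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> TrivariateDistribution:
    """Dirichlet-distributed random joint pmf of the given (|Y|,|B|,|A|) shape."""
    if any(n < 1 for n in shape) or len(shape) != 3:
        raise ValueError("shape must be three positive sizes")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(np.prod(shape))
    pmf = rng.dirichlet(np.full(n, concentration)).reshape(shape)
    return TrivariateDistribution(
        tuple(range(shape[0])), tuple(range(shape[1])), tuple(range(shape[2])), pmf
    )


# ---------------------------------------------------------------------------
# paired-condition trial generator

@dataclass(frozen=True)
class NeuronGenParams:
    """Parameters of the paired-condition trial generator.

    The response drive in each analysis window is

        r = basal_weight * b + g_eff * f(a) * b + noise,

    with f a saturating (sigmoid) apical transfer — so apical input alone
    cannot fire the cell — and g_eff = apical_gain under control,
    apical_gain * inhibition_factor under treatment. Window AP counts are
    the thresholded, discretized drive.
    """

    n_units: int = 15
    amp_levels: tuple[float, ...] = (0.0, 250.0, 500.0, 750.0, 1000.0, 1250.0, 1500.0)
    windows_per_trial: int = 40
    window_ms: float = 120.0
    dt_ms: float = 4.0
    basal_weight: float = 1.0
    apical_gain: float = 1.0
    inhibition_factor: float = 0.3
    noise_sd: float = 0.35
    firing_threshold: float = 0.55
    max_ap: int = 4
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.inhibition_factor <= 1.0:
            raise ValueError("inhibition_factor must lie in [0, 1]")
        if any(a < 0 for a in self.amp_levels):
            raise ValueError("amplitudes must be nonnegative")


def _apical_transfer(a_norm: np.ndarray) -> np.ndarray:
    """Saturating apical efficacy in [0, 1); zero at zero input."""
    return 2.0 / (1.0 + np.exp(-4.0 * a_norm)) - 1.0


def gen_paired_trials(params: NeuronGenParams) -> list[TrialRecord]:
    """Generate matched control/treated trials for every unit.

    Per unit, every (basal amplitude, apical amplitude) combination on the
    grid is presented once under each condition, guaranteeing matched input
    distributions by construction. Traces are per-window modulated current
    levels (mimicking a fluctuating in-vivo-like waveform) sampled at
    ``dt_ms``; AP times place each window's spikes evenly inside it.
    """
    rng = np.random.default_rng(params.seed)
    amax = max(params.amp_levels) or 1.0
    n_w = params.windows_per_trial
    samples_per_window = int(round(params.window_ms / params.dt_ms))
    trials: list[TrialRecord] = []
    for unit in range(params.n_units):
        unit_gain = params.apical_gain * rng.uniform(0.8, 1.2)
        unit_bw = params.basal_weight * rng.uniform(0.8, 1.2)
        for b_amp in params.amp_levels:
            for a_amp in params.amp_levels:
                # shared within-trial waveform modulation across conditions
                mod = rng.uniform(0.25, 1.0, size=n_w)
                mod_a = rng.uniform(0.25, 1.0, size=n_w)
                for condition in ("control", "treated"):
                    g_eff = unit_gain * (
                        1.0 if condition == "control" else params.inhibition_factor
                    )
                    b_sig = (b_amp / amax) * mod
                    a_sig = (a_amp / amax) * mod_a
                    drive = (
                        unit_bw * b_sig
                        + g_eff * _apical_transfer(a_sig) * b_sig
                        + rng.normal(0.0, params.noise_sd, size=n_w)
                    )
                    counts = np.clip(
                        np.floor((drive - params.firing_threshold) / 0.4) + 1,
                        0, params.max_ap,
                    ).astype(int)
                    counts[drive < params.firing_threshold] = 0
                    ap_times = []
                    for w, c in enumerate(counts):
                        t0 = w * params.window_ms
                        for k in range(c):
                            ap_times.append(t0 + (k + 1) * params.window_ms / (c + 1))
                    basal_trace = np.repeat(b_sig * amax, samples_per_window)
                    apical_trace = np.repeat(a_sig * amax, samples_per_window)
                    trials.append(TrialRecord(
                        unit_id=f"unit{unit:02d}",
                        condition=condition,
                        basal_amp=float(b_amp),
                        apical_amp=float(a_amp),
                        basal_trace=basal_trace,
                        apical_trace=apical_trace,
                        ap_times=np.array(ap_times),
                        dt_ms=params.dt_ms,
                    ))
    return trials


# ---------------------------------------------------------------------------
# AP-count grid generator

@dataclass(frozen=True)
class GridGenParams:
    """Parameters of the deterministic AP-count surface.

    The surface is built from two graded drives,

        beta(b)  = max(b - (basal_threshold_alone - basal_step), 0) / basal_step
        alpha(a) = min(max(a - (apical_threshold - apical_step), 0) / apical_step, 1)
        weak(b)  = weak_slope * max(b - basal_floor, 0) / 100

    with the apical and weak-basal drives gated off at or below
    ``basal_floor`` basal inputs (apical input alone can never fire the
    cell), and the weak-basal amplification active only in the presence of
    apical input. The AP count is floor(beta + gated (alpha + weak)) capped
    at ``max_ap``. Consequences, mirroring the qualitative structure of the
    compartmental-model data: basal input alone first fires at
    ``basal_threshold_alone``; weak-but-gating basal input fires from
    ``apical_threshold`` apical inputs upward; nothing fires at
    ``basal_floor`` or fewer basal inputs; counts are graded in basal.

    Scanning nested input ranges of this surface produces a sign change of
    the unique information asymmetry at the basal range ending one grid
    spacing below ``basal_threshold_alone`` (exposed as
    :attr:`uia_switch_level`): below it the output is informed mostly by
    whether the apical input clears its threshold, above it by the graded
    basal drive.
    """

    basal_levels: tuple[int, ...] = tuple(range(0, 310, 10))
    apical_levels: tuple[int, ...] = tuple(range(0, 210, 10))
    basal_floor: int = 20
    basal_threshold_alone: int = 160
    basal_step: int = 50
    apical_threshold: int = 110
    apical_step: int = 50
    weak_slope: float = 0.5
    max_ap: int = 4

    def __post_init__(self):
        if self.basal_floor >= self.basal_threshold_alone:
            raise ValueError("basal_floor must be below basal_threshold_alone")
        if self.basal_step <= 0 or self.apical_step <= 0:
            raise ValueError("gradation steps must be positive")

    @property
    def spacing(self) -> int:
        return self.basal_levels[1] - self.basal_levels[0]

    @property
    def uia_switch_level(self) -> int:
        """Constructed basal level at which the UIA changes sign."""
        return self.basal_threshold_alone - self.spacing


def gen_ap_grid(params: GridGenParams = GridGenParams()) -> APGrid:
    """Deterministic AP-count surface with apical amplification.

    The structural constraints — no apical-alone firing, zero output below
    the basal floor regardless of apical input, basal-alone firing only at
    or above ``basal_threshold_alone``, counts graded in basal — hold for
    every valid parameter set.
    """
    counts: dict[tuple[int, int], int] = {}
    for b in params.basal_levels:
        for a in params.apical_levels:
            beta = max(b - (params.basal_threshold_alone - params.basal_step), 0) / params.basal_step
            alpha = min(max(a - (params.apical_threshold - params.apical_step), 0) / params.apical_step, 1.0)
            weak = params.weak_slope * max(b - params.basal_floor, 0) / 100.0 if a > 0 else 0.0
            drive = beta + ((alpha + weak) if b > params.basal_floor else 0.0)
            counts[(b, a)] = int(min(int(drive), params.max_ap))
    return APGrid(
        basal_levels=tuple(params.basal_levels),
        apical_levels=tuple(params.apical_levels),
        counts=counts,
    )
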