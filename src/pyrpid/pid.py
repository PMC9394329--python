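"""The five partial information decompositions and their consistency links.

Each method splits the joint mutual information I(Y;B,A) into four
components,

    I(Y;B,A) = UnqB + UnqA + Shd + Syn,

tied to the classical measures by

    I(Y;B)   = UnqB + Shd          I(Y;B|A) = UnqB + Syn
    I(Y;A)   = UnqA + Shd          I(Y;A|B) = UnqA + Syn,

from which Syn - Shd = II(Y;B;A) and UnqB - UnqA = I(Y;B) - I(Y;A) (the
unique information asymmetry, identical for every method). Every estimator
here computes one defining quantity and assembles the remaining components
through these equations, so the consistency identities hold to rounding.

Methods
-------
``broja``
    Optimization PID: Syn = I_p(Y;B,A) - min I_q(Y;B,A) over joint pmfs q
    preserving the (Y,B) and (Y,A) marginals. Components nonnegative.
``dep``
    Dependency-constraint lattice: UnqB is the least increase in I(Y;B)
    over lattice edges that add the B-Y dependency to a maximum-entropy
    model. The binding candidates reduce to I(Y;B), I_ci(Y;B|A) with
    ci = p(y)p(b|y)p(a|y), and I_m(Y;B|A) with m the full pairwise maxent.
    Components nonnegative.
``ccs``
    Pointwise common change in surprisal: redundancy sums the local
    co-information over realisations where the local surprisal changes from
    B, from A, and their overlap all share one sign, evaluated on the
    pairwise maximum-entropy distribution. Components may be negative
    (misinformation).
``pm``
    Specificity/ambiguity pointwise decomposition: local mutual information
    i(y;s) = h(s) - h(s|y) is split into an informative part h(s) and a
    misinformative part h(s|y); shared components are per-realisation
    minima over the two inputs on each lattice. Components may be negative
    and synergy can exceed the joint mutual information.
``sx``
    Shared-exclusion pointwise PID: redundancy is the average local
    information the union event {B=b} OR {A=a} carries about y. Components
    may be negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ._kernels import broja_minimize
from .distributions import TrivariateDistribution
from .info import InfoSummary, classical_measures
from .maxent import ipf_pairwise_maxent, maxent_inputs_indep_given_y

__all__ = [
    "PIDResult", "SolverInfo", "ConsistencyReport", "PIDConvergenceError",
    "pid_broja", "pid_dep", "pid_ccs", "pid_pm", "pid_sx",
    "decompose", "METHODS", "check_consistency", "uia", "normalize_pid",
]

#: residual above which a consistency check is flagged
CONSISTENCY_TOL = 1e-6


class PIDConvergenceError(RuntimeError):
    """Solver failed to reach the requested tolerance; carries diagnostics."""

    def __init__(self, message: str, result: "PIDResult | None" = None):
        super().__init__(message)
        self.result = result


@dataclass(frozen=True)
class SolverInfo:
    iterations: int = 0
    residual: float = 0.0       #: objective-gap or marginal residual estimate
    converged: bool = True
    warning: str | None = None


@dataclass(frozen=True)
class PIDResult:
    """Four PID components of one method on one distribution (bits)."""

    method: str
    unq_b: float
    unq_a: float
    shd: float
    syn: float
    jmi: float
    normalized: bool = False
    solver_info: SolverInfo = field(default_factory=SolverInfo, repr=False)

    @property
    def components(self) -> tuple[float, float, float, float]:
        return (self.unq_b, self.unq_a, self.shd, self.syn)


def _assemble(method: str, s: InfoSummary, unq_b: float,
              info: SolverInfo = SolverInfo()) -> PIDResult:
    """Build a full PID from UnqB and the classical measures.

    Using the defining equations guarantees the consistency identities; the
    single method-specific number is UnqB (equivalently Shd or Syn).
    """
    return PIDResult(
        method=method,
        unq_b=unq_b,
        unq_a=unq_b - (s.mi_b - s.mi_a),
        shd=s.mi_b - unq_b,
        syn=s.cmi_b - unq_b,
        jmi=s.jmi,
        solver_info=info,
    )


# ---------------------------------------------------------------------------
# broja

#: estimated objective gaps up to this are accepted with a warning when the
#: iteration cap is reached (sublinear boundary-optimum instances)
BROJA_ACCEPT_GAP = 1e-5


def pid_broja(dist: TrivariateDistribution, tol: float = 1e-9,
              max_iter: int = 100_000) -> PIDResult:
    """Optimization PID of Bertschinger et al. / Griffith & Koch.

    Solves min I_q(Y;B,A) over the marginal polytope (alternating
    I-projections, see :mod:`pyrpid._kernels`); synergy is the observed
    joint mutual information in excess of the minimum. The reported
    objective is always attained at a feasible point, so the estimated
    synergy can only err low and the components stay nonnegative.
    """
    s = classical_measures(dist)
    if s.jmi <= 1e-14:
        return _assemble("broja", s, 0.0)
    p = dist.pmf
    q, obj, iters, gap, converged = broja_minimize(
        p.sum(axis=2), p.sum(axis=1), tol=tol, max_iter=max_iter
    )
    info = SolverInfo(
        iterations=iters, residual=gap, converged=converged,
        warning=None if converged else
        f"objective gap {gap:.2e} above tol (boundary optimum)",
    )
    syn = s.jmi - obj
    result = _assemble("broja", s, s.cmi_b - syn, info)
    if not converged and gap > BROJA_ACCEPT_GAP:
        raise PIDConvergenceError(
            f"broja solver gap {gap:.3e} > tol {tol:g} after {iters} iterations",
            result,
        )
    return result


# ---------------------------------------------------------------------------
# dep

def _jmi_of(q: np.ndarray) -> float:
    """I(Y;B,A) of an array pmf (support-restricted)."""
    py = q.sum(axis=(1, 2))
    qba = q.sum(axis=0)
    denom = py[:, None, None] * qba[None, :, :]
    mask = q > 0
    return float((q[mask] * np.log2(q[mask] / denom[mask])).sum())


def pid_dep(dist: TrivariateDistribution, tol: float = 1e-10) -> PIDResult:
    """Dependency-constraint PID of James, Emenheiser & Crutchfield.

    UnqB is the least change in I(Y;B) over constraint-lattice edges that
    add the B-Y marginal; candidate values for B and for A differ pairwise
    by exactly I(Y;B)-I(Y;A), so the decomposition is consistent whichever
    edge attains the minimum. The conditional-MI forms keep every candidate
    nonnegative under finite IPF error. The two uniques are computed
    independently and then symmetrized through the consistency identity.
    """
    s = classical_measures(dist)
    if s.jmi <= 1e-14:
        return _assemble("dep", s, 0.0)
    p = dist.pmf
    ci = maxent_inputs_indep_given_y(p)
    jmi_ci = _jmi_of(ci)
    fit = ipf_pairwise_maxent(p, tol=tol)
    jmi_m = _jmi_of(fit.pmf)
    # ci and m preserve both pairwise output marginals, so each candidate is
    # a conditional mutual information and nonnegative in exact arithmetic;
    # clipping removes residual IPF noise only
    unq_b = max(0.0, min(s.mi_b, jmi_ci - s.mi_a, jmi_m - s.mi_a))
    unq_a = max(0.0, min(s.mi_a, jmi_ci - s.mi_b, jmi_m - s.mi_b))
    # the candidate pairs differ by a constant; averaging removes IPF noise
    unq_b_sym = 0.5 * (unq_b + unq_a + (s.mi_b - s.mi_a))
    info = SolverInfo(
        iterations=fit.sweeps, residual=fit.residual, converged=fit.converged,
        warning=None if fit.converged else
        f"IPF residual {fit.residual:.2e} above 1e-10 (boundary-support maxent)",
    )
    return _assemble("dep", s, unq_b_sym, info)


# ---------------------------------------------------------------------------
# ccs

def pid_ccs(dist: TrivariateDistribution, tol: float = 1e-10) -> PIDResult:
    """Pointwise common-change-in-surprisal PID of Ince.

    Redundancy is evaluated on the maximum-entropy distribution preserving
    the three pairwise marginals; a realisation contributes its local
    co-information when the local informations from B, from A and the
    co-information itself agree in sign.
    """
    s = classical_measures(dist)
    if s.jmi <= 1e-14:
        return _assemble("ccs", s, 0.0)
    fit = ipf_pairwise_maxent(dist.pmf, tol=tol)
    m = fit.pmf
    py = m.sum(axis=(1, 2))
    pyb = m.sum(axis=2)
    pya = m.sum(axis=1)
    pba = m.sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        i_b = np.log2(pyb / (py[:, None] * pyb.sum(axis=0)[None, :]))[:, :, None]
        i_a = np.log2(pya / (py[:, None] * pya.sum(axis=0)[None, :]))[:, None, :]
        i_ba = np.log2(m / (py[:, None, None] * pba[None, :, :]))
        coi_local = i_b + i_a - i_ba
    supported = m > 0
    agree = (
        supported
        & (np.sign(i_b) == np.sign(i_a))
        & (np.sign(i_b) == np.sign(coi_local))
    )
    shd = float((m * coi_local)[agree & (coi_local != 0)].sum())
    info = SolverInfo(
        iterations=fit.sweeps, residual=fit.residual, converged=fit.converged,
        warning=None if fit.converged else
        f"IPF residual {fit.residual:.2e} above 1e-10 (boundary-support maxent)",
    )
    return _assemble("ccs", s, s.mi_b - shd, info)


# ---------------------------------------------------------------------------
# pm

def pid_pm(dist: TrivariateDistribution) -> PIDResult:
    """Specificity/ambiguity pointwise PID of Finn & Lizier.

    Shared information averages, over the observed joint distribution, the
    difference between the per-realisation minimum specificity
    min(h(b), h(a)) and minimum ambiguity min(h(b|y), h(a|y)).
    """
    s = classical_measures(dist)
    if s.jmi <= 1e-14:
        return _assemble("pm", s, 0.0)
    p = dist.pmf
    py = p.sum(axis=(1, 2))
    pb = p.sum(axis=(0, 2))
    pa = p.sum(axis=(0, 1))
    pyb = p.sum(axis=2)
    pya = p.sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        h_b = -np.log2(pb)[None, :, None]
        h_a = -np.log2(pa)[None, None, :]
        h_b_y = -np.log2(pyb / py[:, None])[:, :, None]
        h_a_y = -np.log2(pya / py[:, None])[:, None, :]
    with np.errstate(invalid="ignore"):
        r_plus = np.minimum(np.broadcast_to(h_b, p.shape), np.broadcast_to(h_a, p.shape))
        r_minus = np.minimum(h_b_y, h_a_y)
        local = p * (r_plus - r_minus)
    mask = p > 0
    shd = float(local[mask].sum())
    return _assemble("pm", s, s.mi_b - shd)


# ---------------------------------------------------------------------------
# sx

def pid_sx(dist: TrivariateDistribution) -> PIDResult:
    """Shared-exclusion pointwise PID of Makkeh, Gutknecht & Wibral.

    The local shared term of a realisation (y, b, a) is
    log2 p(y | {B=b} OR {A=a}) / p(y): the information carried by the event
    that at least one input takes its realized value (equivalently, by the
    probability mass both realisations jointly exclude).
    """
    s = classical_measures(dist)
    if s.jmi <= 1e-14:
        return _assemble("sx", s, 0.0)
    p = dist.pmf
    py = p.sum(axis=(1, 2))
    pb = p.sum(axis=(0, 2))
    pa = p.sum(axis=(0, 1))
    pyb = p.sum(axis=2)
    pya = p.sum(axis=1)
    # P(y, {B=b} or {A=a}) and P({B=b} or {A=a}) by inclusion-exclusion
    p_y_union = pyb[:, :, None] + pya[:, None, :] - p
    p_union = pb[None, :, None] + pa[None, None, :] - p.sum(axis=0)[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        i_sx = np.log2(p_y_union / (py[:, None, None] * p_union))
        local = p * i_sx
    mask = p > 0
    shd = float(local[mask].sum())
    return _assemble("sx", s, s.mi_b - shd)


# ---------------------------------------------------------------------------
# dispatch and derived operations

METHODS: dict[str, Callable[[TrivariateDistribution], PIDResult]] = {
    "broja": pid_broja,
    "dep": pid_dep,
    "ccs": pid_ccs,
    "pm": pid_pm,
    "sx": pid_sx,
}


def decompose(dist: TrivariateDistribution, method: str, **kwargs) -> PIDResult:
    """Run one PID method by name (one of ``broja, dep, ccs, pm, sx``)."""
    try:
        fn = METHODS[method]
    except KeyError:
        raise ValueError(f"unknown PID method {method!r}; choose from {sorted(METHODS)}")
    return fn(dist, **kwargs)


@dataclass(frozen=True)
class ConsistencyReport:
    """Residuals of the five defining equations for one PID."""

    sum_residual: float     #: UnqB+UnqA+Shd+Syn - I(Y;B,A)
    mi_b_residual: float    #: UnqB+Shd - I(Y;B)
    mi_a_residual: float    #: UnqA+Shd - I(Y;A)
    cmi_b_residual: float   #: UnqB+Syn - I(Y;B|A)
    cmi_a_residual: float   #: UnqA+Syn - I(Y;A|B)
    flagged: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.flagged


def check_consistency(pid: PIDResult, s: InfoSummary,
                      tol: float = CONSISTENCY_TOL) -> ConsistencyReport:
    """Residuals of the PID/classical-measure identities, flagging any > tol."""
    residuals = {
        "sum_residual": pid.unq_b + pid.unq_a + pid.shd + pid.syn - s.jmi,
        "mi_b_residual": pid.unq_b + pid.shd - s.mi_b,
        "mi_a_residual": pid.unq_a + pid.shd - s.mi_a,
        "cmi_b_residual": pid.unq_b + pid.syn - s.cmi_b,
        "cmi_a_residual": pid.unq_a + pid.syn - s.cmi_a,
    }
    flagged = tuple(k for k, v in residuals.items() if abs(v) > tol)
    return ConsistencyReport(flagged=flagged, **residuals)


def uia(pid: PIDResult) -> float:
    """Unique information asymmetry UnqB - UnqA (= I(Y;B) - I(Y;A))."""
    return pid.unq_b - pid.unq_a


def normalize_pid(pid: PIDResult) -> PIDResult:
    """Divide the components by the joint mutual information (sum becomes 1).

    No clipping: normalized components outside [0, 1] are preserved (the
    pointwise methods produce them).
    """
    if pid.normalized:
        return pid
    if pid.jmi <= 0:
        raise ZeroDivisionError("cannot normalize a PID with zero joint mutual information")
    j = pid.jmi
    return PIDResult(
        method=pid.method,
        unq_b=pid.unq_b / j, unq_a=pid.unq_a / j,
        shd=pid.shd / j, syn=pid.syn / j,
        jmi=j, normalized=True, solver_info=pid.solver_info,
    )
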