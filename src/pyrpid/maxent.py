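"""Maximum-entropy distributions under marginal constraints.

Two kinds are needed by the PID estimators:

* closed-form conditional-independence models (e.g. the maxent subject to
  the (Y,B) and (Y,A) marginals is p(y) p(b|y) p(a|y)), and
* the maxent subject to all three pairwise marginals, fitted by iterative
  proportional fitting (IPF).

IPF converges linearly when the maxent has full support. When the target
lies on the simplex boundary (common for deterministic logic gates and for
the uniform-over-observed-cells grid distributions used here), convergence
is sublinear (residual ~ 1/sweeps) and machine-precision marginal matching
is unreachable; the fit is then accepted with a warning flag provided the
residual is small (see :data:`IPF_ACCEPT_RESIDUAL`; the induced error on
any information measure is of the residual's order, far below the 0.1%
reporting precision).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import ipf_sweeps

__all__ = ["IPFResult", "ipf_pairwise_maxent", "maxent_inputs_indep_given_y",
           "maxent_y_indep_given_b", "maxent_y_indep_given_a", "IPFError"]

#: IPF is converged below this max marginal discrepancy
IPF_TOL = 1e-10
#: after the sweep cap, residuals up to this are accepted with a warning
IPF_ACCEPT_RESIDUAL = 1e-4
IPF_MAX_SWEEPS = 50_000


class IPFError(RuntimeError):
    """Iterative proportional fitting failed to reach an acceptable residual."""


@dataclass(frozen=True)
class IPFResult:
    pmf: np.ndarray
    residual: float           #: max abs marginal discrepancy
    sweeps: int
    converged: bool           #: residual <= IPF_TOL


def _safediv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.divide(a, b, out=np.zeros_like(a), where=b > 0)


def ipf_pairwise_maxent(
    p: np.ndarray,
    tol: float = IPF_TOL,
    max_sweeps: int = IPF_MAX_SWEEPS,
) -> IPFResult:
    """Maxent distribution preserving the (Y,B), (Y,A) and (B,A) marginals of ``p``.

    Cyclic multiplicative scaling from the uniform distribution; the limit
    is the I-projection of the uniform onto the intersection of the three
    marginal families, i.e. the pairwise maximum-entropy model.
    """
    p = np.ascontiguousarray(p, dtype=np.float64)
    tyb = p.sum(axis=2)
    tya = p.sum(axis=1)
    tba = p.sum(axis=0)
    q = np.ones_like(p) / p.size
    residual, sweeps = ipf_sweeps(q, tyb, tya, tba, tol, max_sweeps)
    residual = float(residual)
    if residual <= tol:
        return IPFResult(q, residual, int(sweeps), True)
    if residual <= IPF_ACCEPT_RESIDUAL:
        return IPFResult(q, residual, int(sweeps), False)
    raise IPFError(
        f"IPF residual {residual:.3e} after {max_sweeps} sweeps "
        f"(acceptance floor {IPF_ACCEPT_RESIDUAL:g})"
    )


def maxent_inputs_indep_given_y(p: np.ndarray) -> np.ndarray:
    """Maxent under the (Y,B) and (Y,A) marginals: q = p(y) p(b|y) p(a|y)."""
    p = np.asarray(p, dtype=float)
    pyb = p.sum(axis=2)
    pya = p.sum(axis=1)
    py = pyb.sum(axis=1)
    pb_y = _safediv(pyb, py[:, None])
    pa_y = _safediv(pya, py[:, None])
    return py[:, None, None] * pb_y[:, :, None] * pa_y[:, None, :]


def maxent_y_indep_given_b(p: np.ndarray) -> np.ndarray:
    """Maxent under the (B,A) and (Y,B) marginals: q = p(b,a) p(y|b)."""
    p = np.asarray(p, dtype=float)
    pba = p.sum(axis=0)
    pyb = p.sum(axis=2)
    pb = pba.sum(axis=1)
    py_b = _safediv(pyb, pb[None, :])
    return pba[None, :, :] * py_b[:, :, None]


def maxent_y_indep_given_a(p: np.ndarray) -> np.ndarray:
    """Maxent under the (B,A) and (Y,A) marginals: q = p(b,a) p(y|a)."""
    p = np.asarray(p, dtype=float)
    pba = p.sum(axis=0)
    pya = p.sum(axis=1)
    pa = pba.sum(axis=0)
    py_a = _safediv(pya, pa[None, :])
    return pba[None, :, :] * py_a[:, None, :]
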