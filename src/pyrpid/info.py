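"""Classical Shannon measures on trivariate distributions, in bits.

All measures use log base 2 and the plug-in convention that zero-probability
cells contribute nothing (support-restricted summation, never epsilon
flooring). The seven quantities collected in :class:`InfoSummary` are the
ones that constrain every partial information decomposition:

    I(Y;B,A) = I(Y;B) + I(Y;A|B) = I(Y;A) + I(Y;B|A)      (chain rule)
    II(Y;B;A) = I(Y;B,A) - I(Y;B) - I(Y;A) = -coi(Y;B;A)

For comparisons across systems of different sizes, a summary can be
normalized by the joint mutual information, after which
I(Y;B) + I(Y;A|B) = 1 = I(Y;A) + I(Y;B|A).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .distributions import TrivariateDistribution

__all__ = [
    "InfoSummary",
    "classical_measures",
    "entropy",
    "mutual_information",
    "local_mi",
    "normalize_summary",
]


def entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits of an arbitrary-shape pmf."""
    p = np.asarray(p, dtype=float).ravel()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(pxy: np.ndarray) -> float:
    """I(X;Y) in bits from a 2-d joint pmf."""
    pxy = np.asarray(pxy, dtype=float)
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float((pxy[mask] * np.log2(pxy[mask] / (px @ py)[mask])).sum())


def local_mi(p_joint: np.ndarray, u: int, v: int) -> float:
    """Local (pointwise) mutual information i(u;v) = log2 p(u|v)/p(u).

    ``p_joint`` is a 2-d joint pmf indexed ``[u, v]``. The value can be
    negative, in which case observing ``v`` made the realized ``u`` less
    expected (misinformation). Undefined for unsupported realisations.
    """
    p_joint = np.asarray(p_joint, dtype=float)
    puv = p_joint[u, v]
    if puv <= 0:
        raise ValueError(f"realisation ({u}, {v}) has zero probability")
    pu = p_joint[u, :].sum()
    pv = p_joint[:, v].sum()
    return float(np.log2(puv / (pu * pv)))


@dataclass(frozen=True)
class InfoSummary:
    """The seven classical measures of one trivariate system (bits)."""

    h_y: float
    jmi: float     #: I(Y; B,A)
    mi_b: float    #: I(Y; B)
    mi_a: float    #: I(Y; A)
    cmi_b: float   #: I(Y; B | A)
    cmi_a: float   #: I(Y; A | B)
    ii: float      #: II(Y;B;A) = jmi - mi_b - mi_a
    coi: float     #: coinformation, -ii
    normalized: bool = False


def classical_measures(dist: TrivariateDistribution) -> InfoSummary:
    """Compute all classical measures of a trivariate distribution."""
    p = dist.pmf
    pyb = p.sum(axis=2)
    pya = p.sum(axis=1)
    pba = p.sum(axis=0)
    py = pyb.sum(axis=1)

    h_y = entropy(py)
    jmi = h_y + entropy(pba) - entropy(p)
    mi_b = mutual_information(pyb)
    mi_a = mutual_information(pya)
    cmi_b = jmi - mi_a          # I(Y;B|A), chain rule
    cmi_a = jmi - mi_b          # I(Y;A|B)
    ii = jmi - mi_b - mi_a
    return InfoSummary(
        h_y=h_y, jmi=jmi, mi_b=mi_b, mi_a=mi_a,
        cmi_b=cmi_b, cmi_a=cmi_a, ii=ii, coi=-ii,
    )


def normalize_summary(s: InfoSummary) -> InfoSummary:
    """Divide every field by the joint mutual information.

    Systems with zero joint mutual information carry no information to
    apportion; normalizing them is an error rather than a 0/0 convention.
    """
    if s.normalized:
        return s
    if s.jmi <= 0:
        raise ZeroDivisionError("cannot normalize a summary with zero joint mutual information")
    j = s.jmi
    return InfoSummary(
        h_y=s.h_y / j, jmi=1.0, mi_b=s.mi_b / j, mi_a=s.mi_a / j,
        cmi_b=s.cmi_b / j, cmi_a=s.cmi_a / j, ii=s.ii / j, coi=s.coi / j,
        normalized=True,
    )
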