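"""Finite trivariate joint distributions over (output Y, basal input B, apical input A).

Every estimator in this package consumes a :class:`TrivariateDistribution`:
a joint probability mass function over three finite, ordered alphabets.
Probabilities are plug-in (empirical) values; cells absent from the support
carry exactly zero mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np

__all__ = ["TrivariateDistribution", "InvalidDistributionError", "pairwise_marginals"]

#: pmfs are accepted when |sum - 1| is below this, then renormalized exactly
SUM_TOLERANCE = 1e-9


class InvalidDistributionError(ValueError):
    """Raised when a pmf has negative mass or does not sum to one."""


@dataclass(frozen=True)
class TrivariateDistribution:
    """Joint pmf over (Y, B, A) on finite ordered alphabets.

    Parameters
    ----------
    alphabet_y, alphabet_b, alphabet_a
        Ordered label sets. The ordering is preserved exactly as given;
        no information measure depends on it.
    pmf
        Array of shape ``(|Y|, |B|, |A|)`` with nonnegative entries summing
        to one (within :data:`SUM_TOLERANCE`; renormalized on construction).
    """

    alphabet_y: tuple
    alphabet_b: tuple
    alphabet_a: tuple
    pmf: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphabet_y", tuple(self.alphabet_y))
        object.__setattr__(self, "alphabet_b", tuple(self.alphabet_b))
        object.__setattr__(self, "alphabet_a", tuple(self.alphabet_a))
        if not (self.alphabet_y and self.alphabet_b and self.alphabet_a):
            raise InvalidDistributionError("alphabets must be non-empty")
        p = np.asarray(self.pmf, dtype=float)
        expected = (len(self.alphabet_y), len(self.alphabet_b), len(self.alphabet_a))
        if p.shape != expected:
            raise InvalidDistributionError(
                f"pmf shape {p.shape} does not match alphabets {expected}"
            )
        if p.min() < -1e-12:
            i = np.unravel_index(np.argmin(p), p.shape)
            raise InvalidDistributionError(
                f"negative probability {p[i]:g} at cell "
                f"({self.alphabet_y[i[0]]}, {self.alphabet_b[i[1]]}, {self.alphabet_a[i[2]]})"
            )
        p = np.clip(p, 0.0, None)
        total = p.sum()
        if abs(total - 1.0) > SUM_TOLERANCE:
            raise InvalidDistributionError(f"pmf sums to {total!r}, not 1")
        p = p / total
        p.setflags(write=False)
        object.__setattr__(self, "pmf", p)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_dict(
        cls,
        cells: Mapping[tuple, float],
        alphabet_y: Sequence[Hashable] | None = None,
        alphabet_b: Sequence[Hashable] | None = None,
        alphabet_a: Sequence[Hashable] | None = None,
    ) -> "TrivariateDistribution":
        """Build from a map ``(y, b, a) -> probability``.

        Alphabets default to first-appearance order of the labels in
        ``cells``; absent cells have probability exactly zero.
        """

        def seen(idx: int) -> tuple:
            out: list = []
            for key in cells:
                if key[idx] not in out:
                    out.append(key[idx])
            return tuple(out)

        ay = tuple(alphabet_y) if alphabet_y is not None else seen(0)
        ab = tuple(alphabet_b) if alphabet_b is not None else seen(1)
        aa = tuple(alphabet_a) if alphabet_a is not None else seen(2)
        iy = {v: i for i, v in enumerate(ay)}
        ib = {v: i for i, v in enumerate(ab)}
        ia = {v: i for i, v in enumerate(aa)}
        p = np.zeros((len(ay), len(ab), len(aa)))
        for (y, b, a), mass in cells.items():
            try:
                p[iy[y], ib[b], ia[a]] += mass
            except KeyError as exc:
                raise InvalidDistributionError(f"label {exc} not in alphabet") from exc
        return cls(ay, ab, aa, p)

    # -- views -------------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pmf.shape

    @property
    def support_size(self) -> int:
        return int(np.count_nonzero(self.pmf))

    def as_dict(self) -> dict[tuple, float]:
        """Supported cells only, in alphabet order."""
        out: dict[tuple, float] = {}
        for (i, j, k) in zip(*np.nonzero(self.pmf)):
            out[(self.alphabet_y[i], self.alphabet_b[j], self.alphabet_a[k])] = float(
                self.pmf[i, j, k]
            )
        return out

    def swap_inputs(self) -> "TrivariateDistribution":
        """Exchange the roles of B and A."""
        return TrivariateDistribution(
            self.alphabet_y, self.alphabet_a, self.alphabet_b, self.pmf.swapaxes(1, 2)
        )


def pairwise_marginals(dist: TrivariateDistribution) -> dict[str, np.ndarray]:
    """All pairwise and single marginals of a trivariate distribution.

    Returns a dict with keys ``yb``, ``ya``, ``ba`` (2-d arrays) and
    ``y``, ``b``, ``a`` (1-d arrays), each summing to one.
    """
    p = dist.pmf
    return {
        "yb": p.sum(axis=2),
        "ya": p.sum(axis=1),
        "ba": p.sum(axis=0),
        "y": p.sum(axis=(1, 2)),
        "b": p.sum(axis=(0, 2)),
        "a": p.sum(axis=(0, 1)),
    }
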