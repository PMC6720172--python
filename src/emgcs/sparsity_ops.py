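"""Support selection and hard truncation: the building blocks of greedy recovery.

``supp_k`` picks the k indices with the largest basis-weighted magnitudes
``|x_i| * ||psi_i||_2``; ``restrict`` zeroes everything off a support; their
composition ``reduce_k`` is the best k-term approximation when the basis is
orthonormal.  Indices are 0-based, matching Python convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bases import BasisMatrix

__all__ = ["SupportSet", "SparseCoefficients", "supp_k", "restrict", "reduce_k"]


@dataclass(frozen=True)
class SupportSet:
    """A fixed-cardinality set of coefficient indices (0-based, sorted)."""

    indices: np.ndarray
    n: int

    def __post_init__(self) -> None:
        indices = np.unique(np.asarray(self.indices, dtype=int))
        if indices.size and (indices[0] < 0 or indices[-1] >= self.n):
            raise ValueError(f"support indices must lie in [0, {self.n})")
        object.__setattr__(self, "indices", indices)

    @property
    def k(self) -> int:
        return self.indices.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SupportSet):
            return NotImplemented
        return self.n == other.n and np.array_equal(self.indices, other.indices)


@dataclass(frozen=True)
class SparseCoefficients:
    """A coefficient vector that is exactly zero off its support."""

    x: np.ndarray
    support: SupportSet

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        mask = np.ones(x.size, dtype=bool)
        mask[self.support.indices] = False
        if np.any(x[mask] != 0.0):
            raise ValueError("coefficients outside the support must be exactly zero")
        object.__setattr__(self, "x", x)


def supp_k(x: np.ndarray, psi: BasisMatrix, k: int) -> SupportSet:
    """Indices of the k largest basis-weighted magnitudes ``|x_i| * ||psi_i||``.

    Ties are broken in favour of the lower index, so the result is
    deterministic.  The support always has cardinality k, even when ``x``
    has fewer than k nonzeros.
    """
    x = np.asarray(x, dtype=float)
    if not 1 <= k <= x.size:
        raise ValueError(f"k={k} must lie in [1, {x.size}]")
    gamma = np.abs(x) * psi.column_norms
    # stable sort on -gamma keeps lower indices first among ties
    order = np.argsort(-gamma, kind="stable")
    return SupportSet(indices=order[:k], n=x.size)


def restrict(x: np.ndarray, lam: SupportSet) -> np.ndarray:
    """Copy of ``x`` that agrees with it on the support and is exactly zero elsewhere."""
    x = np.asarray(x, dtype=float)
    if lam.n != x.size:
        raise ValueError("support and vector dimensions disagree")
    out = np.zeros_like(x)
    out[lam.indices] = x[lam.indices]
    return out


def reduce_k(x: np.ndarray, psi: BasisMatrix, k: int) -> SparseCoefficients:
    """Hard truncation ``[x]_k``: keep the k largest basis-weighted entries.

    For an orthonormal basis this is the best k-term approximation in l2.
    Idempotent: reducing an already reduced vector returns it unchanged.
    """
    lam = supp_k(x, psi, k)
    return SparseCoefficients(x=restrict(x, lam), support=lam)
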