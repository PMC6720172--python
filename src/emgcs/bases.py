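"""Sparsifying bases: orthonormal DCT, Haar and Daubechies-4 synthesis matrices.

A basis is held as a dense N-by-N synthesis matrix ``Psi`` whose columns are
the basis vectors, so a coefficient vector ``x`` synthesises the signal
``f = Psi x``.  The wavelet bases are built from a dyadic filter bank with
periodic (circular) boundary handling — the one extension mode that makes the
square filter-bank matrix exactly orthonormal — by applying the inverse
discrete wavelet transform to each canonical coefficient unit vector.

"DB4" follows the common software naming convention for the Daubechies
wavelet with four vanishing moments (eight filter taps, ``"db4"``).  Pass
``wavelet="db2"`` to :func:`build_db4_basis` to obtain the 4-tap family
instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pywt
import scipy.fft

__all__ = [
    "BasisMatrix",
    "build_dct_basis",
    "build_haar_basis",
    "build_db4_basis",
    "build_basis",
    "synthesize",
    "analyze",
]


@dataclass(frozen=True)
class BasisMatrix:
    """N-by-N synthesis basis ``Psi = [psi_1, ..., psi_N]`` (columns are basis vectors)."""

    matrix: np.ndarray
    kind: str
    levels: Optional[int] = None

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("basis matrix must be square")
        object.__setattr__(self, "matrix", matrix)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def column_norms(self) -> np.ndarray:
        """l2 norm of each basis column (all 1 for the orthonormal constructions)."""
        return np.linalg.norm(self.matrix, axis=0)


def _require_power_of_two(N: int) -> int:
    if N < 2 or (N & (N - 1)) != 0:
        raise ValueError(f"N={N} must be a power of 2 for a dyadic filter bank")
    return int(np.log2(N))


def build_dct_basis(N: int) -> BasisMatrix:
    """Orthonormal type-II DCT synthesis basis: analysis is the DCT, synthesis the IDCT."""
    if N < 2:
        raise ValueError("DCT basis requires N >= 2")
    matrix = scipy.fft.idct(np.eye(N), axis=0, norm="ortho")
    return BasisMatrix(matrix=matrix, kind="dct")


def _wavelet_basis(N: int, levels: int, wavelet: str, kind: str) -> BasisMatrix:
    max_level = _require_power_of_two(N)
    if levels < 1 or levels > max_level:
        raise ValueError(f"levels={levels} must lie in [1, log2(N)={max_level}]")
    w = pywt.Wavelet(wavelet)
    zero_coeffs = pywt.wavedec(np.zeros(N), w, mode="periodization", level=levels)
    _, slices = pywt.coeffs_to_array(zero_coeffs)
    matrix = np.empty((N, N))
    arr = np.zeros(N)
    for j in range(N):
        arr[j] = 1.0
        coeffs = pywt.array_to_coeffs(arr, slices, output_format="wavedec")
        matrix[:, j] = pywt.waverec(coeffs, w, mode="periodization")
        arr[j] = 0.0
    return BasisMatrix(matrix=matrix, kind=kind, levels=levels)


def build_haar_basis(N: int, levels: Optional[int] = None) -> BasisMatrix:
    """Orthonormal Haar synthesis basis from a ``levels``-deep dyadic filter bank.

    ``levels`` defaults to the full depth ``log2(N)``.
    """
    max_level = _require_power_of_two(N)
    if levels is None:
        levels = max_level
    return _wavelet_basis(N, levels, "haar", "haar")


def build_db4_basis(
    N: int, levels: Optional[int] = None, wavelet: str = "db4"
) -> BasisMatrix:
    """Orthonormal Daubechies synthesis basis (periodized filter bank).

    ``levels`` defaults to ``log2(N) - 3``; the decomposition depth is capped
    relative to the filter length so every sub-band is longer than the taps.
    """
    max_level = _require_power_of_two(N)
    if levels is None:
        levels = max(1, max_level - 3)
    return _wavelet_basis(N, levels, wavelet, "db4")


def build_basis(kind: str, N: int, levels: Optional[int] = None) -> BasisMatrix:
    """Build a basis by name: one of ``dct``, ``haar``, ``db4``."""
    kind = kind.lower()
    if kind == "dct":
        return build_dct_basis(N)
    if kind == "haar":
        return build_haar_basis(N, levels)
    if kind == "db4":
        return build_db4_basis(N, levels)
    raise ValueError(f"unknown basis kind {kind!r}; expected dct, haar or db4")


def synthesize(psi: BasisMatrix, x: np.ndarray) -> np.ndarray:
    """Signal from coefficients: ``f = Psi x``."""
    x = np.asarray(x, dtype=float)
    if x.shape != (psi.n,):
        raise ValueError(f"coefficient vector must have length {psi.n}")
    return psi.matrix @ x


def analyze(psi: BasisMatrix, f: np.ndarray) -> np.ndarray:
    """Coefficients of a signal: ``x = Psi^T f`` (valid because Psi is orthonormal)."""
    f = np.asarray(f, dtype=float)
    if f.shape != (psi.n,):
        raise ValueError(f"signal vector must have length {psi.n}")
    return psi.matrix.T @ f
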