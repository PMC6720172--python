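"""Signal framing, Bernoulli measurement encoding, and compression metrics.

The compressed-sensing encoder maps an ``N``-sample frame ``f`` to ``M < N``
measurements ``y = Phi f`` through a random ±1 Bernoulli matrix ``Phi``.
This module owns the frame container, the seeded measurement matrix, the
encoding product, the standard compression/sparsity ratios (CR, CF, SN, SM)
and the mutual-coherence diagnostic between the sensing matrix and a
sparsifying basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .bases import BasisMatrix

__all__ = [
    "SignalFrame",
    "MeasurementMatrix",
    "Measurements",
    "CompressionMetrics",
    "frame_signal",
    "build_bernoulli_matrix",
    "encode",
    "compression_metrics",
    "coherence",
]


@dataclass(frozen=True)
class SignalFrame:
    """One N-sample frame of a single-channel signal.

    Parameters
    ----------
    samples : ndarray
        Real amplitude samples (dimensionless), length ``N``.
    fs : float
        Sampling rate in Hz.
    index : int
        1-based frame ordinal within the source recording.
    """

    samples: np.ndarray
    fs: float
    index: int = 1

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("frame samples must be a 1-D vector")
        if not np.all(np.isfinite(samples)):
            raise ValueError("frame samples must all be finite")
        if self.index < 1:
            raise ValueError("frame index is 1-based and must be >= 1")
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class MeasurementMatrix:
    """M-by-N sensing matrix with entries in {-1, +1}, reproducible from its seed."""

    entries: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.ndim != 2:
            raise ValueError("measurement matrix must be 2-D")
        if not np.all(np.abs(entries) == 1.0):
            raise ValueError("measurement matrix entries must be exactly +1 or -1")
        if entries.shape[0] > entries.shape[1]:
            raise ValueError("measurement matrix requires M <= N")
        object.__setattr__(self, "entries", entries)

    @property
    def m(self) -> int:
        return self.entries.shape[0]

    @property
    def n(self) -> int:
        return self.entries.shape[1]


@dataclass(frozen=True)
class Measurements:
    """Length-M measurement vector, optionally tagged with an injected noise level (dB)."""

    y: np.ndarray
    noise_snr_db: Optional[float] = None

    def __post_init__(self) -> None:
        y = np.atleast_1d(np.asarray(self.y, dtype=float))
        object.__setattr__(self, "y", y)

    @property
    def m(self) -> int:
        return self.y.size


@dataclass(frozen=True)
class CompressionMetrics:
    """Compression ratio CR = N/M, compression factor CF = M/N, and the
    sparsity ratios SN = k/N and SM = k/M, which satisfy SM = CR * SN."""

    CR: float
    CF: float
    SN: float
    SM: float


def frame_signal(signal: np.ndarray, N: int, fs: float) -> list[SignalFrame]:
    """Split a signal into consecutive non-overlapping frames of length ``N``.

    A trailing remainder shorter than ``N`` is dropped; the number of dropped
    samples is available as ``len(signal) - len(frames) * N``.

    Raises
    ------
    ValueError
        If the signal is shorter than one frame.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if N < 1:
        raise ValueError("frame length N must be positive")
    if signal.size < N:
        raise ValueError(
            f"signal has {signal.size} samples but at least N={N} are required"
        )
    n_frames = signal.size // N
    return [
        SignalFrame(samples=signal[i * N : (i + 1) * N], fs=fs, index=i + 1)
        for i in range(n_frames)
    ]


def build_bernoulli_matrix(M: int, N: int, seed: int) -> MeasurementMatrix:
    """Draw an M-by-N matrix of i.i.d. fair ±1 entries from a seeded generator.

    Entries come from a single seeded stream in row-major order, so the
    matrix is exactly reproducible from ``(M, N, seed)``.
    """
    if M < 1 or N < 1:
        raise ValueError("matrix dimensions must be positive")
    if M > N:
        raise ValueError(
            f"M={M} exceeds N={N}: an over-determined sensing matrix is outside "
            "the compressed-sensing regime"
        )
    rng = np.random.default_rng(seed)
    entries = rng.integers(0, 2, size=(M, N)).astype(float) * 2.0 - 1.0
    return MeasurementMatrix(entries=entries, seed=seed)


def encode(frame: SignalFrame, phi: MeasurementMatrix) -> Measurements:
    """Encode a frame into measurements ``y = Phi f``.

    Because the entries of ``Phi`` are ±1 the product reduces to signed
    accumulation in hardware; here it is the exact matrix-vector product.
    """
    if frame.n != phi.n:
        raise ValueError(
            f"frame length {frame.n} does not match matrix width {phi.n}"
        )
    return Measurements(y=phi.entries @ frame.samples)


def compression_metrics(N: int, M: int, k: int) -> CompressionMetrics:
    """Compute CR = N/M, CF = M/N, SN = k/N and SM = k/M for one operating point."""
    if N < 1 or M < 1 or k < 1:
        raise ValueError("N, M and k must all be positive")
    if M > N or k > N:
        raise ValueError("require k <= N and M <= N")
    return CompressionMetrics(CR=N / M, CF=M / N, SN=k / N, SM=k / M)


def coherence(phi, psi) -> float:
    """Mutual coherence between the sensing rows of ``Phi`` and the columns of ``Psi``.

    Returns ``nu = sqrt(N) * max |<phi_i, psi_j>|`` over unit-normalised rows
    and columns, so that ``nu`` lies in ``[1, sqrt(N)]``: incoherent pairs
    (random rows against any fixed basis) sit near 1 and aligned pairs at
    ``sqrt(N)``.  Purely diagnostic — fewer measurements suffice when the
    coherence is low.  Accepts a :class:`MeasurementMatrix` /
    :class:`~emgcs.bases.BasisMatrix` or plain arrays.
    """
    rows = np.asarray(getattr(phi, "entries", phi), dtype=float)
    cols = np.asarray(getattr(psi, "matrix", psi), dtype=float)
    if rows.shape[1] != cols.shape[0]:
        raise ValueError("sensing matrix and basis have incompatible dimensions")
    row_norms = np.linalg.norm(rows, axis=1)
    col_norms = np.linalg.norm(cols, axis=0)
    if np.any(row_norms == 0) or np.any(col_norms == 0):
        raise ValueError("coherence is undefined for zero rows or columns")
    inner = (rows / row_norms[:, None]) @ (cols / col_norms[None, :])
    n = cols.shape[0]
    return float(np.sqrt(n) * np.max(np.abs(inner)))
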