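"""Plain-text I/O for signals, measurement matrices and bases.

Signals are delimited text, one sample per line, or two columns
(time, amplitude) of which the second is used; the sampling rate always
comes from configuration, never from the file.  Matrices and bases carry a
``#``-prefixed header line recording their defining parameters so they can
be rebuilt or validated on load.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np

from .bases import BasisMatrix
from .signal_model import MeasurementMatrix

__all__ = [
    "read_signal",
    "write_signal",
    "write_matrix",
    "read_matrix",
    "write_basis",
]

PathLike = Union[str, Path]


def read_signal(path: PathLike) -> np.ndarray:
    """Load a signal from delimited text (one sample per line, or time/amplitude columns)."""
    data = np.loadtxt(path)
    if data.ndim == 2:
        if data.shape[1] == 2:
            return data[:, 1].astype(float)
        raise ValueError(
            f"{path}: expected 1 or 2 columns, found {data.shape[1]}"
        )
    return np.atleast_1d(data.astype(float))


def write_signal(path: PathLike, samples: np.ndarray) -> None:
    np.savetxt(path, np.asarray(samples, dtype=float), fmt="%.12g")


def write_matrix(path: PathLike, phi: MeasurementMatrix) -> None:
    """Write a ±1 measurement matrix with an M/N/seed header."""
    header = f"M={phi.m} N={phi.n} seed={phi.seed}"
    np.savetxt(path, phi.entries, fmt="%d", header=header)


def read_matrix(path: PathLike) -> MeasurementMatrix:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    fields = dict(item.split("=") for item in header.split())
    entries = np.loadtxt(path)
    phi = MeasurementMatrix(entries=np.atleast_2d(entries), seed=int(fields["seed"]))
    if phi.m != int(fields["M"]) or phi.n != int(fields["N"]):
        raise ValueError(f"{path}: header dimensions do not match the data")
    return phi


def write_basis(path: PathLike, psi: BasisMatrix) -> None:
    """Write a basis matrix with a kind/N/levels header."""
    header = f"kind={psi.kind} N={psi.n} levels={psi.levels}"
    np.savetxt(path, psi.matrix, fmt="%.17g", header=header)
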