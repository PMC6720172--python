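"""Shared result container for the reconstruction algorithms."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sparsity_ops import SparseCoefficients

__all__ = ["ReconstructionResult"]


@dataclass
class ReconstructionResult:
    """Outcome of one reconstruction run.

    Attributes
    ----------
    coefficients : SparseCoefficients
        Recovered coefficient vector with its support.
    frame : ndarray
        Reconstructed signal ``Psi x``.
    iterations : int
        Number of (outer) iterations executed.
    converged : bool
        Whether the stopping tolerance was met before the iteration cap.
    residual_trace : list of float
        Per-iteration residual (or iterate-change) norms, for diagnostics.
    warnings : list of str
        Non-fatal anomalies, e.g. rank-deficient refits or stagnation.
    diagnostics : dict or None
        Optional per-iteration diagnostics (populated only on request),
        e.g. the l1 solver's feasibility residuals and l1-norm trace.
    """

    coefficients: SparseCoefficients
    frame: np.ndarray
    iterations: int
    converged: bool
    residual_trace: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    diagnostics: dict = None

    @property
    def x(self) -> np.ndarray:
        return self.coefficients.x
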