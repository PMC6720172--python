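"""Greedy sparse reconstruction: OMP, CoSaMP and normalized IHT.

All three algorithms operate on the combined matrix ``A = Phi Psi`` and share
two primitives: correlation-based column selection (the indices maximising
``|a_j^T r|``) and a least-squares coefficient refit on a candidate support.

* **OMP** adds the single best-correlated column per iteration, refits, and
  updates the residual; after k iterations the residual is orthogonal to
  every selected column.  Implemented with an incrementally updated QR
  factorisation of the selected columns so a full refit is never re-solved
  from scratch.
* **CoSaMP** selects ``kS = gamma * k`` candidate columns per iteration,
  merges them with the current support, refits on the enlarged set, then
  prunes back to the k largest basis-weighted coefficients.
* **NIHT** descends the residual gradient with a per-coordinate normalised
  direction ``q = rho ⊙ A^T r`` and hard-thresholds to k terms.  The scalar
  step is the exact 1-D minimiser of the residual on a proposed support,
  iterated until the support stabilises.
"""

from __future__ import annotations

from typing import List, Optional, Tuple, Union

import numpy as np
import scipy.linalg

from .bases import BasisMatrix
from .results import ReconstructionResult
from .signal_model import Measurements
from .sparsity_ops import SparseCoefficients, SupportSet, restrict, supp_k

__all__ = [
    "select_columns",
    "least_squares_on_support",
    "omp_reconstruct",
    "cosamp_reconstruct",
    "niht_step_vector",
    "niht_mu",
    "niht_reconstruct",
]

#: relative residual-change threshold for the secondary stop of CoSaMP/NIHT
RESIDUAL_TOL = 1e-8

#: iterations without meaningful residual improvement before declaring stagnation
STAGNATION_PATIENCE = 3


def _as_vector(y: Union[Measurements, np.ndarray]) -> np.ndarray:
    if isinstance(y, Measurements):
        return y.y
    return np.asarray(y, dtype=float)


def select_columns(A: np.ndarray, r: np.ndarray, m: int) -> SupportSet:
    """The m columns of ``A`` most strongly correlated with ``r``.

    Maximises ``sum_{j in W} |a_j^T r|`` over all subsets of size m, which
    separates into picking the m largest single-column correlations.  Ties
    go to the lower index.
    """
    A = np.asarray(A, dtype=float)
    if not 1 <= m <= A.shape[1]:
        raise ValueError(f"m={m} must lie in [1, {A.shape[1]}]")
    corr = np.abs(A.T @ r)
    order = np.argsort(-corr, kind="stable")
    return SupportSet(indices=order[:m], n=A.shape[1])


def least_squares_on_support(
    A: np.ndarray, y: Union[Measurements, np.ndarray], cols: SupportSet
) -> Tuple[np.ndarray, bool]:
    """Coefficients minimising ``||y - A_cols h||_2`` on the given columns.

    Returns ``(h, rank_deficient)`` where ``h`` has one entry per support
    index (in sorted index order).  Rank-deficient sub-matrices yield the
    minimum-norm solution and set the flag instead of aborting, so large
    parameter sweeps run to completion.
    """
    A = np.asarray(A, dtype=float)
    yv = _as_vector(y)
    if cols.k > A.shape[0]:
        raise ValueError(
            f"refit on {cols.k} columns with only {A.shape[0]} measurements is "
            "under-determined"
        )
    sub = A[:, cols.indices]
    h, _, rank, _ = scipy.linalg.lstsq(sub, yv, lapack_driver="gelsy")
    return h, rank < cols.k


def omp_reconstruct(
    A: np.ndarray,
    y: Union[Measurements, np.ndarray],
    k: int,
    psi: BasisMatrix,
) -> ReconstructionResult:
    """Orthogonal matching pursuit: k column selections with a refit each step."""
    A = np.asarray(A, dtype=float)
    yv = _as_vector(y)
    M, N = A.shape
    if not 1 <= k <= M:
        raise ValueError(f"k={k} must lie in [1, M={M}]")

    # Incremental QR of the selected columns: Q (M x t) orthonormal, R upper
    # triangular, so the refit residual is y - Q Q^T y without re-solving.
    Q = np.zeros((M, k))
    R = np.zeros((k, k))
    selected: List[int] = []
    warnings: List[str] = []
    r = yv.copy()
    trace: List[float] = []
    mask = np.zeros(N, dtype=bool)
    for t in range(k):
        corr = np.abs(A.T @ r)
        corr[mask] = -np.inf  # numerical guard: never reselect a column
        lam = int(np.argmax(corr))
        selected.append(lam)
        mask[lam] = True
        a = A[:, lam]
        v = Q[:, :t].T @ a
        u = a - Q[:, :t] @ v
        # second Gram-Schmidt pass for orthogonality at large t
        v2 = Q[:, :t].T @ u
        u -= Q[:, :t] @ v2
        norm_u = np.linalg.norm(u)
        if norm_u < 1e-12 * np.linalg.norm(a):
            warnings.append(f"column {lam} linearly dependent on selection; stopped")
            selected.pop()
            break
        Q[:, t] = u / norm_u
        R[: t + 1, t] = np.concatenate([v + v2, [norm_u]])
        r = r - Q[:, t] * (Q[:, t] @ r)
        trace.append(float(np.linalg.norm(r)))

    t_eff = len(selected)
    coef = scipy.linalg.solve_triangular(
        R[:t_eff, :t_eff], Q[:, :t_eff].T @ yv, lower=False
    )
    x = np.zeros(N)
    x[selected] = coef
    support = SupportSet(indices=np.array(selected, dtype=int), n=N)
    coeffs = SparseCoefficients(x=restrict(x, support), support=support)
    return ReconstructionResult(
        coefficients=coeffs,
        frame=psi.matrix @ coeffs.x,
        iterations=t_eff,
        converged=True,
        residual_trace=trace,
        warnings=warnings,
    )


def cosamp_reconstruct(
    A: np.ndarray,
    y: Union[Measurements, np.ndarray],
    k: int,
    psi: BasisMatrix,
    gamma: float = 0.5,
    n_iter: int = 50,
) -> ReconstructionResult:
    """Compressive sampling matching pursuit.

    Per iteration: select ``kS = max(1, round(gamma * k))`` new columns
    against the residual, merge with the current support, refit on the
    merged set, prune to the k largest basis-weighted coefficients and
    update the residual.  Stops at ``n_iter``, on a relative residual
    change below ``RESIDUAL_TOL``, or after ``STAGNATION_PATIENCE``
    iterations without improvement.
    """
    A = np.asarray(A, dtype=float)
    yv = _as_vector(y)
    M, N = A.shape
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    kS = max(1, int(round(gamma * k)))
    if k + kS > M:
        raise ValueError(
            f"k + kS = {k + kS} exceeds M={M}; the merged-support refit would be "
            "under-determined"
        )

    lam = select_columns(A, yv, k)
    x = np.zeros(N)
    r = yv.copy()
    warnings: List[str] = []
    trace: List[float] = []
    converged = False
    best_res = np.inf
    stalled = 0
    t = 0
    prev_res = float(np.linalg.norm(r))
    while t < n_iter:
        w = select_columns(A, r, kS)
        merged = SupportSet(
            indices=np.union1d(lam.indices, w.indices), n=N
        )
        h, deficient = least_squares_on_support(A, yv, merged)
        if deficient and "rank-deficient refit" not in warnings:
            warnings.append("rank-deficient refit")
        full = np.zeros(N)
        full[merged.indices] = h
        lam = supp_k(full, psi, k)
        x = restrict(full, lam)
        r = yv - A[:, lam.indices] @ x[lam.indices]
        res = float(np.linalg.norm(r))
        trace.append(res)
        t += 1
        if abs(prev_res - res) <= RESIDUAL_TOL * max(prev_res, 1e-300):
            converged = True
            break
        if res < best_res * (1.0 - 1e-6):
            best_res = res
            stalled = 0
        else:
            stalled += 1
            if stalled >= STAGNATION_PATIENCE:
                warnings.append("residual stagnated")
                break
        prev_res = res

    coeffs = SparseCoefficients(x=x, support=lam)
    return ReconstructionResult(
        coefficients=coeffs,
        frame=psi.matrix @ x,
        iterations=t,
        converged=converged,
        residual_trace=trace,
        warnings=warnings,
    )


def niht_step_vector(A: np.ndarray) -> np.ndarray:
    """Per-coordinate normalisation ``rho_j = min_i ||a_i|| / ||a_j||``, in (0, 1]."""
    A = np.asarray(A, dtype=float)
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms == 0):
        raise ValueError("step vector undefined: A has a zero column")
    return norms.min() / norms


def niht_mu(
    A: np.ndarray,
    q: np.ndarray,
    x: np.ndarray,
    y: Union[Measurements, np.ndarray],
    lam_star: SupportSet,
) -> Tuple[float, bool]:
    """Exact 1-D residual minimiser on a proposed support.

    With ``w = A q|_lam`` and ``eps = A x|_lam - y``, the step
    ``mu = (w^T eps) / (w^T w)`` minimises
    ``||A (x|_lam - mu q|_lam) - y||_2^2``.  Returns ``(mu, stagnated)``;
    a zero ``w`` yields ``mu = 0`` with the stagnation flag set.
    """
    A = np.asarray(A, dtype=float)
    yv = _as_vector(y)
    w = A @ restrict(q, lam_star)
    denom = float(w @ w)
    if denom == 0.0:
        return 0.0, True
    eps = A @ restrict(x, lam_star) - yv
    return float(w @ eps) / denom, False


def niht_reconstruct(
    A: np.ndarray,
    y: Union[Measurements, np.ndarray],
    k: int,
    psi: BasisMatrix,
    n_iter: int = 100,
    max_inner: int = 10,
) -> ReconstructionResult:
    """Normalized iterative hard thresholding.

    Initialised from a least-squares fit on the k best-correlated columns.
    Each outer iteration forms the normalised gradient
    ``q = rho ⊙ A^T (A x - y)`` and runs an inner loop that alternates the
    closed-form step on a proposed support with re-thresholding until the
    support stops changing (at most ``max_inner`` passes).  The first outer
    iteration takes its step on the full index set, as the support proposal
    is not yet meaningful.
    """
    A = np.asarray(A, dtype=float)
    yv = _as_vector(y)
    M, N = A.shape
    if not 1 <= k <= M:
        raise ValueError(f"k={k} must lie in [1, M={M}]")

    lam = select_columns(A, yv, k)
    h, deficient = least_squares_on_support(A, yv, lam)
    warnings: List[str] = []
    if deficient:
        warnings.append("rank-deficient initial refit")
    x = np.zeros(N)
    x[lam.indices] = h
    rho = niht_step_vector(A)
    trace: List[float] = []
    converged = False
    best_res = np.inf
    stalled = 0
    prev_res = float(np.linalg.norm(A @ x - yv))
    t = 0
    while t < n_iter:
        r = A @ x - yv
        q = rho * (A.T @ r)
        if t == 0:
            lam_star = SupportSet(indices=np.arange(N), n=N)
            mu, stagnated = niht_mu(A, q, x, yv, lam_star)
            x_tilde = x - mu * q
            lam = supp_k(x_tilde, psi, k)
        else:
            lam_star = lam
            stagnated = False
            for _ in range(max_inner):
                mu, stagnated = niht_mu(A, q, x, yv, lam_star)
                x_tilde = x - mu * q
                lam_new = supp_k(x_tilde, psi, k)
                if lam_new == lam_star or stagnated:
                    lam = lam_new
                    break
                lam_star = lam_new
            else:
                lam = lam_star
        x = restrict(x_tilde, lam)
        res = float(np.linalg.norm(A @ x - yv))
        trace.append(res)
        t += 1
        if stagnated:
            warnings.append("zero step direction; stagnated")
            break
        if abs(prev_res - res) <= RESIDUAL_TOL * max(prev_res, 1e-300):
            converged = True
            break
        if res < best_res * (1.0 - 1e-6):
            best_res = res
            stalled = 0
        else:
            stalled += 1
            if stalled >= STAGNATION_PATIENCE:
                warnings.append("residual stagnated")
                break
        prev_res = res

    coeffs = SparseCoefficients(x=x, support=lam)
    return ReconstructionResult(
        coefficients=coeffs,
        frame=psi.matrix @ x,
        iterations=t,
        converged=converged,
        residual_trace=trace,
        warnings=warnings,
    )
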