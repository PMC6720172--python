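"""Evaluation harness: SNR metric, noise injection, noise bound, and sweeps.

Reconstruction quality is scored as an equivalent signal-to-noise ratio

    SNR = 20 log10( ||f||_2 / ||f - f_rec||_2 )   [dB]

measured against the *original* frame, so the score folds together the
k-term approximation loss of the basis and the recovery error of the
algorithm.  ``run_cell`` evaluates one (algorithm, basis, CF, SM, noise)
operating point over a set of frames, drawing one fresh seeded Bernoulli
matrix per frame; ``sweep`` runs the Cartesian grid and returns a tidy
table.

For noisy measurements the achievable SNR obeys

    SNR <= SNR_NF * SNR_noise / (SNR_NF - SNR_noise)

where SNR_NF is the noise-free result and SNR_noise = ||f|| / ||Psi x_e||
is set by the noise component x_e propagated through the reconstruction
(for the l1 solver, x_e = A^+ n, independent of k).  All three quantities
are linear amplitude ratios; conversion to dB happens only at reporting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .bases import BasisMatrix, build_basis
from .greedy_reconstruction import (
    cosamp_reconstruct,
    niht_reconstruct,
    omp_reconstruct,
)
from .l1_reconstruction import l1_reconstruct
from .results import ReconstructionResult
from .signal_model import Measurements, SignalFrame, build_bernoulli_matrix, encode
from .sparsity_ops import reduce_k

__all__ = [
    "ALGORITHMS",
    "NoiseBound",
    "snr_db",
    "add_noise",
    "noise_snr_bound",
    "run_cell",
    "sweep",
]

ALGORITHMS = ("l1", "omp", "cosamp", "niht")

#: offset added to the per-frame matrix seed to derive the noise seed
_NOISE_SEED_OFFSET = 700_001

#: dB value reported for an error-free reconstruction
DEFAULT_SNR_CAP_DB = 300.0


@dataclass(frozen=True)
class NoiseBound:
    """Noise-limited SNR bound; all fields are linear amplitude ratios."""

    snr_nf: float
    snr_noise: float
    bound: float


def snr_db(
    reference: np.ndarray,
    reconstructed: np.ndarray,
    cap_db: float = DEFAULT_SNR_CAP_DB,
) -> float:
    """Equivalent SNR in dB between a reference vector and its reconstruction.

    An error-free reconstruction returns ``cap_db`` (standing in for
    +infinity so tables stay finite).
    """
    reference = np.asarray(reference, dtype=float)
    reconstructed = np.asarray(reconstructed, dtype=float)
    if reference.shape != reconstructed.shape:
        raise ValueError("reference and reconstruction must have equal length")
    ref_norm = np.linalg.norm(reference)
    if ref_norm == 0:
        raise ValueError("SNR undefined for an all-zero reference")
    err_norm = np.linalg.norm(reference - reconstructed)
    if err_norm == 0:
        return cap_db
    return float(min(20.0 * np.log10(ref_norm / err_norm), cap_db))


def add_noise(
    y: Union[Measurements, np.ndarray], target_snr_db: float, seed: int
) -> Measurements:
    """Superimpose seeded white Gaussian noise at an exact measurement SNR.

    The noise vector is rescaled so that ``20 log10(||y|| / ||n||)`` equals
    ``target_snr_db`` exactly (norm-exact, not merely in expectation).  A
    target of +infinity returns the measurements unchanged.
    """
    yv = y.y if isinstance(y, Measurements) else np.asarray(y, dtype=float)
    y_norm = np.linalg.norm(yv)
    if y_norm == 0:
        raise ValueError("cannot set a noise SNR against all-zero measurements")
    if np.isinf(target_snr_db):
        return Measurements(y=yv.copy(), noise_snr_db=None)
    rng = np.random.default_rng(seed)
    n = rng.standard_normal(yv.size)
    n *= y_norm * 10.0 ** (-target_snr_db / 20.0) / np.linalg.norm(n)
    return Measurements(y=yv + n, noise_snr_db=float(target_snr_db))


def noise_snr_bound(snr_nf: float, snr_noise: float) -> NoiseBound:
    """Upper bound on the noisy-case SNR given the noise-free SNR and the
    noise-component SNR (linear ratios).

    When ``snr_nf <= snr_noise`` the triangle-inequality bound is vacuous
    and +infinity is returned.  In the high-noise limit the bound tends to
    ``snr_noise``: the noise floor dominates the reconstruction.
    """
    if snr_nf <= 0 or snr_noise <= 0:
        raise ValueError("SNR ratios must be positive")
    if snr_nf <= snr_noise:
        bound = np.inf
    else:
        bound = snr_nf * snr_noise / (snr_nf - snr_noise)
    return NoiseBound(snr_nf=snr_nf, snr_noise=snr_noise, bound=float(bound))


def _round_half_away(v: float) -> int:
    return int(np.floor(v + 0.5)) if v >= 0 else -int(np.floor(-v + 0.5))


def _default_params() -> dict:
    return {
        "eps_max": 1e-3,
        "n_iter_l1": 2000,
        "n_iter_greedy": 100,
        "n_iter_cosamp": 50,
        "gamma": 0.5,
        "base_seed": 0,
        "snr_cap_db": DEFAULT_SNR_CAP_DB,
    }


def _reconstruct(
    algo: str,
    A: np.ndarray,
    y: Measurements,
    k: int,
    psi: BasisMatrix,
    params: dict,
    cache: Optional[dict],
    cache_key: Optional[tuple],
) -> ReconstructionResult:
    if algo == "l1":
        # The l1 iteration does not depend on k (truncation is applied on
        # output only), so the dense solution is shared across SM cells.
        if cache is not None and cache_key in cache:
            dense = cache[cache_key]
        else:
            dense = l1_reconstruct(
                A, y, psi,
                eps_max=params["eps_max"],
                n_iter=params["n_iter_l1"],
            )
            if cache is not None:
                cache[cache_key] = dense
        coeffs = reduce_k(dense.x, psi, k)
        return ReconstructionResult(
            coefficients=coeffs,
            frame=psi.matrix @ coeffs.x,
            iterations=dense.iterations,
            converged=dense.converged,
            residual_trace=dense.residual_trace,
            warnings=list(dense.warnings),
        )
    if algo == "omp":
        return omp_reconstruct(A, y, k, psi)
    if algo == "cosamp":
        return cosamp_reconstruct(
            A, y, k, psi,
            gamma=params["gamma"],
            n_iter=params["n_iter_cosamp"],
        )
    if algo == "niht":
        return niht_reconstruct(A, y, k, psi, n_iter=params["n_iter_greedy"])
    raise ValueError(f"unknown algorithm {algo!r}; expected one of {ALGORITHMS}")


def run_cell(
    frames: Sequence[SignalFrame],
    algo: str,
    basis: BasisMatrix,
    CF: float,
    SM: float,
    noise_snr_db: Optional[float] = None,
    seeds: Optional[Sequence[int]] = None,
    params: Optional[dict] = None,
    cache: Optional[dict] = None,
) -> dict:
    """Evaluate one operating point over a set of frames.

    ``M = round(CF * N)`` and ``k = round(SM * M)`` (half away from zero,
    minimum 1).  Each frame gets its own Bernoulli matrix seeded as
    ``base_seed + frame.index`` unless an explicit seed list is given, so
    frame averages are not conditioned on a single matrix draw.  A cell
    whose preconditions fail (e.g. ``k > M`` for a greedy solver) is
    returned flagged rather than raised, so sweeps run to completion.
    """
    if not frames:
        raise ValueError("run_cell requires at least one frame")
    p = _default_params()
    if params:
        p.update(params)
    N = frames[0].n
    M = max(1, _round_half_away(CF * N))
    k = max(1, _round_half_away(SM * M))
    row = {
        "algorithm": algo,
        "basis": basis.kind,
        "CF": CF,
        "SM": SM,
        "noise_snr_db": noise_snr_db,
        "N": N,
        "M": M,
        "k": k,
        "n_frames": len(frames),
        "mean_snr_db": np.nan,
        "std_snr_db": np.nan,
        "mean_iterations": np.nan,
        "flagged": False,
        "message": "",
    }
    snrs, iters = [], []
    try:
        for i, frame in enumerate(frames):
            seed = int(seeds[i]) if seeds is not None else p["base_seed"] + frame.index
            phi = build_bernoulli_matrix(M, N, seed)
            y = encode(frame, phi)
            if noise_snr_db is not None:
                y = add_noise(y, noise_snr_db, seed + _NOISE_SEED_OFFSET)
            A = phi.entries @ basis.matrix
            result = _reconstruct(
                algo, A, y, k, basis, p, cache,
                cache_key=(frame.index, seed, noise_snr_db, M, basis.kind),
            )
            snrs.append(snr_db(frame.samples, result.frame, cap_db=p["snr_cap_db"]))
            iters.append(result.iterations)
    except ValueError as exc:
        row["flagged"] = True
        row["message"] = str(exc)
        return row
    row["mean_snr_db"] = float(np.mean(snrs))
    row["std_snr_db"] = float(np.std(snrs))
    row["mean_iterations"] = float(np.mean(iters))
    return row


def sweep(
    frames: Sequence[SignalFrame],
    algorithms: Sequence[str],
    basis_kinds: Sequence[str],
    cf_grid: Sequence[float],
    sm_grid: Sequence[float],
    noise_levels: Sequence[Optional[float]] = (None,),
    params: Optional[dict] = None,
    levels: Optional[int] = None,
) -> pd.DataFrame:
    """Cartesian sweep over algorithms × bases × CF × SM × noise levels.

    Returns one tidy row per cell (see :func:`run_cell`).  Bases are built
    once per kind; the l1 dense solution is cached per (frame, CF, noise)
    and shared across the SM axis.
    """
    for name, axis in [
        ("algorithms", algorithms),
        ("basis_kinds", basis_kinds),
        ("cf_grid", cf_grid),
        ("sm_grid", sm_grid),
        ("noise_levels", noise_levels),
    ]:
        if len(axis) == 0:
            raise ValueError(f"sweep grid axis {name!r} is empty")
    if not frames:
        raise ValueError("sweep requires at least one frame")
    N = frames[0].n
    bases = {kind: build_basis(kind, N, levels) for kind in basis_kinds}
    rows = []
    cache: dict = {}
    for algo, kind, cf, sm, noise in itertools.product(
        algorithms, basis_kinds, cf_grid, sm_grid, noise_levels
    ):
        rows.append(
            run_cell(
                frames, algo, bases[kind], cf, sm,
                noise_snr_db=noise, params=params, cache=cache,
            )
        )
    return pd.DataFrame(rows)
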