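"""Synthetic test signals: band-limited EMG-like frames and exactly-sparse fixtures.

Surface-EMG recordings are, to a first approximation, band-limited stochastic
processes whose amplitude is modulated by muscle activation: quiescent
baseline interrupted by bursts during contractions.  The generator emulates
that structure with seeded Gaussian noise shaped to the classical
surface-EMG power spectrum of Shwedyk et al. (a band-pass characteristic
peaking near 80–120 Hz and rolling off as 1/f^4 above),

    P(f)  ∝  fh^4 f^2 / ((f^2 + fl^2) (f^2 + fh^2)^2),   fl = 60 Hz, fh = 120 Hz,

band-pass filtered to the acquisition passband (default 5–500 Hz at 2 kHz,
the standard conditioning chain), multiplied by a smooth burst envelope
with raised-cosine edges, and standardised to unit RMS per frame.  The
spectral shaping matters: flat in-band noise has equal-magnitude transform
coefficients and is essentially incompressible in any basis, whereas the
decaying EMG spectrum gives the realistic k-term coefficient decay the
compression study presumes.  The generator does not model individual
motor-unit action-potential trains, electrode crosstalk or motion
artefacts.

Exactly-k-sparse fixtures (a known coefficient vector with k nonzeros and
its synthesised frame) provide ground truth for exact-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

from .bases import BasisMatrix, analyze, synthesize
from .evaluation import snr_db
from .signal_model import SignalFrame
from .sparsity_ops import SparseCoefficients, reduce_k

__all__ = ["EmgSynthesisParams", "generate_sparse_fixture", "generate_emg_like", "compressibility_report"]


@dataclass(frozen=True)
class EmgSynthesisParams:
    """Parameters of the EMG-like generator.

    Defaults reflect a typical surface-EMG acquisition chain: 2 kHz sampling
    with 5–500 Hz analogue conditioning, about one contraction burst per
    second lasting 0.3 s, with an active/rest amplitude ratio of 8.
    """

    fs: float = 2000.0
    N: int = 1024
    band: tuple = (5.0, 500.0)
    burst_rate: float = 1.0
    burst_duration: float = 0.3
    burst_gain: float = 8.0
    #: corner frequencies (Hz) of the Shwedyk spectral-shape model
    shape_fl: float = 60.0
    shape_fh: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high < self.fs / 2:
            raise ValueError(
                f"passband {self.band} must satisfy 0 < low < high < fs/2 = {self.fs / 2}"
            )
        if self.burst_duration * self.burst_rate >= 1.0:
            raise ValueError("bursts must not overlap: burst_duration * burst_rate < 1")


def generate_sparse_fixture(
    N: int, k: int, psi: BasisMatrix, seed: int, fs: float = 2000.0
) -> tuple[SignalFrame, SparseCoefficients]:
    """Exactly-k-sparse ground truth: coefficients x and the frame ``f = Psi x``.

    The k support indices are drawn uniformly without replacement; the
    coefficient magnitudes are log-uniform in [0.1, 1] (a decade of dynamic
    range, so support identification is non-trivial) with random signs.
    """
    if not 1 <= k <= N:
        raise ValueError(f"k={k} must lie in [1, {N}]")
    if psi.n != N:
        raise ValueError("basis dimension must equal N")
    rng = np.random.default_rng(seed)
    support = rng.choice(N, size=k, replace=False)
    magnitudes = 10.0 ** rng.uniform(-1.0, 0.0, size=k)
    signs = rng.choice([-1.0, 1.0], size=k)
    x = np.zeros(N)
    x[support] = magnitudes * signs
    coeffs = reduce_k(x, psi, k)
    frame = SignalFrame(samples=synthesize(psi, coeffs.x), fs=fs, index=1)
    return frame, coeffs


def _burst_envelope(params: EmgSynthesisParams, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Rest-level-1 envelope with raised-cosine-edged bursts at burst_gain."""
    fs = params.fs
    env = np.ones(n_samples)
    period = 1.0 / params.burst_rate
    ramp = min(0.05, params.burst_duration / 4.0)  # seconds per cosine edge
    burst_len = int(round(params.burst_duration * fs))
    ramp_len = max(1, int(round(ramp * fs)))
    edge = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_len) / ramp_len))
    shape = np.ones(burst_len)
    shape[:ramp_len] = edge
    shape[-ramp_len:] = edge[::-1]
    t = 0.0
    while True:
        # jitter the onset within the free part of each period
        slack = period - params.burst_duration
        onset = t + rng.uniform(0.1, 0.9) * slack
        start = int(round(onset * fs))
        if start >= n_samples:
            break
        stop = min(start + burst_len, n_samples)
        env[start:stop] += (params.burst_gain - 1.0) * shape[: stop - start]
        t += period
    return env


def generate_emg_like(params: EmgSynthesisParams, n_frames: int) -> list[SignalFrame]:
    """Generate ``n_frames`` frames of band-limited, burst-modulated noise.

    White Gaussian noise is shaped to the Shwedyk surface-EMG spectrum in
    the frequency domain, band-pass filtered with a zero-phase 4th-order
    Butterworth (zero-phase so the burst envelope is not skewed), multiplied
    by the burst envelope, split into frames of length N and standardised to
    unit RMS per frame.  Deterministic per seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(params.seed)
    n_samples = n_frames * params.N
    white = rng.standard_normal(n_samples)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / params.fs)
    f2 = freqs**2
    fl2, fh2 = params.shape_fl**2, params.shape_fh**2
    shape = np.sqrt(fh2**2 * f2 / ((f2 + fl2) * (f2 + fh2) ** 2 + 1e-30))
    shaped = np.fft.irfft(np.fft.rfft(white) * shape, n_samples)
    sos = scipy.signal.butter(
        4, params.band, btype="bandpass", fs=params.fs, output="sos"
    )
    band = scipy.signal.sosfiltfilt(sos, shaped)
    signal = band * _burst_envelope(params, n_samples, rng)
    frames = []
    for i in range(n_frames):
        chunk = signal[i * params.N : (i + 1) * params.N]
        rms = np.sqrt(np.mean(chunk**2))
        frames.append(
            SignalFrame(samples=chunk / rms, fs=params.fs, index=i + 1)
        )
    return frames


def compressibility_report(
    frames: list[SignalFrame], psi: BasisMatrix, k_grid: list[int]
) -> pd.DataFrame:
    """k-term approximation quality of each frame in a basis.

    For each frame f and sparsity k, reports the SNR between f and its best
    k-term approximation ``Psi [Psi^T f]_k`` — the quantity that bounds what
    any k-sparse reconstruction can achieve and underlies basis comparison.
    Columns: frame, k, snr_db.
    """
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    rows = []
    for frame in frames:
        x = analyze(psi, frame.samples)
        for k in k_grid:
            approx = synthesize(psi, reduce_k(x, psi, int(k)).x)
            rows.append(
                {
                    "frame": frame.index,
                    "k": int(k),
                    "snr_db": snr_db(frame.samples, approx),
                }
            )
    return pd.DataFrame(rows)
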