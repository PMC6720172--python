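# Methods

This note records the models implemented in `emgcs`, the numerical choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real recordings.

## Sensing model

A frame is a vector f ∈ R^N (default N = 1024) cut from a single-channel
recording without overlap; a trailing remainder shorter than N is dropped.
Measurements are y = Φf with Φ an M×N matrix of i.i.d. fair ±1 entries
drawn row-major from one seeded NumPy `default_rng` stream, so a matrix is
a pure function of (M, N, seed). Entries are kept as raw ±1 (no 1/√M
scaling): none of the implemented algorithms depends on the overall scale
of A = ΦΨ, and raw signs match the multiplication-free accumulation a
hardware encoder would use.

Compression bookkeeping: CR = N/M, CF = M/N, SN = k/N, SM = k/M, with
SM = CR·SN. Grids specify CF and SM as reals; M = round(CF·N) and
k = round(SM·M) use round-half-away-from-zero with a floor of 1, since SM
grids rarely hit integers.

The coherence diagnostic is reported as ν = √N · max |⟨φᵢ/‖φᵢ‖, ψⱼ/‖ψⱼ‖⟩|,
which places ν in [1, √N]: random sensing rows against any fixed basis sit
near 1, aligned spike pairs at √N.

## Bases

All three bases are dense orthonormal N×N synthesis matrices (a deliberate
choice: the algorithms are formulated on the explicit product A = ΦΨ, and
at N = 1024 a dense basis is ~8 MB).

- **DCT**: orthonormal type-II (synthesis = IDCT of the canonical unit
  vectors).
- **Haar / DB4**: columns are the inverse discrete wavelet transform of
  the canonical coefficient unit vectors of a dyadic filter bank
  (PyWavelets), with **periodic boundary handling** — the only extension
  mode for which the square filter-bank matrix is exactly orthonormal.
  Decomposition depth defaults to full depth (log₂N) for Haar and
  log₂N − 3 for DB4, keeping every sub-band longer than the filter;
  both are configurable.
- "DB4" follows the prevailing software naming: the Daubechies family
  member with four vanishing moments (8 taps, `"db4"`). Users preferring
  the 4-tap reading can pass `wavelet="db2"`.

Support selection weighs coefficients by basis-column norm,
γᵢ = |xᵢ|·‖ψᵢ‖₂, with ties broken toward the lower index so every run is
reproducible. For the orthonormal bases the weights are all 1 and γ reduces
to plain magnitude; the weighted form is what is implemented. The support
returned by `supp_k` always has cardinality k, admitting zero-valued
indices when the vector has fewer than k nonzeros.

## ℓ₁ solver

The basis-pursuit problem min ‖x‖₁ s.t. Ax = y is solved by projected
sub-gradient descent entirely inside the feasible affine space:

    x₀ = A⁺y,   A⁺ = Aᵀ(AAᵀ)⁻¹,   P = I − A⁺A,
    x_{t+1} = x_t − μ (‖x_t‖₁/N) P sgn(x_t).

Since AP = 0, feasibility ‖Ax_t − y‖ ≤ 1e−8·‖y‖ holds at every iterate
(verified by test). The normalisation ‖x_t‖₁/N decouples μ from signal
power; μ is set once from the target steady-state ripple ε_max as
μ = ε_max·N/‖P sgn(x₀)‖₂. Numerical choices:

- **sgn(0) = 0.** The update then simply leaves zero coordinates alone;
  transitions through zero are treated as sign changes by the incremental
  update.
- **Incremental update.** q_t = P sgn(x_t) is patched between iterations
  by summing projector columns only at coordinates whose sign changed
  (Δ = ±2 for a full flip, ±1 through zero), preserving q_t = P sgn(x_t)
  to machine precision; the per-iteration cost is proportional to the
  number of sign changes instead of N².
- **Convergence** is declared when the relative iterate change (ripple)
  stays below ε_max for 5 consecutive iterations — a single sub-tolerance
  ripple is noise. Defaults: ε_max = 1e−3, iteration cap 2000.
- ‖P sgn(x₀)‖ below 1e−9·√N is treated as an exact fixed point (covers
  the determined case M = N, where P = 0 up to rounding and x₀ = A⁻¹y).
- AAᵀ with condition number above 1e12 is refused rather than silently
  pseudo-inverted.
- The sparsity parameter k plays no role inside the iteration; when given,
  the output is hard-truncated to its k largest weighted coefficients,
  with no least-squares refit on that support.

## Greedy solvers

All three share correlation-based selection (top-m |aⱼᵀr|, ties to the
lower index) and least-squares refits computed by complete orthogonal
factorisation (`gelsy`), which returns the minimum-norm solution and a
flag instead of failing on rank-deficient supports — so large sweeps run
to completion.

- **OMP** runs exactly k iterations, one column per iteration, maintaining
  an incrementally updated QR factorisation of the selected columns (with
  a second Gram–Schmidt pass for orthogonality); the refit never needs to
  be re-solved from scratch and equals the `lstsq` refit to 1e−8 (tested).
  The residual is orthogonal to every selected column, so no column is
  selected twice; a numerical guard masks selected columns anyway.
- **CoSaMP** selects kS = max(1, round(γk)) candidates per iteration
  (γ defaults to 0.5; γ = 0 is clamped to one column), merges, refits on
  the ≤ k + kS columns, prunes to k, and requires k + kS ≤ M so the merged
  refit stays over-determined.
- **NIHT** starts from a least-squares fit on the k best-correlated
  columns. Each outer iteration forms the per-coordinate normalised
  gradient q = ρ ⊙ Aᵀ(Ax − y), ρⱼ = minᵢ‖aᵢ‖/‖aⱼ‖, and takes the scalar
  step μ = (wᵀε)/(wᵀw) with w = A q|_Λ★, ε = A x|_Λ★ − y — the exact
  minimiser of the residual on the proposed support (tested against a
  golden-section line search). Because μ depends on the support selected
  *after* the step, the inner loop alternates step and re-thresholding
  until the support stops changing, capped at 10 passes; the first outer
  iteration steps on the full index set, where no support proposal exists
  yet.
- **Stopping** (CoSaMP/NIHT): iteration cap (defaults 50/100), relative
  residual change below 1e−8, or — an addition beyond the published
  pseudo-code — no residual improvement for 3 consecutive iterations.
  Without the stagnation stop, noisy sweep cells always burn the full cap
  while the residual plateaus.

A structural property worth knowing: NIHT's least-squares initialisation
leaves the residual orthogonal to the initial support, so when the
correlation-based init misses the true support and the off-support
normalised gradient is smaller than the kept coefficients, the iteration
sits at an exact fixed point. At generous sampling ratios (M ≳ 12× the
sparsity) this never bites — recovery is 100/100 at N = 256, M = 128,
k = 8 — but at M = 8k the measured exact-recovery rate drops to 77–85%
depending on the basis, consistent with NIHT's reputation as the least
accurate of the four.

## Evaluation

Reconstruction quality is the equivalent SNR in dB between the *original*
frame and Ψx̂ (a flag selects measurement-domain SNR instead). Perfect
reconstructions report a 300 dB cap so tables stay finite. Noise is
injected in the measurement domain with exact-norm scaling:
20·log₁₀(‖y‖/‖n‖) equals the requested level to rounding, not merely in
expectation.

Each frame in a sweep cell gets its own Bernoulli matrix (seed =
base_seed + frame index) so frame averages are not conditioned on one
matrix draw; the noise seed adds a fixed offset to the matrix seed. Cells
whose preconditions fail (e.g. k > M for a greedy solver, or k + kS > M
for CoSaMP) are returned as flagged rows rather than exceptions. The ℓ₁
solution is independent of k, so sweeps cache the dense solution per
(frame, CF, noise) and re-truncate along the SM axis.

The noise-limited bound SNR ≤ SNR_NF·SNR_noise/(SNR_NF − SNR_noise)
(linear amplitude ratios; vacuous, +∞, when SNR_NF ≤ SNR_noise) follows
from the triangle inequality applied to the error decomposition
x = x_NF + A⁺n of the *untruncated* ℓ₁ solution. It is checked on the
untruncated output: hard truncation discards most of the noise component
and routinely beats the bound, which would make a naive comparison
meaningless. In the high-noise limit the bound degenerates to SNR_noise,
and since A⁺n does not depend on k, the ℓ₁ solver's noisy-case SNR is flat
in k/M — the flatness the sweep tests confirm.

## Synthetic EMG

The generator emulates a standard surface-EMG acquisition chain: seeded
white Gaussian noise shaped in the frequency domain to the classical
Shwedyk sEMG spectrum P(f) ∝ f_h⁴f² / ((f² + f_l²)(f² + f_h²)²) with
f_l = 60 Hz, f_h = 120 Hz; zero-phase 4th-order Butterworth band-pass to
the acquisition band (default 5–500 Hz at fs = 2 kHz); multiplication by a
burst envelope (rest level 1, bursts at `burst_gain` = 8, one 0.3 s burst
per second with 50 ms raised-cosine edges and seeded onset jitter — a
plausible dynamic-contraction pattern); unit RMS per frame. The spectral
shaping is essential: flat in-band noise has equal-magnitude transform
coefficients and is essentially incompressible in any basis, which would
contradict the premise of compressive acquisition. With the shaped
spectrum the DB4 k-term approximation SNR at k/N = 0.25 is ≈ 19 dB and
exceeds Haar's, and the OMP SNR-versus-SM curve at CF = 0.5 peaks at
SM ≈ 0.3–0.4 across seeds.

What the generator does **not** model: motor-unit action-potential trains
(so the within-burst signal is Gaussian rather than impulsive), electrode
crosstalk, motion artefacts, and non-stationary spectra. Real EMG is
noticeably *more* compressible than these frames; consequently the
absolute SNR levels here are conservative, and noise-robustness contrasts
that depend on a high noiseless SNR (e.g. a steep post-peak collapse of
OMP under measurement noise) are weaker on this synthetic data than on
real recordings. Passing sweeps therefore demonstrate ordering and shape
phenomena, not clinical-grade reconstruction quality.

## Problem sizes used by the test suite

Exact-recovery and noise-bound studies run at N = 256, M = 128, k = 8
(100 and 50 seeded trials); oracle comparisons use exhaustive search at
8×32 (subset selection), 12-choose-2 refits (OMP versus ℓ₀), and a 1-D
golden-section search (NIHT step). Sweep reproductions use 10–20 frames of
N = 1024. These sizes give stable averages while keeping the full suite in
the low minutes on one CPU.
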