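# Methods

This note documents the models, parameter defaults, numerical choices and
known limitations behind `mfecg`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Generalized multiscale sample entropy

A series `x_1..x_N` is coarse-grained at scale `s` into
`y_j = statistic(x_{(j−1)s+1..js})`, `j = 1..⌊N/s⌋`, with the block mean
(first moment, MSEN1) or the unbiased block variance (second moment,
MSEN2; requires `s ≥ 2`). Sample entropy of the coarse series uses
Chebyshev template matching with strict `d < r`, self-matches excluded,
and the per-order averages

```
A^m    = (1/(Ns−m+1)) Σ_i  N_m(i) / (Ns−m+1),   i = 1..Ns−m+1
A^{m+1}= (1/(Ns−m))   Σ_i  N_{m+1}(i) / (Ns−m), i = 1..Ns−m
SampEn = −ln(A^{m+1}/A^m)
```

Note the per-order denominators: with them a constant series does not give
exactly 0 but `−ln[(Nt'−1)Nt / ((Nt−1)Nt')] = O(1/Nt²)` (≈ 2.6e−5 at
Nt = 199); the degenerate constant case is special-cased to 0 at the
profile level. When either count is zero the entropy is undefined and is
reported as NaN — never imputed — and excluded from scale aggregates; a
feature is NaN when more than half of its scales are undefined.

Matching is implemented with KD-trees on the embedded vectors
(`count_neighbors` with Chebyshev metric; strict `<` is obtained exactly by
shrinking the radius one ulp). The test suite pins the implementation to a
brute-force double-loop oracle to 1e−12 across 50+ seeded series,
undefined cases included.

**Tolerance convention.** The default recomputes the tolerance per scale,
`r = r_frac · σ(coarse series)` (`r_mode='scalewise'`, `r_frac = 0.15`,
`m = 2`). This measures the *shape* of the coarse-grained fluctuations
independent of their shrinking amplitude. It also has a provable
consequence: since `SampEn(a·y, m, a·r) = SampEn(y, m, r)`, the entropy of
i.i.d. noise becomes nearly scale-free (only the marginal shape changes,
uniform → Gaussian), measured ≈ 2.47 at every scale for uniform white
noise, *above* 1/f noise (≈ 1.9). The classic multiscale-entropy
convention that produces the textbook picture — white-noise entropy
falling with scale and crossing below flat 1/f noise — fixes `r` from the
original series (`r_mode='global'`); both conventions are implemented and
both are exercised by the tests and the acceptance script. The
classification features use the scalewise default.

**Feature scales.** The per-segment features average the defined entropies
over scales 10..20 of a 64-s segment (8192 samples at 128 Hz; 16000 at
250 Hz), where the coarse series still has ≥ 400 points and class contrast
is large. Segments shorter than 32 s produce many undefined entropies and
are not recommended.

## Wavelet-leaders multifractal analysis

Pipeline: L1-normalized DWT magnitudes `d(j,k) = 2^{−j/2}|⟨x, ψ_{j,k}⟩|`
(orthonormal pyramid, 'db3' by default, `Nψ = 3`) → leaders
`L(j,k) = sup{ d(j',k') : λ_{j',k'} ⊆ 3λ_{j,k}, j' ≤ j }` → structure
functions `S(j,q) = (1/n_j) Σ_k L(j,k)^q` → `ζ(q)` as the unweighted OLS
slope of `log2 S(j,q)` against `j` over `j = j1..j2` → spectrum by the
discretized Legendre transform (`α = dζ/dq` by second-order finite
differences; `f = qα − ζ + 1`) or by the direct canonical-weights method:
with `P(j,k) = L^q(j,k)/Σ_k L^q(j,k)`, `α(q)` is the slope of
`Σ_k P log2 L` and `f(q) − 1` the slope of `Σ_k P log2 P + log2 n_j`
against `j`. The `+ log2 n_j` term makes uniform weights give slope 0, so
the returned `f` adds 1; this offset is pinned by the monofractal closed
form (uniform leaders `L = 2^{jH}` must give `α ≡ H`, `f ≡ 1`, which the
tests assert exactly).

Defaults: symmetric moment grid `q ∈ [−5, 5]`, `Δq = 0.25`; `j1 = 1`;
`j2 = ⌊log2(N/(2Nψ+1))⌋` (= 10 for N = 8192 with 'db3'). Summary features:
`α_min = α(+q_max)`, `α_0 = α(0)`, `α_max = α(−q_max)`,
`Δα = α_max − α_min`.

Numerical choices:

* **Periodized transform + bridge removal.** The pyramid uses
  `mode='periodization'`, giving exactly `⌈N/2^j⌉` coefficients per scale
  so the dyadic parent/child indexing of the leader sup is exact. Because
  periodization wraps the segment end onto its start, the linear bridge
  between first and last sample is subtracted first; wavelets with ≥ 2
  vanishing moments annihilate it in the interior, and without it a
  monotone signal (e.g. a cascade primitive) acquires a spurious
  jump singularity that saturates `ζ(q > 1)` near 1.
* **Zero leaders** (exactly-zero coefficient neighbourhoods, which arise
  only for locally polynomial signals) are floored at 1e−300 in the
  structure functions for `q ≥ 0`, excluded for `q < 0`, and dropped from
  the canonical-weight sums.
* **Uniform Hölder bounds.** `hmin`/`hmax` are regression slopes of
  `log2 sup_k d(j,k)` / `log2 min_k d(j,k)` against `j`. Because `n_j`
  halves per octave, the raw sup statistic is depleted at coarse scales
  (`sup ≈ σ_j √(2 ln n_j)` for Gaussian-tailed coefficients), biasing the
  plain slope downward by ≈ 0.1 over 13 octaves. An optional
  `depletion_correction` renormalizes the extremes (`sup/√(2 ln n_j)`,
  `min·n_j`) before the fit; it is exact for Gaussian tails and is used
  for the stochastic fixtures (fBm H = 0.7: plain ≈ 0.59, corrected
  ≈ 0.68). The plain form remains the default.
* **Wavelet adequacy.** `check_wavelet_adequacy` applies the sufficient
  condition `hmax < min(rψ, Nψ)` with the conservative convention
  `rψ = Nψ` for Daubechies wavelets.

**Known estimator limitation.** On the binomial-cascade primitive
(`2^14` cells, weights 0.6/0.4, analytic `ζ(q) = 1 − log2(0.6^q+0.4^q)`),
the leaders estimate of `ζ` carries a finite-resolution bias: the ratio of
a leader to the underlying interval mass drifts over the first ~6 octaves
(a transient of initializing the pyramid from point samples), leaving too
few clean octaves at this length. Measured worst-case error over
`q ∈ [−2, 5]` is ≈ 0.25–0.5 at `2^14` cells, halving by `2^18`; an oracle
fed the exact interval masses recovers the closed form almost exactly, so
the bias is in the coefficient statistics, not the formula chain. The two
spectrum estimators (Legendre vs canonical weights) agree to < 0.03 on the
same data, and monofractal recovery on fBm is accurate
(`α_0 = 0.69 ± 0.01` at H = 0.7, `Δα ≈ 0.19`, 20-seed means, n = 65536).

## Denoising

8-level 'bior2.6' decomposition with symmetric extension; the level-8
approximation (baseline wander, < 0.25 Hz at 128 Hz) is zeroed and the two
finest detail bands are soft-thresholded with the universal threshold
`σ̂ √(2 ln N)`, `σ̂ = MAD(d_1)/0.6745`. Requires > 256 samples. The
operation is idempotent to < 5‰ RMS and preserves a clean PQRST template
under a slow drift (correlation ≥ 0.9, asserted in tests).

## Extreme learning machine

Features are z-scored with training statistics (sigmoids saturate on raw
entropy/exponent scales — an addition to the bare formulation). Hidden
weights and biases are `U[−1, 1]` from a seeded generator; hidden layer
`H = sigmoid(ZW + b)` with `l = 60` nodes by default; output weights
`β = pinv(H)·T` (SVD pseudoinverse, relative cutoff 1e−12) for one-hot
targets; prediction is the class argmax with ties to the lower index. The
model is bit-reconstructible from (seed, dims, activation, scaler, β) and
serializes to JSON.

## Evaluation protocol

Stratified 5-fold cross-validation (plain "equal parts" splitting could
leave a fold without the minority class on unbalanced sets). Per-fold
confusion matrices are pooled before computing the headline metrics —
pooling reproduces the published tables' arithmetic exactly — and per-fold
metrics plus their plain averages are reported alongside. The positive
class is Normal (NSR): the published sensitivity values are computed over
the Normal row, which fixes the TP convention despite contradictory prose
definitions. Percentages are rounded half-up to two decimals. Recomputing
precision and F1 from the published Set-A/Set-B matrices differs from the
printed values by one unit in the last decimal (99.45 vs 99.44, 99.63 vs
99.62, 99.45 vs 99.46, 99.72 vs 99.73) — rounding artifacts of the source
tables; accuracy, sensitivity and specificity reproduce exactly.
`compare_classifiers` runs identical folds through the ELM, an RBF-kernel
SVM (γ = 0.05) and KNN with `k = round(√(training size))`; that rule
gives k = 27 for 720 training segments.

## Synthetic data

The generator exists so every stage is testable without downloads:

* `white_noise` — i.i.d. uniform, zero-centred.
* `one_over_f_noise` — uniform white noise, FFT, amplitude × `1/√f`
  (power ∝ 1/f), DC zeroed, inverse FFT; periodogram slope −1 ± 0.2.
* `binomial_cascade(J, p)` — primitive of a deterministic binomial measure
  on `2^J` cells (per-node weight order shuffled when seeded); carries the
  closed forms `τ(q) = −log2(p^q + (1−p)^q)`, `ζ = 1 + τ`, and analytic
  `α(q)`.
* `fbm(n, H)` — circulant-embedding (Davies–Harte) synthesis; exact
  increment autocovariance `γ(k) = (|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})/2`.
* `synthetic_ecg` — a fixed PQRST template (five Gaussians: P 0.12 mV at
  −200 ms, Q −0.10 at −30 ms, R 1.0 at 0, S −0.15 at +30 ms, T 0.30 at
  +250 ms; widths 25/10/12/10/45 ms) repeated at ~1 Hz plus a 0.05-Hz
  baseline drift. The classes differ *only* in the stochastic part, making
  complexity the controlled variable: NSR-like adds 6% 1/f-correlated RR
  jitter and 0.12 mV 1/f noise; CHF-like adds 0.5% jitter and 0.04 mV
  white noise. Jitter and noise levels were chosen once so that the
  coarse-grained entropy ordering (NSR > CHF at scales 10–20) is large
  against cohort variance, mirroring the separation reported for real
  recordings.

What the fixtures do **not** emulate: real ECG morphology variation,
arrhythmic beats, electrode artifacts, class-dependent waveform changes,
or any physiological CHF mechanism — the synthetic classes encode only the
large-scale complexity ordering. Perfect synthetic classification
therefore validates the pipeline's mechanics, not clinical performance;
real-data reproduction requires the PhysioNet databases
(`scripts/reproduce_physionet.py`).

## Problem sizes used in the automated checks

Noise benchmarks use n = 65536 samples; the cascade fixture `2^14` cells;
fBm 20 × 65536; the classification check 60 + 60 denoised 64-s segments at
128 Hz with 5-fold cross-validation and 10 label-shuffled controls. The
full suite and the acceptance script each run in well under a minute of
CPU apiece on a single core.
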