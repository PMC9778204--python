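# mfecg

Complexity features for ECG classification: **generalized multiscale sample
entropy** and **wavelet-leaders multifractal spectra**, combined with an
**extreme learning machine** (ELM), to separate normal-sinus-rhythm (NSR)
from congestive-heart-failure (CHF) recordings — without R-peak detection.

Congestive heart failure alters the beat-to-beat complexity of the ECG:
healthy hearts produce signals whose fluctuations stay irregular across a
wide range of time scales, while failing hearts produce more regular,
lower-complexity traces. `mfecg` quantifies this with two complementary
tools and classifies segments with a one-shot-trained neural network.

## The method

**Generalized multiscale entropy.** A segment `x_1..x_N` is coarse-grained
at scale `s` by replacing non-overlapping blocks of length `s` with the
block mean (first moment, MSEN1) or the unbiased block variance (second
moment, MSEN2). The sample entropy

```
SampEn(m, r) = −ln( A^{m+1}(r) / A^m(r) )
```

is computed per scale with Chebyshev template matching, self-matches
excluded, embedding `m = 2`, and tolerance `r = 0.15 σ_s`, where `σ_s` is
the standard deviation of the coarse-grained series of that scale. The
per-segment feature is the mean entropy over scales `s = 10..20` of a 64-s
segment.

**Wavelet-leaders multifractal analysis.** L1-normalized discrete wavelet
coefficients `d(j,k) = 2^{−j/2}⟨x, ψ_{j,k}⟩` ('db3') are turned into
leaders `L(j,k)` — the sup of coefficient magnitudes over all
finer-or-equal scales inside the dyadic interval plus its two neighbours.
Structure functions `S(j,q) = ⟨L(j,k)^q⟩_k` scale as `2^{j ζ(q)}`; the
scaling function `ζ(q)` (fit over `j = 1..⌊log2(N/7)⌋`, `q ∈ [−5, 5]` in
steps of 0.25) yields the singularity spectrum either by Legendre
transform, `α = dζ/dq`, `f(α) = qα − ζ(q) + 1`, or directly from the
canonical weights `P(j,k) ∝ L^q(j,k)` (matrix-entropy method). The
classification features are `α_0 = α(0)` (spectrum apex) and
`α_min = α(q = 5)` (strength of the largest fluctuations).

**Classifier.** A 60-node ELM: random uniform input weights, logistic
hidden units, output weights solved once by pseudoinverse. Evaluation uses
stratified 5-fold cross-validation; per-fold confusion matrices are pooled
and accuracy, precision, sensitivity, specificity and F1 are reported in
percent (NSR is the positive class).

Preprocessing removes baseline wander and high-frequency noise by an
8-level 'bior2.6' wavelet decomposition (coarsest approximation zeroed,
two finest detail bands soft-thresholded); segments must be longer than
256 samples.

## Worked example

Sixty synthetic 64-s segments (30 per class at 128 Hz; the package ships a
seed-deterministic generator whose two ECG-like classes differ only in
their noise and beat-timing processes):

```python
import numpy as np
from mfecg import (SegmentFeaturizer, denoise, run_pipeline, synthetic_ecg)

segs, labels = [], []
for i in range(30):
    for kind, lab in (("ecg_nsr_like", "NSR"), ("ecg_chf_like", "CHF")):
        sig = synthetic_ecg(kind, fs=128, duration=64,
                            seed=50 * i + (0 if lab == "NSR" else 25))
        segs.append(denoise(sig.values))
        labels.append(lab)
labels = np.array(labels)
X = SegmentFeaturizer().transform(segs)   # columns: MSEN1, MSEN2, α0, αmin
for lab in ("NSR", "CHF"):
    m = X[labels == lab].mean(axis=0)
    print(f"{lab}-like cohort means: MSEN1={m[0]:.3f} MSEN2={m[1]:.3f} "
          f"alpha0={m[2]:.3f} alpha_min={m[3]:.3f}")
rep = run_pipeline(X, labels, K=5, n_hidden=60, seed=0)
print("pooled 5-fold metrics:", rep.metrics)
```

which prints

```
NSR-like cohort means: MSEN1=2.368 MSEN2=0.620 alpha0=0.585 alpha_min=0.148
CHF-like cohort means: MSEN1=1.174 MSEN2=0.481 alpha0=0.662 alpha_min=0.129
pooled 5-fold metrics: {'ACC': 100.0, 'PPV': 100.0, 'SEN': 100.0, 'SPE': 100.0, 'F1': 100.0}
```

The NSR-like class keeps a much higher first-moment multiscale entropy
(2.37 vs 1.17): its 1/f noise and beat jitter survive coarse-graining,
whereas the CHF-like class's low-amplitude white noise averages away,
leaving a nearly periodic — hence low-entropy — coarse series. With this
separation the cross-validated ELM classifies every held-out segment
correctly; a label-shuffled control sits at chance (~50%).

A command-line interface mirrors the library:

```bash
mfecg simulate --kind ecg_nsr_like --fs 128 --duration 64 --seed 1 --out nsr.csv
mfecg preprocess --in nsr.csv --label NSR --segment-seconds 64 --out segments/
mfecg entropy --in nsr.csv --scales 10:20 --m 2 --r 0.15
mfecg mfa --in nsr.csv --wavelet db3 --qmax 5 --dq 0.25
mfecg run --data segments/ --hidden 60 --folds 5 --seed 0
mfecg metrics --tp 539 --tn 357 --fp 3 --fn 1
```

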