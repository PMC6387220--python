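# emgburg

Classification of surface electromyography (sEMG) hand movements from
Burg maximal-entropy reflection coefficients and standard time-domain
features.

## The problem

Myoelectric control — prosthetics, rehabilitation devices, muscle–machine
interfaces — needs to tell hand gestures apart from a few forearm
electrodes, cheaply enough to run on embedded hardware. This package
implements a complete pipeline for that task: minimal signal
conditioning, linear-complexity feature extraction, labelled dataset
assembly, feature selection, and a cross-validated classifier benchmark.
The protocol it targets records the flexor carpi ulnaris and extensor
carpi radialis at 500 Hz while five subjects perform six grasps
(spherical, tip, palmar, lateral, cylindrical, hook) thirty times for
6 s each — 900 two-channel trials, 1800 single-channel series.

## The model at the core

Each conditioned channel x(n), n = 0..N−1, is summarised by an
order-p autoregressive model estimated with the Burg lattice. The
lattice filter propagates forward and backward prediction errors

    f_0(n) = b_0(n) = x(n)
    f_m(n) = f_{m−1}(n) + K_m b_{m−1}(n−1)
    b_m(n) = K_m f_{m−1}(n) + b_{m−1}(n−1)

and chooses each reflection coefficient K_m to minimise the summed error
power ε_m = Σ_n [f_m(n)² + b_m(n)²], giving

    K_m = −2 Σ f_{m−1}(n) b_{m−1}(n−1) / Σ [f_{m−1}(n)² + b_{m−1}(n−1)²]

— a harmonic-mean-normalised cross-correlation, so |K_m| ≤ 1 always.
The AR coefficients follow by the Levinson step-up
a_m(k) = a_{m−1}(k) + K_m a_{m−1}(m−k), a_m(m) = K_m. The vector
K = [K_1 .. K_10] per channel is the pattern used for classification,
alongside the AR coefficients (Arb) and ten time-domain features
(IEMG, MAV, SSI, VAR, RMS, WL, WAMP, SSC, ZC, MYOP).

A synthetic corpus generator produces gesture classes as stationary AR
processes with distinct per-class reflection coefficients, amplitude
envelopes, silent lead-ins and measurement noise, so the entire pipeline
is testable without downloading any recordings.

## Worked example

```python
import numpy as np
from emgburg import (BurgAR, ModelSpec, ProtocolConfig, build_dataset,
                     crossval, simulate_ar, simulate_corpus)

# fit one AR(2) model on a simulated zero-mean series
x = simulate_ar([0.6, -0.4], 2000, np.random.default_rng(0))
print(BurgAR(x, order=2).fit().summary())

# full pipeline: corpus -> reflection-coefficient dataset -> 10-fold CV
corpus = simulate_corpus(ProtocolConfig(seed=42))       # 900 recordings
ds = build_dataset(corpus, "K")                         # 900 x 20 features
print(crossval(ds, ModelSpec("knn", {"k": 1}), k_folds=10, seed=42).summary())
```

prints

```
Burg AR model (lattice / maximal entropy)
  order: 2    nobs: 2000    sigma2: 0.9872
  stage           K_m        a_p(m)           eps_m
      1      0.584311      0.355667         4659.44
      2     -0.391305     -0.391305         3944.85

knn(k=1)                     acc 100.00%  wauc 1.000  sens 1.000  spec 1.000  (10-fold, seed 42)
```

The first block is the fitted lattice: the generating reflection
coefficients (0.6, −0.4) are recovered to about ±0.02, the final-stage
coefficient equals K_2, and the error power ε_m decreases stage by
stage; sigma2 ≈ 1 matches the unit-variance innovations. The second
line is the cross-validated benchmark on the synthetic corpus: with the
default well-separated class bank, 1-nearest-neighbour classifies every
held-out trial correctly from 20 reflection coefficients.

The same pipeline is available from the shell:

```
emgburg simulate --out corpus --seed 42
emgburg build --corpus corpus --variant K --out k.csv
emgburg classify --in k.csv --model knn --k 1 --folds 10 --report report.csv
```

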