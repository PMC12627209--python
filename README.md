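# ffr — Feature Frequency Report simulation and analysis

`ffr` is a Python toolkit for the *Feature Frequency Report* (FFR)
paradigm in ensemble perception. In an FFR trial an observer briefly
sees 36 colored disks whose hues form a fixed, symmetric distribution
(gaussian, uniform, or bimodal) around a random mean on a 48-hue
circular color wheel (neighboring hues ≈ 1 JND apart), and then reports
on a 0–8 slider how many disks had a probed hue. The probed hue lies
0, ±3, …, ±21 JND from the mean — inside the presented ±12 JND range or
up to 9 JND beyond it. Because the response curve over probe offsets
traces the *shape* of the presented distribution, the paradigm tests
whether observers have explicit access to feature distributions rather
than just summary statistics.

The package is for researchers who want to simulate FFR sessions,
analyze response curves (their own or simulated), and test the
*sub-sampling* alternative account by model fitting.

## What it does

- **Stimuli** (`ffr.stimuli`): the color wheel, the three exemplar-count
  distributions (gaussian 8/7/4/2/1 per side, uniform 4 per value,
  bimodal 0/2/3/6/7), trial and session generation with intermixed
  conditions; CSV round-tripping (`ffr.io`).
- **Observer models** (`ffr.observers`): the sub-sampling observer —
  Gaussian perceptual noise with SD σ on each hue, a random sample of
  *N* of the 36 disks, a count of noisy hues that round to the probe,
  extrapolated by a uniform random integer multiplier in
  [1, ⌊36/N⌋] and clipped to the slider — plus a veridical-noisy
  observer used as an analysis-stage fixture.
- **Response curves** (`ffr.curves`): folding of ±k offsets, per-observer
  and aggregated curves with SEM, and paired t-tests (with Cohen's *d*)
  of the mean-offset response against every other offset.
- **Segmented regression** (`ffr.segmented`): two-segment broken-line
  fits y = β₀ + β₁x + (β₂−β₁)(x−ψ)₊ with the break point ψ estimated by
  iterative linearization, delta-method CIs, a conservative Davies-type
  test for the existence of a slope change, fixed-ψ per-observer slopes,
  and group slope t-tests.
- **Model fitting** (`ffr.fitting`): the *exact* response distribution of
  the sub-sampling observer, computed by dynamic programming over disks
  (a hypergeometric average of Poisson-binomial match counts), exact
  maximum-likelihood fitting of (N, σ) by exhaustive search over N with
  bounded scalar optimization of σ, and a simulate-and-refit parameter
  recovery study.
- **CLI** (`ffr.cli`): `ffr simulate | analyze | fit | recover`.

## Worked example

Simulate ten sub-sampling observers (N = 30, σ = 5 JND, 450 trials
each), analyze, and fit one observer:

```python
import ffr

sessions = []
for i in range(10):
    s = ffr.generate_session(450, observer_id=f"o{i}", seed=100 + i)
    sessions.append(ffr.simulate_dataset(s, ffr.SubsamplingParams(30, 5.0), seed=200 + i))

# folded response curves and the slope signature of each shape
import numpy as np
for cond in ffr.CONDITIONS:
    x = np.array([abs(t.test_offset) for s in sessions for t in s.trials if t.condition == cond], float)
    y = np.array([t.response for s in sessions for t in s.trials if t.condition == cond], float)
    f = ffr.fit_broken_line(x, y)
    print(f"{cond:9s} psi={f.psi:5.2f}  b1={f.b1:+.3f}  b2={f.b2:+.3f}  davies p={f.davies_p:.2g}")

fit = ffr.fit_mle(sessions[0])
print(f"MLE: N={fit.params_hat.N}, sigma={fit.params_hat.sigma:.2f}")
```

Output:

```
gaussian  psi=13.58  b1=-0.113  b2=-0.034  davies p=1e-06
uniform   psi= 6.89  b1=+0.009  b2=-0.070  davies p=7.3e-06
bimodal   psi=10.64  b1=+0.043  b2=-0.095  davies p=3.1e-23
MLE: N=28, sigma=5.08
```

The slope pattern mirrors the presented shapes: the gaussian curve falls
from the mean (b₁ < 0), the uniform curve is flat inside the range
(b₁ ≈ 0) and falls beyond it (b₂ < 0), and the bimodal curve rises
toward its ±12 JND peaks (b₁ > 0) before falling (b₂ < 0). The Davies
p-values reject a single straight line in every condition, and the MLE
recovers the generating parameters.

The same pipeline runs from the shell:

```bash
ffr simulate --seed 1 --n-trials 450 --out run1
ffr analyze run1/session.csv --out run1
ffr fit run1/session.csv --out run1/fit.json
ffr recover --seed 1 --n-runs 400 --out recovery
```

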