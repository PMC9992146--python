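# cestmrf

Quantitative CEST and semisolid-MT MR fingerprinting at desk scale:
Bloch-McConnell simulation, dictionary matching, synthetic digital
phantoms, a dictionary-trained reference quantifier, and a conditional
adversarial network that reconstructs exchange-parameter maps from a
truncated acquisition.

## The problem

Saturation-transfer MRI (CEST for mobile solutes such as amide or amine
protons; semisolid MT for macromolecules) encodes millimolar chemistry in
the water signal: selectively saturated solute protons exchange with water
at rate *k*<sub>sw</sub>, attenuating it in proportion to the exchangeable
proton fraction *f*<sub>s</sub>.  Fingerprinting makes this quantitative —
a pseudo-random saturation schedule produces a per-voxel signal trajectory
that is matched against Bloch-McConnell-simulated dictionaries — but needs
many (M ≈ 30) encoding images, and brute-force matching is slow.

This package implements and validates, on fully synthetic data, the
accelerated alternative: a pix2pix-style conditional GAN that maps only the
**first N = 9** raw images (70% fewer acquisitions; images can only be
dropped from the schedule's *end*, because spin history carries across
entries) directly to the proton volume-fraction and exchange-rate maps,
trained against a fully connected reference network that sees all M = 30
images.  The generator (a U-Net) and a conditional patch discriminator are
trained with the composite objective

&nbsp;&nbsp;&nbsp;&nbsp;*L*<sub>total</sub> = λ₁*L*₁ + λ₂*L*<sub>adv</sub> + λ₃*L*<sub>tv</sub> + λ₄*L*<sub>p</sub>

(pixelwise ℓ₁ content, adversarial, total-variation and perceptual terms).
Because no scanner data ship with the package, a synthetic-phantom module
generates the study world: L-arginine vials (25–100 mM, pH 4–6, exchange
rate tied to pH through base catalysis *k*<sub>sw</sub> = *k*₀ +
*k*<sub>base</sub>·10^(pH−6)) and procedural brain-like scenes with
literature WM/GM semisolid parameters, plus Rician noise and localized
B0/susceptibility artifacts.

## A worked example

```python
import numpy as np
from cestmrf import (PoolParameters, TissueParameters,
                     generate_pseudorandom_schedule, simulate_schedule)

tissue = TissueParameters(
    water=PoolParameters(t1=2.5, t2=0.8),
    solute=PoolParameters(t1=1.0, t2=0.04, chemical_shift=3.0,
                          exchange_rate=400.0, volume_fraction=1.35e-3))
schedule = generate_pseudorandom_schedule(m=30, mode="cest_3ppm", seed=7)
signal = simulate_schedule(tissue, schedule)
print(np.round(signal[:5], 5))
```

prints

```
[0.09025 0.13505 0.07847 0.19457 0.11211]
```

— the first five raw saturation-encoded signals (water M<sub>z</sub> ×
sin 15°): entries with strong saturation pulses leave less longitudinal
magnetization, and the pattern over all 30 entries is the fingerprint that
encodes (*f*<sub>s</sub>, *k*<sub>sw</sub>).  Doubling the exchange rate to
800 Hz lowers the mean signal from 0.1362 to 0.1342 — faster exchange
saturates the water pool more (at this millimolar volume fraction the
effect is a percent-level signal change, which is exactly why careful
quantification is needed).

The `examples/` directory walks through each capability: trajectory
simulation, dictionary matching, phantom rendering and segmentation, the
reference quantifier, a miniature adversarial study, and the evaluation
metrics.  A thin CLI wraps the same functions:

```bash
cestmrf make-schedule --m 30 --truncate 9 sched.tsv
cestmrf demo --seed 1 out/          # the full scaled-down study
```

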