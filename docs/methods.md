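# Methods

`cestmrf` implements a desk-scale, fully synthetic version of accelerated
quantitative saturation-transfer MRI fingerprinting: a Bloch-McConnell
simulator and dictionary matcher provide classical quantification, a
dictionary-trained fully connected network (FCN) provides the reference
quantifier, and a conditional adversarial network learns to reconstruct the
two exchange-parameter maps from a truncated acquisition.  This note records
the models, the defaults and why, and what the synthetic experiments do and
do not show.

## Spin physics

The signal model is the two-pool Bloch-McConnell system: free water plus one
exchanging pool — a mobile CEST solute (here the L-arginine amine pool at
3 ppm) or a broad semisolid-MT pool.  Proton exchange couples the pools with
rate `k_sw` (solute to water, Hz) and, by detailed balance, `k_ws = f_s·k_sw`
back, where `f_s` is the water-referenced exchangeable proton fraction; the
solute equilibrium longitudinal magnetization is `f_s` (water's is 1).

Each interval of constant RF (a block saturation pulse, an inter-pulse gap,
a recovery delay) makes the 6-dimensional system (x, y, z per pool) linear
with constant coefficients; it is solved exactly as the exponential of the
augmented 7×7 matrix, so the only numerical error is floating point.
Conversions use γ/2π = 42.5764 MHz/T and B0 = 3 T by default (1 ppm =
127.73 Hz).

A semisolid pool (microsecond-scale T2) is not given transverse dynamics;
RF saturation enters as the lineshape-weighted rate
`R_rfb = π·ω1²·g(Δω)` with `g` a Lorentzian or super-Lorentzian absorption
lineshape.  The super-Lorentzian fiber-angle integral is evaluated by
trapezoid quadrature (8000 nodes); its on-resonance divergence is handled
by substituting the value at a 1 kHz cutoff.  The default lineshape is
Lorentzian — cheap and adequate for desk-scale validation; super-Lorentzian
is available and conventional for in-vivo work.

The acquisition element is a spin-lock-style saturation train: 13 block
pulses of 100 ms separated by 100 ms free-relaxation gaps, no trailing gap
(2500 ms total, 50% duty cycle), followed by a snapshot readout modeled as
an instantaneous sample `signal = Mz·sin(15°)`, perfect transverse
spoiling, and a longitudinal scaling by cos(flip) (configurable); k-space
and the 3D EPI readout are deliberately not simulated — quantification here
operates on magnitude images.  The recovery delay between schedule entries
is a schedule-file column; the default 2.5 s makes one entry ≈5 s so a
30-entry protocol spans ≈2.5 min, consistent with the class of protocols
emulated.  Spin history is carried across the schedule without
re-equilibration, which is why schedules may only ever be truncated from
the end.

An independent cross-validation integrator implements classical RK4 time
stepping of the same ODE.  For a linear constant-coefficient system one RK4
step of size h is algebraically identical to multiplying by the degree-4
Taylor polynomial of `exp(hA)`; the integrator therefore forms that
polynomial once per interval and applies its n-th matrix power (binary
exponentiation), which makes 10 µs stepping tractable while remaining
exactly the RK4 recurrence (the literal four-stage loop is kept and tested
equal to machine precision).  The exact solver agrees with this oracle to
≤1e-6 relative over full 30-entry schedules.

## Schedules

Pseudo-random schedules draw per-entry saturation powers uniformly from
[0, 4] µT; offsets are fixed at 3 ppm (CEST phantom mode) or uniform on
[6, 14] ppm (semisolid-MT mode).  The PCG64 generator makes schedules
reproducible across platforms for a fixed seed.  Truncation to N keeps the
first N entries.  The end-to-end study generates its schedule with the
first entry forced to zero power: an unsaturated M0 image at the schedule
head, the customary protocol design when the processing chain normalizes
the stack by its first image (see below).  Schedules serialize to TSV at 17
significant digits (bit-exact round trip).

## Dictionary and matching

The dictionary simulates one trajectory per point of a Cartesian
(f_s × k_sw) grid — default 41×41 over f_s ∈ [1e-4, 3.5e-3] and
k_sw ∈ [20, 1400] Hz, covering 25–100 mM L-arginine over pH 4–6 — and
stores unit-l2-normalized rows.  Matching maximizes the inner product of
unit vectors (cosine similarity); ties break to the lowest flat grid index;
all-zero voxels return a sentinel.  Self-matching is exact and total.  Noise
moves matches preferentially along the f_s–k_sw ridge (the two parameters
trade off in their effect on saturation depth), so "within one grid step"
is a meaningful yardstick only near the rendering noise level of the
synthetic study (σ ≈ 1.25e-3 per normalized sample), where ~95% of
Monte-Carlo matches land within one step.

## Synthetic phantoms

**L-arginine scenes.**  Circular vials on a saline-like background
(f_s = 0) in a 64×64 field of view at 1.8 mm.  Vial concentration ∈ {25,
50, 100} mM converts to `f_s = n_protons·C/111000` with n_protons = 3 (the
3-ppm guanidinium pool; configurable).  pH maps to exchange rate through
base catalysis, `k_sw = k_0 + k_base·10^(pH−6)` with k_0 = 50 Hz and
k_base = 1200 Hz — calibration constants of the synthetic world chosen so
the pH 4–6 ladder spans slow (~60 Hz) to fast (~1250 Hz) exchange with the
characteristic weak CEST signal at low pH; they are not literature
measurements.  Water T1/T2 default to 2.5/0.8 s (plausible buffer values;
the true phantom relaxation times are not published) with a ±5% per-vial
jitter so scenes differ in relaxation.

**Brain-like scenes.**  An elliptical head mask partitioned into WM/GM by
thresholding a smoothed random field (procedural, not an atlas — keeps the
package download-free), with per-voxel semisolid parameters drawn from
truncated Gaussians: WM f_ss 18.7 ± 2.0%, k_ssw 33.9 ± 5.2 Hz; GM
12.4 ± 2.7%, 49.1 ± 8.5 Hz — the full-length-MRF literature reference
distributions for healthy tissue — plus an optional tumor disk with a
shifted distribution.

**Artifacts and noise.**  Localized susceptibility-like B0 perturbations
are injected as Gaussian-profile blobs peaking at ±max_shift ppm
(default 0.3).  Rendering noise is Rician by default (magnitude MRI;
Gaussian available for analytic checks) at σ = 1e-3 on raw signals of
~0.1–0.25, i.e. image SNR of order 100–250, plausible for a 3D snapshot
readout at 1.8 mm.  Rendering simulates each unique tissue tuple once;
blob B0 maps are quantized to 0.01 ppm in the study so caching stays
effective.

**Segmentation and augmentation.**  Vials are recovered with Canny edges +
circle Hough transform.  Training data are augmented sevenfold: original,
horizontal and vertical flips, and four seeded translations, the identical
transform applied to input stack and target maps.

## Reference quantifier (FCN)

A pixelwise fully connected network (default 2×300 rectifier units; the
desk-scale study uses 2×100) maps unit-normalized M = 30 trajectories to
(f_s, k_sw), trained on the dictionary rows with fresh Gaussian input noise
(σ = 1e-3) every epoch; targets are min-max scaled to [0, 1] and the output
sigmoid plus inverse scaling keeps predictions in range by construction.
In brain mode the voxel's (T1, T2, ΔB0) are appended to the input.  Inputs
are standardized per feature with the dictionary's statistics — across-grid
trajectory variation is small against its mean, and standardization is what
conditions the regression (noiseless grid-row recovery improves from ~5% to
~1% NRMSE).  Loss is mean-squared error under Adam (lr 1e-3 with a 1×/0.3×/0.1× step
decay at 60%/85% of the epochs, batch 128, 400 epochs); the decay pins the
final weights — constant-rate finishes oscillate enough to make noiseless
grid recovery seed-sensitive around 2%, with decay it is 1.0–1.4% for every
seed.  The original work does not print its loss/optimizer, so these are
package choices.  Training is exactly seeded.

## Adversarial reconstructor

The generator is a U-Net (stride-2 encoder, nearest-upsampling decoder with
skip concatenations, depth 3, base width 12 at desk scale) taking the N = 9
normalized raw images and emitting 2 channels through a sigmoid; the
discriminator is a conditional patch network (input stack ⊕ candidate maps
→ logit map over (H/8 × W/8) patches).  Input stacks are normalized by
dividing every image by the first (the M0 image) and clipping to [0, 2],
then standardized per channel with training-set statistics stored in the
model: the ratio images have channel means near 1 with only percent-scale
informative variation, and standardization — the same conditioning fix as
in the FCN — is what lets the network resolve weak-contrast vials (held-out
agreement improves from r ≈ 0.83 to ≥ 0.9 on the volume-fraction channel).

Training minimizes
`L_total = λ1·L1 + λ2·L_adv + λ3·L_tv + λ4·L_p`
with λ = (100, 1, 0.1, 1) — l1-dominant in the pix2pix tradition, fixed
once on the synthetic validation split.  `L_adv` is binary cross-entropy of
the patch discriminator against the "real" label; `L_tv` is anisotropic
total variation (sum over channels of mean absolute first differences along
both axes); `L_p` is the l2 distance between frozen convolutional feature
maps — by default a fixed-seed random-weight stack (two stride-2 conv
layers), so no pretrained weights need shipping; a hook accepts externally
supplied pretrained kernels.  Generator and discriminator alternate one
Adam update per minibatch (lr 1e-4 / 5e-4, batch 4).  The discriminator
uses the adversarial momentum convention β₁ = 0.5; the generator uses
β₁ = 0.9 — its l1-dominant objective behaves like supervised regression,
where full momentum converges materially faster within the 100-epoch cap.
Early stopping monitors the validation l1 content loss and restores the
best generator.  With λ2 = 0 the discriminator is never built and training
degenerates to supervised regression.

Two numerical design points matter at this scale:

* **Output margin.**  The physical parameter range maps to [0.05, 0.95] of
  the sigmoid rather than [0, 1].  Background-masked target maps are mostly
  exactly at the lower range endpoint; an endpoint attainable only at
  infinite logits exerts a never-vanishing l1 pull that drives the whole
  network into saturation while the (minority) foreground gradients die.
  With the margin every target value is reachable at finite logits and the
  background gradient vanishes on attainment.
* **Warm-started retraining.**  When targets are swapped to direct
  quantities (concentration, pH), the generator is retrained starting from
  the exchange-parameter generator's weights.  Cold-started training on
  vials-on-zero-background targets spends most of its budget escaping the
  all-background solution; warm starting re-aims the output head instead.

The whole network stack is a purpose-built deterministic numpy core
(explicit im2col convolutions with hand-written backward passes, single
precision, seeded He initialization): training is bit-reproducible for a
fixed seed in a single-threaded BLAS configuration, and numerical gradients
validate every layer to ~1e-7.

## The synthetic end-to-end study

One run of `cestmrf.experiments.run_larg_study` (the `demo` CLI command and
the acceptance script call exactly this):

1. Generate the M = 30 schedule (M0-first) and its N = 9 truncation.
2. Build the 41×41 dictionary and train the reference FCN on it.
3. Generate 29 training and 6 held-out test scenes, 6 vials each, pH drawn
   from the ladder {4.0, 4.4, 4.8, 5.2, 5.6, 6.0} and concentrations from
   {25, 50, 100} mM; half the scenes receive B0 blobs.
4. For each scene, render a full-length artifact-free stack (Rician noise)
   and quantify it with the FCN → reference maps, background-masked to the
   vials; independently render the scene as given (with its blobs) and keep
   the first 9 images, M0-normalized → input stack.  Sevenfold augmentation
   yields 203 training pairs.
5. Train the GAN; evaluate on the held-out scenes: voxelwise Pearson r/ICC
   inside the vials between generated and reference maps, per-vial median
   concentration (from f_s) against truth, and — on blob scenes — the
   in-blob k_sw error of the GAN versus brute-force dictionary matching of
   the full-length artifacted stack.  A truncated-classical comparator (a
   pixelwise network trained on the first-N dictionary, quantifying the
   same N images) is evaluated alongside: it reaches only r ≈ 0.6 / 0.7
   against the reference where the spatial adversarial reconstruction
   reaches ≥ 0.9 — the acceleration claim in one number.
6. Retrain (warm-started) on (concentration, pH) targets painted uniformly
   over the vials and check that held-out per-vial median pH is monotone in
   true pH across the ladder.

Training the reference against artifact-free renderings while inputs carry
the artifacts is the study's supervision design: it is what gives the
spatial reconstructor its artifact-mitigation behaviour, probed directly by
the in-blob comparison.

The evaluation region is the vials because outside them f_s = 0 makes the
exchange parameters unidentifiable — the reference quantifier's output
there is reproducible-in-distribution noise (test–retest r ≈ 0 in saline
versus ≈0.97–0.998 inside vials), and any correlation computed over it
would be meaningless; the emulated protocol likewise masks the background
before analysis.

## What the synthetic study does and does not show

The generator's scenes are piecewise-constant disks with known chemistry, a
single exchanging pool, no motion, no coil structure, no EPI distortion,
and noise that is exactly Rician.  Passing the end-to-end criteria shows
the pipeline is internally consistent — the adversarial reconstructor can
recover the reference quantifier's output from 30% of the data under
realistic noise, artifact and augmentation conditions — not that the
trained weights transfer to scanner data.  Conversely the physics,
dictionary, metric and geometry components are validated against
independent oracles (RK4 integration, adaptive quadrature, closed forms,
hand ANOVA) and hold regardless of scene realism.

## Problem sizes and determinism

The desk-scale defaults (29+6 scenes, 64×64, 41×41 dictionary, 2×100 FCN,
U-Net depth 3 base width 12, ≤100 GAN epochs with early stopping) keep a
full study in the tens of minutes on one CPU; they are the package's chosen
study conditions, not tuned per run.  Every stochastic stage fans its seed out of
one master seed via `numpy.random.SeedSequence`; identical configurations
reproduce identical schedules, scenes, noise, initializations and training
trajectories (single-threaded).
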