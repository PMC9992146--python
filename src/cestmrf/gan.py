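"""Conditional adversarial reconstruction of exchange-parameter maps.

The centerpiece of the package: a pix2pix-style conditional GAN that maps a
*truncated* stack of N raw saturation-encoded images directly to the two
quantitative exchange-parameter maps (proton volume fraction and exchange
rate), trained against the reference quantifier's full-length (M-image)
output.  Because the spin system carries history across the schedule, images
may only be dropped from the end of the acquisition — the generator's job is
to recover from the first N images what the full M encode.

The composite training objective is

    L_total = lambda1 * L1 + lambda2 * L_adv + lambda3 * L_tv + lambda4 * L_p

with a pixelwise l1 content term, a binary-cross-entropy adversarial term
from a conditional patch discriminator, an anisotropic total-variation
smoothness term, and a perceptual term (l2 between frozen convolutional
feature maps of prediction and target).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import nn
from .phantom import RawImageStack

__all__ = ["LossWeights", "GanConfig", "TrainingPair", "UNetGenerator",
           "PatchDiscriminator", "FeatureExtractor", "TrainedGenerator",
           "normalize_stack", "total_variation_loss", "perceptual_loss",
           "composite_loss", "build_generator", "build_discriminator",
           "build_feature_extractor", "train_gan", "reconstruct_volume",
           "retarget_to_direct_quantities"]

#: default min/max scaling ranges of the two output channels
DEFAULT_OUTPUT_RANGES: Dict[str, Tuple[float, float]] = {
    "volume_fraction": (0.0, 4e-3),
    "exchange_rate": (0.0, 1500.0),
}

#: the physical parameter range is mapped to [margin, 1 - margin] of the
#: generator's sigmoid output.  A range endpoint placed exactly at 0 or 1
#: would only be attainable at infinite logits; background-dominated target
#: maps (mostly exactly at the lower endpoint) would then exert a
#: never-vanishing l1 pull that saturates the network.  The margin keeps
#: every target value reachable at finite logits.
OUTPUT_MARGIN = 0.05


@dataclass
class LossWeights:
    """Weights (lambda1..lambda4) of the composite objective.

    The study that fixes them does so on a separate validation split; the
    defaults follow the pix2pix tradition of an l1-dominant objective with
    unit adversarial weight and light smoothness/perceptual terms.
    """

    lambda1: float = 100.0   # pixelwise l1 content loss
    lambda2: float = 1.0     # adversarial loss
    lambda3: float = 0.1     # total-variation loss
    lambda4: float = 1.0     # perceptual loss

    def __post_init__(self) -> None:
        ws = (self.lambda1, self.lambda2, self.lambda3, self.lambda4)
        if any(w < 0 for w in ws):
            raise ValueError("loss weights must be non-negative")
        if not any(w > 0 for w in ws):
            raise ValueError("at least one loss weight must be positive")


@dataclass
class GanConfig:
    """Architecture and optimization settings of the adversarial pair."""

    n_input_channels: int = 9
    gen_base_width: int = 16
    gen_depth: int = 2            # number of 2x downsamplings in the U-Net
    disc_base_width: int = 16
    disc_depth: int = 2           # patch grid is (H, W) / 2**disc_depth
    lr_generator: float = 1e-4
    lr_discriminator: float = 5e-4
    batch_size: int = 4
    epochs: int = 400
    early_stopping_patience: int = 10
    seed: int = 0
    feature_extractor: str = "fixed_random_conv"   # or "pretrained_vgg19_hook"
    output_names: Tuple[str, str] = ("volume_fraction", "exchange_rate")
    output_ranges: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OUTPUT_RANGES))

    def __post_init__(self) -> None:
        if self.lr_generator <= 0 or self.lr_discriminator <= 0:
            raise ValueError("learning rates must be positive")
        if self.n_input_channels < 1:
            raise ValueError("need at least one input channel")


@dataclass
class TrainingPair:
    """One training slice: N-channel input, 2-channel target, evaluation mask.

    ``input_stack`` is the normalized truncated raw stack (N, H, W);
    ``target_maps`` holds the physical-unit maps named by ``target_names``.
    """

    input_stack: np.ndarray
    target_maps: np.ndarray
    mask: Optional[np.ndarray] = None
    target_names: Tuple[str, str] = ("volume_fraction", "exchange_rate")

    def __post_init__(self) -> None:
        if self.input_stack.shape[1:] != self.target_maps.shape[1:]:
            raise ValueError("input and target spatial dims differ")
        if self.mask is None:
            self.mask = np.ones(self.target_maps.shape[1:], dtype=bool)


# ---------------------------------------------------------------------------
# Stack normalization
# ---------------------------------------------------------------------------

def normalize_stack(images: np.ndarray, clip: float = 2.0,
                    eps: float = 1e-8) -> np.ndarray:
    """Normalize a raw stack by its first (lowest-saturation) image.

    Every image is divided pixelwise by image 0 and clipped to [0, clip];
    pixels where the reference image is ~0 (background) are set to 0.  This
    removes receive-field and proton-density scaling from the input space.
    """
    ref = images[0]
    ok = np.abs(ref) > eps
    out = np.zeros_like(images, dtype=float)
    out[:, ok] = images[:, ok] / ref[ok]
    return np.clip(out, 0.0, clip)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class UNetGenerator(nn.Module):
    """U-Net: N input channels -> 2 sigmoid-bounded output channels.

    ``depth`` stride-2 encoder stages with skip connections into a
    nearest-upsampling decoder; spatial dims must be divisible by 2**depth.
    The sigmoid output lives in [0, 1] and is mapped to physical parameter
    ranges outside the network, so outputs respect the configured ranges
    everywhere by construction.
    """

    def __init__(self, c_in: int, c_out: int, base: int, depth: int,
                 rng: np.random.Generator):
        self.depth = depth
        self.enc0 = nn.Conv2d(c_in, base, rng)
        self.act0 = nn.LeakyReLU()
        self.downs, self.dacts = [], []
        for d in range(1, depth + 1):
            self.downs.append(nn.Conv2d(base * 2 ** (d - 1), base * 2 ** d,
                                        rng, stride=2))
            self.dacts.append(nn.LeakyReLU())
        self.bott = nn.Conv2d(base * 2 ** depth, base * 2 ** depth, rng)
        self.bact = nn.LeakyReLU()
        self.ups, self.uconvs, self.uacts = [], [], []
        for d in range(depth, 0, -1):
            self.ups.append(nn.Upsample2x())
            self.uconvs.append(nn.Conv2d(base * 2 ** d + base * 2 ** (d - 1),
                                         base * 2 ** (d - 1), rng))
            self.uacts.append(nn.LeakyReLU())
        self.out_conv = nn.Conv2d(base, c_out, rng)
        self.out_act = nn.Sigmoid()

    def params(self):
        mods = [self.enc0, *self.downs, self.bott, *self.uconvs, self.out_conv]
        return [p for m in mods for p in m.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h, w = x.shape[2:]
        if h % 2 ** self.depth or w % 2 ** self.depth:
            raise ValueError(f"spatial dims {h}x{w} not divisible by "
                             f"2**depth = {2 ** self.depth}")
        skips = [self.act0.forward(self.enc0.forward(x))]
        for conv, act in zip(self.downs, self.dacts):
            skips.append(act.forward(conv.forward(skips[-1])))
        hid = self.bact.forward(self.bott.forward(skips[-1]))
        self._cat_splits = []
        for i, (up, conv, act) in enumerate(zip(self.ups, self.uconvs,
                                                self.uacts)):
            u = up.forward(hid)
            skip = skips[self.depth - 1 - i]
            self._cat_splits.append(u.shape[1])
            hid = act.forward(conv.forward(np.concatenate([u, skip], axis=1)))
        return self.out_act.forward(self.out_conv.forward(hid))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.out_conv.backward(self.out_act.backward(dy))
        dskips = [None] * (self.depth + 1)
        for i in range(self.depth - 1, -1, -1):
            dcat = self.uconvs[i].backward(self.uacts[i].backward(dh))
            split = self._cat_splits[i]
            du, dskip = dcat[:, :split], dcat[:, split:]
            level = self.depth - 1 - i
            dskips[level] = dskip if dskips[level] is None \
                else dskips[level] + dskip
            dh = self.ups[i].backward(du)
        g = self.bott.backward(self.bact.backward(dh))
        for d in range(self.depth, 0, -1):
            if dskips[d] is not None:
                g = g + dskips[d]
            g = self.downs[d - 1].backward(self.dacts[d - 1].backward(g))
        if dskips[0] is not None:
            g = g + dskips[0]
        return self.enc0.backward(self.act0.backward(g))


class PatchDiscriminator(nn.Sequential):
    """Conditional patch discriminator on (input stack, candidate maps).

    ``depth`` stride-2 convolutions then a 1-channel head: the output is a
    logit map over (H / 2**depth) x (W / 2**depth) patches, each judging
    whether its receptive field looks like a real (reference) pair.
    """

    def __init__(self, c_in: int, base: int, depth: int,
                 rng: np.random.Generator):
        layers: List[nn.Module] = []
        c = c_in
        for d in range(depth):
            layers += [nn.Conv2d(c, base * 2 ** d, rng, stride=2),
                       nn.LeakyReLU()]
            c = base * 2 ** d
        layers.append(nn.Conv2d(c, 1, rng))
        super().__init__(*layers)
        self.depth = depth


class FeatureExtractor(nn.Sequential):
    """Frozen convolutional feature stack for the perceptual loss.

    The default is a fixed-seed random-weight stack (no external weight
    download needed); :meth:`from_weights` accepts externally supplied
    pretrained convolution kernels (e.g. exported from a VGG19-style
    network) for exact correspondence with a pretrained extractor.
    """

    _FIXED_SEED = 0x5EED

    def __init__(self, c_in: int = 2, widths: Sequence[int] = (8, 16),
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(self._FIXED_SEED)
        layers: List[nn.Module] = []
        c = c_in
        for w in widths:
            layers += [nn.Conv2d(c, w, rng, stride=2), nn.ReLU()]
            c = w
        super().__init__(*layers)

    @classmethod
    def from_weights(cls, kernels: Sequence[np.ndarray],
                     biases: Sequence[np.ndarray]) -> "FeatureExtractor":
        """Build an extractor from externally supplied (c_out, c_in*k*k) kernels."""
        widths = [k.shape[0] for k in kernels]
        c_in = kernels[0].shape[1] // 9
        ext = cls(c_in=c_in, widths=widths)
        convs = [l for l in ext.layers if isinstance(l, nn.Conv2d)]
        for conv, k, b in zip(convs, kernels, biases):
            conv.w.value[...] = k
            conv.b.value[...] = b
        return ext


def build_generator(config: GanConfig, seed: Optional[int] = None) -> UNetGenerator:
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 11]))
    return UNetGenerator(config.n_input_channels, len(config.output_names),
                         config.gen_base_width, config.gen_depth, rng)


def build_discriminator(config: GanConfig, seed: Optional[int] = None,
                        ) -> PatchDiscriminator:
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 13]))
    return PatchDiscriminator(config.n_input_channels + len(config.output_names),
                              config.disc_base_width, config.disc_depth, rng)


def build_feature_extractor(config: GanConfig) -> FeatureExtractor:
    if config.feature_extractor == "fixed_random_conv":
        return FeatureExtractor(c_in=len(config.output_names))
    if config.feature_extractor == "pretrained_vgg19_hook":
        raise ValueError(
            "pretrained extractor weights must be supplied via "
            "FeatureExtractor.from_weights and passed to train_gan(extractor=...)")
    raise ValueError(f"unknown feature_extractor {config.feature_extractor!r}")


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def total_variation_loss(maps: np.ndarray) -> float:
    """Anisotropic total variation of a (C, H, W) or (B, C, H, W) map stack."""
    return nn.tv_loss(maps)[0]


def perceptual_loss(pred: np.ndarray, target: np.ndarray,
                    extractor: FeatureExtractor) -> float:
    """Mean-squared difference between frozen conv features of pred/target."""
    p = pred if pred.ndim == 4 else pred[None]
    t = target if target.ndim == 4 else target[None]
    ft = extractor.forward(t).copy()
    fp = extractor.forward(p)
    return float(np.mean((fp - ft) ** 2))


def composite_loss(pred: np.ndarray, target: np.ndarray,
                   disc_output: Optional[np.ndarray], weights: LossWeights,
                   extractor: Optional[FeatureExtractor] = None,
                   ) -> Tuple[float, Dict[str, float]]:
    """Evaluate L_total = l1*L1 + l2*L_adv + l3*L_tv + l4*L_p with breakdown.

    ``disc_output`` are the discriminator's logits on the generated pair;
    the adversarial term scores them against the "real" label.  Terms with
    zero weight are reported as 0 and never computed.
    """
    terms = {"l1": 0.0, "adv": 0.0, "tv": 0.0, "perceptual": 0.0}
    if weights.lambda1 > 0:
        terms["l1"] = nn.l1_loss(pred, target)[0]
    if weights.lambda2 > 0:
        if disc_output is None:
            raise ValueError("adversarial term requires discriminator output")
        terms["adv"] = nn.bce_with_logits(disc_output, 1.0)[0]
    if weights.lambda3 > 0:
        terms["tv"] = total_variation_loss(pred)
    if weights.lambda4 > 0:
        if extractor is None:
            raise ValueError("perceptual term requires a feature extractor")
        terms["perceptual"] = perceptual_loss(pred, target, extractor)
    total = (weights.lambda1 * terms["l1"] + weights.lambda2 * terms["adv"]
             + weights.lambda3 * terms["tv"]
             + weights.lambda4 * terms["perceptual"])
    return float(total), terms


# ---------------------------------------------------------------------------
# Scaling helpers
# ---------------------------------------------------------------------------

def _scale_targets(maps: np.ndarray, names: Sequence[str],
                   ranges: Dict[str, Tuple[float, float]]) -> np.ndarray:
    out = np.empty_like(maps, dtype=float)
    m = OUTPUT_MARGIN
    for j, name in enumerate(names):
        lo, hi = ranges[name]
        t01 = np.clip((maps[..., j, :, :] - lo) / (hi - lo), 0, 1)
        out[..., j, :, :] = m + (1 - 2 * m) * t01
    return out


def _unscale(maps_sig: np.ndarray, names: Sequence[str],
             ranges: Dict[str, Tuple[float, float]]) -> np.ndarray:
    out = np.empty_like(maps_sig, dtype=float)
    m = OUTPUT_MARGIN
    for j, name in enumerate(names):
        lo, hi = ranges[name]
        t01 = np.clip((maps_sig[..., j, :, :] - m) / (1 - 2 * m), 0, 1)
        out[..., j, :, :] = lo + (hi - lo) * t01
    return out


@dataclass
class TrainedGenerator:
    """A trained U-Net plus its input/output scalings.

    ``input_mean``/``input_sd`` hold the per-channel standardization fitted
    on the training stacks: the normalized ratio images have channel means
    near 1 with percent-scale informative variation, and standardizing is
    what conditions the network on the weak-contrast structures.
    """

    net: UNetGenerator
    config: GanConfig
    target_names: Tuple[str, str]
    input_mean: Optional[np.ndarray] = None    # (N, 1, 1)
    input_sd: Optional[np.ndarray] = None

    def standardize(self, stack: np.ndarray) -> np.ndarray:
        if self.input_mean is None:
            return stack.astype(nn.DTYPE, copy=False)
        return ((stack - self.input_mean) / self.input_sd).astype(nn.DTYPE)

    def predict_slice(self, stack_slice: np.ndarray) -> np.ndarray:
        """(N, H, W) normalized input -> (2, H, W) physical-unit maps."""
        if stack_slice.shape[0] != self.config.n_input_channels:
            raise ValueError(
                f"expected {self.config.n_input_channels} input channels, "
                f"got {stack_slice.shape[0]}")
        y01 = self.net.forward(self.standardize(stack_slice)[None])[0]
        return _unscale(y01, self.target_names, self.config.output_ranges)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_gan(pairs: Sequence[TrainingPair], config: GanConfig,
              weights: LossWeights = LossWeights(),
              val_pairs: Optional[Sequence[TrainingPair]] = None,
              val_fraction: float = 0.15,
              extractor: Optional[FeatureExtractor] = None,
              init_from: Optional[TrainedGenerator] = None,
              ) -> Tuple[TrainedGenerator, pd.DataFrame]:
    """Adversarial training of the generator against the reference targets.

    Alternates one discriminator update (real pair vs generated pair, both
    conditioned on the input stack) and one generator update (composite
    loss) per minibatch.  Early stopping monitors the validation l1 content
    loss and restores the best generator.  With ``lambda2 = 0`` the
    discriminator is never built nor updated and training degenerates to
    (possibly TV/perceptually regularized) supervised regression.

    ``init_from`` warm-starts the generator from an already-trained one of
    identical architecture — the retraining mode used when swapping the
    target quantities, which sidesteps the cold-start bias towards the
    all-background solution.

    Returns the trained generator and a per-epoch log with the loss-term
    breakdown; the logged ``total`` is exactly the weighted sum of the
    logged terms.
    """
    if len(pairs) == 0:
        raise ValueError("training requires at least one pair")
    names = pairs[0].target_names
    x = np.stack([p.input_stack for p in pairs]).astype(nn.DTYPE)
    y = _scale_targets(np.stack([p.target_maps for p in pairs]), names,
                       config.output_ranges).astype(nn.DTYPE)
    if x.shape[1] != config.n_input_channels:
        raise ValueError(f"pairs have {x.shape[1]} channels, config expects "
                         f"{config.n_input_channels}")

    # per-channel input standardization, fitted on the training stacks
    ch_mean = x.mean(axis=(0, 2, 3), keepdims=True)[0]
    ch_sd = x.std(axis=(0, 2, 3), keepdims=True)[0]
    ch_sd = np.where(ch_sd > 0, ch_sd, 1.0).astype(nn.DTYPE)
    ch_mean = ch_mean.astype(nn.DTYPE)
    x = (x - ch_mean) / ch_sd

    ss = np.random.SeedSequence([config.seed, 17])
    rng = np.random.default_rng(ss)
    if val_pairs is not None:
        xv = np.stack([p.input_stack for p in val_pairs]).astype(nn.DTYPE)
        xv = ((xv - ch_mean) / ch_sd).astype(nn.DTYPE)
        yv = _scale_targets(np.stack([p.target_maps for p in val_pairs]),
                            names, config.output_ranges).astype(nn.DTYPE)
    else:
        n_val = max(1, int(round(val_fraction * len(pairs)))) \
            if len(pairs) > 1 else 0
        order = rng.permutation(len(pairs))
        val_idx, trn_idx = order[:n_val], order[n_val:]
        if len(trn_idx) == 0:
            trn_idx, val_idx = order, order
        xv, yv = x[val_idx], y[val_idx]
        x, y = x[trn_idx], y[trn_idx]

    gen = build_generator(config)
    if init_from is not None:
        gen.set_weights(init_from.net.get_weights())
    # beta1 = 0.9 for the generator: its l1-dominant objective behaves like
    # supervised regression, where full momentum converges faster; the
    # discriminator keeps the adversarial convention beta1 = 0.5
    opt_g = nn.Adam(gen.params(), lr=config.lr_generator, betas=(0.9, 0.999))
    adversarial = weights.lambda2 > 0
    disc = build_discriminator(config) if adversarial else None
    opt_d = nn.Adam(disc.params(), lr=config.lr_discriminator) \
        if adversarial else None
    if weights.lambda4 > 0 and extractor is None:
        extractor = build_feature_extractor(config)

    n = len(x)
    bs = config.batch_size
    best_val, best_weights, best_epoch, bad = math.inf, gen.get_weights(), 0, 0
    log: List[Dict[str, float]] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        sums = {"l1": 0.0, "adv": 0.0, "tv": 0.0, "perceptual": 0.0,
                "total": 0.0, "d_loss": 0.0}
        n_batches = 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xb, yb = x[idx], y[idx]
            fake = gen.forward(xb)

            d_loss = 0.0
            if adversarial:
                disc.zero_grad()
                lr_, dlr = nn.bce_with_logits(
                    disc.forward(np.concatenate([xb, yb], axis=1)), 1.0)
                disc.backward(0.5 * dlr)
                lf_, dlf = nn.bce_with_logits(
                    disc.forward(np.concatenate([xb, fake], axis=1)), 0.0)
                disc.backward(0.5 * dlf)
                opt_d.step()
                d_loss = 0.5 * (lr_ + lf_)

            # generator update; discriminator judged but not stepped
            terms = {"l1": 0.0, "adv": 0.0, "tv": 0.0, "perceptual": 0.0}
            dfake = np.zeros_like(fake)
            if weights.lambda1 > 0:
                terms["l1"], d1 = nn.l1_loss(fake, yb)
                dfake += weights.lambda1 * d1
            if adversarial:
                disc.zero_grad()
                terms["adv"], dlg = nn.bce_with_logits(
                    disc.forward(np.concatenate([xb, fake], axis=1)), 1.0)
                dcat = disc.backward(dlg)
                dfake += weights.lambda2 * dcat[:, xb.shape[1]:]
            if weights.lambda3 > 0:
                terms["tv"], dtv = nn.tv_loss(fake)
                dfake += weights.lambda3 * dtv
            if weights.lambda4 > 0:
                ft = extractor.forward(yb).copy()
                fp = extractor.forward(fake)
                terms["perceptual"], dfp = nn.mse_loss(fp, ft)
                dfake += weights.lambda4 * extractor.backward(dfp)
            gen.zero_grad()
            gen.backward(dfake)
            opt_g.step()

            total = (weights.lambda1 * terms["l1"]
                     + weights.lambda2 * terms["adv"]
                     + weights.lambda3 * terms["tv"]
                     + weights.lambda4 * terms["perceptual"])
            for k in terms:
                sums[k] += terms[k]
            sums["total"] += total
            sums["d_loss"] += d_loss
            n_batches += 1

        val_l1 = 0.0
        for start in range(0, len(xv), bs):
            pv = gen.forward(xv[start:start + bs])
            val_l1 += nn.l1_loss(pv, yv[start:start + bs])[0] \
                * len(pv) / len(xv)
        row = {k: v / n_batches for k, v in sums.items()}
        row.update(epoch=epoch, val_l1=val_l1)
        log.append(row)
        if val_l1 < best_val - 1e-7:
            best_val, best_weights, best_epoch, bad = \
                val_l1, gen.get_weights(), epoch, 0
        else:
            bad += 1
            if bad >= config.early_stopping_patience:
                break
    gen.set_weights(best_weights)
    df = pd.DataFrame(log)
    df.attrs["best_epoch"] = best_epoch
    return TrainedGenerator(gen, config, names, input_mean=ch_mean,
                            input_sd=ch_sd), df


# ---------------------------------------------------------------------------
# Inference and retargeting
# ---------------------------------------------------------------------------

def reconstruct_volume(generator: TrainedGenerator, stack: RawImageStack,
                       normalized: bool = False,
                       ) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    """Slice-wise 2D inference over a 2D or 3D raw stack.

    ``stack.images`` is (N, H, W) or (N, H, W, S); slices are normalized
    (unless ``normalized``), padded to the U-Net's divisibility requirement,
    reconstructed independently and reassembled.  Returns (maps, valid) where
    ``valid`` marks unpadded voxels with nonzero input signal.
    """
    imgs = stack.images
    cfg = generator.config
    if imgs.shape[0] != cfg.n_input_channels:
        raise ValueError(f"stack has {imgs.shape[0]} images, generator "
                         f"expects {cfg.n_input_channels}")
    vol = imgs[..., None] if imgs.ndim == 3 else imgs
    n, h, w, n_slices = vol.shape
    div = 2 ** cfg.gen_depth
    ph, pw = (-h) % div, (-w) % div
    names = generator.target_names
    maps = np.zeros((2, h, w, n_slices))
    valid = np.zeros((h, w, n_slices), dtype=bool)
    for s in range(n_slices):
        sl = vol[..., s]
        sln = sl if normalized else normalize_stack(sl)
        slp = np.pad(sln, ((0, 0), (0, ph), (0, pw)))
        out = generator.predict_slice(slp)[:, :h, :w]
        maps[..., s] = out
        valid[..., s] = np.linalg.norm(sl, axis=0) > 0
    maps[:, ~valid] = 0.0
    if imgs.ndim == 3:
        maps, valid = maps[..., 0], valid[..., 0]
    return {names[0]: maps[0], names[1]: maps[1]}, valid


DIRECT_QUANTITY_RANGES: Dict[str, Tuple[float, float]] = {
    "concentration": (0.0, 120.0),   # mM
    "pH": (0.0, 7.0),
}


def retarget_to_direct_quantities(pairs: Sequence[TrainingPair],
                                  aux_maps: Sequence[Dict[str, np.ndarray]],
                                  config: GanConfig,
                                  ) -> Tuple[List[TrainingPair], GanConfig]:
    """Swap training targets from (f_s, k_sw) to (concentration, pH).

    ``aux_maps[i]`` must carry the scene-truth ``concentration`` (mM) and
    ``pH`` maps matching pair *i* — piecewise-constant over the segmented
    vials, emulating targets painted from bench measurements.  Returns new
    pairs plus a config whose output scaling matches the new units; the
    training path is unchanged.
    """
    if len(aux_maps) != len(pairs):
        raise ValueError("need one aux-map dict per pair")
    out: List[TrainingPair] = []
    for p, aux in zip(pairs, aux_maps):
        if "concentration" not in aux or "pH" not in aux:
            raise ValueError("aux maps must contain 'concentration' and 'pH'")
        target = np.stack([aux["concentration"], aux["pH"]])
        out.append(TrainingPair(input_stack=p.input_stack, target_maps=target,
                                mask=p.mask,
                                target_names=("concentration", "pH")))
    new_cfg = replace(config, output_names=("concentration", "pH"),
                      output_ranges=dict(DIRECT_QUANTITY_RANGES))
    return out, new_cfg
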