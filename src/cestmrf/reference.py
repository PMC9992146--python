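"""Dictionary-trained fully connected reference quantifier.

The classical neural replacement for brute-force dictionary matching: a
pixelwise fully connected network trained on simulated dictionary rows
(unit-normalized trajectories in, min-max-scaled tissue parameters out).
Gaussian input-noise augmentation is refreshed every epoch so the network
generalizes off the noiseless grid.  In brain mode the per-voxel water T1,
T2 and B0 values are appended to the input vector.

Its output maps are the training targets ("ground truth") for the
adversarial reconstructor in :mod:`cestmrf.gan`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .dictionary import MRFDictionary
from .phantom import RawImageStack
from .physics import normalize_trajectory

__all__ = ["FCNConfig", "ReferenceFCN", "train_reference_fcn", "quantify_stack"]


@dataclass
class FCNConfig:
    """Architecture and training settings of the reference network."""

    input_length: int                      # M (+3 in brain mode)
    hidden_layers: Sequence[int] = (300, 300)
    output_names: Sequence[str] = ("volume_fraction", "exchange_rate")
    output_scaling: Optional[Dict[str, Tuple[float, float]]] = None
    epochs: int = 400
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0
    noise_augmentation_sigma: float = 0.001
    brain_mode: bool = False

    def __post_init__(self) -> None:
        if self.output_scaling is not None:
            for name, (lo, hi) in self.output_scaling.items():
                if hi < lo:
                    raise ValueError(f"output_scaling for {name!r} inverted")


class ReferenceFCN:
    """Trained pixelwise quantifier: trajectory -> (f_s, k_sw)."""

    def __init__(self, config: FCNConfig,
                 scaling: Dict[str, Tuple[float, float]]):
        self.config = config
        self.scaling = scaling
        # per-feature standardization fitted on the training dictionary;
        # identity until train_reference_fcn fills it in
        self.input_mean = np.zeros(config.input_length)
        self.input_sd = np.ones(config.input_length)
        rng = np.random.default_rng(config.seed)
        widths = [config.input_length, *config.hidden_layers,
                  len(config.output_names)]
        layers: List[nn.Module] = []
        for i in range(len(widths) - 1):
            layers.append(nn.Dense(widths[i], widths[i + 1], rng))
            if i < len(widths) - 2:
                layers.append(nn.ReLU())
        layers.append(nn.Sigmoid())     # outputs live in [0, 1] by construction
        self.net = nn.Sequential(*layers)

    # -- scaling -----------------------------------------------------------
    def _scale_targets(self, targets: np.ndarray) -> np.ndarray:
        out = np.empty_like(targets)
        for j, name in enumerate(self.config.output_names):
            lo, hi = self.scaling[name]
            width = hi - lo
            # a width-0 range (1-point grid axis) maps everything to lo
            out[:, j] = np.clip((targets[:, j] - lo) / width, 0, 1) \
                if width > 0 else 0.5
        return out

    def _unscale(self, scaled: np.ndarray) -> np.ndarray:
        out = np.empty_like(scaled)
        for j, name in enumerate(self.config.output_names):
            lo, hi = self.scaling[name]
            out[..., j] = lo + (hi - lo) * scaled[..., j]
        return out

    # -- inference ---------------------------------------------------------
    def predict(self, trajectories: np.ndarray,
                aux: Optional[np.ndarray] = None) -> np.ndarray:
        """Quantify unit-normalized trajectories (P, M) -> (P, n_outputs).

        Normalization is applied internally, so predictions are invariant to
        positive scaling of the raw trajectory.
        """
        x = normalize_trajectory(np.atleast_2d(trajectories))
        if self.config.brain_mode:
            if aux is None:
                raise ValueError("brain mode requires aux (T1, T2, B0) inputs")
            x = np.concatenate([x, np.atleast_2d(aux)], axis=1)
        if x.shape[1] != self.config.input_length:
            raise ValueError(f"input length {x.shape[1]} != configured "
                             f"{self.config.input_length}")
        xs = (x - self.input_mean) / self.input_sd
        return self._unscale(self.net.forward(xs))


def train_reference_fcn(dictionary: MRFDictionary, config: FCNConfig,
                        aux_values: Optional[np.ndarray] = None) -> ReferenceFCN:
    """Train the reference network on a simulated dictionary.

    Inputs are the dictionary's unit-norm rows with fresh white noise of
    ``noise_augmentation_sigma`` added every epoch; targets are the grid
    coordinates named in ``config.output_names``, min-max scaled to [0, 1]
    over the grid range (mean-squared-error objective, Adam).  Inputs are
    standardized per feature with statistics of the (noiseless) dictionary —
    the across-grid variation of a normalized trajectory is small compared to
    its mean, and standardization conditions the regression.  Fully seeded:
    identical configs give identical predictors.
    """
    grid = dictionary.grid
    base_len = dictionary.m + (3 if config.brain_mode else 0)
    if config.input_length != base_len:
        raise ValueError(f"config.input_length {config.input_length} does not "
                         f"match dictionary M {dictionary.m}"
                         + (" + 3 aux" if config.brain_mode else ""))
    pts = grid.points()
    name_to_col = {n: j for j, n in enumerate(grid.axis_names)}
    targets = np.empty((grid.size, len(config.output_names)))
    for j, name in enumerate(config.output_names):
        if name not in name_to_col:
            raise ValueError(f"output {name!r} is not a grid axis")
        targets[:, j] = pts[:, name_to_col[name]]
    scaling = dict(config.output_scaling or {})
    for j, name in enumerate(config.output_names):
        scaling.setdefault(name, (float(targets[:, j].min()),
                                  float(targets[:, j].max())))

    model = ReferenceFCN(config, scaling)
    x = dictionary.trajectories
    if config.brain_mode:
        if aux_values is None or aux_values.shape != (grid.size, 3):
            raise ValueError("brain mode needs aux_values of shape (grid size, 3)")
        x = np.concatenate([x, aux_values], axis=1)
    y = model._scale_targets(targets)
    model.input_mean = x.mean(axis=0)
    sd = x.std(axis=0)
    model.input_sd = np.where(sd > 0, sd, 1.0)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    opt = nn.Adam(model.net.params(), lr=config.learning_rate,
                  betas=(0.9, 0.999))
    n = x.shape[0]
    for epoch in range(config.epochs):
        # step decay: late-stage refinement at reduced rate stabilizes the
        # final weights (constant-rate runs oscillate around the optimum)
        frac = epoch / max(1, config.epochs)
        opt.lr = config.learning_rate * (1.0 if frac < 0.6
                                         else 0.3 if frac < 0.85 else 0.1)
        order = rng.permutation(n)
        noise = rng.normal(0.0, config.noise_augmentation_sigma,
                           size=(n, dictionary.m))
        xn = x.copy()
        xn[:, :dictionary.m] += noise
        xn = (xn - model.input_mean) / model.input_sd
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            model.net.zero_grad()
            pred = model.net.forward(xn[idx])
            _, dpred = nn.mse_loss(pred, y[idx])
            model.net.backward(dpred)
            opt.step()
    return model


def quantify_stack(model: ReferenceFCN, stack: RawImageStack,
                   aux_maps: Optional[Dict[str, np.ndarray]] = None,
                   ) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    """Pixelwise quantification of a raw image stack.

    Returns (maps, valid): one map per model output in physical units, and a
    boolean validity mask; all-zero (background) voxels are invalid and set
    to 0.  In brain mode ``aux_maps`` must supply ``t1``, ``t2`` and ``b0``.
    """
    imgs = stack.images
    m = imgs.shape[0]
    spatial = imgs.shape[1:]
    flat = imgs.reshape(m, -1).T                     # (P, M)
    valid = np.linalg.norm(flat, axis=1) > 0
    aux = None
    if model.config.brain_mode:
        if aux_maps is None or not all(k in aux_maps for k in ("t1", "t2", "b0")):
            raise ValueError("brain mode requires aux maps t1, t2, b0")
        aux = np.stack([aux_maps[k].reshape(-1) for k in ("t1", "t2", "b0")],
                       axis=1)[valid]
    out = np.zeros((flat.shape[0], len(model.config.output_names)))
    if np.any(valid):
        out[valid] = model.predict(flat[valid], aux=aux)
    maps = {name: out[:, j].reshape(spatial)
            for j, name in enumerate(model.config.output_names)}
    return maps, valid.reshape(spatial)
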