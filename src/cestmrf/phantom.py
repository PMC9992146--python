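"""Synthetic digital phantoms: ground-truth scenes and rendered raw MRF stacks.

Two scene families are provided.  ``make_larg_scene`` builds an L-arginine
vial phantom — circular vials of known concentration (25–100 mM) and pH
(4.0–6.0) in a saline-like background — with exchange physics tied to pH
through base catalysis.  ``make_brain_scene`` builds a procedural brain-like
scene with white/gray-matter semisolid-MT parameters drawn from the
literature WM/GM distributions.  ``render_raw_stack`` turns a scene plus an
acquisition schedule into the raw molecular-information-encoding image stack,
optionally with Rician (magnitude-MRI) or Gaussian noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .physics import simulate_trajectories

__all__ = [
    "PhantomScene", "RawImageStack", "larg_exchange_rate",
    "fs_from_concentration", "make_larg_scene", "random_vial_layout",
    "make_brain_scene", "inject_b0_artifact", "render_raw_stack",
    "segment_vials", "augment_pairs",
    "WATER_PROTON_MM", "LARG_DEFAULTS", "BRAIN_TISSUES",
]

#: water proton pool concentration, mM (2 protons x 55,500 mM water)
WATER_PROTON_MM = 111000.0

TRUTH_KEYS = ("volume_fraction", "exchange_rate", "t1_water", "t2_water",
              "b0_shift")

#: synthetic-world defaults for the L-arginine phantom.  k_base / k_0 are
#: calibration constants of the generator (chosen so the 3-ppm amine pool
#: spans slow exchange at pH 4 to ~1.2 kHz at pH 6, the base-catalysis
#: regime in which low-pH vials give the weakest CEST signal); water T1/T2
#: are plausible buffer values, not measured ones.
LARG_DEFAULTS = {
    "k_base": 1200.0,   # Hz at pH 6.0 (base-catalyzed component)
    "k_0": 50.0,        # Hz, pH-independent floor
    "n_protons": 3,     # exchangeable guanidinium protons at 3 ppm
    "t1_water": 2.5,    # s
    "t2_water": 0.8,    # s
    "t1_solute": 1.0,   # s
    "t2_solute": 0.04,  # s
    "chemical_shift": 3.0,  # ppm
}

#: WM/GM semisolid-MT parameter distributions (mean, SD) used by the brain
#: scene generator: f_ss as a fraction, k_ssw in Hz, plus water relaxation.
BRAIN_TISSUES = {
    "wm": {"fss": (0.187, 0.020), "kssw": (33.9, 5.2),
           "t1_water": 0.85, "t2_water": 0.07},
    "gm": {"fss": (0.124, 0.027), "kssw": (49.1, 8.5),
           "t1_water": 1.30, "t2_water": 0.09},
    "tumor": {"fss": (0.09, 0.03), "kssw": (40.0, 8.0),
              "t1_water": 1.60, "t2_water": 0.12},
}


@dataclass
class PhantomScene:
    """Geometric scene: region labels, ground-truth maps, optional aux maps."""

    region_labels: np.ndarray                # int map; 0 background, 1..K regions
    truth_maps: Dict[str, np.ndarray]        # per-voxel physics (TRUTH_KEYS)
    aux_maps: Dict[str, np.ndarray] = field(default_factory=dict)
    voxel_size_mm: Tuple[float, ...] = (1.8, 1.8)
    solute: Dict[str, float] = field(default_factory=lambda: dict(
        t1=LARG_DEFAULTS["t1_solute"], t2=LARG_DEFAULTS["t2_solute"],
        chemical_shift=LARG_DEFAULTS["chemical_shift"]))
    lineshape: Optional[str] = None          # None = CEST pool, else semisolid
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.region_labels.shape
        for k in TRUTH_KEYS:
            if k not in self.truth_maps:
                raise ValueError(f"missing truth map {k!r}")
            if self.truth_maps[k].shape != shape:
                raise ValueError(f"truth map {k!r} shape mismatch")
        for k, v in self.aux_maps.items():
            if v.shape != shape:
                raise ValueError(f"aux map {k!r} shape mismatch")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.region_labels.shape

    @property
    def foreground(self) -> np.ndarray:
        """Voxels with simulable physics (positive water T1)."""
        return self.truth_maps["t1_water"] > 0


@dataclass
class RawImageStack:
    """M (or N) saturation-encoded images sharing the scene geometry."""

    images: np.ndarray            # (n_images, *spatial)
    schedule_label: str = ""
    noise_sigma: float = 0.0

    def __len__(self) -> int:
        return self.images.shape[0]


# ---------------------------------------------------------------------------
# Chemistry of the L-arginine pool
# ---------------------------------------------------------------------------

def larg_exchange_rate(ph, k_base: float = LARG_DEFAULTS["k_base"],
                       k_0: float = LARG_DEFAULTS["k_0"]):
    """Base-catalyzed amine proton exchange rate, Hz.

    k_sw(pH) = k_0 + k_base * 10**(pH - 6.0): a tenfold rate increase per pH
    unit, anchored so the base-catalyzed component equals ``k_base`` at
    pH 6.0.  Monotonically increasing in pH.
    """
    ph = np.asarray(ph, dtype=float)
    if np.any(ph < 0) or np.any(ph > 14):
        raise ValueError("pH must lie in [0, 14]")
    if k_base <= 0 or k_0 < 0:
        raise ValueError("require k_base > 0 and k_0 >= 0")
    out = k_0 + k_base * 10.0 ** (ph - 6.0)
    return float(out) if out.ndim == 0 else out


def fs_from_concentration(concentration, n_protons: int = LARG_DEFAULTS["n_protons"]):
    """Exchangeable proton volume fraction from solute concentration (mM).

    f_s = n_protons * C / 111000, referencing the two-proton, 55.5 M water
    pool.  50 mM with 3 protons gives f_s ≈ 1.35e-3.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    if n_protons < 1:
        raise ValueError("n_protons must be >= 1")
    out = n_protons * c / WATER_PROTON_MM
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# L-arginine vial scenes
# ---------------------------------------------------------------------------

def random_vial_layout(n_vials: int, shape: Tuple[int, int], seed: int = 0,
                       radius_range: Tuple[float, float] = (5.0, 8.0),
                       margin: int = 4, max_tries: int = 2000,
                       ) -> List[Tuple[float, float, float]]:
    """Random non-overlapping (row, col, radius) vial placements."""
    rng = np.random.default_rng(seed)
    placed: List[Tuple[float, float, float]] = []
    tries = 0
    while len(placed) < n_vials:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place non-overlapping vials")
        r = rng.uniform(*radius_range)
        cy = rng.uniform(margin + r, shape[0] - margin - r)
        cx = rng.uniform(margin + r, shape[1] - margin - r)
        if all(np.hypot(cy - y, cx - x) > r + rr + 1.5 for y, x, rr in placed):
            placed.append((cy, cx, r))
    return placed


def make_larg_scene(layout: Sequence[Tuple[float, float, float]],
                    concentrations: Sequence[float], phs: Sequence[float],
                    shape: Tuple[int, int] = (64, 64), seed: int = 0,
                    voxel_size_mm: Tuple[float, float] = (1.8, 1.8),
                    defaults: Dict[str, float] = LARG_DEFAULTS,
                    t1_jitter: float = 0.05) -> PhantomScene:
    """Circular L-arg vials on a saline-like background (f_s = 0).

    ``layout`` is a list of (row, col, radius) in voxels; vials must not
    overlap.  ``seed`` drives a small per-vial water-T1/T2 jitter so that
    repeated scenes are not pixel-identical in relaxation.
    """
    if not len(concentrations) == len(phs) == len(layout):
        raise ValueError("layout, concentrations and phs must have equal length")
    for i, (y1, x1, r1) in enumerate(layout):
        for y2, x2, r2 in layout[i + 1:]:
            if np.hypot(y1 - y2, x1 - x2) <= r1 + r2:
                raise ValueError("vials overlap")
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    truth = {k: np.zeros(shape) for k in TRUTH_KEYS}
    truth["t1_water"][:] = defaults["t1_water"]
    truth["t2_water"][:] = defaults["t2_water"]
    aux = {"concentration": np.zeros(shape), "pH": np.zeros(shape)}
    for i, ((cy, cx, r), conc, ph) in enumerate(zip(layout, concentrations, phs),
                                                start=1):
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        labels[mask] = i
        truth["volume_fraction"][mask] = fs_from_concentration(
            conc, defaults["n_protons"])
        truth["exchange_rate"][mask] = larg_exchange_rate(
            ph, defaults["k_base"], defaults["k_0"])
        truth["t1_water"][mask] = defaults["t1_water"] * \
            (1.0 + t1_jitter * rng.uniform(-1, 1))
        truth["t2_water"][mask] = defaults["t2_water"] * \
            (1.0 + t1_jitter * rng.uniform(-1, 1))
        aux["concentration"][mask] = conc
        aux["pH"][mask] = ph
    return PhantomScene(region_labels=labels, truth_maps=truth, aux_maps=aux,
                        voxel_size_mm=voxel_size_mm,
                        meta={"kind": "larg", "seed": seed,
                              "concentrations": list(map(float, concentrations)),
                              "phs": list(map(float, phs))})


# ---------------------------------------------------------------------------
# Brain-like semisolid-MT scenes
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def make_brain_scene(shape: Tuple[int, int] = (64, 64), tumor: bool = False,
                     seed: int = 0, smooth_sigma: float = 3.0,
                     tissues: Dict = BRAIN_TISSUES) -> PhantomScene:
    """Procedural WM/GM (optionally tumor) scene with semisolid-MT truth maps.

    An elliptical head mask is partitioned into white and gray matter by
    thresholding a smoothed random field (no anatomical atlas involved);
    per-voxel f_ss and k_ssw are drawn from the tissue Gaussians truncated at
    physical bounds.  The solute pool is a semisolid (Lorentzian lineshape,
    T2s = 10 us) centered at 0 ppm.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    head = ((yy - cy) / (0.45 * shape[0])) ** 2 + \
           ((xx - cx) / (0.42 * shape[1])) ** 2 <= 1.0
    fieldr = gaussian_filter(rng.normal(size=shape), smooth_sigma)
    wm = head & (fieldr > np.median(fieldr[head]))
    gm = head & ~wm
    labels = np.zeros(shape, dtype=np.int32)
    labels[wm] = 1
    labels[gm] = 2
    truth = {k: np.zeros(shape) for k in TRUTH_KEYS}
    aux: Dict[str, np.ndarray] = {}
    regions = [("wm", wm), ("gm", gm)]
    if tumor:
        ty = rng.uniform(0.3, 0.7) * shape[0]
        tx = rng.uniform(0.3, 0.7) * shape[1]
        tr = 0.12 * min(shape)
        tmask = head & (((yy - ty) ** 2 + (xx - tx) ** 2) <= tr ** 2)
        labels[tmask] = 3
        regions = [("wm", wm & ~tmask), ("gm", gm & ~tmask), ("tumor", tmask)]
    for name, mask in regions:
        spec = tissues[name]
        n = int(mask.sum())
        truth["volume_fraction"][mask] = _truncated_normal(
            rng, *spec["fss"], 1e-4, 0.5, n)
        truth["exchange_rate"][mask] = _truncated_normal(
            rng, *spec["kssw"], 1.0, 150.0, n)
        truth["t1_water"][mask] = spec["t1_water"]
        truth["t2_water"][mask] = spec["t2_water"]
    return PhantomScene(region_labels=labels, truth_maps=truth, aux_maps=aux,
                        solute=dict(t1=1.0, t2=10e-6, chemical_shift=0.0),
                        lineshape="lorentzian",
                        meta={"kind": "brain", "seed": seed, "tumor": tumor})


def inject_b0_artifact(scene: PhantomScene, n_blobs: int = 2,
                       max_shift_ppm: float = 0.3, seed: int = 0,
                       sigma_range: Tuple[float, float] = (3.0, 6.0),
                       ) -> PhantomScene:
    """Add smooth localized Gaussian-profile B0 offsets (susceptibility blobs).

    Each blob peaks at +/- ``max_shift_ppm`` ppm at its centre; other truth
    maps are untouched.  Returns a new scene; blob masks (|shift| > 10% of
    peak) are stored in ``meta['b0_blob_mask']``.
    """
    if max_shift_ppm < 0:
        raise ValueError("max_shift_ppm must be >= 0")
    rng = np.random.default_rng(seed)
    shape = scene.shape
    b0 = scene.truth_maps["b0_shift"].copy()
    blob_mask = np.zeros(shape, dtype=bool)
    if max_shift_ppm > 0:
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        fg = np.argwhere(scene.foreground)
        for _ in range(n_blobs):
            cy, cx = fg[rng.integers(len(fg))]
            sig = rng.uniform(*sigma_range)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            prof = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig ** 2)))
            b0 += sign * max_shift_ppm * prof
            blob_mask |= prof > 0.1
    truth = dict(scene.truth_maps)
    truth["b0_shift"] = b0
    meta = dict(scene.meta)
    meta["b0_blob_mask"] = blob_mask
    return PhantomScene(region_labels=scene.region_labels.copy(),
                        truth_maps=truth, aux_maps=dict(scene.aux_maps),
                        voxel_size_mm=scene.voxel_size_mm,
                        solute=dict(scene.solute), lineshape=scene.lineshape,
                        meta=meta)


# ---------------------------------------------------------------------------
# Rendering and segmentation
# ---------------------------------------------------------------------------

def render_raw_stack(scene: PhantomScene, schedule, noise_sigma: float = 0.0,
                     noise_model: str = "rician", seed: int = 0,
                     b0_field: float = 3.0) -> RawImageStack:
    """Simulate the raw image stack of a scene through a schedule.

    Per-voxel trajectories are computed once per unique tissue-parameter
    tuple (piecewise-constant scenes render in a handful of simulations).
    Noise is added per image: Gaussian, or Rician as appropriate for
    magnitude MRI (sqrt((s+n1)^2 + n2^2)).  Voxels without physics
    (t1_water = 0) stay at signal 0 before noise.
    """
    if noise_model not in ("gaussian", "rician"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    for k in TRUTH_KEYS:
        if k not in scene.truth_maps:
            raise ValueError(f"scene lacks truth map {k!r}")
    shape = scene.shape
    m = len(schedule)
    fg = scene.foreground
    cols = np.stack([scene.truth_maps[k][fg] for k in TRUTH_KEYS], axis=1)
    uniq, inv = np.unique(cols, axis=0, return_inverse=True)
    params = {
        "fs": uniq[:, 0], "ksw": uniq[:, 1], "t1w": uniq[:, 2],
        "t2w": uniq[:, 3], "b0_shift": uniq[:, 4],
        "t1s": np.full(len(uniq), scene.solute["t1"]),
        "t2s": np.full(len(uniq), scene.solute["t2"]),
        "shift_ppm": np.full(len(uniq), scene.solute["chemical_shift"]),
        "b1_scale": np.ones(len(uniq)),
    }
    traj = simulate_trajectories(params, schedule, b0_field=b0_field,
                                 lineshape=scene.lineshape)
    stack = np.zeros((m,) + shape)
    vox = traj[inv]                      # (n_fg, M)
    for i in range(m):
        img = np.zeros(shape)
        img[fg] = vox[:, i]
        stack[i] = img
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        if noise_model == "gaussian":
            stack = stack + rng.normal(0.0, noise_sigma, size=stack.shape)
        else:
            n1 = rng.normal(0.0, noise_sigma, size=stack.shape)
            n2 = rng.normal(0.0, noise_sigma, size=stack.shape)
            stack = np.sqrt((stack + n1) ** 2 + n2 ** 2)
    return RawImageStack(images=stack,
                         schedule_label=getattr(schedule, "label", ""),
                         noise_sigma=noise_sigma)


def segment_vials(image: np.ndarray, radius_range: Tuple[int, int] = (4, 10),
                  max_vials: int = 12, canny_sigma: float = 1.5,
                  ) -> Tuple[np.ndarray, List[Tuple[float, float, float]]]:
    """Detect circular vials via Canny edges + circle Hough transform.

    Returns (labeled mask, list of (row, col, radius)).  Zero detected
    circles yields an empty result with a warning rather than an exception.
    """
    img = np.asarray(image, dtype=float)
    rng_ = img.max() - img.min()
    edges = canny(((img - img.min()) / rng_) if rng_ > 0 else img,
                  sigma=canny_sigma)
    radii = np.arange(radius_range[0], radius_range[1] + 1)
    h = hough_circle(edges, radii)
    accums, cxs, cys, rads = hough_circle_peaks(
        h, radii, total_num_peaks=max_vials, min_xdistance=radius_range[0],
        min_ydistance=radius_range[0], threshold=0.45 * h.max() if h.size else None)
    labels = np.zeros(img.shape, dtype=np.int32)
    circles: List[Tuple[float, float, float]] = []
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    for i, (cy, cx, r) in enumerate(zip(cys, cxs, rads), start=1):
        if any(np.hypot(cy - y0, cx - x0) < 0.8 * (r + r0)
               for y0, x0, r0 in circles):
            continue
        circles.append((float(cy), float(cx), float(r)))
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2] = len(circles)
    if not circles:
        warnings.warn("no circles detected", stacklevel=2)
    return labels, circles


# ---------------------------------------------------------------------------
# Data augmentation
# ---------------------------------------------------------------------------

def _translate(arr: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift the trailing two (spatial) axes, zero-filling exposed borders."""
    out = np.zeros_like(arr)
    h, w = arr.shape[-2:]
    ys, yd = (slice(0, h - dy), slice(dy, h)) if dy >= 0 else \
        (slice(-dy, h), slice(0, h + dy))
    xs, xd = (slice(0, w - dx), slice(dx, w)) if dx >= 0 else \
        (slice(-dx, w), slice(0, w + dx))
    out[..., yd, xd] = arr[..., ys, xs]
    return out


def augment_pairs(pairs: Sequence[Tuple[np.ndarray, np.ndarray]], seed: int = 0,
                  max_shift: int = 5) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Sevenfold augmentation: original + flips + seeded translations.

    Each (input stack, target maps) source pair — arrays with spatial axes
    last, e.g. (C, H, W) — yields exactly 7 pairs: the original, horizontal
    and vertical flips, and four random translations.  The identical
    transform is applied to input and target, preserving pairing.
    """
    rng = np.random.default_rng(seed)
    out: List[Tuple[np.ndarray, np.ndarray]] = []
    for x, y in pairs:
        out.append((x, y))
        out.append((x[..., :, ::-1].copy(), y[..., :, ::-1].copy()))
        out.append((x[..., ::-1, :].copy(), y[..., ::-1, :].copy()))
        for _ in range(4):
            dy = int(rng.integers(-max_shift, max_shift + 1))
            dx = int(rng.integers(-max_shift, max_shift + 1))
            out.append((_translate(x, dy, dx), _translate(y, dy, dx)))
    return out
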