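"""Desk-scale end-to-end studies on synthetic phantoms.

This module wires the full pipeline together: simulate an acquisition,
build the dictionary, train the reference quantifier, render synthetic
L-arginine scenes, train the adversarial reconstructor on truncated (N-of-M)
stacks against the reference maps, and evaluate agreement on held-out
scenes.  It is what the command-line ``demo``, the examples and the
acceptance script all call, so every consumer runs the same study.

Study design notes
------------------
* Reference ("ground truth") maps are produced by the reference FCN applied
  to a full-length, artifact-free (but noisy) rendering of each scene.
  Input stacks are rendered independently — with localized B0/susceptibility
  blobs injected into half of the scenes — and truncated to the first N
  images.  Training towards artifact-free references is what gives the
  spatial reconstructor its artifact-mitigation behaviour, which is then
  probed on held-out blob scenes against brute-force dictionary matching.
* Vial pH values are drawn from a fixed ladder of levels so that held-out
  vials can be grouped by true pH when checking the direct pH-mapping
  monotonicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .dictionary import (MRFDictionary, ParameterGrid, dot_product_match,
                         generate_dictionary)
from .gan import (GanConfig, LossWeights, TrainedGenerator, TrainingPair,
                  normalize_stack, reconstruct_volume,
                  retarget_to_direct_quantities, train_gan)
from .metrics import pearson_and_icc
from .phantom import (LARG_DEFAULTS, PhantomScene, RawImageStack,
                      augment_pairs, inject_b0_artifact, make_larg_scene,
                      random_vial_layout, render_raw_stack)
from .physics import PoolParameters, TissueParameters
from .reference import FCNConfig, ReferenceFCN, quantify_stack, train_reference_fcn
from .schedule import (AcquisitionSchedule, generate_pseudorandom_schedule,
                       truncate_schedule)

__all__ = ["StudyConfig", "StudyResult", "default_larg_tissue", "larg_grid",
           "build_scene_set", "run_larg_study"]

#: pH ladder of the synthetic vials: five levels across the 4.0-6.0
#: titration range
PH_LEVELS = (4.0, 4.5, 5.0, 5.5, 6.0)
#: vial concentrations, mM
CONCENTRATIONS = (25.0, 50.0, 100.0)


def default_larg_tissue() -> TissueParameters:
    """Baseline L-arginine tissue (water + 3-ppm amine pool)."""
    d = LARG_DEFAULTS
    return TissueParameters(
        water=PoolParameters(t1=d["t1_water"], t2=d["t2_water"]),
        solute=PoolParameters(t1=d["t1_solute"], t2=d["t2_solute"],
                              chemical_shift=d["chemical_shift"],
                              exchange_rate=400.0, volume_fraction=1.35e-3))


def larg_grid(n_fs: int = 41, n_ksw: int = 41) -> ParameterGrid:
    """Default (f_s x k_sw) dictionary grid covering the vial range."""
    return ParameterGrid(axes={
        "volume_fraction": list(np.linspace(1e-4, 3.5e-3, n_fs)),
        "exchange_rate": list(np.linspace(20.0, 1400.0, n_ksw)),
    })


@dataclass
class StudyConfig:
    """Knobs of the desk-scale L-arginine study (defaults = study conditions)."""

    m: int = 30                    # full schedule length
    n: int = 9                     # truncated input length
    shape: Tuple[int, int] = (64, 64)
    n_train_scenes: int = 29       # x7 augmentation ~= 200 training slices
    n_test_scenes: int = 6
    n_vials: int = 6
    noise_sigma: float = 1e-3      # Rician noise on raw images
    b0_blob_fraction: float = 0.5  # fraction of scenes given B0 artifacts
    b0_max_shift_ppm: float = 0.3
    grid_size: Tuple[int, int] = (41, 41)
    fcn_hidden: Tuple[int, ...] = (100, 100)
    fcn_epochs: int = 400
    gan_epochs: int = 100
    gan_patience: int = 12
    retarget_epochs: int = 30
    gan_base_width: int = 12
    gan_depth: int = 3
    seed: int = 1


@dataclass
class StudyResult:
    """Everything the demo/acceptance path reports."""

    schedule: AcquisitionSchedule
    dictionary: MRFDictionary
    fcn: ReferenceFCN
    generator: TrainedGenerator
    generator_direct: Optional[TrainedGenerator]
    metrics: Dict[str, float]
    tables: Dict[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

def build_scene_set(config: StudyConfig, seed: int, n_scenes: int,
                    with_blobs: bool = True) -> List[PhantomScene]:
    """Random vial scenes with pH drawn from the ladder, seeded.

    Assignment cycles through pH levels and concentrations with a random
    offset per scene, so any handful of scenes covers the full ladder.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    scenes = []
    for i in range(n_scenes):
        layout = random_vial_layout(config.n_vials, config.shape,
                                    seed=int(rng.integers(2 ** 31)))
        off = int(rng.integers(len(PH_LEVELS)))
        phs = [PH_LEVELS[(off + j) % len(PH_LEVELS)]
               for j in range(config.n_vials)]
        offc = int(rng.integers(len(CONCENTRATIONS)))
        concs = [CONCENTRATIONS[(offc + j) % len(CONCENTRATIONS)]
                 for j in range(config.n_vials)]
        scene = make_larg_scene(layout, concs, phs, shape=config.shape,
                                seed=int(rng.integers(2 ** 31)))
        if with_blobs and config.b0_blob_fraction > 0 \
                and rng.random() < config.b0_blob_fraction:
            scene = inject_b0_artifact(scene, n_blobs=2,
                                       max_shift_ppm=config.b0_max_shift_ppm,
                                       seed=int(rng.integers(2 ** 31)))
            # quantize the blob profile so rendering caches per-level
            b0 = scene.truth_maps["b0_shift"]
            scene.truth_maps["b0_shift"] = np.round(b0 / 0.01) * 0.01
        scenes.append(scene)
    return scenes


def _scene_pairs(scene: PhantomScene, sched_full: AcquisitionSchedule,
                 n: int, fcn: ReferenceFCN, noise_sigma: float,
                 seed: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Input stack (N,H,W), reference target (2,H,W), mask, aux maps.

    The reference maps come from the FCN on an artifact-free full-length
    rendering; the input stack from an independent rendering of the scene as
    given (possibly with B0 blobs), truncated to the first ``n`` images.
    """
    clean = scene
    if np.any(scene.truth_maps["b0_shift"] != 0):
        truth = dict(scene.truth_maps)
        truth["b0_shift"] = np.zeros(scene.shape)
        clean = PhantomScene(region_labels=scene.region_labels,
                             truth_maps=truth, aux_maps=scene.aux_maps,
                             voxel_size_mm=scene.voxel_size_mm,
                             solute=scene.solute, lineshape=scene.lineshape,
                             meta=scene.meta)
    full = render_raw_stack(clean, sched_full, noise_sigma=noise_sigma,
                            noise_model="rician", seed=seed)
    ref_maps, valid = quantify_stack(fcn, full)
    # background masking (the vial-segmentation preprocessing step): outside
    # the vials f_s = 0 and the exchange parameters are unidentifiable, so
    # reference maps are zeroed there rather than carrying quantifier noise
    vials = scene.region_labels > 0
    target = np.stack([ref_maps["volume_fraction"] * vials,
                       ref_maps["exchange_rate"] * vials])
    acq = render_raw_stack(scene, sched_full, noise_sigma=noise_sigma,
                           noise_model="rician", seed=seed + 1)
    inp = normalize_stack(acq.images[:n])
    # evaluation region = the vials, matching the background masking above
    mask = vials & valid
    return inp, target, mask, dict(scene.aux_maps)


# ---------------------------------------------------------------------------
# The study
# ---------------------------------------------------------------------------

def run_larg_study(config: StudyConfig = StudyConfig(),
                   with_retarget: bool = True,
                   with_blob_eval: bool = True) -> StudyResult:
    """Run the full accelerated-quantification study at desk scale.

    Returns the trained models plus a metrics dict with, among others,
    ``pearson_fs`` / ``pearson_ksw`` (held-out voxelwise agreement between
    the adversarial reconstruction from N images and the full-length
    reference), per-concentration and per-pH group medians, and the in-blob
    error comparison against dictionary matching.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(8)]
    sched_seed, fcn_seed, gan_seed, scn_seed, tst_seed, rnd_seed, rt_seed, _ \
        = seeds

    sched_full = generate_pseudorandom_schedule(config.m, "cest_3ppm",
                                                seed=sched_seed,
                                                m0_first=True)
    sched_n = truncate_schedule(sched_full, config.n)
    base = default_larg_tissue()
    grid = larg_grid(*config.grid_size)
    dictionary = generate_dictionary(grid, sched_full, base)
    fcn = train_reference_fcn(dictionary, FCNConfig(
        input_length=config.m, hidden_layers=config.fcn_hidden,
        epochs=config.fcn_epochs, seed=fcn_seed))

    # the truncated-classical-matching comparator: a pixelwise quantifier
    # trained on the first-N dictionary, quantifying the same N images
    fcn9 = train_reference_fcn(
        generate_dictionary(grid, sched_n, base),
        FCNConfig(input_length=config.n, hidden_layers=config.fcn_hidden,
                  epochs=config.fcn_epochs, seed=fcn_seed))

    train_scenes = build_scene_set(config, scn_seed, config.n_train_scenes)
    test_scenes = build_scene_set(config, tst_seed, config.n_test_scenes)

    # -- training pairs (targets carry 4 channels so augmentation stays
    #    paired across the exchange-parameter and direct-quantity targets)
    raw_pairs = []
    for i, scene in enumerate(train_scenes):
        inp, target, mask, aux = _scene_pairs(
            scene, sched_full, config.n, fcn, config.noise_sigma,
            seed=rnd_seed + 7 * i)
        ext_target = np.concatenate([
            target, aux["concentration"][None], aux["pH"][None],
            mask[None].astype(float)])
        raw_pairs.append((inp, ext_target))
    aug = augment_pairs(raw_pairs, seed=rnd_seed)
    pairs, pairs_direct = [], []
    for inp, ext in aug:
        mask = ext[4] > 0.5
        pairs.append(TrainingPair(input_stack=inp, target_maps=ext[:2],
                                  mask=mask))
        pairs_direct.append(TrainingPair(
            input_stack=inp, target_maps=ext[2:4], mask=mask,
            target_names=("concentration", "pH")))

    gan_cfg = GanConfig(n_input_channels=config.n,
                        gen_base_width=config.gan_base_width,
                        disc_base_width=config.gan_base_width,
                        gen_depth=config.gan_depth,
                        disc_depth=config.gan_depth,
                        epochs=config.gan_epochs,
                        early_stopping_patience=config.gan_patience,
                        seed=gan_seed)
    generator, log = train_gan(pairs, gan_cfg, LossWeights())

    # -- held-out evaluation versus the full-length reference
    metrics: Dict[str, float] = {}
    pooled = {"volume_fraction": ([], []), "exchange_rate": ([], [])}
    pooled9 = {"volume_fraction": [], "exchange_rate": []}
    vial_rows = []
    blob_gan_err, blob_mrf_err = [], []
    for i, scene in enumerate(test_scenes):
        inp, target, mask, aux = _scene_pairs(
            scene, sched_full, config.n, fcn, config.noise_sigma,
            seed=rnd_seed + 1000 + 7 * i)
        maps, _ = reconstruct_volume(
            generator, RawImageStack(images=inp), normalized=True)
        acq9 = render_raw_stack(scene, sched_n,
                                noise_sigma=config.noise_sigma,
                                noise_model="rician",
                                seed=rnd_seed + 1001 + 7 * i)
        maps9, _ = quantify_stack(fcn9, acq9)
        ref = {"volume_fraction": target[0], "exchange_rate": target[1]}
        for j, name in enumerate(("volume_fraction", "exchange_rate")):
            pooled[name][0].append(maps[name][mask])
            pooled[name][1].append(ref[name][mask])
            pooled9[name].append(maps9[name][mask])
        labels = scene.region_labels
        for lab in np.unique(labels[labels > 0]):
            vm = (labels == lab) & mask
            if vm.sum() < 5:
                continue
            est_fs = float(np.median(maps["volume_fraction"][vm]))
            vial_rows.append({
                "scene": i, "vial": int(lab),
                "true_concentration": float(np.median(aux["concentration"][vm])),
                "true_pH": float(np.median(aux["pH"][vm])),
                "est_concentration": est_fs * 111000.0 / LARG_DEFAULTS["n_protons"],
                "est_ksw": float(np.median(maps["exchange_rate"][vm])),
            })
        if with_blob_eval and "b0_blob_mask" in scene.meta \
                and scene.meta["b0_blob_mask"].any():
            bm = scene.meta["b0_blob_mask"] & mask
            if bm.sum() >= 10:
                acq = render_raw_stack(scene, sched_full,
                                       noise_sigma=config.noise_sigma,
                                       noise_model="rician",
                                       seed=rnd_seed + 2000 + i)
                est, _ = dot_product_match(
                    np.moveaxis(acq.images, 0, -1), dictionary)
                truth_k = scene.truth_maps["exchange_rate"]
                blob_mrf_err.append(np.abs(est["exchange_rate"][bm] - truth_k[bm]))
                blob_gan_err.append(np.abs(maps["exchange_rate"][bm] - truth_k[bm]))

    def _safe_corr(a, b):
        # miniature configurations can produce constant predictions; report
        # them as nan agreement rather than failing the whole study
        if np.std(a) == 0 or np.std(b) == 0:
            return (float("nan"), float("nan")), float("nan")
        return pearson_and_icc(a, b)

    for name, key in (("volume_fraction", "fs"), ("exchange_rate", "ksw")):
        p = np.concatenate(pooled[name][0])
        r = np.concatenate(pooled[name][1])
        (rho, pval), icc = _safe_corr(p, r)
        metrics[f"pearson_{key}"] = rho
        metrics[f"icc_{key}"] = icc
        metrics[f"p_value_{key}"] = pval
        (rho9, _), _ = _safe_corr(np.concatenate(pooled9[name]), r)
        metrics[f"pearson_{key}_mrf_n{config.n}"] = rho9
        metrics["n_eval_voxels"] = len(p)
    metrics["n_eval_vials"] = len(vial_rows)

    from scipy import stats as _st
    true_c = np.array([v["true_concentration"] for v in vial_rows])
    est_c = np.array([v["est_concentration"] for v in vial_rows])
    metrics["conc_spearman"] = float("nan") if np.std(est_c) == 0 else \
        float(_st.spearmanr(true_c, est_c).statistic)
    conc_medians = {c: float(np.median(est_c[true_c == c]))
                    for c in sorted(set(true_c))}
    metrics["conc_group_medians"] = conc_medians
    levels = sorted(conc_medians)
    metrics["conc_rank_ordered"] = all(
        conc_medians[a] < conc_medians[b] for a, b in zip(levels, levels[1:]))
    if blob_mrf_err:
        metrics["blob_ksw_mae_gan"] = float(np.mean(np.concatenate(blob_gan_err)))
        metrics["blob_ksw_mae_mrf"] = float(np.mean(np.concatenate(blob_mrf_err)))

    # -- direct concentration/pH mapping (retargeted training)
    generator_direct = None
    if with_retarget:
        pairs_d, cfg_d = retarget_to_direct_quantities(
            pairs_direct, [{"concentration": p.target_maps[0],
                            "pH": p.target_maps[1]} for p in pairs_direct],
            gan_cfg)
        cfg_d.epochs = config.retarget_epochs
        cfg_d.seed = rt_seed
        generator_direct, _ = train_gan(pairs_d, cfg_d, LossWeights(),
                                        init_from=generator)
        ph_true, ph_est = [], []
        for i, scene in enumerate(test_scenes):
            inp, _, mask, aux = _scene_pairs(
                scene, sched_full, config.n, fcn, config.noise_sigma,
                seed=rnd_seed + 1000 + 7 * i)
            maps_d, _ = reconstruct_volume(
                generator_direct, RawImageStack(images=inp), normalized=True)
            labels = scene.region_labels
            for lab in np.unique(labels[labels > 0]):
                vm = (labels == lab) & mask
                if vm.sum() < 5:
                    continue
                ph_true.append(float(np.median(aux["pH"][vm])))
                ph_est.append(float(np.median(maps_d["pH"][vm])))
        ph_true, ph_est = np.array(ph_true), np.array(ph_est)
        ph_medians = {lv: float(np.median(ph_est[ph_true == lv]))
                      for lv in sorted(set(ph_true))}
        metrics["ph_group_medians"] = ph_medians
        lv = sorted(ph_medians)
        steps = [ph_medians[a] < ph_medians[b] for a, b in zip(lv, lv[1:])]
        metrics["ph_levels_evaluated"] = len(lv)
        metrics["ph_monotone"] = all(steps)
        metrics["ph_monotone_fraction"] = float(np.mean(steps))
        metrics["ph_spearman"] = float(_st.spearmanr(ph_true, ph_est).statistic)

    metrics["n_training_pairs"] = len(pairs)
    metrics["best_epoch"] = int(log.attrs.get("best_epoch", -1))
    return StudyResult(schedule=sched_full, dictionary=dictionary, fcn=fcn,
                       generator=generator, generator_direct=generator_direct,
                       metrics=metrics,
                       tables={"vials": vial_rows, "training_log": log})
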