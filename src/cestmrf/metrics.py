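"""Evaluation statistics for quantitative parameter maps.

NRMSE (range-normalized, in %), SSIM, Pearson correlation and the
intraclass correlation coefficient, with masked and per-region variants —
the statistics used to compare an accelerated reconstruction against its
full-length reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from skimage.metrics import structural_similarity

__all__ = ["nrmse", "ssim", "pearson_and_icc", "region_table",
           "EvaluationReport", "evaluate_maps"]


def nrmse(pred: np.ndarray, ref: np.ndarray, mask: Optional[np.ndarray] = None,
          normalizer: str = "range") -> float:
    """Normalized root-mean-square error between two maps, in percent.

    RMSE over the mask divided by the reference's in-mask dynamic range
    (``normalizer="range"``, the default) or its mean (``"mean"``), x100.
    """
    pred, ref = np.asarray(pred, float), np.asarray(ref, float)
    if pred.shape != ref.shape:
        raise ValueError("shape mismatch")
    m = np.ones(ref.shape, bool) if mask is None else np.asarray(mask, bool)
    if not m.any():
        raise ValueError("mask is empty")
    p, r = pred[m], ref[m]
    if normalizer == "range":
        scale = r.max() - r.min()
    elif normalizer == "mean":
        scale = abs(r.mean())
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    if scale == 0:
        raise ValueError("reference is constant within the mask; "
                         "NRMSE normalization undefined")
    return float(np.sqrt(np.mean((p - r) ** 2)) / scale * 100.0)


def ssim(pred: np.ndarray, ref: np.ndarray, mask: Optional[np.ndarray] = None,
         data_range: Optional[float] = None) -> float:
    """Mean structural similarity index over the mask.

    Standard SSIM with a Gaussian window (sigma 1.5) and the canonical
    stabilizing constants K1 = 0.01, K2 = 0.03 over ``data_range`` (default:
    the reference's dynamic range).  Images smaller than the 11-pixel
    Gaussian window fall back to a uniform window spanning the shorter side.
    """
    pred, ref = np.asarray(pred, float), np.asarray(ref, float)
    if pred.shape != ref.shape:
        raise ValueError("shape mismatch")
    if data_range is None:
        data_range = float(ref.max() - ref.min()) or 1.0
    if min(ref.shape) >= 11:
        kw = dict(gaussian_weights=True, sigma=1.5,
                  use_sample_covariance=False)
    else:
        win = min(ref.shape) if min(ref.shape) % 2 else min(ref.shape) - 1
        kw = dict(win_size=win)
    _, smap = structural_similarity(
        ref, pred, data_range=data_range, full=True, **kw)
    m = np.ones(ref.shape, bool) if mask is None else np.asarray(mask, bool)
    return float(smap[m].mean())


def pearson_and_icc(pred: np.ndarray, ref: np.ndarray,
                    icc_type: str = "ICC2",
                    ) -> Tuple[Tuple[float, float], float]:
    """Pearson r (with two-sided p) and the intraclass correlation.

    The ICC is the two-way mixed-effects, single-rater, absolute-agreement
    form (ICC2 in the Shrout-Fleiss nomenclature) computed from the standard
    ANOVA decomposition; pass ``icc_type="ICC3"`` for the consistency form.
    """
    pred = np.asarray(pred, float).ravel()
    ref = np.asarray(ref, float).ravel()
    if pred.size != ref.size:
        raise ValueError("length mismatch")
    if pred.size < 3:
        raise ValueError("need at least 3 paired values")
    if not (np.isfinite(pred).all() and np.isfinite(ref).all()):
        raise ValueError("non-finite values")
    if np.std(pred) == 0 or np.std(ref) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(pred, ref)
    n = pred.size
    df = pd.DataFrame({
        "targets": np.tile(np.arange(n), 2),
        "raters": np.repeat(["pred", "ref"], n),
        "score": np.concatenate([pred, ref]),
    })
    table = pg.intraclass_corr(data=df, targets="targets", raters="raters",
                               ratings="score").set_index("Type")
    # pingouin labels the Shrout-Fleiss forms ICC2/ICC3 or ICC(A,1)/ICC(C,1)
    # depending on version; accept either
    aliases = {"ICC2": ("ICC2", "ICC(A,1)"), "ICC3": ("ICC3", "ICC(C,1)")}
    for lab in aliases.get(icc_type, (icc_type,)):
        if lab in table.index:
            return (float(r), float(p)), float(table.loc[lab, "ICC"])
    raise KeyError(f"ICC type {icc_type!r} not in pingouin output")


def region_table(maps: Dict[str, np.ndarray], labels: np.ndarray,
                 ) -> pd.DataFrame:
    """Per-region (vial/tissue label) median and IQR of each map."""
    rows = []
    for lab in np.unique(labels[labels > 0]):
        m = labels == lab
        for name, arr in maps.items():
            q1, med, q3 = np.percentile(arr[m], [25, 50, 75])
            rows.append({"region": int(lab), "map": name, "median": med,
                         "q1": q1, "q3": q3, "n_voxels": int(m.sum())})
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Bundle of per-map image statistics and voxelwise agreement."""

    per_map: Dict[str, Dict[str, float]]        # map -> {nrmse, ssim}
    per_volume: Dict[str, Dict[str, float]]     # map -> {pearson_r, icc, p}
    regions: Optional[pd.DataFrame] = None
    mask_voxels: int = 0

    def to_dict(self) -> dict:
        out = {"per_map": self.per_map, "per_volume": self.per_volume,
               "mask_voxels": self.mask_voxels}
        if self.regions is not None:
            out["regions"] = self.regions.to_dict(orient="records")
        return out


def evaluate_maps(pred: Dict[str, np.ndarray], ref: Dict[str, np.ndarray],
                  mask: np.ndarray,
                  labels: Optional[np.ndarray] = None) -> EvaluationReport:
    """Full comparison of predicted vs reference maps over a mask."""
    per_map, per_volume = {}, {}
    for name in pred:
        per_map[name] = {"nrmse": nrmse(pred[name], ref[name], mask),
                         "ssim": ssim(pred[name], ref[name], mask)}
        (r, p), icc = pearson_and_icc(pred[name][mask], ref[name][mask])
        per_volume[name] = {"pearson_r": r, "p_value": p, "icc": icc}
    regions = region_table(pred, labels) if labels is not None else None
    return EvaluationReport(per_map=per_map, per_volume=per_volume,
                            regions=regions, mask_voxels=int(mask.sum()))
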