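"""File formats: NIfTI volumes with JSON sidecars, configs, reports.

Conventions: all volumes are written as NIfTI (.nii.gz) with the voxel size
in the header affine; every volume gets a JSON sidecar recording units,
seeds and provenance.  Parameter maps store the proton volume fraction as a
dimensionless fraction (display as %), exchange rates in Hz, concentration
in mM and pH unitless.  Axis order is (x, y, slice), 0-based.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

from .phantom import RawImageStack

__all__ = ["save_map", "load_map", "save_stack", "load_stack",
           "save_json", "load_json", "save_fcn", "load_fcn",
           "save_generator", "load_generator"]

UNITS = {"volume_fraction": "fraction", "exchange_rate": "Hz",
         "concentration": "mM", "pH": "pH", "b0_shift": "ppm",
         "t1_water": "s", "t2_water": "s"}


def _affine(voxel_size: Tuple[float, ...]) -> np.ndarray:
    aff = np.eye(4)
    for i, v in enumerate(voxel_size[:3]):
        aff[i, i] = v
    return aff


def _default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if is_dataclass(obj):
        return asdict(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def save_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_default))


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


def save_map(arr: np.ndarray, path, name: str = "",
             voxel_size: Tuple[float, ...] = (1.8, 1.8, 1.8),
             sidecar: Optional[dict] = None) -> None:
    """Write a parameter map as NIfTI plus a JSON sidecar with units."""
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), _affine(voxel_size)),
             str(path))
    meta = {"name": name, "units": UNITS.get(name, "unknown"),
            "voxel_size_mm": list(voxel_size)}
    meta.update(sidecar or {})
    save_json(meta, path.with_suffix("").with_suffix(".json")
              if path.suffix == ".gz" else path.with_suffix(".json"))


def _sidecar_path(path: Path) -> Path:
    p = Path(path)
    if p.suffix == ".gz":
        p = p.with_suffix("")
    return p.with_suffix(".json")


def load_map(path) -> Tuple[np.ndarray, dict]:
    img = nib.load(str(path))
    meta = {}
    sp = _sidecar_path(Path(path))
    if sp.exists():
        meta = load_json(sp)
    return np.asarray(img.dataobj), meta


def save_stack(stack: RawImageStack, path,
               voxel_size: Tuple[float, ...] = (1.8, 1.8, 1.8),
               sidecar: Optional[dict] = None) -> None:
    """Write a raw image stack (images along the last axis) with sidecar."""
    path = Path(path)
    data = np.moveaxis(stack.images, 0, -1).astype(np.float64)
    nib.save(nib.Nifti1Image(data, _affine(voxel_size)), str(path))
    meta = {"n_images": len(stack), "schedule_label": stack.schedule_label,
            "noise_sigma": stack.noise_sigma,
            "voxel_size_mm": list(voxel_size)}
    meta.update(sidecar or {})
    save_json(meta, _sidecar_path(path))


def load_stack(path) -> RawImageStack:
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.dataobj), -1, 0)
    meta = {}
    sp = _sidecar_path(Path(path))
    if sp.exists():
        meta = load_json(sp)
        if "n_images" in meta and meta["n_images"] != data.shape[0]:
            raise ValueError(
                f"{path}: sidecar records {meta['n_images']} images but the "
                f"volume holds {data.shape[0]}")
    return RawImageStack(images=data,
                         schedule_label=meta.get("schedule_label", ""),
                         noise_sigma=meta.get("noise_sigma", 0.0))


# ---------------------------------------------------------------------------
# Model checkpoints (npz weights + embedded JSON config/provenance)
# ---------------------------------------------------------------------------

def save_fcn(model, path, provenance: Optional[dict] = None) -> None:
    """Checkpoint a reference FCN (weights, scaling, config, provenance)."""
    from .reference import ReferenceFCN  # local import avoids cycles
    cfg = dict(model.config.__dict__)
    cfg["hidden_layers"] = list(cfg["hidden_layers"])
    cfg["output_names"] = list(cfg["output_names"])
    meta = {"config": cfg, "scaling": {k: list(v) for k, v in model.scaling.items()},
            "provenance": provenance or {}}
    weights = {f"w{i}": w for i, w in enumerate(model.net.get_weights())}
    np.savez(path, meta=json.dumps(meta, default=_default),
             input_mean=model.input_mean, input_sd=model.input_sd, **weights)


def load_fcn(path):
    from .reference import FCNConfig, ReferenceFCN
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    cfg = meta["config"]
    cfg["hidden_layers"] = tuple(cfg["hidden_layers"])
    cfg["output_names"] = tuple(cfg["output_names"])
    cfg["output_scaling"] = None
    model = ReferenceFCN(FCNConfig(**cfg),
                         {k: tuple(v) for k, v in meta["scaling"].items()})
    n = len(model.net.get_weights())
    model.net.set_weights([data[f"w{i}"] for i in range(n)])
    model.input_mean = data["input_mean"]
    model.input_sd = data["input_sd"]
    return model


def save_generator(generator, path, provenance: Optional[dict] = None) -> None:
    """Checkpoint a trained generator (weights + config + provenance)."""
    cfg = dict(generator.config.__dict__)
    cfg["output_names"] = list(cfg["output_names"])
    cfg["output_ranges"] = {k: list(v) for k, v in cfg["output_ranges"].items()}
    meta = {"config": cfg, "target_names": list(generator.target_names),
            "provenance": provenance or {}}
    weights = {f"w{i}": w for i, w in enumerate(generator.net.get_weights())}
    extra = {}
    if generator.input_mean is not None:
        extra = {"input_mean": generator.input_mean,
                 "input_sd": generator.input_sd}
    np.savez(path, meta=json.dumps(meta, default=_default), **extra, **weights)


def load_generator(path):
    from .gan import GanConfig, TrainedGenerator, build_generator
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    cfg = meta["config"]
    cfg["output_names"] = tuple(cfg["output_names"])
    cfg["output_ranges"] = {k: tuple(v) for k, v in cfg["output_ranges"].items()}
    config = GanConfig(**cfg)
    net = build_generator(config)
    n = len(net.get_weights())
    net.set_weights([data[f"w{i}"] for i in range(n)])
    mean = data["input_mean"] if "input_mean" in data else None
    sd = data["input_sd"] if "input_sd" in data else None
    return TrainedGenerator(net, config, tuple(meta["target_names"]),
                            input_mean=mean, input_sd=sd)
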