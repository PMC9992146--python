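"""Simulated-signal dictionaries and brute-force dot-product matching.

The dictionary is the classical-fingerprinting quantifier: simulate one
trajectory per point of a tissue-parameter grid, unit-normalize, and match a
measured trajectory to the grid point whose simulated trajectory has the
largest inner product (cosine similarity).  It is the oracle both neural
quantifiers are trained on or validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import h5py
import numpy as np

from .physics import (InvalidParameterError, TissueParameters,
                      normalize_trajectory, simulate_trajectories)

__all__ = ["ParameterGrid", "MRFDictionary", "generate_dictionary",
           "dot_product_match", "save_dictionary", "load_dictionary",
           "UNMATCHED"]

#: sentinel returned for unmatchable (all-zero) voxels
UNMATCHED = -1

#: grid axes the generator understands, mapped to simulate_trajectories keys
_AXIS_KEYS = {"volume_fraction": "fs", "exchange_rate": "ksw",
              "t1_water": "t1w", "t2_water": "t2w", "b0_shift": "b0_shift"}


@dataclass
class ParameterGrid:
    """Cartesian tissue-parameter grid.

    ``axes`` maps axis names (a subset of ``volume_fraction, exchange_rate,
    t1_water, t2_water, b0_shift``) to strictly increasing value lists;
    ``fixed`` holds parameters shared by every grid point.
    """

    axes: Dict[str, Sequence[float]]
    fixed: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.axes:
            raise ValueError("grid needs at least one axis")
        for name, vals in self.axes.items():
            if name not in _AXIS_KEYS:
                raise ValueError(f"unknown grid axis {name!r}")
            vals = np.asarray(vals, dtype=float)
            if len(vals) < 1 or np.any(np.diff(vals) <= 0):
                raise ValueError(f"axis {name!r} must be strictly increasing")
            self.axes[name] = vals

    @property
    def axis_names(self) -> List[str]:
        return list(self.axes)

    @property
    def shape(self) -> Tuple[int, ...]:
        return tuple(len(v) for v in self.axes.values())

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    def points(self) -> np.ndarray:
        """All grid points as an array (size, n_axes), C-order (last axis fastest)."""
        mesh = np.meshgrid(*self.axes.values(), indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)

    def flat_index(self, multi_index: Sequence[int]) -> int:
        return int(np.ravel_multi_index(tuple(multi_index), self.shape))


@dataclass
class MRFDictionary:
    """Parameter grid plus the matrix of unit-normalized simulated signals."""

    grid: ParameterGrid
    trajectories: np.ndarray  # (grid size, M), unit l2 rows
    schedule_label: str = ""

    def __post_init__(self) -> None:
        if self.trajectories.shape[0] != self.grid.size:
            raise ValueError("row count must equal grid size")

    @property
    def m(self) -> int:
        return self.trajectories.shape[1]


def _tissue_param_arrays(grid: ParameterGrid, base: TissueParameters) -> Dict[str, np.ndarray]:
    pts = grid.points()
    params = {
        "t1w": base.water.t1, "t2w": base.water.t2,
        "t1s": base.solute.t1, "t2s": base.solute.t2,
        "fs": base.solute.volume_fraction, "ksw": base.solute.exchange_rate,
        "shift_ppm": base.solute.chemical_shift,
        "b0_shift": base.b0_shift, "b1_scale": base.b1_scale,
    }
    params = {k: np.full(grid.size, float(v)) for k, v in params.items()}
    for j, name in enumerate(grid.axis_names):
        params[_AXIS_KEYS[name]] = pts[:, j]
    for name, v in grid.fixed.items():
        if name in _AXIS_KEYS:
            params[_AXIS_KEYS[name]] = np.full(grid.size, float(v))
    return params


def generate_dictionary(grid: ParameterGrid, schedule,
                        base_tissue: TissueParameters,
                        b0_field: float = 3.0) -> MRFDictionary:
    """Simulate and unit-normalize one trajectory per grid point.

    Deterministic; invalid grid values raise naming the offending point.
    """
    params = _tissue_param_arrays(grid, base_tissue)
    bad = (params["fs"] < 0) | (params["fs"] >= 1) | (params["ksw"] < 0) \
        | (params["t1w"] <= 0) | (params["t2w"] <= 0)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        pt = {n: params[_AXIS_KEYS[n]][i] for n in grid.axis_names}
        raise InvalidParameterError(f"unphysical grid point {i}: {pt}")
    raw = simulate_trajectories(params, schedule, b0_field=b0_field,
                                lineshape=base_tissue.solute.lineshape)
    return MRFDictionary(grid=grid, trajectories=normalize_trajectory(raw),
                         schedule_label=getattr(schedule, "label", ""))


def dot_product_match(signals: np.ndarray, dictionary: MRFDictionary,
                      ) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    """Match trajectories to the grid by maximum inner product.

    Parameters
    ----------
    signals : array (..., M)
        Raw or normalized trajectories; normalization is applied internally,
        so matching is invariant to positive scaling.

    Returns
    -------
    estimates : dict of axis name -> array of matched grid values (shape of
        the leading dims of ``signals``); unmatchable (all-zero) voxels get 0.
    indices : int array of flat grid indices, ``UNMATCHED`` where all-zero.

    Ties are broken toward the lowest flat grid index (numpy argmax order).
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != dictionary.m:
        raise ValueError(
            f"signal length {signals.shape[-1]} != dictionary M {dictionary.m}")
    lead = signals.shape[:-1]
    flat = signals.reshape(-1, dictionary.m)
    norms = np.linalg.norm(flat, axis=1)
    ok = norms > 0
    idx = np.full(flat.shape[0], UNMATCHED, dtype=np.int64)
    if np.any(ok):
        scores = (flat[ok] / norms[ok, None]) @ dictionary.trajectories.T
        idx[ok] = np.argmax(scores, axis=1)
    pts = dictionary.grid.points()
    estimates = {}
    for j, name in enumerate(dictionary.grid.axis_names):
        vals = np.zeros(flat.shape[0])
        vals[ok] = pts[idx[ok], j]
        estimates[name] = vals.reshape(lead)
    return estimates, idx.reshape(lead)


def save_dictionary(dictionary: MRFDictionary, path) -> None:
    """Write the dictionary to an HDF5 container (grid, fixed params, rows)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("trajectories", data=dictionary.trajectories)
        f.attrs["schedule_label"] = dictionary.schedule_label
        g = f.create_group("axes")
        for i, (name, vals) in enumerate(dictionary.grid.axes.items()):
            d = g.create_dataset(name, data=np.asarray(vals))
            d.attrs["order"] = i
        fx = f.create_group("fixed")
        for name, v in dictionary.grid.fixed.items():
            fx.attrs[name] = v


def load_dictionary(path) -> MRFDictionary:
    with h5py.File(path, "r") as f:
        traj = f["trajectories"][()]
        names = sorted(f["axes"], key=lambda n: f["axes"][n].attrs["order"])
        axes = {n: f["axes"][n][()] for n in names}
        fixed = dict(f["fixed"].attrs)
        label = str(f.attrs.get("schedule_label", ""))
    return MRFDictionary(ParameterGrid(axes, fixed), traj, schedule_label=label)
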