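"""Synaptic-strength containers and their random initialization.

The circuit has two lateralized granular reservoirs.  Each side owns

* a mossy-fiber input matrix ``w_mf_grc`` (N x 2, one column per MF
  channel: target command and burst efference copy), drawn uniformly in
  [-30, 30];
* a sparse nonnegative recurrent matrix ``w_rec`` (N x N) drawn uniformly
  in [0, 0.2] on a random sparsity mask, then rescaled to spectral radius
  exactly 1 so that the configured spectral-radius parameter ``rho``
  multiplies it into a stable regime (recurrence is inhibitory: it enters
  the granule drive with a minus sign);
* a plastic parallel-fiber-to-Purkinje readout vector ``w_pf_pc``
  (length N), initialized to zero and shaped by training.

The seed that generated the fixed arrays is stored with them: the random
structure is part of the model's identity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np

from .config import ModelConfig

__all__ = ["NetworkWeights", "init_weights", "save_weights", "load_weights"]

_ARRAY_FIELDS = (
    "w_mf_grc_contra",
    "w_mf_grc_ipsi",
    "w_rec_contra",
    "w_rec_ipsi",
    "w_pf_pc_contra",
    "w_pf_pc_ipsi",
)


@dataclass
class NetworkWeights:
    """All synaptic strength arrays of the bilateral circuit."""

    w_mf_grc_contra: np.ndarray  #: (N, 2) MF -> granule strengths
    w_mf_grc_ipsi: np.ndarray
    w_rec_contra: np.ndarray     #: (N, N) nonnegative recurrent strengths
    w_rec_ipsi: np.ndarray
    w_pf_pc_contra: np.ndarray   #: (N,) plastic PF -> PC readout
    w_pf_pc_ipsi: np.ndarray
    seed: int = 0                #: seed that generated the fixed arrays

    @property
    def n_units(self) -> int:
        return self.w_rec_contra.shape[0]

    def copy(self) -> "NetworkWeights":
        return replace(
            self, **{name: getattr(self, name).copy() for name in _ARRAY_FIELDS}
        )

    def with_readout(
        self, w_pf_pc_contra: np.ndarray, w_pf_pc_ipsi: np.ndarray
    ) -> "NetworkWeights":
        """A copy carrying new plastic readout vectors."""
        out = self.copy()
        out.w_pf_pc_contra = np.asarray(w_pf_pc_contra, dtype=float).copy()
        out.w_pf_pc_ipsi = np.asarray(w_pf_pc_ipsi, dtype=float).copy()
        return out

    def validate(self) -> None:
        n = self.n_units
        shapes = {
            "w_mf_grc_contra": (n, 2),
            "w_mf_grc_ipsi": (n, 2),
            "w_rec_contra": (n, n),
            "w_rec_ipsi": (n, n),
            "w_pf_pc_contra": (n,),
            "w_pf_pc_ipsi": (n,),
        }
        for name, shape in shapes.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {shape}")
        for name in ("w_rec_contra", "w_rec_ipsi"):
            if getattr(self, name).min() < 0:
                raise ValueError(f"{name} must be nonnegative")


def _spectral_radius(w: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(w))))


def _random_recurrent(rng: np.random.Generator, n: int,
                      density: float) -> np.ndarray:
    """Sparse nonnegative matrix, uniform [0, 0.2], spectral radius 1."""
    w = rng.uniform(0.0, 0.2, size=(n, n))
    mask = rng.uniform(size=(n, n)) < density
    w = w * mask
    sr = _spectral_radius(w)
    if sr <= 0:
        # pathologically empty draw (possible only at tiny N * density);
        # keep at least one self-loop so normalization is defined
        w[0, 0] = 0.1
        sr = _spectral_radius(w)
    return w / sr


def init_weights(config: ModelConfig, seed: int | None = None) -> NetworkWeights:
    """Draw the fixed random structure; identical seeds give identical arrays.

    ``w_rec`` per side is sparse (``config.density`` nonzero), nonnegative,
    uniform in [0, 0.2] before being scaled to unit spectral radius.
    ``w_mf_grc`` is uniform in [-30, 30].  The plastic readouts start at 0.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    n = config.N
    rng = np.random.default_rng(seed)
    arrays: dict[str, np.ndarray] = {}
    for side in ("contra", "ipsi"):
        arrays[f"w_rec_{side}"] = _random_recurrent(rng, n, config.density)
        arrays[f"w_mf_grc_{side}"] = rng.uniform(-30.0, 30.0, size=(n, 2))
    weights = NetworkWeights(
        w_pf_pc_contra=np.zeros(n),
        w_pf_pc_ipsi=np.zeros(n),
        seed=int(seed),
        **arrays,
    )
    weights.validate()
    return weights


def save_weights(weights: NetworkWeights, path: str | Path,
                 config_hash: str | None = None) -> None:
    """HDF5 layout: one dataset per array, seed (and config hash) as attrs."""
    with h5py.File(path, "w") as h5:
        for name in _ARRAY_FIELDS:
            h5.create_dataset(name, data=getattr(weights, name))
        h5.attrs["seed"] = weights.seed
        if config_hash is not None:
            h5.attrs["config_hash"] = config_hash


def load_weights(path: str | Path) -> NetworkWeights:
    with h5py.File(path, "r") as h5:
        arrays = {name: h5[name][...] for name in _ARRAY_FIELDS}
        seed = int(h5.attrs["seed"])
    w = NetworkWeights(seed=seed, **arrays)
    w.validate()
    return w
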