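"""Model configuration for the saccade control loop.

All fixed parameters of the circuit live in a single :class:`ModelConfig`
dataclass: brainstem burst-generator constants, oculomotor-plant
coefficients, mossy-fiber encoding gains, granular-reservoir settings,
fastigial readout gains, the learning regularizer, and the numerical
integration grid.  The defaults are the parameter set used throughout the
simulation experiments: monkey oculomotor constants for the internal
feedback loop and the second-order plant, plus the calibration gains of
the cerebellar pathway.

Configurations are plain flat documents on disk (YAML, which includes JSON)
with keys named exactly as the dataclass fields; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ModelConfig", "default_config", "load_config", "save_config"]


@dataclass
class ModelConfig:
    """Every fixed parameter of the saccade model plus numerical settings.

    Units are SI seconds for times, degrees for eye position and target
    eccentricity, and Hz for burst-generator rates.
    """

    # --- brainstem burst generator (internal feedback loop) ---
    A: float = 1100.0          #: burst amplitude (Hz)
    k: float = 0.72            #: displacement-integrator gain, dimensionless
    sigma: float = 16.0        #: burst-generator slope constant (drive units)

    # --- second-order oculomotor plant ---
    k1: float = 0.003          #: inertial coefficient (s^2)
    k2: float = 0.6            #: viscous coefficient (s)
    k3: float = 4.0            #: elastic coefficient (dimensionless)

    # --- mossy-fiber encodings ---
    lam: float = 2.0           #: MF_target gain lambda (Hz per degree)
    alpha: float = 0.015       #: MF_target build-up spread (s)

    # --- granular reservoir ---
    rho: float = 0.5           #: recurrent spectral radius, 0 < rho <= 1
    tau: float = 0.020         #: granule time constant (s)
    N: int = 100               #: granule units per side
    density: float = 0.1       #: recurrent connection density, (0, 1]
    f_max: float = 1.0         #: saturation of the granule drive function
    mf_gain: float = 0.3       #: scale of normalized MF drive into granules

    # --- fastigial / output pathway ---
    r1: float = 0.02           #: contralateral cFN responsibility gain
    r2: float = -0.02          #: ipsilateral cFN responsibility gain
    w_pc_cfn_contra: float = 20.0  #: PC -> cFN inhibitory strength, contra
    w_pc_cfn_ipsi: float = 20.0    #: PC -> cFN inhibitory strength, ipsi
    w_mf_cfn_contra: float = 0.25  #: MF -> cFN excitatory strength, contra
    w_mf_cfn_ipsi: float = 0.75    #: MF -> cFN excitatory strength, ipsi

    # --- learning criterion ---
    gamma: float = 1e-4        #: weight-regularization coefficient

    # --- numerics / trial protocol ---
    dt: float = 0.001              #: integration step (s)
    trial_duration: float = 0.4    #: total simulated time per trial (s)
    cutoff_after_onset: float = 0.150  #: eye-hold switch delay T (s)
    t_on: float = 0.050            #: movement-initiation (command) time (s)
    onset_speed_threshold: float = 30.0  #: movement-onset criterion (deg/s)
    plant_integrator: str = "exact"      #: "exact" or "euler"
    seed: int = 0                  #: RNG seed for fixed random structure

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field on any violation."""
        checks = [
            ("A", self.A > 0, "A must be > 0"),
            ("sigma", self.sigma > 0, "sigma must be > 0"),
            ("k", 0.0 <= self.k <= 1.0, "k must lie in [0, 1]"),
            ("tau", self.tau > 0, "tau must be > 0"),
            ("dt", self.dt > 0, "dt must be > 0"),
            ("dt", self.dt < self.tau, "dt must be smaller than tau"),
            ("N", self.N >= 1, "N must be >= 1"),
            ("rho", 0.0 < self.rho <= 1.0, "rho must lie in (0, 1]"),
            ("density", 0.0 < self.density <= 1.0,
             "density must lie in (0, 1]"),
            ("f_max", self.f_max > 0, "f_max must be > 0"),
            ("mf_gain", self.mf_gain > 0, "mf_gain must be > 0"),
            ("lam", self.lam > 0, "lam must be > 0"),
            ("alpha", self.alpha > 0, "alpha must be > 0"),
            ("trial_duration",
             self.trial_duration >= self.t_on + self.cutoff_after_onset,
             "trial_duration must cover t_on + cutoff_after_onset"),
            ("plant_integrator", self.plant_integrator in ("exact", "euler"),
             "plant_integrator must be 'exact' or 'euler'"),
        ]
        for name, ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid ModelConfig.{name}: {msg}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown configuration key(s): {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def replace(self, **kwargs: Any) -> "ModelConfig":
        cfg = dataclasses.replace(self, **kwargs)
        cfg.validate()
        return cfg

    def content_hash(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @property
    def n_steps(self) -> int:
        return int(round(self.trial_duration / self.dt))

    @property
    def mf_target_norm(self) -> float:
        """Normalization of the target mossy-fiber channel (lam * 20 deg)."""
        return self.lam * 20.0


def default_config() -> ModelConfig:
    """The reference parameter set (validated)."""
    cfg = ModelConfig()
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> ModelConfig:
    """Load a flat YAML/JSON config; omitted keys take default values."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} is not a mapping")
    return ModelConfig.from_dict(data)


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
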