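"""Model / Results interface over the saccade control loop.

:class:`SaccadeModel` bundles a configuration with the fixed random
network structure; ``fit`` runs the visual-error-driven adaptation of the
parallel-fiber readouts and returns a :class:`SaccadeFitResults` carrying
the trained weights, the optimization trace, per-target endpoint errors
and, when requested, the converged reservoir parameters.  Simulation and
the scripted analyses hang off both objects: the model simulates with its
current (possibly untrained) weights, the results with the trained ones.

    >>> model = SaccadeModel.from_config(seed=7)
    >>> fit = model.fit(seed=7)
    >>> print(fit.summary())
    >>> rec = fit.simulate(target=15.0)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import experiments
from .adaptation import TrainingResult, train
from .config import ModelConfig, default_config
from .records import TrialRecord
from .simulation import SimulationEngine, simulate_trial
from .weights import NetworkWeights, init_weights

__all__ = ["SaccadeModel", "SaccadeFitResults"]


class SaccadeModel:
    """The saccade circuit as a fittable model.

    Parameters
    ----------
    config
        Full parameter set; ``default_config()`` if omitted.
    weights
        Fixed random structure plus (possibly pre-trained) readouts;
        drawn from ``config.seed`` if omitted.
    """

    def __init__(self, config: ModelConfig | None = None,
                 weights: NetworkWeights | None = None):
        self.config = config if config is not None else default_config()
        self.config.validate()
        if weights is None:
            weights = init_weights(self.config)
        self.weights = weights
        self.engine = SimulationEngine(self.config, self.weights)

    @classmethod
    def from_config(cls, config: ModelConfig | None = None,
                    seed: int | None = None, **overrides: Any
                    ) -> "SaccadeModel":
        """Build a model from a config, optional field overrides and seed."""
        cfg = config if config is not None else default_config()
        if overrides:
            cfg = cfg.replace(**overrides)
        if seed is not None:
            cfg = cfg.replace(seed=int(seed))
        return cls(cfg, init_weights(cfg, cfg.seed))

    # -- simulation with the model's current weights ----------------------

    def simulate(self, target: float, motivation_scale: float = 1.0,
                 clamp_yc: np.ndarray | None = None) -> TrialRecord:
        return simulate_trial(self.config, self.weights, target,
                              motivation_scale=motivation_scale,
                              clamp_yc=clamp_yc, engine=self.engine)

    # -- fitting ----------------------------------------------------------

    def fit(self, target_range: tuple[float, float] = (4.0, 20.0),
            seed: int | None = None,
            optimize_reservoir_params: bool = False,
            **train_kwargs: Any) -> "SaccadeFitResults":
        """Adapt the PF-PC readouts; see :func:`omvsim.adaptation.train`."""
        if seed is None:
            seed = self.config.seed
        result = train(self.config, self.weights,
                       target_range=target_range, seed=seed,
                       optimize_reservoir_params=optimize_reservoir_params,
                       engine=self.engine, **train_kwargs)
        return SaccadeFitResults(self, result)


@dataclass
class SaccadeFitResults:
    """Estimates and diagnostics of one adaptation run."""

    model: SaccadeModel
    training: TrainingResult
    _engine: SimulationEngine | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        cfg = self.model.config
        if self.training.free_params is not None:
            tau, rho = self.training.free_params
            cfg = cfg.replace(tau=tau, rho=rho)
        self.config = cfg
        self.weights = self.training.weights
        self._engine = SimulationEngine(cfg, self.weights)

    # -- estimates ---------------------------------------------------------

    @property
    def params(self) -> np.ndarray:
        """The fitted parameter vector (contra then ipsi readouts)."""
        return np.concatenate([self.weights.w_pf_pc_contra,
                               self.weights.w_pf_pc_ipsi])

    @property
    def cost_history(self) -> np.ndarray:
        return self.training.cost_history

    @property
    def per_target_error(self) -> dict[float, float]:
        return self.training.per_target_error

    @property
    def free_params(self):
        return self.training.free_params

    # -- simulation and analyses with the trained weights ------------------

    def simulate(self, target: float, motivation_scale: float = 1.0,
                 clamp_yc: np.ndarray | None = None) -> TrialRecord:
        return simulate_trial(self.config, self.weights, target,
                              motivation_scale=motivation_scale,
                              clamp_yc=clamp_yc, engine=self._engine)

    def main_sequence(self, targets) -> pd.DataFrame:
        return experiments.main_sequence(self.config, self.weights, targets,
                                         engine=self._engine)

    def pc_encoding(self, targets, side: str = "ipsi"):
        return experiments.pc_encoding_analysis(
            self.config, self.weights, targets, side=side,
            engine=self._engine)

    def cfn_patterns(self, targets):
        return experiments.cfn_pattern_analysis(
            self.config, self.weights, targets, engine=self._engine)

    def variability(self, target: float, burst_reduction: float) -> dict:
        return experiments.variability_experiment(
            self.config, self.weights, target, burst_reduction,
            engine=self._engine)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Plain-text fit report."""
        cfg = self.config
        head = [
            "Saccade adaptation fit",
            "=" * 54,
            f"granule units per side: {cfg.N}    dt: {cfg.dt * 1e3:.1f} ms"
            f"    trial: {cfg.trial_duration:.2f} s",
            f"tau: {cfg.tau * 1e3:.1f} ms    rho: {cfg.rho:.3f}"
            f"    gamma: {cfg.gamma:g}",
            f"training seed         : {self.training.rng_seed}",
        ]
        body = self.training.summary_lines()
        err = ["per-target endpoint error (deg):"] + [
            f"    {t:5.1f} deg : {e:+.3f}"
            for t, e in sorted(self.per_target_error.items())
        ]
        return "\n".join(head + body + err)
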