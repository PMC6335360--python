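"""Deterministic ready-made (config, weights) pairs for tests and demos."""

from __future__ import annotations

from .config import ModelConfig, default_config
from .weights import NetworkWeights, init_weights

__all__ = ["make_fixture"]


def make_fixture(kind: str = "tiny", seed: int = 0
                 ) -> tuple[ModelConfig, NetworkWeights]:
    """Return a validated (config, weights) pair.

    ``"tiny"`` is a 10-unit, 2 ms, short-trial setup for fast tests;
    ``"default"`` is the reference parameter set.  Both are deterministic
    per seed.
    """
    if kind == "tiny":
        cfg = default_config().replace(
            N=10, dt=0.002, trial_duration=0.3, cutoff_after_onset=0.12,
            t_on=0.04, seed=seed)
    elif kind == "default":
        cfg = default_config().replace(seed=seed)
    else:
        raise ValueError(f"unknown fixture kind: {kind!r}")
    return cfg, init_weights(cfg, seed)
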