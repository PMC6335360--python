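"""Scripted analyses of simulated saccades.

Four result families, each a deterministic function of a (config,
weights) pair:

* ``main_sequence`` -- amplitude, peak speed and duration across targets,
  the stereotyped kinematic relations of saccades;
* ``pc_encoding_analysis`` -- baseline-subtracted Purkinje population
  traces and ordinary least-squares fits of the peak activity change
  against peak eye speed and against amplitude (the CS-off population is
  the ipsilateral Purkinje layer, CS-on the contralateral);
* ``cfn_pattern_analysis`` -- baseline-subtracted fastigial traces with
  burst-before-pause (contra) / pause-before-burst (ipsi) pattern flags;
* ``variability_experiment`` -- endpoint and peak-speed consequences of a
  reduced burst amplitude with the vermal output either intact (adapting
  online through the efference copy) or clamped to its unperturbed-trial
  time course.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelConfig
from .records import SaccadeMetrics, TrialRecord
from .simulation import SimulationEngine, simulate_trial
from .weights import NetworkWeights

__all__ = [
    "PopulationTrace",
    "LinearFit",
    "saccade_metrics",
    "main_sequence",
    "pc_encoding_analysis",
    "cfn_pattern_analysis",
    "variability_experiment",
]

#: pre-movement window (s) whose mean defines a population baseline
BASELINE_WINDOW = 0.020
#: minimum duration (s) of a positive speed excursion to count as a bulge
BULGE_MIN_DURATION = 0.005


@dataclass
class PopulationTrace:
    """Baseline-subtracted population activity of one trial."""

    time: np.ndarray
    delta_activity: np.ndarray
    baseline_value: float
    peak_change: float
    time_of_peak: float
    target: float


@dataclass
class LinearFit:
    """Ordinary least-squares line with its coefficient of determination."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float


def saccade_metrics(record: TrialRecord,
                    speed_threshold: float | None = None) -> SaccadeMetrics:
    """Kinematic metrics of one trial by threshold crossings of the speed.

    Onset is the first up-crossing of the threshold, offset the first
    down-crossing after the speed peak.  Records whose speed never
    reaches the threshold yield the degenerate (all-NaN) metrics.
    """
    if speed_threshold is None:
        speed_threshold = 30.0
    speed = record.theta_dot
    above = speed >= speed_threshold
    if not np.any(above):
        return SaccadeMetrics.degenerate_metrics()
    onset_idx = int(np.argmax(above))
    peak_idx = int(np.argmax(speed))
    after_peak = speed[peak_idx:] < speed_threshold
    if np.any(after_peak):
        offset_idx = peak_idx + int(np.argmax(after_peak))
    else:
        offset_idx = record.n_samples - 1
    t = record.time
    return SaccadeMetrics(
        onset_time=float(t[onset_idx]),
        offset_time=float(t[offset_idx]),
        duration=float(t[offset_idx] - t[onset_idx]),
        amplitude=float(record.theta[-1] - record.theta[0]),
        peak_speed=float(speed[peak_idx]),
        time_of_peak_speed=float(t[peak_idx]),
        endpoint_error=record.endpoint_error,
    )


def main_sequence(config: ModelConfig, weights: NetworkWeights,
                  targets, engine: SimulationEngine | None = None
                  ) -> pd.DataFrame:
    """One row of (target, amplitude, peak_speed, duration) per target."""
    if engine is None:
        engine = SimulationEngine(config, weights)
    rows = []
    for target in np.asarray(targets, dtype=float):
        record = simulate_trial(config, weights, target, engine=engine)
        m = saccade_metrics(record, config.onset_speed_threshold)
        rows.append({"target": target, "amplitude": m.amplitude,
                     "peak_speed": m.peak_speed, "duration": m.duration,
                     "endpoint_error": m.endpoint_error,
                     "degenerate": m.degenerate})
    return pd.DataFrame(rows)


def _population_trace(record: TrialRecord, series: np.ndarray
                      ) -> PopulationTrace:
    pre = record.time < BASELINE_WINDOW
    baseline = float(series[pre].mean())
    delta = series - baseline
    peak_idx = int(np.argmax(np.abs(delta)))
    return PopulationTrace(
        time=record.time,
        delta_activity=delta,
        baseline_value=baseline,
        peak_change=float(np.abs(delta[peak_idx])),
        time_of_peak=float(record.time[peak_idx]),
        target=record.target,
    )


def pc_encoding_analysis(config: ModelConfig, weights: NetworkWeights,
                         targets, side: str = "ipsi",
                         engine: SimulationEngine | None = None):
    """Purkinje-population speed encoding across targets.

    Returns ``(traces, fit_speed, fit_amplitude, details)`` where
    ``details`` is a tidy DataFrame with one row per valid trial (peak
    change, peak speed, amplitude, and the two peak times).  Degenerate
    trials are excluded; fewer than 3 valid trials is an error.
    """
    if side not in ("ipsi", "contra"):
        raise ValueError("side must be 'ipsi' or 'contra'")
    if engine is None:
        engine = SimulationEngine(config, weights)
    traces: list[PopulationTrace] = []
    rows = []
    for target in np.asarray(targets, dtype=float):
        record = simulate_trial(config, weights, target, engine=engine)
        metrics = saccade_metrics(record, config.onset_speed_threshold)
        if metrics.degenerate:
            continue
        series = record.y_pc_ipsi if side == "ipsi" else record.y_pc_contra
        trace = _population_trace(record, series)
        traces.append(trace)
        rows.append({
            "target": target,
            "peak_change": trace.peak_change,
            "time_of_peak_change": trace.time_of_peak,
            "peak_speed": metrics.peak_speed,
            "time_of_peak_speed": metrics.time_of_peak_speed,
            "amplitude": metrics.amplitude,
        })
    if len(rows) < 3:
        raise ValueError(
            f"need at least 3 valid trials for the fit, got {len(rows)}")
    details = pd.DataFrame(rows)

    def _fit(xname: str) -> LinearFit:
        res = stats.linregress(details[xname], details["peak_change"])
        return LinearFit(slope=float(res.slope),
                         intercept=float(res.intercept),
                         r_squared=float(res.rvalue**2),
                         p_value=float(res.pvalue))

    return traces, _fit("peak_speed"), _fit("amplitude"), details


def cfn_pattern_analysis(config: ModelConfig, weights: NetworkWeights,
                         targets, engine: SimulationEngine | None = None):
    """Baseline-subtracted fastigial traces with burst/pause pattern flags.

    Baseline is the pre-trial resting value (sample 0).  The contralateral
    nucleus should depart above baseline before it goes below
    (burst-before-pause); the ipsilateral nucleus the opposite.  Early
    phase is everything up to the time of peak eye speed; its magnitude
    should grow with target size.  Returns ``(per_target, table)``.
    """
    if engine is None:
        engine = SimulationEngine(config, weights)
    per_target = {}
    rows = []
    for target in np.asarray(targets, dtype=float):
        record = simulate_trial(config, weights, target, engine=engine)
        metrics = saccade_metrics(record, config.onset_speed_threshold)
        peak_speed_idx = int(np.argmax(record.theta_dot))
        entry = {}
        for side, series in (("contra", record.ycfn_contra),
                             ("ipsi", record.ycfn_ipsi)):
            delta = series - series[0]
            early = delta[: peak_speed_idx + 1]
            entry[side] = {
                "delta": delta,
                "time_of_max": float(record.time[np.argmax(delta)]),
                "time_of_min": float(record.time[np.argmin(delta)]),
                "early_burst_peak": float(early.max(initial=0.0)),
                "early_pause_depth": float((-early).max(initial=0.0)),
            }
        contra, ipsi = entry["contra"], entry["ipsi"]
        rows.append({
            "target": target,
            # burst-before-pause: the main positive excursion precedes the
            # main negative one (and vice versa for the ipsilateral side)
            "contra_burst_before_pause": (
                contra["time_of_max"] < contra["time_of_min"]),
            "ipsi_pause_before_burst": (
                ipsi["time_of_min"] < ipsi["time_of_max"]),
            "contra_early_burst_peak": contra["early_burst_peak"],
            "ipsi_early_pause_depth": ipsi["early_pause_depth"],
            "peak_speed": metrics.peak_speed,
        })
        per_target[float(target)] = entry
    return per_target, pd.DataFrame(rows)


def _has_bulge(speed: np.ndarray, reference: np.ndarray, dt: float,
               after_idx: int) -> bool:
    """A contiguous window >= BULGE_MIN_DURATION where speed > reference."""
    excess = (speed > reference)[after_idx:]
    needed = int(round(BULGE_MIN_DURATION / dt))
    run = 0
    for flag in excess:
        run = run + 1 if flag else 0
        if run >= needed:
            return True
    return False


def variability_experiment(config: ModelConfig, weights: NetworkWeights,
                           target: float, burst_reduction: float,
                           engine: SimulationEngine | None = None) -> dict:
    """Burst-amplitude perturbation with intact vs. clamped vermal output.

    Runs (a) an unperturbed trial, (b) the perturbed trial with the vermis
    in the loop, and (c) the perturbed trial with the vermal output
    clamped to the recording from (a).  Dysmetria is |endpoint error|;
    peak-speed reductions are relative to (a); the late corrective bulge
    is a positive excursion of one perturbed speed trace over the other
    after the time of peak speed.
    """
    if not 0.0 <= burst_reduction < 1.0:
        raise ValueError("burst_reduction must lie in [0, 1)")
    if engine is None:
        engine = SimulationEngine(config, weights)
    scale = 1.0 - burst_reduction
    normal = simulate_trial(config, weights, target, engine=engine)
    intact = simulate_trial(config, weights, target,
                            motivation_scale=scale, engine=engine)
    clamped = simulate_trial(config, weights, target,
                             motivation_scale=scale, clamp_yc=normal.y_c,
                             engine=engine)
    peak_normal = float(normal.theta_dot.max())
    dt = config.dt

    def _entry(rec: TrialRecord, other: TrialRecord) -> dict:
        peak = float(rec.theta_dot.max())
        return {
            "dysmetria": abs(rec.endpoint_error),
            "endpoint_error": rec.endpoint_error,
            "peak_speed": peak,
            "peak_speed_reduction_pct": 100.0 * (1.0 - peak / peak_normal),
            "late_bulge_present": _has_bulge(
                rec.theta_dot, other.theta_dot, dt,
                int(np.argmax(rec.theta_dot))),
        }

    return {
        "target": float(target),
        "burst_reduction": float(burst_reduction),
        "normal_peak_speed": peak_normal,
        "normal_endpoint_error": normal.endpoint_error,
        "intact": _entry(intact, clamped),
        "clamped": _entry(clamped, intact),
        "records": {"normal": normal, "intact": intact, "clamped": clamped},
    }
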