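"""Trial records and per-saccade kinematic metrics.

A :class:`TrialRecord` stores every signal of one simulated saccade on the
uniform time grid: burst output, displacement-integrator state, mossy
fiber rates, granule activity of both sides, Purkinje and fastigial
readouts, the net cerebellar correction, and the eye trajectory.  Records
round-trip exactly through HDF5 and export to CSV (scalar signals in one
tidy table, granule vectors in companion wide tables).

:class:`SaccadeMetrics` is the small value object produced by the
experiment analyses: onset/offset, amplitude, duration, peak speed and
signed endpoint error of one trial.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["TrialRecord", "SaccadeMetrics", "save_record", "load_record"]

_SERIES = (
    "time", "u", "D", "mf_target", "mf_burst",
    "y_pc_contra", "y_pc_ipsi", "ycfn_contra", "ycfn_ipsi",
    "y_c", "theta", "theta_dot",
)
_MATRICES = ("z_contra", "z_ipsi")
_SCALARS = ("target", "motivation_scale", "t_on", "onset_time", "hold_time")


@dataclass
class TrialRecord:
    """Uniformly sampled time series of all signals for one saccade trial."""

    time: np.ndarray         #: (T,) s
    u: np.ndarray            #: (T,) burst output, Hz
    D: np.ndarray            #: (T,) displacement-integrator state, deg
    mf_target: np.ndarray    #: (T,) Hz
    mf_burst: np.ndarray     #: (T,) Hz
    z_contra: np.ndarray     #: (T, N) granule activity
    z_ipsi: np.ndarray       #: (T, N)
    y_pc_contra: np.ndarray  #: (T,) PC population activity
    y_pc_ipsi: np.ndarray
    ycfn_contra: np.ndarray  #: (T,) fastigial activity
    ycfn_ipsi: np.ndarray
    y_c: np.ndarray          #: (T,) net cerebellar correction (drive units)
    theta: np.ndarray        #: (T,) eye position, deg
    theta_dot: np.ndarray    #: (T,) eye speed, deg/s
    target: float            #: commanded displacement y_d, deg
    motivation_scale: float  #: multiplier applied to the burst amplitude
    t_on: float              #: command time, s
    onset_time: float = np.nan   #: detected movement onset (NaN if none)
    hold_time: float = np.nan    #: time the eye-hold switch fired
    clamped: bool = False    #: True if the vermal output was replayed

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def endpoint(self) -> float:
        """Final (held) eye position, deg."""
        return float(self.theta[-1])

    @property
    def endpoint_error(self) -> float:
        """Signed error, target minus final position, deg."""
        return self.target - self.endpoint

    def desired_displacement(self) -> np.ndarray:
        """Desired eye displacement trace: 0 before t_on, target after."""
        return np.where(self.time >= self.t_on, self.target, 0.0)

    # -- export ------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        """Scalar signals, one row per timestep (granule vectors excluded)."""
        return pd.DataFrame({name: getattr(self, name) for name in _SERIES})

    def to_csv(self, path: str | Path, granule: bool = True) -> None:
        """Write the tidy signal table; optionally companion granule CSVs."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")
        if granule:
            for name in _MATRICES:
                wide = pd.DataFrame(
                    getattr(self, name),
                    columns=[f"unit_{i}" for i in
                             range(getattr(self, name).shape[1])])
                wide.insert(0, "time", self.time)
                wide.to_csv(path.with_suffix(f".{name}.csv"), index=False,
                            float_format="%.17g")


@dataclass
class SaccadeMetrics:
    """Kinematic summary of one trial; all-NaN when degenerate."""

    onset_time: float
    offset_time: float
    duration: float
    amplitude: float
    peak_speed: float
    time_of_peak_speed: float
    endpoint_error: float
    degenerate: bool = False

    @classmethod
    def degenerate_metrics(cls) -> "SaccadeMetrics":
        nan = float("nan")
        return cls(onset_time=nan, offset_time=nan, duration=nan,
                   amplitude=nan, peak_speed=nan, time_of_peak_speed=nan,
                   endpoint_error=nan, degenerate=True)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def save_record(record: TrialRecord, path: str | Path) -> None:
    """Exact HDF5 round-trip: one dataset per series, scalars as attrs."""
    with h5py.File(path, "w") as h5:
        for name in _SERIES + _MATRICES:
            h5.create_dataset(name, data=getattr(record, name))
        for name in _SCALARS:
            h5.attrs[name] = getattr(record, name)
        h5.attrs["clamped"] = bool(record.clamped)


def load_record(path: str | Path) -> TrialRecord:
    with h5py.File(path, "r") as h5:
        data = {name: h5[name][...] for name in _SERIES + _MATRICES}
        scalars = {name: float(h5.attrs[name]) for name in _SCALARS}
        clamped = bool(h5.attrs["clamped"])
    return TrialRecord(clamped=clamped, **data, **scalars)
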