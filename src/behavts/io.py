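"""CSV and MAT-file I/O for the temporal data types.

All native formats are plain UTF-8 CSV with a one-line header:

* events:      ``onset,offset,code``
* timeseries:  ``time,value`` (or value-only with the rate supplied)
* spike train: one 0/1 value per line, rate supplied externally

MAT reading is limited to simple sample-data layouts (two named nominal
series such as ``PP1``/``PP2``, and a single multivariate spike-train
matrix); everything else should arrive as CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import BinarySpikeTrain, EventSequence, NominalTimeSeries, import_annotation_table
from .errors import ConfigurationError, InvalidInputError


def read_events_csv(path, **kwargs) -> EventSequence:
    frame = pd.read_csv(path)
    required = {"onset", "offset", "code"}
    if not required.issubset(frame.columns):
        raise ConfigurationError(
            f"events CSV must have columns {sorted(required)}, got {list(frame.columns)}"
        )
    return import_annotation_table(frame, **kwargs)


def write_events_csv(seq: EventSequence, path) -> None:
    seq.to_frame().to_csv(path, index=False)


def read_timeseries_csv(path, rate: float | None = None) -> NominalTimeSeries:
    """Read ``time,value`` CSV (rate inferred from the time column) or a
    value-only CSV with the rate supplied explicitly."""
    frame = pd.read_csv(path)
    if "value" in frame.columns and "time" in frame.columns:
        times = frame["time"].to_numpy(dtype=float)
        if len(times) > 1:
            steps = np.diff(times)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise InvalidInputError("time column is not regularly sampled")
            rate = 1.0 / steps[0]
        elif rate is None:
            raise ConfigurationError("rate required for a single-sample series")
        return NominalTimeSeries(frame["value"].to_numpy(), rate=rate, start_time=times[0] if len(times) else 0.0)
    if rate is None:
        raise ConfigurationError("rate must be supplied for a value-only CSV")
    col = "value" if "value" in frame.columns else frame.columns[0]
    return NominalTimeSeries(frame[col].to_numpy(), rate=rate)


def write_timeseries_csv(ts: NominalTimeSeries, path) -> None:
    pd.DataFrame({"time": ts.times(), "value": ts.values}).to_csv(path, index=False)


def read_spike_train_csv(path, rate: float, label: str = "") -> BinarySpikeTrain:
    values = pd.read_csv(path, header=None).to_numpy().ravel()
    # tolerate a single header line such as "value"
    if values.dtype == object:
        values = pd.to_numeric(pd.Series(values), errors="coerce").dropna().to_numpy()
    return BinarySpikeTrain(values.astype(int), rate=rate, label=label)


def write_spike_train_csv(train: BinarySpikeTrain, path) -> None:
    np.savetxt(path, train.values, fmt="%d")


def read_ensemble_csv(path, rate: float):
    """Read a multivariate spike ensemble (one column per variable)."""
    from .granger import SpikeEnsemble

    frame = pd.read_csv(path)
    return SpikeEnsemble(frame.to_numpy(dtype=int), rate=rate, labels=list(map(str, frame.columns)))


def load_mat_nominal_pair(path, keys=("PP1", "PP2"), rate: float = 1.0):
    """Load a two-series nominal sample file (MAT format)."""
    from scipy.io import loadmat

    mat = loadmat(path)
    out = []
    for key in keys:
        if key not in mat:
            raise ConfigurationError(f"variable {key!r} not found in {path}")
        out.append(NominalTimeSeries(np.asarray(mat[key]).ravel(), rate=rate, label=key))
    return tuple(out)


def load_mat_ensemble(path, key: str = None, rate: float = 3.0):
    """Load a multivariate spike-train sample file (MAT format)."""
    from scipy.io import loadmat

    from .granger import SpikeEnsemble

    mat = loadmat(path)
    candidates = {k: v for k, v in mat.items() if not k.startswith("__")}
    if key is None:
        if len(candidates) != 1:
            raise ConfigurationError(
                f"ambiguous MAT contents {sorted(candidates)}; pass key="
            )
        key = next(iter(candidates))
    arr = np.asarray(candidates[key])
    if arr.shape[0] < arr.shape[1]:
        arr = arr.T
    labels = [f"var{i + 1}" for i in range(arr.shape[1])]
    return SpikeEnsemble(arr.astype(int), rate=rate, labels=labels)
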