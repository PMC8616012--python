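"""Plain-text serialization for traces, instrument matrices, calibration sets
and feature tables.

Trace dialect (version 1): tab-separated columns ``time, IL, I0, I90, I135,
FL`` preceded by ``#``-prefixed header lines carrying key/value metadata
(``sampling_rate_hz`` is required).  Instrument matrices are 4×4 whitespace
tables with a metadata header.  Feature tables are ordinary CSV.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationSet
from .psa import InstrumentMatrix
from .pulses import TRACE_CHANNELS, FeatureRecord, TraceSet

__all__ = [
    "write_traces", "read_traces",
    "write_instrument_matrix", "read_instrument_matrix",
    "write_calibration_set", "read_calibration_set",
    "features_to_frame", "write_features", "read_features",
]

TRACE_DIALECT_VERSION = 1


def _read_header(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
    return meta


def write_traces(traces: TraceSet, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# trace_dialect_version: {TRACE_DIALECT_VERSION}\n")
        fh.write(f"# sampling_rate_hz: {traces.sampling_rate!r}\n")
        fh.write(f"# t0_s: {traces.t0!r}\n")
        fh.write("time\t" + "\t".join(TRACE_CHANNELS) + "\n")
        data = np.column_stack([traces.times] + [traces.channels[c] for c in TRACE_CHANNELS])
        np.savetxt(fh, data, fmt="%.9g", delimiter="\t")


def read_traces(path) -> TraceSet:
    meta = _read_header(path)
    if "sampling_rate_hz" not in meta:
        raise ValueError(f"{path}: missing required header 'sampling_rate_hz'")
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(TRACE_CHANNELS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing channels {sorted(missing)}")
    return TraceSet(
        sampling_rate=float(meta["sampling_rate_hz"]),
        t0=float(meta.get("t0_s", 0.0)),
        channels={c: df[c].to_numpy(dtype=float) for c in TRACE_CHANNELS})


def write_instrument_matrix(a: InstrumentMatrix, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("# instrument_matrix: 4x4, rows = channels L,0,90,135; "
                 "cols = Stokes I,Q,U,V\n")
        if comment:
            fh.write(f"# comment: {comment}\n")
        fh.write(f"# condition_number: {a.condition_number!r}\n")
        np.savetxt(fh, a.matrix, fmt="%.17g")


def read_instrument_matrix(path) -> InstrumentMatrix:
    m = np.loadtxt(path, comments="#")
    return InstrumentMatrix(m)


def write_calibration_set(cal: CalibrationSet, path) -> None:
    df = pd.DataFrame(
        np.hstack([cal.stokes, cal.voltages]),
        columns=["I", "Q", "U", "V", "IL", "I0", "I90", "I135"])
    df.insert(0, "probe", cal.labels)
    df.to_csv(path, sep="\t", index=False)


def read_calibration_set(path) -> CalibrationSet:
    df = pd.read_csv(path, sep="\t")
    return CalibrationSet(
        stokes=df[["I", "Q", "U", "V"]].to_numpy(dtype=float),
        voltages=df[["IL", "I0", "I90", "I135"]].to_numpy(dtype=float),
        labels=list(df["probe"].astype(str)))


def features_to_frame(records: list[FeatureRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


def write_features(records, path) -> None:
    df = records if isinstance(records, pd.DataFrame) else features_to_frame(records)
    df.to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path)
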