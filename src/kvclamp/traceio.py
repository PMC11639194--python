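"""Trace file I/O: CSV (canonical) and a minimal Axon Text File (ATF 1.0) dialect.

CSV traces carry columns ``time_ms, current, voltage_mV, sweep_id`` plus a
single ``#`` comment line holding the segment markers and metadata as JSON,
so a round trip preserves the information the analysis pipeline needs.  The
ATF dialect writes the standard ``ATF 1.0`` header with the same JSON in a
``Comment=`` record.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .protocols import SegSpan, SimTrace

__all__ = ["write_csv", "read_csv", "write_atf", "read_atf", "read_trace"]


def _meta_json(trace: SimTrace) -> str:
    return json.dumps(
        {
            "meta": trace.meta,
            "segments": [[s.label, s.t0, s.t1, s.V] for s in trace.segments],
        }
    )


def _trace_from(df: pd.DataFrame, doc: dict) -> SimTrace:
    return SimTrace(
        t=df["time_ms"].to_numpy(float),
        i=df["current"].to_numpy(float),
        v=df["voltage_mV"].to_numpy(float),
        segments=tuple(SegSpan(l, float(a), float(b), float(v)) for l, a, b, v in doc["segments"]),
        meta=doc.get("meta", {}),
    )


def write_csv(trace: SimTrace, path: str | Path) -> Path:
    path = Path(path)
    sweep = trace.meta.get("sweep", 0)
    df = pd.DataFrame(
        {
            "time_ms": trace.t,
            "current": trace.i,
            "voltage_mV": trace.v,
            "sweep_id": np.full(trace.t.size, sweep, dtype=int),
        }
    )
    with path.open("w") as fh:
        fh.write(f"# kvclamp-trace {_meta_json(trace)}\n")
        df.to_csv(fh, index=False, float_format="%.10g")
    return path


def read_csv(path: str | Path) -> SimTrace:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    doc = {"segments": [], "meta": {}}
    if first.startswith("# kvclamp-trace"):
        doc = json.loads(first[len("# kvclamp-trace") :])
    df = pd.read_csv(path, comment="#")
    if not doc["segments"]:
        doc["segments"] = _segments_from_voltage(df)
    return _trace_from(df, doc)


def _segments_from_voltage(df: pd.DataFrame) -> list:
    """Reconstruct generic segment markers from command-voltage changes."""
    t = df["time_ms"].to_numpy(float)
    v = df["voltage_mV"].to_numpy(float)
    edges = [0] + list(np.where(np.diff(v) != 0)[0] + 1) + [t.size]
    return [
        [f"seg{k}", float(t[a]), float(t[b - 1]), float(v[a])]
        for k, (a, b) in enumerate(zip(edges[:-1], edges[1:]))
    ]


def write_atf(trace: SimTrace, path: str | Path) -> Path:
    path = Path(path)
    records = [
        f'"Comment=kvclamp-trace {_meta_json(trace).replace(chr(34), chr(39))}"',
        '"SignalsExported=current,voltage"',
    ]
    with path.open("w") as fh:
        fh.write("ATF\t1.0\n")
        fh.write(f"{len(records)}\t3\n")
        for rec in records:
            fh.write(rec + "\n")
        fh.write('"Time (ms)"\t"Current"\t"Voltage (mV)"\n')
        for t, i, v in zip(trace.t, trace.i, trace.v):
            fh.write(f"{t:.10g}\t{i:.10g}\t{v:.10g}\n")
    return path


def read_atf(path: str | Path) -> SimTrace:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines[0].startswith("ATF"):
        raise ValueError(f"{path} is not an ATF file")
    n_rec, _n_cols = (int(x) for x in lines[1].split("\t"))
    doc = {"segments": [], "meta": {}}
    for rec in lines[2 : 2 + n_rec]:
        body = rec.strip('"')
        if body.startswith("Comment=kvclamp-trace"):
            doc = json.loads(body[len("Comment=kvclamp-trace") :].replace("'", '"'))
    data = np.array(
        [[float(x) for x in ln.split("\t")] for ln in lines[3 + n_rec :] if ln.strip()]
    )
    df = pd.DataFrame(
        {"time_ms": data[:, 0], "current": data[:, 1], "voltage_mV": data[:, 2]}
    )
    if not doc["segments"]:
        doc["segments"] = _segments_from_voltage(df)
    return _trace_from(df, doc)


def read_trace(path: str | Path) -> SimTrace:
    path = Path(path)
    if path.suffix.lower() == ".atf":
        return read_atf(path)
    return read_csv(path)
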