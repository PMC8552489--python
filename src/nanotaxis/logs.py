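"""COLVAR- and HILLS-style tabular logs for CV traces and deposited kernels.

Both formats are whitespace tables with a ``#! FIELDS ...`` header naming
the columns, mirroring the convention of enhanced-sampling plug-ins, plus
optional ``#`` metadata lines (seed, config hash).  Numeric values
round-trip at full precision ('%.17g'), so rewriting a parsed log is
byte-stable and the acceleration factor computed from a round-tripped log
is identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .sampling import BiasState

__all__ = ["write_colvar", "read_colvar", "write_hills", "read_hills",
           "LogSchemaError"]

_FMT = "%.17g"


class LogSchemaError(ValueError):
    """Header/column mismatch in a tabular log."""


def _write_table(path, fields: list[str], rows: np.ndarray,
                 metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        for k, v in (metadata or {}).items():
            fh.write(f"# {k} {v}\n")
        for row in np.atleast_2d(rows):
            fh.write(" ".join(_FMT % x for x in row) + "\n")


def _read_table(path) -> tuple[list[str], np.ndarray, dict]:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#! FIELDS"):
        raise LogSchemaError("missing '#! FIELDS' header")
    fields = lines[0].split()[2:]
    metadata: dict = {}
    rows = []
    for ln_no, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        if ln.startswith("#"):
            parts = ln[1:].split(None, 1)
            if len(parts) == 2:
                metadata[parts[0]] = parts[1]
            continue
        vals = ln.split()
        if len(vals) != len(fields):
            raise LogSchemaError(
                f"line {ln_no}: {len(vals)} columns, header names {len(fields)}"
            )
        rows.append([float(v) for v in vals])
    data = np.asarray(rows) if rows else np.zeros((0, len(fields)))
    return fields, data, metadata


def write_colvar(path, times, cvs, bias, metadata: dict | None = None) -> None:
    """Write a (time, CV components, bias) table."""
    times = np.asarray(times, dtype=float)
    cvs = np.atleast_2d(np.asarray(cvs, dtype=float))
    if cvs.shape[0] != len(times):
        cvs = cvs.T
    bias = np.asarray(bias, dtype=float)
    fields = ["time"] + [f"cv{k + 1}" for k in range(cvs.shape[1])] + ["bias"]
    rows = np.column_stack([times, cvs, bias])
    _write_table(path, fields, rows, metadata)


def read_colvar(path) -> dict:
    """Read a COLVAR-style log -> {'time', 'cv' (n, d), 'bias', 'metadata'}."""
    fields, data, metadata = _read_table(path)
    if len(fields) < 2 or fields[0] != "time" or fields[-1] != "bias":
        raise LogSchemaError(f"unexpected COLVAR fields {fields}")
    return {
        "time": data[:, 0],
        "cv": data[:, 1:-1],
        "bias": data[:, -1],
        "metadata": metadata,
    }


def write_hills(path, bias: BiasState, metadata: dict | None = None) -> None:
    """Write deposited kernels: time, centers, widths, effective height."""
    d = len(bias.widths)
    fields = (
        ["time"]
        + [f"center{k + 1}" for k in range(d)]
        + [f"sigma{k + 1}" for k in range(d)]
        + ["height"]
    )
    n = bias.n_kernels
    rows = np.zeros((n, 2 * d + 2))
    if n:
        rows[:, 0] = bias.times
        rows[:, 1:1 + d] = np.asarray(bias.centers)
        rows[:, 1 + d:1 + 2 * d] = np.asarray(bias.widths)[None, :]
        rows[:, -1] = bias.heights
    _write_table(path, fields, rows, metadata)


def read_hills(path) -> BiasState:
    """Read a HILLS-style kernel table back into a :class:`BiasState`."""
    fields, data, _ = _read_table(path)
    d = sum(1 for f in fields if f.startswith("center"))
    if d == 0 or fields[0] != "time" or fields[-1] != "height":
        raise LogSchemaError(f"unexpected HILLS fields {fields}")
    widths = data[0, 1 + d:1 + 2 * d] if len(data) else np.ones(d)
    state = BiasState(widths=np.asarray(widths, dtype=float))
    for row in data:
        state.centers.append(row[1:1 + d].copy())
        state.heights.append(float(row[-1]))
        state.times.append(float(row[0]))
    return state
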