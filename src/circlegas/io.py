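"""CSV trace files and YAML run configuration.

Trace files are plain CSV with the header
``time_s,phase,fio2_pct,fisevo_pct,fin2o_pct,fico2_pct``: time in seconds
on a uniform grid, a phase label, and the four monitored gas channels in
percent.  N2 is not stored (the monitor does not report it) and is
reconstructed as the clamped balance on read, so a written-then-read
trace matches the original to the declared precision on every stored
column.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .kinetics import CircuitConfig, PatientModel
from .scenario import DEFAULT_DT, GasTrace
from .synthetic import MonitorModel

TRACE_HEADER = ["time_s", "phase", "fio2_pct", "fisevo_pct", "fin2o_pct", "fico2_pct"]
#: Decimal places of the stored percentages.
TRACE_PRECISION = 4


class TraceParseError(ValueError):
    """A trace file is malformed; the message carries the line number."""


def write_trace(trace: GasTrace, path) -> None:
    """Write a trace as CSV (times in seconds, gases in %)."""
    path = Path(path)
    pct = trace.fractions * 100.0
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TRACE_HEADER)
        for i, t in enumerate(trace.times):
            w.writerow(
                [
                    f"{t * 60.0:.3f}",
                    str(trace.phases[i]),
                    f"{pct[i, 0]:.{TRACE_PRECISION}f}",
                    f"{pct[i, 1]:.{TRACE_PRECISION}f}",
                    f"{pct[i, 2]:.{TRACE_PRECISION}f}",
                    f"{pct[i, 3]:.{TRACE_PRECISION}f}",
                ]
            )


def read_trace(path) -> GasTrace:
    """Read a trace CSV, validating header, times and percentage ranges.

    The returned trace is marked ``quantized`` (stored readings need not
    sum to 100 % exactly); N2 is reconstructed as the clamped balance.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TraceParseError(f"{path}: empty file") from None
        if [h.strip() for h in header] != TRACE_HEADER:
            raise TraceParseError(
                f"{path}:1: bad header {header!r}; expected {TRACE_HEADER}"
            )
        times, phases, rows = [], [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(TRACE_HEADER):
                raise TraceParseError(
                    f"{path}:{lineno}: expected {len(TRACE_HEADER)} fields, "
                    f"got {len(row)}"
                )
            try:
                t = float(row[0])
                gases = [float(x) for x in row[2:6]]
            except ValueError as exc:
                raise TraceParseError(f"{path}:{lineno}: {exc}") from None
            if times and t <= times[-1]:
                raise TraceParseError(
                    f"{path}:{lineno}: time {t} s does not increase"
                )
            for name, v in zip(TRACE_HEADER[2:], gases):
                if not 0.0 <= v <= 100.0:
                    raise TraceParseError(
                        f"{path}:{lineno}: {name}={v} outside [0, 100] %"
                    )
            times.append(t)
            phases.append(row[1])
            rows.append(gases)
    if len(times) < 2:
        raise TraceParseError(f"{path}: need at least two samples")
    pct = np.asarray(rows)
    fractions = np.zeros((len(times), 5))
    fractions[:, :4] = pct / 100.0
    fractions[:, 4] = np.clip(1.0 - fractions[:, :4].sum(axis=1), 0.0, 1.0)
    try:
        return GasTrace(
            times=np.asarray(times) / 60.0,
            fractions=fractions,
            phases=np.array(phases, dtype=object),
            quantized=True,
        )
    except ValueError as exc:
        raise TraceParseError(f"{path}: {exc}") from None


@dataclass(frozen=True)
class RunConfig:
    """Resolved run configuration: circuit, patient, monitor, step size."""

    circuit: CircuitConfig
    patient: PatientModel
    monitor: MonitorModel
    dt: float = DEFAULT_DT


def load_run_config(path=None, seed: int | None = None) -> RunConfig:
    """Build a RunConfig from an optional YAML file.

    The file may contain ``circuit``, ``patient``, ``monitor`` and
    ``simulation`` mappings whose keys mirror the dataclass fields; any
    omitted key keeps its default.  ``seed`` (if given) overrides the
    monitor seed.
    """
    data: dict = {}
    if path is not None:
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: top level must be a mapping")
        unknown = set(data) - {"circuit", "patient", "monitor", "simulation"}
        if unknown:
            raise ValueError(f"{path}: unknown sections {sorted(unknown)}")
    monitor_kwargs = dict(data.get("monitor") or {})
    if seed is not None:
        monitor_kwargs["seed"] = seed
    return RunConfig(
        circuit=CircuitConfig(**(data.get("circuit") or {})),
        patient=PatientModel(**(data.get("patient") or {})),
        monitor=MonitorModel(**monitor_kwargs),
        dt=float((data.get("simulation") or {}).get("dt", DEFAULT_DT)),
    )
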