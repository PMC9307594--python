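"""Trace and manifest file formats.

Each trace is one UTF-8 delimited text file with a header line naming
the columns ``frame\ttime_s\tdonor\tacceptor`` and optional ``#``
comment lines; an ensemble ships with a YAML manifest carrying the
generating mixture, photophysics, seeds and ground-truth event times
(when simulated) plus per-trace file names.  Plain text is the canonical
format — smFRET has no universal standard — and round-trips exactly.
"""

from __future__ import annotations

import glob
import os

import numpy as np
import yaml

from .simulate import FluorescenceTrace

__all__ = [
    "TraceSchemaError",
    "write_trace",
    "read_trace",
    "write_traces",
    "read_traces",
    "write_manifest",
    "read_manifest",
    "RunReport",
]

COLUMNS = ("frame", "time_s", "donor", "acceptor")
MANIFEST_NAME = "manifest.yaml"


class TraceSchemaError(ValueError):
    def __init__(self, path, line, message):
        super().__init__(f"{path}:{line}: {message}")
        self.path = path
        self.line = line


def write_trace(trace, path):
    with open(path, "w") as fh:
        fh.write(f"# frame_interval_s = {float(trace.frame_interval)!r}\n")
        fh.write("\t".join(COLUMNS) + "\n")
        t = trace.times
        for i in range(trace.n_frames):
            fh.write(f"{i}\t{float(t[i])!r}\t{float(trace.donor[i])!r}\t"
                     f"{float(trace.acceptor[i])!r}\n")


def read_trace(path):
    frame_interval = None
    rows = []
    header = None
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "frame_interval_s" in line and "=" in line:
                    frame_interval = float(line.split("=", 1)[1])
                continue
            if header is None:
                header = tuple(line.split("\t"))
                missing = [c for c in COLUMNS if c not in header]
                if missing:
                    raise TraceSchemaError(
                        path, line_no, f"missing column(s): {', '.join(missing)}")
                idx = {c: header.index(c) for c in COLUMNS}
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise TraceSchemaError(
                    path, line_no,
                    f"expected {len(header)} fields, got {len(parts)}")
            try:
                rows.append(tuple(float(parts[idx[c]]) for c in COLUMNS))
            except ValueError as exc:
                raise TraceSchemaError(path, line_no, str(exc)) from None
    if header is None:
        raise TraceSchemaError(path, 0, "no header line")
    if not rows:
        raise TraceSchemaError(path, 0, "no data rows")
    arr = np.array(rows)
    times = arr[:, 1]
    if np.any(np.diff(times) <= 0):
        bad = int(np.argmax(np.diff(times) <= 0)) + 1
        raise TraceSchemaError(path, bad + 2, "time_s must increase strictly")
    if frame_interval is None:
        frame_interval = float(times[1] - times[0]) if times.size > 1 else 1.0
    return FluorescenceTrace(arr[:, 2], arr[:, 3], frame_interval,
                             meta={"source": os.fspath(path)})


def _trace_filename(i):
    return f"trace_{i:05d}.tsv"


def write_traces(traces, directory, manifest=None):
    """Write one .tsv per trace plus the ensemble manifest."""
    os.makedirs(directory, exist_ok=True)
    names = []
    for i, tr in enumerate(traces):
        name = _trace_filename(i)
        write_trace(tr, os.path.join(directory, name))
        names.append(name)
    if manifest is not None:
        manifest = dict(manifest)
        manifest["trace_files"] = names
        write_manifest(manifest, os.path.join(directory, MANIFEST_NAME))
    return names


def read_traces(directory):
    """Read an ensemble directory; returns (traces, manifest or None)."""
    manifest_path = os.path.join(directory, MANIFEST_NAME)
    manifest = read_manifest(manifest_path) if os.path.exists(manifest_path) \
        else None
    if manifest and "trace_files" in manifest:
        files = [os.path.join(directory, f) for f in manifest["trace_files"]]
    else:
        files = sorted(glob.glob(os.path.join(directory, "*.tsv")))
    if not files:
        raise FileNotFoundError(f"no trace files in {directory}")
    traces = [read_trace(f) for f in files]
    if manifest is not None:
        for tr, rec in zip(traces, manifest.get("traces", [])):
            tr.meta.update({k: v for k, v in rec.items() if k != "path"})
            tr.meta["ground_truth_path"] = rec.get("path")
    return traces, manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_manifest(manifest, path):
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(manifest), fh, sort_keys=False)


def read_manifest(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


class RunReport:
    """Structured record of one analysis run.

    Carries the config snapshot, per-stage trace counts (every excluded
    trace accounted for with a reason), the rates table, fractions,
    classifications, and warnings; serializes to YAML.
    """

    def __init__(self, config):
        self.config = config.to_dict() if hasattr(config, "to_dict") else dict(config)
        self.stages = []
        self.rates = []
        self.fractions = {}
        self.classifications = {}
        self.warnings = []

    def add_stage(self, name, n_in, n_out, excluded_reasons=None):
        self.stages.append({
            "stage": name, "n_in": int(n_in), "n_out": int(n_out),
            "excluded": _jsonable(excluded_reasons or {}),
        })

    def add_rate(self, estimate):
        self.rates.append(_jsonable(estimate.to_row()))

    def warn(self, message):
        self.warnings.append(str(message))

    def to_dict(self):
        return {
            "config": _jsonable(self.config),
            "stages": self.stages,
            "rates": self.rates,
            "fractions": _jsonable(self.fractions),
            "classifications": _jsonable(self.classifications),
            "warnings": self.warnings,
        }

    def save(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        rep = cls(d.get("config", {}))
        rep.stages = d.get("stages", [])
        rep.rates = d.get("rates", [])
        rep.fractions = d.get("fractions", {})
        rep.classifications = d.get("classifications", {})
        rep.warnings = d.get("warnings", [])
        return rep
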