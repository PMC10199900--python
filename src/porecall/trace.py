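"""Uniformly sampled current recordings and their on-disk formats.

A :class:`TraceRecording` is a 1-D array of current samples in nA at a
fixed sampling rate, plus a provenance map (seed, config digest, filter
chain).  Two interchange formats are supported: a two-column delimited
text file (time_s, current_nA) and a raw little-endian float32 stream
with a JSON sidecar header carrying the sampling rate and provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, ValidationError

__all__ = ["TraceRecording", "write_trace", "read_trace"]


@dataclass
class TraceRecording:
    samples: np.ndarray  # current, nA
    sampling_rate: float  # Hz
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("trace samples must be 1-D")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValidationError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    def with_samples(self, samples: np.ndarray, **meta) -> "TraceRecording":
        merged = {**self.meta, **meta}
        return TraceRecording(samples, self.sampling_rate, merged)


def write_trace(trace: TraceRecording, path: str | Path, fmt: str = "binary") -> None:
    """Write a trace as text (``fmt="text"``) or float32 raw + JSON sidecar."""
    path = Path(path)
    if fmt == "text":
        header = f"# sampling_rate_hz={trace.sampling_rate!r}\n# units=nA\ntime_s\tcurrent_nA\n"
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(
                fh,
                np.column_stack([trace.times(), trace.samples]),
                fmt="%.7g",
                delimiter="\t",
            )
    elif fmt == "binary":
        trace.samples.astype("<f4").tofile(path)
        sidecar = {
            "sampling_rate_hz": trace.sampling_rate,
            "units": "nA",
            "dtype": "<f4",
            "n_samples": int(trace.samples.size),
            "meta": _jsonable(trace.meta),
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValidationError(f"unknown trace format {fmt!r}")


def read_trace(path: str | Path) -> TraceRecording:
    """Read a trace written by :func:`write_trace` (format auto-detected)."""
    path = Path(path)
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        head = json.loads(sidecar.read_text())
        samples = np.fromfile(path, dtype=head.get("dtype", "<f4")).astype(float)
        return TraceRecording(samples, float(head["sampling_rate_hz"]), head.get("meta", {}))
    # text format
    rate = None
    with open(path) as fh:
        first = fh.read(4096)
    if not first.strip():
        raise FormatError(f"empty trace file: {path}")
    for line in first.splitlines():
        if line.startswith("#") and "sampling_rate_hz=" in line:
            rate = float(line.split("=", 1)[1])
    return _finish_text_read(path, rate)


def _finish_text_read(path: Path, rate: float | None) -> TraceRecording:
    import pandas as pd

    table = pd.read_csv(path, sep="\t", comment="#")
    if "current_nA" not in table.columns or "time_s" not in table.columns:
        raise FormatError(f"trace text file lacks time_s/current_nA columns: {path}")
    t = table["time_s"].to_numpy(dtype=float)
    x = table["current_nA"].to_numpy(dtype=float)
    if rate is None:
        if len(t) < 2:
            raise FormatError("cannot infer sampling rate from a <2-sample trace")
        rate = 1.0 / float(np.median(np.diff(t)))
    return TraceRecording(x, rate, {"source": str(path)})


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
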