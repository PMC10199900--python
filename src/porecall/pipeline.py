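"""End-to-end helpers: simulate → detect → tabulate.

These glue the simulator and the detector together for the common
workflow of this package: generate a ground-truthed recording for one
or more analytes, run the detection chain, transfer ground-truth labels
onto detected events by midpoint containment, and hand the resulting
event table to the density/classification stages.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .detect import DetectionConfig, EventDetector, EventRecord
from .errors import FormatError
from .signals import SignalLibrary, default_library
from .simulate import SimulationConfig, simulate_trace
from .trace import TraceRecording

__all__ = [
    "events_to_frame",
    "write_events",
    "read_events",
    "label_events",
    "match_ground_truth",
    "simulate_events",
]

EVENT_COLUMNS = [
    "label", "start_s", "dwell_s", "I0_nA", "dI_nA", "rel_blockade",
]


def events_to_frame(
    events: list[EventRecord], device: str = "", voltage_mV: float = np.nan
) -> pd.DataFrame:
    rows = [
        {
            "label": e.label,
            "start_s": e.start_s,
            "dwell_s": e.dwell,
            "I0_nA": e.I0_local,
            "dI_nA": e.dI,
            "rel_blockade": e.relative_blockade,
        }
        for e in events
    ]
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    frame.attrs["device"] = device
    frame.attrs["voltage_mV"] = voltage_mV
    return frame


def write_events(frame: pd.DataFrame, path: str | Path) -> None:
    """Event table as TSV; '#'-prefixed header lines carry metadata."""
    with open(path, "w") as fh:
        for key, val in frame.attrs.items():
            fh.write(f"# {key}={val}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    from ._util import read_tsv

    frame = read_tsv(path)
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns and c != "label"]
    if missing:
        raise FormatError(f"event table missing columns: {missing}")
    return frame


def match_ground_truth(
    events: list[EventRecord], truth: pd.DataFrame
) -> np.ndarray:
    """Index of the ground-truth row whose span contains each detected
    event's midpoint; −1 where none does."""
    starts = truth["start_index"].to_numpy()
    ends = truth["end_index"].to_numpy()
    out = np.full(len(events), -1)
    for i, e in enumerate(events):
        mid = (e.start_index + e.end_index) // 2
        hit = np.flatnonzero((starts <= mid) & (mid < ends))
        if hit.size:
            out[i] = hit[0]
    return out


def label_events(events: list[EventRecord], truth: pd.DataFrame) -> list[EventRecord]:
    """Attach ground-truth labels by midpoint containment; events whose
    midpoint falls outside every true event stay unlabeled."""
    idx = match_ground_truth(events, truth)
    labels = truth["label"].to_numpy()
    for e, i in zip(events, idx):
        e.label = str(labels[i]) if i >= 0 else None
    return events


def simulate_events(
    analytes: list[tuple[str, str, float]] | tuple[str, str],
    n_events: int,
    seed: int,
    library: SignalLibrary | None = None,
    detection: DetectionConfig | None = None,
    **config_overrides,
) -> tuple[pd.DataFrame, pd.DataFrame, TraceRecording]:
    """Simulate a recording long enough for ~``n_events`` events, detect,
    and label.  Returns (labeled event table, ground truth, trace).

    ``analytes`` is either one ``(label, device)`` pair or a list of
    ``(label, device, abundance)`` triples.
    """
    library = library or default_library()
    if isinstance(analytes, tuple) and len(analytes) == 2 and isinstance(analytes[0], str):
        analytes = [(analytes[0], analytes[1], 1.0)]
    rate = config_overrides.pop("event_rate", 10.0)
    # sub-Poisson thinning plus dwell occupancy: pad the duration ~15%
    duration = config_overrides.pop("duration", 1.15 * n_events / rate)
    config = SimulationConfig(
        duration=duration,
        event_rate=rate,
        analytes=tuple(tuple(a) for a in analytes),
        seed=seed,
        **config_overrides,
    )
    trace, truth = simulate_trace(config, library)
    detector = EventDetector(**(detection.__dict__ if detection else {}))
    events = label_events(detector.transform(trace), truth)
    frame = events_to_frame(
        events,
        device=analytes[0][1],
        voltage_mV=trace.meta.get("voltage_mV", np.nan),
    )
    return frame, truth, trace
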