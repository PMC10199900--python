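"""Event detection on nanopore current traces.

Processing chain: zero-phase 2nd-order Butterworth low-pass at 10 kHz,
moving-average baseline over a 300 ms window, dual-threshold event
calling against the local noise level, per-event feature extraction
(dwell Δt, local open-pore current I0, mean blockade depth ΔI, relative
blockade ΔI/I0), and a dwell filter that drops events shorter than
0.1 ms.

Event calling uses hysteresis: an event opens where the current drops
more than ``threshold_k``·σ below the baseline and its boundaries are
the surrounding crossings of ``boundary_k``·σ, with σ a robust (MAD)
noise estimate from event-free stretches.  On effectively noiseless
input the thresholds fall back to 1% of the baseline current.  The
baseline is estimated twice: a first pass without masking finds
candidate events, a second pass excludes them so that deep blockades do
not drag the baseline down.

ΔI is the mean of in-event samples after trimming a filter settle
margin from each boundary; both the acquisition electronics and the
zero-phase analysis filter smear rectangular edges into the event, and
an untrimmed mean would be biased shallow for millisecond-scale dwells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import ValidationError
from .trace import TraceRecording

__all__ = [
    "DetectionConfig",
    "EventRecord",
    "lowpass_filter",
    "estimate_baseline",
    "detect_events",
    "filter_events",
    "downsample_for_display",
    "EventDetector",
]


@dataclass(frozen=True)
class DetectionConfig:
    filter_type: str = "butterworth"
    filter_order: int = 2
    filter_cutoff: float = 10_000.0  # Hz
    apply_filter: bool = True  # disable for already-clean traces
    baseline_window: float = 0.3  # s
    threshold_k: float = 5.0  # event-opening threshold, multiples of sigma
    boundary_k: float = 2.5  # boundary-crossing threshold
    min_dwell: float = 1e-4  # s; events with dwell < min_dwell are excluded
    min_events_warning: int = 300
    edge_trim: float = 6e-5  # s trimmed from each boundary for the dI mean
    context_frac: float = 0.5  # waveform snippet context per side, x dwell

    def __post_init__(self) -> None:
        if not self.boundary_k < self.threshold_k:
            raise ValidationError("boundary_k must be < threshold_k")
        if self.min_dwell < 0:
            raise ValidationError("min_dwell must be >= 0")


@dataclass
class EventRecord:
    """One detected translocation event (indices half-open, 0-based)."""

    start_index: int
    end_index: int
    sampling_rate: float
    I0_local: float  # nA
    dI: float  # nA, mean blockade depth
    waveform: np.ndarray  # snippet with context, rectified nA
    waveform_start: int  # trace index of waveform[0]
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.end_index > self.start_index:
            raise ValidationError("event end must exceed start")
        if not self.I0_local > 0:
            raise ValidationError("local baseline must be positive")

    @property
    def dwell(self) -> float:
        return (self.end_index - self.start_index) / self.sampling_rate

    @property
    def relative_blockade(self) -> float:
        return self.dI / self.I0_local

    @property
    def start_s(self) -> float:
        return self.start_index / self.sampling_rate


def lowpass_filter(
    trace: TraceRecording, config: DetectionConfig = DetectionConfig()
) -> TraceRecording:
    """Zero-phase (forward-backward) Butterworth low-pass.

    Zero-phase application keeps event boundaries unshifted, so dwell
    times are unbiased by the analysis filter.
    """
    if config.filter_cutoff >= trace.sampling_rate / 2:
        raise ValidationError("filter cutoff must be below Nyquist")
    sos = sps.butter(
        config.filter_order, config.filter_cutoff, btype="low",
        fs=trace.sampling_rate, output="sos",
    )
    y = sps.sosfiltfilt(sos, trace.samples)
    chain = list(trace.meta.get("filter_chain", []))
    chain.append({"type": config.filter_type, "order": config.filter_order,
                  "cutoff_hz": config.filter_cutoff, "zero_phase": True})
    return trace.with_samples(y, filter_chain=chain)


def estimate_baseline(
    trace: TraceRecording,
    baseline_window: float = 0.3,
    event_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Centered moving-average baseline, optionally excluding events.

    Samples under ``event_mask`` are excluded from the average and the
    baseline across them is the window mean of the surrounding unmasked
    samples, so deep blockades do not drag the baseline.  Edges use
    shrinking windows.
    """
    x = trace.samples
    size = int(round(baseline_window * trace.sampling_rate))
    if size < 10:
        raise ValidationError("baseline window must span at least 10 samples")
    if size > x.size:
        raise ValidationError("baseline window longer than trace")
    if event_mask is None:
        w = np.ones(x.size)
    else:
        if event_mask.shape != x.shape:
            raise ValidationError("event_mask must align with trace")
        w = (~event_mask).astype(float)
    # shrinking-window mean: zero padding drops out of both sums
    num = uniform_filter1d(x * w, size, mode="constant", cval=0.0)
    den = uniform_filter1d(w, size, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        baseline = num / den
    bad = ~np.isfinite(baseline)
    if bad.any():
        good = np.flatnonzero(~bad)
        if good.size == 0:
            raise ValidationError("event_mask covers the entire trace")
        baseline[bad] = np.interp(np.flatnonzero(bad), good, baseline[good])
    return baseline


def robust_sigma(residual: np.ndarray, mask: np.ndarray | None = None) -> float:
    """MAD-based noise SD estimate, insensitive to sparse events."""
    r = residual if mask is None else residual[~mask]
    if r.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(r - np.median(r))))


def detect_events(
    trace: TraceRecording,
    baseline: np.ndarray,
    config: DetectionConfig = DetectionConfig(),
    sigma: float | None = None,
) -> list[EventRecord]:
    """Dual-threshold event calling against a baseline.

    The trace is assumed rectified (positive baseline, downward
    blockades); :class:`EventDetector` handles polarity.
    """
    x = trace.samples
    if baseline.shape != x.shape:
        raise ValidationError("baseline must align with trace")
    fs = trace.sampling_rate
    resid = baseline - x  # positive inside blockades

    if sigma is None:
        sigma = robust_sigma(-resid)
    i0_scale = float(np.median(baseline))
    floor = 0.01 * i0_scale
    if sigma <= 0 or config.threshold_k * sigma < floor:
        thr, bthr = floor, 0.5 * floor
    else:
        thr = config.threshold_k * sigma
        bthr = config.boundary_k * sigma

    shallow = resid > bthr
    deep = resid > thr
    if not deep.any():
        return []
    edges = np.diff(shallow.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if shallow[0]:
        starts = np.concatenate([[0], starts])
    if shallow[-1]:
        ends = np.concatenate([ends, [x.size]])

    deep_cum = np.concatenate([[0], np.cumsum(deep)])
    trim_n = int(round(config.edge_trim * fs))
    events: list[EventRecord] = []
    for s0, s1 in zip(starts, ends):
        if deep_cum[s1] - deep_cum[s0] == 0:
            continue  # never crossed the opening threshold
        trim = min(trim_n, (s1 - s0) // 4)
        core = slice(s0 + trim, s1 - trim)
        dI = float(np.mean(resid[core]))
        I0_local = float(np.mean(baseline[s0:s1]))
        if dI <= 0 or I0_local <= 0:
            continue
        dI = min(dI, I0_local)  # relative blockade capped at 1
        ctx = max(5, int(round(config.context_frac * (s1 - s0))))
        w0, w1 = max(0, s0 - ctx), min(x.size, s1 + ctx)
        events.append(
            EventRecord(
                start_index=int(s0),
                end_index=int(s1),
                sampling_rate=fs,
                I0_local=I0_local,
                dI=dI,
                waveform=x[w0:w1].copy(),
                waveform_start=int(w0),
            )
        )
    return events


def filter_events(events: list[EventRecord], min_dwell: float) -> list[EventRecord]:
    """Keep events with dwell >= ``min_dwell`` (boundary inclusive),
    preserving order and leaving every retained record untouched."""
    return [e for e in events if e.dwell >= min_dwell]


def downsample_for_display(
    trace: TraceRecording, target_rate: float = 10_000.0
) -> TraceRecording:
    """Anti-aliased decimation for plotting; never feeds detection."""
    if target_rate > trace.sampling_rate:
        raise ValidationError("target rate must not exceed the sampling rate")
    q = int(round(trace.sampling_rate / target_rate))
    if q == 1:
        return trace.with_samples(trace.samples.copy())
    # polyphase FIR decimation; linear edge padding keeps DC exact
    y = sps.resample_poly(trace.samples, 1, q, padtype="line")
    return TraceRecording(y, trace.sampling_rate / q,
                          {**trace.meta, "display_downsampled": True})


class EventDetector:
    """Full detection chain as a transform-style estimator.

    ``transform`` runs filter → baseline → detect → (masked baseline,
    redetect) → dwell filter on a :class:`TraceRecording` and returns a
    list of :class:`EventRecord`.  Traces of either polarity are
    accepted; detection operates on the rectified current.

    Parameters mirror :class:`DetectionConfig`.
    """

    def __init__(self, **params) -> None:
        self.config = DetectionConfig(**params)

    # sklearn-style param plumbing
    def get_params(self, deep: bool = True) -> dict:
        return dict(self.config.__dict__)

    def set_params(self, **params) -> "EventDetector":
        self.config = DetectionConfig(**{**self.config.__dict__, **params})
        return self

    def fit(self, X: TraceRecording | None = None, y=None) -> "EventDetector":
        return self  # stateless: detection needs no training

    def transform(self, X: TraceRecording) -> list[EventRecord]:
        cfg = self.config
        polarity = 1.0 if np.median(X.samples) >= 0 else -1.0
        rect = X.with_samples(polarity * X.samples, polarity=polarity)
        filt = lowpass_filter(rect, cfg) if cfg.apply_filter else rect
        base1 = estimate_baseline(filt, cfg.baseline_window)
        first = detect_events(filt, base1, cfg)

        mask = np.zeros(filt.samples.size, dtype=bool)
        pad = max(1, int(round(cfg.edge_trim * filt.sampling_rate)))
        for e in first:
            mask[max(0, e.start_index - pad): e.end_index + pad] = True
        base2 = estimate_baseline(filt, cfg.baseline_window, event_mask=mask)
        sigma = robust_sigma(filt.samples - base2, mask=mask)
        events = detect_events(filt, base2, cfg, sigma=sigma)
        kept = filter_events(events, cfg.min_dwell)
        if len(kept) < cfg.min_events_warning:
            warnings.warn(
                f"only {len(kept)} events detected; population statistics "
                f"are typically based on at least {cfg.min_events_warning}",
                stacklevel=2,
            )
        return kept

    def fit_transform(self, X: TraceRecording, y=None) -> list[EventRecord]:
        return self.fit(X).transform(X)
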