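"""Synthetic nanopore current recordings with exhaustive ground truth.

The simulator emulates an electrophoretically driven solid-state
nanopore measurement: an open-pore current I0 carrying additive white
Gaussian noise, interrupted by rectangular translocation events whose
depth is drawn from a per-analyte blockade model and whose duration is
drawn from its dwell model.  Event arrivals follow a Poisson process
thinned so that events never overlap (slightly sub-Poisson at high
rates).  An acquisition chain — a causal 2nd-order low-pass Bessel at
10 kHz, matching typical patch-clamp recording electronics at 100 kHz
sampling — smooths the rectangles and sets the post-filter noise RMS.

Sign conventions: ``voltage`` is the trans-side bias in mV.  The sign
must be opposite to the analytes' charge sign (a positively charged
analyte is driven by a negative trans bias).  The recorded current
carries the sign of the bias; blockades always reduce its magnitude.
Blockade amplitudes grow with |voltage|; an ohmic (linear) scaling from
the 200 mV reference is used.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ValidationError
from .signals import SignalLibrary
from .trace import TraceRecording

__all__ = [
    "SimulationConfig",
    "scale_blockade_with_voltage",
    "acquisition_filter_sos",
    "add_acquisition_chain",
    "simulate_trace",
    "write_ground_truth",
    "read_ground_truth",
]

REFERENCE_VOLTAGE_MV = 200.0

GROUND_TRUTH_COLUMNS = [
    "label",
    "start_s",
    "dwell_s",
    "start_index",
    "end_index",
    "depth_nA",
    "rel_blockade",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one simulated measurement.

    ``analytes`` lists ``(label, device_tag, abundance)`` triples resolved
    against a :class:`~porecall.signals.SignalLibrary`; abundances must
    sum to 1.  ``noise_rms`` is the post-filter target in nA.  ``voltage``
    defaults to the reference bias with the sign required by the
    analytes' charge; set it explicitly to simulate other biases.
    """

    duration: float = 60.0  # s
    sampling_rate: float = 100_000.0  # Hz
    I0: float = 3.0  # open-pore current magnitude, nA
    voltage: float | None = None  # mV, signed; None = ±200 per charge sign
    noise_rms: float = 0.01  # nA, post-filter
    event_rate: float = 10.0  # events / s
    analytes: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0
    filter_cutoff: float = 10_000.0  # Hz
    filter_order: int = 2
    apply_filter: bool = True
    min_gap: float = 1e-3  # s of clean baseline enforced between events
    baseline_drift_amp: float = 0.0  # nA, optional slow sinusoidal drift
    baseline_drift_period: float = 30.0  # s

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValidationError("duration must be positive")
        if not self.I0 > 0:
            raise ValidationError("I0 must be positive")
        if self.event_rate < 0:
            raise ValidationError("event_rate must be >= 0")
        if self.apply_filter and self.sampling_rate < 2 * self.filter_cutoff:
            raise ValidationError("sampling_rate must be >= 2x filter cutoff")
        if self.analytes:
            total = sum(a[2] for a in self.analytes)
            if abs(total - 1.0) > 1e-9:
                raise ValidationError("analyte abundances must sum to 1")

    def digest(self) -> str:
        payload = json.dumps(
            {k: (list(map(list, v)) if k == "analytes" else v)
             for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def scale_blockade_with_voltage(
    depth_at_reference: float,
    voltage: float,
    reference_voltage: float = REFERENCE_VOLTAGE_MV,
) -> float:
    """Ohmic scaling of a blockade amplitude from the reference bias.

    ΔI(V) = ΔI(V_ref) · |V| / |V_ref|, strictly increasing in |V|.  The
    two voltages must share a sign: the driving polarity cannot flip
    within one model.
    """
    if voltage == 0 or reference_voltage == 0:
        raise ValidationError("voltages must be nonzero")
    if np.sign(voltage) != np.sign(reference_voltage):
        raise ValidationError("voltage sign mismatch with reference")
    return depth_at_reference * abs(voltage) / abs(reference_voltage)


def acquisition_filter_sos(
    sampling_rate: float, cutoff: float = 10_000.0, order: int = 2
) -> np.ndarray:
    """Causal low-pass Bessel section emulating recording electronics."""
    if cutoff >= sampling_rate / 2:
        raise ValidationError("cutoff must be below Nyquist")
    return sps.bessel(order, cutoff, btype="low", fs=sampling_rate,
                      output="sos", norm="mag")


def _noise_gain(sos: np.ndarray, sampling_rate: float) -> float:
    """RMS gain of the filter for white input noise.

    sqrt of the mean squared magnitude response over [0, Nyquist]; used
    to pre-scale white noise so the post-filter RMS hits its target.
    """
    w, h = sps.sosfreqz(sos, worN=4096, fs=sampling_rate)
    return float(np.sqrt(np.mean(np.abs(h) ** 2)))


def add_acquisition_chain(
    trace: TraceRecording,
    cutoff: float = 10_000.0,
    order: int = 2,
    noise_rms: float = 0.0,
    rng: np.random.Generator | None = None,
) -> TraceRecording:
    """Apply the acquisition filter, optionally injecting white noise
    pre-scaled so the post-filter noise RMS ≈ ``noise_rms``."""
    sos = acquisition_filter_sos(trace.sampling_rate, cutoff, order)
    x = trace.samples
    if noise_rms > 0:
        if rng is None:
            rng = np.random.default_rng()
        sigma_in = noise_rms / _noise_gain(sos, trace.sampling_rate)
        x = x + rng.normal(0.0, sigma_in, size=x.size)
    y = sps.sosfilt(sos, x)
    chain = list(trace.meta.get("filter_chain", []))
    chain.append({"type": "bessel", "order": order, "cutoff_hz": cutoff,
                  "noise_rms_nA": noise_rms})
    return trace.with_samples(y, filter_chain=chain)


def _draw_events(
    config: SimulationConfig, library: SignalLibrary, rng: np.random.Generator
) -> tuple[pd.DataFrame, float]:
    """Poisson arrivals thinned to forbid overlap, with per-event depth
    and dwell drawn from the analyte models."""
    fs = config.sampling_rate
    labels = [a[0] for a in config.analytes]
    devices = [a[1] for a in config.analytes]
    probs = np.array([a[2] for a in config.analytes])
    models = [library.get(l, d) for l, d in zip(labels, devices)]

    signs = {m.charge_sign for m in models}
    if len(signs) > 1:
        raise ValidationError(
            "analytes of opposite charge cannot be driven in one run"
        )
    charge_sign = signs.pop()
    voltage = config.voltage
    if voltage is None:
        voltage = -charge_sign * REFERENCE_VOLTAGE_MV
    if np.sign(voltage) != -charge_sign:
        raise ValidationError(
            f"bias {voltage} mV cannot drive analytes of charge sign "
            f"{charge_sign:+d}; the trans bias must have the opposite sign"
        )

    mean_dwell = float(np.mean([
        m.dwell.median_s * np.exp(m.dwell.sigma_log**2 / 2) for m in models
    ]))
    if config.event_rate * (mean_dwell + config.min_gap) > 0.5:
        raise ValidationError(
            "event_rate x (mean dwell + gap) exceeds duty cycle 0.5; "
            "cannot place non-overlapping events"
        )

    rows = []
    t = 0.0
    while True:
        t += config.min_gap + rng.exponential(1.0 / config.event_rate)
        which = int(rng.choice(len(models), p=probs))
        m = models[which]
        dwell = float(m.sample_dwells(1, rng)[0])
        if t + dwell + config.min_gap > config.duration:
            break
        blockade = float(m.sample_blockades(1, rng)[0])
        if m.blockade_units == "relative":
            depth_ref = blockade * config.I0
        else:
            depth_ref = blockade
        depth = scale_blockade_with_voltage(
            depth_ref, abs(voltage), REFERENCE_VOLTAGE_MV
        )
        depth = min(depth, config.I0)  # current cannot go below zero
        s0 = int(round(t * fs))
        s1 = s0 + max(1, int(round(dwell * fs)))
        rows.append(
            {
                "label": m.label,
                "start_s": s0 / fs,
                "dwell_s": (s1 - s0) / fs,
                "start_index": s0,
                "end_index": s1,
                "depth_nA": depth,
                "rel_blockade": depth / config.I0,
            }
        )
        t = s1 / fs
    return pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS), voltage


def simulate_trace(
    config: SimulationConfig,
    library: SignalLibrary,
    rng: np.random.Generator | None = None,
) -> tuple[TraceRecording, pd.DataFrame]:
    """Generate one recording and its exhaustive ground-truth table.

    With ``apply_filter=False`` and ``noise_rms=0`` the trace is the
    ideal piecewise-constant signal: exactly I0 outside events and
    I0 − ΔI inside (before sign), which detection oracle tests rely on.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))

    if config.event_rate > 0 and config.analytes:
        truth, voltage = _draw_events(config, library, rng)
    else:
        truth = pd.DataFrame(columns=GROUND_TRUTH_COLUMNS)
        voltage = config.voltage if config.voltage is not None else REFERENCE_VOLTAGE_MV

    x = np.full(n, config.I0)
    if config.baseline_drift_amp > 0:
        tgrid = np.arange(n) / fs
        x += config.baseline_drift_amp * np.sin(
            2 * np.pi * tgrid / config.baseline_drift_period
        )
    for s0, s1, depth in zip(
        truth["start_index"], truth["end_index"], truth["depth_nA"]
    ):
        x[int(s0): int(s1)] -= depth

    meta = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "voltage_mV": float(voltage),
        "I0_nA": config.I0,
        "polarity": int(np.sign(voltage)),
    }
    trace = TraceRecording(x, fs, meta)
    if config.apply_filter or config.noise_rms > 0:
        if config.apply_filter:
            trace = add_acquisition_chain(
                trace, config.filter_cutoff, config.filter_order,
                noise_rms=config.noise_rms, rng=rng,
            )
        else:
            trace = trace.with_samples(
                x + rng.normal(0.0, config.noise_rms, size=n)
            )
    trace.samples *= np.sign(voltage)
    return trace, truth


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
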