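"""Generative per-analyte signal models for nanopore blockade populations.

Each analyte measured on a given device is summarised by a one- or
two-component Gaussian distribution of its current blockade — either the
relative blockade ΔI/I0 (dimensionless) or the absolute depth ΔI in nA —
plus a lognormal dwell-time model.  The packaged parameter table
(``data/signal_library.tsv``) transcribes the published population means
and standard deviations for every (analyte, device) pair; a
:class:`SignalLibrary` maps ``(label, device_tag)`` keys to models and
exposes seeded samplers used by the trace simulator.

Blockade samples in relative units are truncated to (0, 1] by rejection:
a molecule cannot increase the current, and the pore can be blocked
almost completely, so values near 1 are legitimate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import read_tsv as _read_tsv
from .errors import FormatError, ValidationError

__all__ = [
    "DwellModel",
    "AminoAcidSignalModel",
    "SignalLibrary",
    "load_signal_library",
    "default_library",
    "sample_blockades",
    "sample_dwells",
]

#: Default lognormal dwell model: median 0.5 ms, log-sd 0.6.  With these
#: values ~0.4% of dwells fall below the 0.1 ms analysis cut-off, so the
#: dwell filter retains essentially the whole population.
DEFAULT_DWELL_MEDIAN_S = 5e-4
DEFAULT_DWELL_SIGMA_LOG = 0.6

_TABLE_COLUMNS = ["label", "device", "weight", "mean", "sd", "units", "charge_sign"]


@dataclass(frozen=True)
class DwellModel:
    """Lognormal dwell-time model (seconds)."""

    family: str = "lognormal"
    median_s: float = DEFAULT_DWELL_MEDIAN_S
    sigma_log: float = DEFAULT_DWELL_SIGMA_LOG

    def __post_init__(self) -> None:
        if self.family != "lognormal":
            raise ValidationError(f"unsupported dwell family: {self.family!r}")
        if not (self.median_s > 0 and self.sigma_log > 0):
            raise ValidationError("dwell median and sigma_log must be positive")

    def fraction_below(self, t: float) -> float:
        """CDF of the dwell distribution at time ``t`` (closed form)."""
        from scipy.stats import norm

        return float(norm.cdf((np.log(t) - np.log(self.median_s)) / self.sigma_log))


@dataclass(frozen=True)
class AminoAcidSignalModel:
    """Blockade + dwell generative model for one analyte on one device.

    ``components`` is a list of ``(weight, mean, sd)`` tuples; a single
    component for most analytes, two for populations with a bimodal
    blockade histogram (attributed to distinct pore-entry orientations).
    ``blockade_units`` is ``"relative"`` (ΔI/I0) or ``"nA"`` (ΔI).
    ``charge_sign`` is the net charge sign of the analyte at the working
    pH; the driving trans-side bias must have the opposite sign.
    """

    label: str
    components: tuple[tuple[float, float, float], ...]
    blockade_units: str = "relative"
    dwell: DwellModel = field(default_factory=DwellModel)
    charge_sign: int = -1
    device_tag: str = ""

    def __post_init__(self) -> None:
        if self.blockade_units not in ("relative", "nA"):
            raise ValidationError(f"unknown blockade units: {self.blockade_units!r}")
        if self.charge_sign not in (-1, 1):
            raise ValidationError("charge_sign must be +1 or -1")
        if not self.components:
            raise ValidationError("model needs at least one component")
        w = sum(c[0] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValidationError(
                f"component weights must sum to 1 (got {w!r}) for {self.label}"
            )
        for _, mean, sd in self.components:
            if sd <= 0:
                raise ValidationError(f"nonpositive sd in model {self.label}")
            if mean <= 0:
                raise ValidationError(f"nonpositive mean in model {self.label}")

    @property
    def is_bimodal(self) -> bool:
        return len(self.components) > 1

    @property
    def mean(self) -> float:
        """Mixture mean of the blockade distribution."""
        return float(sum(w * m for w, m, _ in self.components))

    def sample_blockades(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return sample_blockades(self, n, rng)

    def sample_dwells(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return sample_dwells(self, n, rng)


def sample_blockades(
    model: AminoAcidSignalModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` blockade values from the model's Gaussian mixture.

    Relative blockades are rejection-sampled into (0, 1]; absolute (nA)
    blockades are rejection-sampled to be strictly positive.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    if n == 0:
        return np.empty(0)
    weights = np.array([c[0] for c in model.components])
    means = np.array([c[1] for c in model.components])
    sds = np.array([c[2] for c in model.components])
    upper = 1.0 if model.blockade_units == "relative" else np.inf

    out = np.empty(n)
    filled = 0
    while filled < n:
        need = n - filled
        comp = rng.choice(len(weights), size=need, p=weights)
        draw = rng.normal(means[comp], sds[comp])
        ok = draw[(draw > 0) & (draw <= upper)]
        out[filled : filled + ok.size] = ok
        filled += ok.size
    return out


def sample_dwells(
    model: AminoAcidSignalModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` dwell times (seconds) from the lognormal dwell model."""
    if n < 0:
        raise ValidationError("n must be >= 0")
    if n == 0:
        return np.empty(0)
    d = model.dwell
    return np.exp(rng.normal(np.log(d.median_s), d.sigma_log, size=n))


@dataclass(frozen=True)
class SignalLibrary:
    """Map from ``(label, device_tag)`` to :class:`AminoAcidSignalModel`."""

    entries: dict[tuple[str, str], AminoAcidSignalModel]

    def get(self, label: str, device: str) -> AminoAcidSignalModel:
        try:
            return self.entries[(label, device)]
        except KeyError:
            raise KeyError(
                f"no signal model for analyte {label!r} on {device!r}; "
                f"known keys: {sorted(self.entries)}"
            ) from None

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.entries

    def labels(self) -> list[tuple[str, str]]:
        return sorted(self.entries)

    def with_dwell(self, dwell: DwellModel) -> "SignalLibrary":
        """Return a copy of the library with every model's dwell replaced."""
        return SignalLibrary(
            {k: replace(m, dwell=dwell) for k, m in self.entries.items()}
        )

    def to_frame(self) -> pd.DataFrame:
        """Serialize to the canonical parameter-table layout (one row per
        mixture component)."""
        rows = []
        for (label, device), m in sorted(self.entries.items()):
            for w, mean, sd in m.components:
                rows.append(
                    {
                        "label": label,
                        "device": device,
                        "weight": w,
                        "mean": mean,
                        "sd": sd,
                        "units": m.blockade_units,
                        "charge_sign": m.charge_sign,
                    }
                )
        return pd.DataFrame(rows, columns=_TABLE_COLUMNS)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_signal_library(
    source: str | Path | io.IOBase | pd.DataFrame,
    dwell: DwellModel | None = None,
) -> SignalLibrary:
    """Parse a delimited parameter table into a :class:`SignalLibrary`.

    The table has one row per mixture component, with columns
    ``label, device, weight, mean, sd, units, charge_sign`` (header row;
    lines beginning ``#`` are comments).  Rows sharing ``(label, device)``
    become components of one mixture model, in file order.
    """
    if isinstance(source, pd.DataFrame):
        table = source.copy()
    else:
        try:
            table = _read_tsv(source)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise FormatError(f"cannot parse parameter table: {exc}") from exc
    missing = [c for c in _TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"parameter table missing columns: {missing}")
    if len(table) == 0:
        raise FormatError("parameter table is empty")

    dwell = dwell or DwellModel()
    entries: dict[tuple[str, str], AminoAcidSignalModel] = {}
    for (label, device), grp in table.groupby(["label", "device"], sort=False):
        comps = []
        seen: set[tuple[float, float]] = set()
        for _, row in grp.iterrows():
            key = (float(row["mean"]), float(row["sd"]))
            if key in seen:
                raise FormatError(
                    f"duplicate component {key} for ({label}, {device})"
                )
            seen.add(key)
            comps.append((float(row["weight"]), float(row["mean"]), float(row["sd"])))
        signs = set(int(s) for s in grp["charge_sign"])
        units = set(str(u) for u in grp["units"])
        if len(signs) > 1 or len(units) > 1:
            raise FormatError(
                f"inconsistent units/charge_sign for ({label}, {device})"
            )
        entries[(str(label), str(device))] = AminoAcidSignalModel(
            label=str(label),
            components=tuple(comps),
            blockade_units=units.pop(),
            dwell=dwell,
            charge_sign=signs.pop(),
            device_tag=str(device),
        )
    return SignalLibrary(entries)


def default_library(dwell: DwellModel | None = None) -> SignalLibrary:
    """The packaged library of published (analyte, device) populations."""
    ref = resources.files("porecall.data") / "signal_library.tsv"
    with resources.as_file(ref) as path:
        return load_signal_library(path, dwell=dwell)
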