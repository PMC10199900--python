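"""Population statistics of blockade features.

The discriminating feature of this measurement is the location of the
peak ("mean peak value") of the relative-blockade distribution of an
event population.  Unimodal populations are summarised by the mode of a
Gaussian-kernel density estimate (Silverman bandwidth by default, grid
argmax with parabolic refinement); bimodal populations by a
two-component Gaussian-mixture fit (EM, best of 10 restarts), because a
broad second component need not produce a second KDE mode.  Pairs of
populations are compared with a two-sample unequal-variance z-test, and
joint dwell/blockade structure with a 2-D histogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, norm
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "DensityFit",
    "ZTestResult",
    "BlockadeKDE",
    "BlockadeMixture",
    "kde_fit",
    "fit_gaussian_mixture",
    "two_sample_ztest",
    "bootstrap_mode_se",
    "dwell_blockade_heatmap",
]


@dataclass
class DensityFit:
    """A fitted 1-D density with located modes / components."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    modes: list[tuple[float, float]]  # (location, density), sorted by location
    method: str  # "kde_normal" | "gaussian_mixture"
    components: list[tuple[float, float, float]] | None = None  # (w, mean, sd)

    @property
    def mode(self) -> float:
        """Location of the highest-density mode (ties: lower location)."""
        best = max(self.modes, key=lambda m: (m[1], -m[0]))
        return best[0]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"grid": self.grid, "density": self.density}).to_csv(
            path, sep="\t", index=False
        )

    def summary(self) -> dict:
        return {
            "method": self.method,
            "bandwidth": self.bandwidth,
            "modes": [list(m) for m in self.modes],
            "components": None if self.components is None
            else [list(c) for c in self.components],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=1))


@dataclass(frozen=True)
class ZTestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int


def _parabolic_refine(grid: np.ndarray, density: np.ndarray, i: int) -> tuple[float, float]:
    """Refine a grid argmax by fitting a parabola through 3 points."""
    if i == 0 or i == len(grid) - 1:
        return float(grid[i]), float(density[i])
    y0, y1, y2 = density[i - 1], density[i], density[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(grid[i]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    h = grid[1] - grid[0]
    return float(grid[i] + delta * h), float(y1 - 0.25 * (y0 - y2) * delta)


class BlockadeKDE(BaseEstimator):
    """Gaussian-kernel density estimate with mode calling.

    Parameters
    ----------
    bandwidth : float or None
        Kernel SD in feature units; Silverman's rule when None.
    grid_size : int
        Number of evaluation points.
    min_rel_height : float
        Local maxima below this fraction of the global maximum are not
        reported as modes (suppresses tail wiggles).

    Fitted attributes: ``grid_``, ``density_``, ``bandwidth_``,
    ``modes_`` (sorted by location) and ``mode_`` (highest-density mode,
    parabolically refined).
    """

    def __init__(self, bandwidth: float | None = None, grid_size: int = 1024,
                 min_rel_height: float = 0.05):
        self.bandwidth = bandwidth
        self.grid_size = grid_size
        self.min_rel_height = min_rel_height

    def fit(self, X, y=None) -> "BlockadeKDE":
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 30:
            raise InsufficientDataError(
                f"KDE needs at least 30 values, got {x.size}"
            )
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValidationError("KDE input is constant")
        if self.bandwidth is not None:
            bw = float(self.bandwidth)
        else:
            # Silverman's rule of thumb for a Gaussian kernel
            iqr = np.subtract(*np.percentile(x, [75, 25]))
            spread = min(sd, iqr / 1.349) if iqr > 0 else sd
            bw = 0.9 * spread * x.size ** (-1 / 5)
        kde = gaussian_kde(x, bw_method=bw / sd)
        lo, hi = x.min() - 4 * bw, x.max() + 4 * bw
        grid = np.linspace(lo, hi, self.grid_size)
        dens = kde(grid)

        peaks = np.flatnonzero(
            (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
        ) + 1
        floor = self.min_rel_height * dens.max()
        modes = [_parabolic_refine(grid, dens, int(i))
                 for i in peaks if dens[i] >= floor]
        if not modes:  # monotone density: fall back to the grid argmax
            modes = [_parabolic_refine(grid, dens, int(np.argmax(dens)))]
        modes.sort(key=lambda m: m[0])

        self.grid_ = grid
        self.density_ = dens
        self.bandwidth_ = bw
        self.modes_ = modes
        self.mode_ = max(modes, key=lambda m: (m[1], -m[0]))[0]
        return self

    def to_density_fit(self) -> DensityFit:
        return DensityFit(self.grid_, self.density_, self.bandwidth_,
                          self.modes_, method="kde_normal")


class BlockadeMixture(BaseEstimator):
    """Gaussian-mixture fit (EM, multiple restarts) for bimodal
    blockade populations.

    Fitted attributes: ``weights_``, ``means_``, ``sds_`` (sorted by
    mean), ``components_`` as (weight, mean, sd) tuples, and ``bic_``.
    """

    def __init__(self, n_components: int = 2, n_init: int = 10,
                 random_state: int = 0):
        self.n_components = n_components
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None) -> "BlockadeMixture":
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 50:
            raise InsufficientDataError(
                f"mixture fit needs at least 50 values, got {x.size}"
            )
        gm = GaussianMixture(
            n_components=self.n_components,
            n_init=self.n_init,
            random_state=self.random_state,
            covariance_type="full",
        ).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        self.weights_ = gm.weights_[order]
        self.means_ = gm.means_.ravel()[order]
        self.sds_ = np.sqrt(gm.covariances_.ravel()[order])
        self.components_ = list(zip(self.weights_, self.means_, self.sds_))
        self.bic_ = float(gm.bic(x[:, None]))
        self._gm = gm
        self._x = x
        return self

    def to_density_fit(self, grid_size: int = 1024) -> DensityFit:
        lo = self.means_[0] - 4 * self.sds_[0]
        hi = self.means_[-1] + 4 * self.sds_[-1]
        grid = np.linspace(lo, hi, grid_size)
        dens = np.zeros_like(grid)
        for w, m, s in self.components_:
            dens += w * norm.pdf(grid, m, s)
        peaks = np.flatnonzero(
            (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
        ) + 1
        modes = [_parabolic_refine(grid, dens, int(i)) for i in peaks]
        if not modes:
            modes = [_parabolic_refine(grid, dens, int(np.argmax(dens)))]
        modes.sort(key=lambda m: m[0])
        return DensityFit(grid, dens, float(np.mean(self.sds_)), modes,
                          method="gaussian_mixture",
                          components=[tuple(map(float, c))
                                      for c in self.components_])


def kde_fit(values, bandwidth: float | None = None) -> DensityFit:
    """Gaussian-kernel KDE of a blockade sample (n >= 30)."""
    return BlockadeKDE(bandwidth=bandwidth).fit(values).to_density_fit()


def fit_gaussian_mixture(values, k: int = 2, random_state: int = 0) -> DensityFit:
    """EM mixture fit with ``k`` components, best of 10 restarts."""
    return BlockadeMixture(n_components=k, random_state=random_state).fit(
        values
    ).to_density_fit()


def bootstrap_mode_se(
    values, n_boot: int = 20, seed: int = 0, bandwidth: float | None = None
) -> float:
    """Bootstrap standard error of the KDE mode of a sample."""
    x = np.asarray(values, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    modes = []
    for _ in range(n_boot):
        xb = rng.choice(x, size=x.size, replace=True)
        modes.append(BlockadeKDE(bandwidth=bandwidth).fit(xb).mode_)
    return float(np.std(modes, ddof=1))


def two_sample_ztest(a, b) -> ZTestResult:
    """Two-sided unequal-variance (Welch) z-test on two blockade samples.

    z = (mean_a − mean_b) / sqrt(s_a²/n1 + s_b²/n2), p from N(0, 1).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 30 or b.size < 30:
        raise InsufficientDataError("z-test needs n >= 30 per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return ZTestResult(0.0, 1.0, a.size, b.size)
        raise ValidationError("both samples have zero variance")
    se = np.sqrt(va / a.size + vb / b.size)
    z = float((a.mean() - b.mean()) / se)
    p = float(2 * norm.sf(abs(z)))
    return ZTestResult(z, p, int(a.size), int(b.size))


def dwell_blockade_heatmap(
    events: pd.DataFrame,
    bins: int | tuple[int, int] = 30,
    blockade_column: str = "rel_blockade",
    log_dwell: bool = True,
):
    """2-D histogram of dwell time vs blockade.

    Returns (counts, dwell_edges, blockade_edges); counts sum to the
    number of events.  With ``log_dwell`` the dwell axis is binned in
    log10 seconds (edges returned in seconds).
    """
    if len(events) < 1:
        raise InsufficientDataError("heatmap needs at least one event")
    dwell = events["dwell_s"].to_numpy(dtype=float)
    blockade = events[blockade_column].to_numpy(dtype=float)
    d = np.log10(dwell) if log_dwell else dwell
    counts, d_edges, b_edges = np.histogram2d(d, blockade, bins=bins)
    if log_dwell:
        d_edges = 10.0 ** d_edges
    return counts, d_edges, b_edges
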