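"""Potential-of-mean-force estimation with GaMD cumulant-expansion reweighting.

Free-energy surfaces are built by histogramming collective-variable samples:
W(bin) = -kB*T*ln p(bin), anchored at the most probable bin and shifted so
the minimum over retained bins is zero. Bins below a count cutoff are
masked. Samples drawn under a GaMD boost dV >= 0 are reweighted back to the
canonical ensemble with the second-order cumulant expansion,

    ln <exp(beta*dV)>_bin  ~=  beta*c1 + beta^2*c2/2,

where c1 and c2 are the per-bin mean and variance of the boost. Entropy-like
higher-order terms are deliberately not included (they are dominated by
noise on realistic sample sizes).

Binning conventions: uniform widths per dimension (0.5 A for distances, 5
degrees for angles are the conventional choices), grid spanning
[floor(min), ceil(max)] in whole bin widths, 10-configuration cutoff for 2D
grids.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import DEFAULT_TEMPERATURE, KB

__all__ = ["PMFGrid", "BoostedSamples", "pmf_unbiased", "pmf_reweighted",
           "pmf_2d", "minima_and_barrier", "MinimaResult", "write_pmf_csv"]


@dataclass(frozen=True)
class PMFGrid:
    """Binned free-energy surface (kcal/mol), 1D or 2D.

    ``free_energy`` is NaN on masked (low-count) bins; the minimum over
    unmasked bins is exactly 0.
    """

    bin_edges: Tuple[np.ndarray, ...]
    free_energy: np.ndarray
    count: np.ndarray
    mask: np.ndarray  # True where the bin is masked out
    temperature: float

    def __post_init__(self) -> None:
        if self.dims not in (1, 2):
            raise ValueError("only 1D and 2D grids are supported")
        if not np.all(self.mask | np.isfinite(self.free_energy)):
            raise ValueError("unmasked bins must carry finite free energies")
        if np.any(~self.mask):
            m = np.nanmin(self.free_energy[~self.mask])
            if abs(m) > 1e-9:
                raise ValueError("unmasked minimum must be 0 after shifting")

    @property
    def dims(self) -> int:
        return len(self.bin_edges)

    @property
    def bin_centers(self) -> Tuple[np.ndarray, ...]:
        return tuple((e[:-1] + e[1:]) / 2.0 for e in self.bin_edges)


@dataclass(frozen=True)
class BoostedSamples:
    """CV samples with their per-frame GaMD boost potential (kcal/mol)."""

    cv: np.ndarray  # (n,) or (n, d)
    deltaV: np.ndarray  # (n,)
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        cv = np.asarray(self.cv, dtype=float)
        dv = np.asarray(self.deltaV, dtype=float)
        if dv.ndim != 1 or cv.shape[0] != dv.shape[0]:
            raise ValueError("cv and deltaV must have one entry per frame")
        if np.any(dv < 0):
            raise ValueError("boost potential must be >= 0")
        object.__setattr__(self, "cv", cv)
        object.__setattr__(self, "deltaV", dv)


def _edges(samples: np.ndarray, width: float) -> np.ndarray:
    lo = width * np.floor(samples.min() / width)
    hi = width * np.ceil(samples.max() / width)
    if hi <= lo:
        hi = lo + width
    n = int(round((hi - lo) / width))
    return lo + width * np.arange(n + 1)


def _pmf(samples: np.ndarray, bin_widths: Sequence[float], count_cutoff: int,
         temperature: float, deltaV: Optional[np.ndarray], order: int) -> PMFGrid:
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    n, d = samples.shape
    if n < 1:
        raise ValueError("need at least one sample")
    if len(bin_widths) != d:
        raise ValueError("one bin width per dimension required")
    if any(w <= 0 for w in bin_widths):
        raise ValueError("bin widths must be positive")
    if order not in (1, 2):
        raise ValueError("cumulant expansion order must be 1 or 2")

    edges = tuple(_edges(samples[:, j], bin_widths[j]) for j in range(d))
    shape = tuple(len(e) - 1 for e in edges)
    # flat bin index per sample (right edge inclusive in the last bin)
    flat = np.zeros(n, dtype=np.int64)
    for j in range(d):
        idx = np.clip(np.searchsorted(edges[j], samples[:, j], side="right") - 1,
                      0, shape[j] - 1)
        flat = flat * shape[j] + idx
    nbins = int(np.prod(shape))
    count = np.bincount(flat, minlength=nbins).astype(int)

    mask = count < max(count_cutoff, 1)
    if deltaV is not None:
        beta = 1.0 / (KB * temperature)
        # A constant offset in the boost cancels in the normalisation;
        # removing it up front keeps the constant-boost case exactly equal
        # to the unbiased estimator and conditions the exponentials.
        deltaV = deltaV - deltaV[0]
        s1 = np.bincount(flat, weights=deltaV, minlength=nbins)
        with np.errstate(invalid="ignore", divide="ignore"):
            c1 = s1 / count
        g = beta * c1
        if order == 2:
            s2 = np.bincount(flat, weights=deltaV**2, minlength=nbins)
            with np.errstate(invalid="ignore", divide="ignore"):
                # unbiased per-bin variance of the boost
                c2 = (s2 - count * c1**2) / np.maximum(count - 1, 1)
                c2 = np.maximum(c2, 0.0)
            g = g + 0.5 * beta**2 * c2
            mask = mask | (count < 2)
        # center the exponent so a constant boost contributes exactly zero
        g = np.where(count > 0, g, -np.inf)
        g_ref = np.max(g[count > 0])
        g = g - g_ref
    else:
        g = np.zeros(nbins)
    mask = mask | (count == 0)
    if np.all(mask):
        raise ValueError("all bins fall below the count cutoff")

    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(count > 0, np.log(count.astype(float)), -np.inf) + g
    kT = KB * temperature
    w = -kT * (logp - np.max(logp[~mask]))
    w = w - np.min(w[~mask])
    w = np.where(mask, np.nan, w)
    return PMFGrid(
        bin_edges=edges,
        free_energy=w.reshape(shape),
        count=count.reshape(shape),
        mask=mask.reshape(shape),
        temperature=temperature,
    )


def pmf_unbiased(samples: np.ndarray, bin_width: float = 0.5,
                 count_cutoff: int = 1,
                 temperature: float = DEFAULT_TEMPERATURE) -> PMFGrid:
    """1D PMF from canonical-ensemble samples: W = -kB*T*ln(count/count_max)."""
    return _pmf(np.asarray(samples), (bin_width,), count_cutoff, temperature,
                deltaV=None, order=2)


def pmf_reweighted(samples: BoostedSamples, bin_width: float = 0.5,
                   count_cutoff: int = 1, order: int = 2) -> PMFGrid:
    """1D PMF from GaMD-boosted samples via cumulant-expansion reweighting.

    With dV identically zero (or constant) this is bit-identical to
    :func:`pmf_unbiased`. Bins with fewer than two samples cannot estimate
    the boost variance at order 2 and are masked.
    """
    cv = samples.cv
    if cv.ndim == 2 and cv.shape[1] != 1:
        raise ValueError("use pmf_2d for two-dimensional CVs")
    return _pmf(cv.reshape(len(samples.deltaV)), (bin_width,), count_cutoff,
                samples.temperature, deltaV=samples.deltaV, order=order)


def pmf_2d(samples_x: np.ndarray, samples_y: np.ndarray,
           bin_widths: Tuple[float, float] = (0.5, 0.5),
           count_cutoff: int = 10, deltaV: Optional[np.ndarray] = None,
           temperature: float = DEFAULT_TEMPERATURE, order: int = 2) -> PMFGrid:
    """2D PMF from a pair of CV sample arrays, unbiased or GaMD-reweighted.

    Default 10-configuration count cutoff; bins with 9 samples are masked,
    bins with 10 retained.
    """
    x = np.asarray(samples_x, dtype=float)
    y = np.asarray(samples_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("samples_x and samples_y must be equal-length 1D arrays")
    if deltaV is not None:
        deltaV = np.asarray(deltaV, dtype=float)
        if deltaV.shape != x.shape:
            raise ValueError("deltaV must match the sample arrays")
        if np.any(deltaV < 0):
            raise ValueError("boost potential must be >= 0")
    return _pmf(np.column_stack([x, y]), bin_widths, count_cutoff, temperature,
                deltaV=deltaV, order=order)


@dataclass(frozen=True)
class MinimaResult:
    """Local minima of a PMF and the lowest barrier between the two deepest."""

    minima: Tuple[Tuple[Tuple[float, ...], float], ...]  # ((location), depth)
    barrier: Optional[float]  # kcal/mol above the deeper of the two minima


def _neighbors(idx: Tuple[int, ...], shape: Tuple[int, ...]):
    for ax in range(len(shape)):
        for step in (-1, 1):
            j = idx[ax] + step
            if 0 <= j < shape[ax]:
                yield idx[:ax] + (j,) + idx[ax + 1:]


def _bottleneck(W: np.ndarray, mask: np.ndarray, start, goals) -> Optional[Tuple[tuple, float]]:
    """Minimax path cost from start to the nearest of ``goals`` on the grid
    graph (Dijkstra on max-along-path free energy). Returns (goal, cost)."""
    shape = W.shape
    goals = set(goals)
    best = {start: float(W[start])}
    heap = [(float(W[start]), start)]
    while heap:
        cost, idx = heapq.heappop(heap)
        if cost > best.get(idx, np.inf):
            continue
        if idx in goals:
            return idx, cost
        for j in _neighbors(idx, shape):
            if mask[j]:
                continue
            c = max(cost, float(W[j]))
            if c < best.get(j, np.inf):
                best[j] = c
                heapq.heappush(heap, (c, j))
    return None


def minima_and_barrier(pmf: PMFGrid, min_prominence: float = 0.0) -> MinimaResult:
    """Find local minima and the bottleneck barrier between the two deepest.

    A bin is a local minimum when its free energy is strictly below every
    unmasked axis-neighbour. ``min_prominence`` (kcal/mol) prunes shallow
    statistical dimples: a minimum is kept only if every path to a deeper
    minimum must climb at least that much above it. The barrier is computed
    exactly on the grid graph as the minimax free energy over connecting
    paths minus the origin-minimum value (bottleneck shortest path).
    """
    W = pmf.free_energy
    mask = pmf.mask
    shape = W.shape
    centers = pmf.bin_centers
    minima: List[Tuple[Tuple[int, ...], float]] = []
    for idx in np.ndindex(*shape):
        if mask[idx]:
            continue
        w = W[idx]
        nb = [W[j] for j in _neighbors(idx, shape) if not mask[j]]
        if not nb or all(w < x for x in nb):
            minima.append((idx, float(w)))
    minima.sort(key=lambda t: t[1])
    if min_prominence > 0 and len(minima) > 1:
        kept = [minima[0]]
        for idx, depth in minima[1:]:
            deeper = {i for i, d in minima if d < depth and i != idx}
            hit = _bottleneck(W, mask, idx, deeper) if deeper else None
            if hit is None or hit[1] - depth >= min_prominence:
                kept.append((idx, depth))
        minima = kept
    located = tuple(
        (tuple(float(centers[ax][i]) for ax, i in enumerate(idx)), depth)
        for idx, depth in minima
    )
    if len(minima) < 2:
        return MinimaResult(minima=located, barrier=None)
    hit = _bottleneck(W, mask, minima[0][0], {minima[1][0]})
    barrier = None if hit is None else hit[1] - minima[0][1]
    return MinimaResult(minima=located, barrier=barrier)


def write_pmf_csv(pmf: PMFGrid, path) -> None:
    """Write the grid as CSV: bin centers, free energy, count, mask flag."""
    import pandas as pd

    centers = pmf.bin_centers
    rows = []
    for idx in np.ndindex(*pmf.free_energy.shape):
        row = {f"center_{ax}": centers[ax][i] for ax, i in enumerate(idx)}
        row["free_energy"] = pmf.free_energy[idx]
        row["count"] = int(pmf.count[idx])
        row["masked"] = bool(pmf.mask[idx])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def plot_pmf(pmf: PMFGrid, path, contour_interval: float = 0.5) -> None:
    """Optional contour/line rendering of the surface (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    if pmf.dims == 1:
        ax.plot(pmf.bin_centers[0], pmf.free_energy)
        ax.set_xlabel("CV")
        ax.set_ylabel("PMF (kcal/mol)")
    else:
        X, Y = np.meshgrid(*pmf.bin_centers, indexing="ij")
        Z = np.ma.masked_invalid(pmf.free_energy)
        levels = np.arange(0.0, np.nanmax(pmf.free_energy) + contour_interval,
                           contour_interval)
        cf = ax.contourf(X, Y, Z, levels=levels)
        ax.contour(X, Y, Z, levels=levels, colors="k", linewidths=0.5)
        fig.colorbar(cf, ax=ax, label="PMF (kcal/mol)")
    fig.savefig(path, dpi=150)
    plt.close(fig)
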