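"""Potential-of-mean-force surfaces and minimum-energy paths from CV series.

The PMF over a collective variable is estimated by histogramming the
sampled values and converting the normalized bin probabilities p to free
energies F = -kT ln(p / p_max) in kcal/mol, so the best-sampled bin sits at
exactly zero.  Empty bins are masked (infinite F) rather than imputed.

The minimum-energy path between two occupied bins is the 8-connected grid
path minimizing the maximum free energy encountered (the minimax/widest-path
criterion, the standard barrier estimate on a discretized surface); ties are
broken by path length and then lexicographically.  The barrier is the peak
free energy along the path above the starting bin.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from foldcv.constants import CALORIE, GAS_CONSTANT
from foldcv.errors import GridError

__all__ = [
    "PMFGrid",
    "MEPath",
    "thermal_energy",
    "build_pmf",
    "minimum_energy_path",
]


def thermal_energy(temperature: float) -> float:
    """Thermal energy kT at the given temperature, in kcal/mol.

    Computed as R*T via the molar gas constant; 300 K gives 0.596 kcal/mol.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return GAS_CONSTANT * temperature / (1000.0 * CALORIE)


@dataclass
class PMFGrid:
    """Binned free-energy surface (1D or 2D).

    ``prob`` sums to 1 over occupied bins; ``free_energy`` holds +inf in
    empty bins, with ``mask`` True there; the minimum over occupied bins is
    exactly 0.  ``edges`` has one bin-edge array per axis.
    """

    edges: tuple[np.ndarray, ...]
    prob: np.ndarray
    free_energy: np.ndarray
    mask: np.ndarray
    kT: float

    @property
    def ndim(self) -> int:
        return len(self.edges)

    def centers(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)

    def argmin(self) -> tuple[int, ...]:
        """Index of the occupied bin with the lowest free energy."""
        f = np.where(self.mask, np.inf, self.free_energy)
        return tuple(int(i) for i in np.unravel_index(np.argmin(f), f.shape))

    def plot(self, ax=None):
        """Quick-look plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.ndim == 1:
            ax.step(self.centers()[0], self.free_energy, where="mid")
            ax.set_ylabel("F / kcal mol$^{-1}$")
        else:
            f = np.ma.masked_where(self.mask, self.free_energy)
            x, y = self.edges
            pc = ax.pcolormesh(x, y, f.T)
            ax.figure.colorbar(pc, ax=ax, label="F / kcal mol$^{-1}$")
        return ax


def build_pmf(
    series_x,
    series_y=None,
    bins: int = 50,
    kT: float | None = None,
    range=None,
) -> PMFGrid:
    """Histogram CV samples into a PMF grid.

    ``series_y`` switches between a 1D and a 2D surface.  ``kT`` defaults to
    the 300 K thermal energy.  ``range`` follows the numpy histogram
    convention and is required when the data have zero spread.
    """
    x = np.asarray(series_x, dtype=float)
    if x.size == 0:
        raise GridError("empty CV series")
    if np.isnan(x).any():
        raise GridError("CV series contains NaN; drop or flag frames first")
    if kT is None:
        kT = thermal_energy(300.0)
    if kT <= 0:
        raise GridError("kT must be positive")
    if np.isscalar(bins) and bins < 2:
        raise GridError("need at least 2 bins")
    if series_y is None:
        if range is None and np.ptp(x) == 0.0:
            raise GridError("all values identical; pass an explicit range")
        counts, ex = np.histogram(x, bins=bins, range=range)
        edges: tuple[np.ndarray, ...] = (ex,)
    else:
        y = np.asarray(series_y, dtype=float)
        if y.shape != x.shape:
            raise GridError("series_x and series_y must have equal length")
        if np.isnan(y).any():
            raise GridError("CV series contains NaN; drop or flag frames first")
        if range is None and (np.ptp(x) == 0.0 or np.ptp(y) == 0.0):
            raise GridError("all values identical; pass an explicit range")
        counts, ex, ey = np.histogram2d(x, y, bins=bins, range=range)
        edges = (ex, ey)
    counts = counts.astype(float)
    prob = counts / counts.sum()
    mask = counts == 0
    f = np.full_like(prob, np.inf)
    occ = ~mask
    pmax = prob[occ].max()
    f[occ] = -kT * np.log(prob[occ] / pmax)
    return PMFGrid(edges=edges, prob=prob, free_energy=f, mask=mask, kT=kT)


@dataclass
class MEPath:
    """Minimum-energy path over a PMF grid."""

    path: list[tuple[int, ...]]
    f_along: np.ndarray
    barrier: float


def _as_2d_index(idx, shape2d) -> tuple[int, int]:
    if np.isscalar(idx):
        idx = (int(idx),)
    idx = tuple(int(i) for i in idx)
    if len(idx) == 1:
        idx = (idx[0], 0)
    if not (0 <= idx[0] < shape2d[0] and 0 <= idx[1] < shape2d[1]):
        raise GridError(f"bin index {idx} outside the grid")
    return idx


_NEIGHBORS = [
    (di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
]


def minimum_energy_path(grid: PMFGrid, start, end) -> MEPath:
    """Minimax path between two occupied bins (8-connected, mask-avoiding).

    Among all paths from ``start`` to ``end`` that avoid masked bins, finds
    one minimizing the maximum free energy along it; ties are broken by
    fewer steps, then lexicographically on the bin-index sequence.  The
    barrier is max(F on path) - F(start).
    """
    f2 = grid.free_energy if grid.free_energy.ndim == 2 else grid.free_energy[:, None]
    m2 = grid.mask if grid.mask.ndim == 2 else grid.mask[:, None]
    s = _as_2d_index(start, f2.shape)
    e = _as_2d_index(end, f2.shape)
    for name, idx in (("start", s), ("end", e)):
        if m2[idx]:
            raise GridError(f"{name} bin {idx} is empty")
    squeeze = grid.free_energy.ndim == 1

    def out_idx(ij: tuple[int, int]):
        return (ij[0],) if squeeze else ij

    if s == e:
        return MEPath(path=[], f_along=np.array([]), barrier=0.0)

    def neighbors(node):
        for di, dj in _NEIGHBORS:
            ni, nj = node[0] + di, node[1] + dj
            if 0 <= ni < f2.shape[0] and 0 <= nj < f2.shape[1] and not m2[ni, nj]:
                yield ni, nj

    # Phase 1: widest-path Dijkstra for the optimal minimax level.
    best_f: dict[tuple[int, int], float] = {s: float(f2[s])}
    heap: list[tuple[float, tuple[int, int]]] = [(float(f2[s]), s)]
    level = None
    while heap:
        maxf, node = heapq.heappop(heap)
        if node == e:
            level = maxf
            break
        if maxf > best_f.get(node, np.inf):
            continue
        for nb in neighbors(node):
            nf = max(maxf, float(f2[nb]))
            if nf < best_f.get(nb, np.inf):
                best_f[nb] = nf
                heapq.heappush(heap, (nf, nb))
    if level is None:
        raise GridError("no unmasked path connects start and end")

    # Phase 2: within bins at or below that level, the shortest path wins,
    # lexicographic order breaking remaining ties.
    def allowed(node):
        return f2[node] <= level

    pheap: list[tuple[int, tuple]] = [(1, (s,))]
    pbest: dict[tuple[int, int], tuple] = {s: (1, (s,))}
    while pheap:
        key = heapq.heappop(pheap)
        length, path = key
        node = path[-1]
        if node == e:
            f_along = np.array([f2[p] for p in path])
            return MEPath(
                path=[out_idx(p) for p in path],
                f_along=f_along,
                barrier=float(level - f2[s]),
            )
        if pbest.get(node, key) < key:
            continue
        for nb in neighbors(node):
            if not allowed(nb):
                continue
            nkey = (length + 1, path + (nb,))
            if nb in pbest and pbest[nb] <= nkey:
                continue
            pbest[nb] = nkey
            heapq.heappush(pheap, nkey)
    raise GridError("no unmasked path connects start and end")
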