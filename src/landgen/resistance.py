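"""Resistance surfaces and effective distances (least-cost and circuit theory).

Landscape layers are turned into per-cell cost (resistance) surfaces by
categorical or equal-interval continuous reclassification; effective
distances between sites are then computed either as the cumulative cost of
the single least-cost path (8-neighbour Dijkstra) or as the pairwise
effective resistance of the landscape graph (all paths, solved through the
graph Laplacian). A Mantel-based optimizer selects the categorical cost
ratio best supported by a genetic distance matrix.

Conventions: a move between adjacent cells costs the arithmetic mean of the
two cell values, scaled by sqrt(2) on diagonals; least-cost distances are
additionally scaled by the cell size, circuit resistances are not.
Continuous reclassification emits costs 1..n_classes — a zero cost would
break shortest-path positivity, and an additive offset changes least-cost
geometry only by a constant per step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from scipy.sparse.linalg import splu

from .io_formats import PairwiseMatrix, PointSet, RasterSurface

__all__ = [
    "CostSurface", "EffectiveDistanceResult", "reclassify_categorical",
    "reclassify_continuous", "buffer_streams", "aggregate",
    "least_cost_distance", "resistance_distance", "optimize_cost_ratio",
]

SQRT2 = math.sqrt(2.0)


@dataclass
class CostSurface:
    """Per-cell traversal cost; NaN cells are non-traversable."""

    grid: RasterSurface
    provenance: str = ""

    def __post_init__(self) -> None:
        v = self.grid.values
        if np.nanmin(v) <= 0:
            raise ValueError("all traversable cells must have positive cost")


@dataclass
class EffectiveDistanceResult:
    """Pairwise effective distances plus optional per-path / per-cell extras."""

    metric: str  # cumulative_cost | resistance
    matrix: PairwiseMatrix
    path_length: PairwiseMatrix | None = None
    current_map: RasterSurface | None = None
    snap_offsets: dict[str, float] = field(default_factory=dict)
    disconnected_pairs: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# reclassification
# ---------------------------------------------------------------------------

def reclassify_categorical(layer: RasterSurface, favored_classes,
                           cost_ratio: tuple[float, float] = (1, 2)) -> CostSurface:
    """Binary reclassification: favoured classes get the low cost, all other
    data cells the high cost. NODATA stays non-traversable."""
    low, high = cost_ratio
    if not low <= high:
        raise ValueError("cost_ratio must be (low, high) with low <= high")
    fav = set(np.atleast_1d(favored_classes).tolist())
    v = layer.values
    present = set(np.unique(v[~np.isnan(v)]).tolist())
    if not fav & present:
        warnings.warn("no favoured class present in layer; surface is uniform high cost")
    isfav = np.isin(v, list(fav))
    out = np.where(np.isnan(v), np.nan, np.where(isfav, float(low), float(high)))
    return CostSurface(layer.copy_with(out),
                       f"categorical {sorted(fav)} ratio {low}:{high}")


def reclassify_continuous(layer: RasterSurface, n_classes: int = 32,
                          invert: bool = False) -> CostSurface:
    """Equal-interval binning of the observed value range into ``n_classes``
    classes mapped linearly onto costs 1..n_classes. ``invert=True`` maps
    high raw values to low costs (e.g. minimum temperature)."""
    v = layer.values
    data = v[~np.isnan(v)]
    lo, hi = data.min(), data.max()
    if lo == hi:
        raise ValueError("cannot reclassify a constant layer")
    cls = np.floor((v - lo) / (hi - lo) * n_classes).astype(float)
    cls = np.clip(cls, 0, n_classes - 1)
    cost = (n_classes - cls) if invert else (cls + 1.0)
    cost = np.where(np.isnan(v), np.nan, cost)
    return CostSurface(layer.copy_with(cost),
                       f"continuous {n_classes} classes invert={invert}")


def buffer_streams(stream_mask: RasterSurface, buffer_dist: float) -> RasterSurface:
    """Morphological dilation of a binary stream raster by Euclidean distance
    ``buffer_dist`` (same length units as the cell size), distances measured
    between cell centers."""
    v = stream_mask.values
    mask = np.nan_to_num(v, nan=0.0) > 0
    if not mask.any():
        raise ValueError("empty stream mask")
    dist = ndimage.distance_transform_edt(~mask,
                                          sampling=stream_mask.cell_size)
    out = (dist <= buffer_dist + 1e-9).astype(float)
    return stream_mask.copy_with(out)


def aggregate(layer: RasterSurface, factor: int) -> RasterSurface:
    """Block-mean aggregation by an integer factor (NODATA-aware); output
    dimensions are ceil-divided and the cell size multiplied."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor > max(layer.n_rows, layer.n_cols):
        raise ValueError("aggregation factor larger than the grid")
    if factor == 1:
        return layer.copy_with(layer.values.copy())
    r = math.ceil(layer.n_rows / factor)
    c = math.ceil(layer.n_cols / factor)
    padded = np.full((r * factor, c * factor), np.nan)
    padded[: layer.n_rows, : layer.n_cols] = layer.values
    blocks = padded.reshape(r, factor, c, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        out = np.nanmean(blocks, axis=(1, 3))
    return RasterSurface(out, layer.cell_size * factor, layer.origin, layer.nodata)


# ---------------------------------------------------------------------------
# landscape graph
# ---------------------------------------------------------------------------

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _grid_edges(values: np.ndarray):
    """8-neighbour edges among finite cells: (i_idx, j_idx, mean_cost, diag)."""
    nr, nc = values.shape
    finite = np.isfinite(values)
    node_id = np.full((nr, nc), -1, dtype=np.int64)
    node_id[finite] = np.arange(finite.sum())
    ii, jj, mc, dg = [], [], [], []
    for dr, dc in [(-1, -1), (-1, 0), (-1, 1), (0, 1)]:  # upper half; graph undirected
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        a = node_id[r0:r1, c0:c1]
        b = node_id[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        va = values[r0:r1, c0:c1]
        vb = values[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = (a >= 0) & (b >= 0)
        ii.append(a[ok])
        jj.append(b[ok])
        mc.append(0.5 * (va[ok] + vb[ok]))
        dg.append(np.full(ok.sum(), dr != 0 and dc != 0))
    return (np.concatenate(ii), np.concatenate(jj), np.concatenate(mc),
            np.concatenate(dg), node_id)


def _snap_points(cs: CostSurface, pts: PointSet):
    """Map points to the nearest traversable cell; returns node ids, (row,col)
    per point and the snap offset per label (in map units)."""
    grid = cs.grid
    finite = np.isfinite(grid.values)
    rows, cols = np.nonzero(finite)
    centers = np.stack([np.array([grid.cell_center(r, c) for r, c in zip(rows, cols)])])[0]
    node_of: dict[str, tuple[int, int]] = {}
    offsets: dict[str, float] = {}
    for lab, (x, y) in zip(pts.labels, pts.coordinates):
        d2 = (centers[:, 0] - x) ** 2 + (centers[:, 1] - y) ** 2
        k = int(np.argmin(d2))
        node_of[lab] = (int(rows[k]), int(cols[k]))
        offsets[lab] = float(math.sqrt(d2[k]))
    return node_of, offsets


def least_cost_distance(cs: CostSurface, pts: PointSet) -> EffectiveDistanceResult:
    """Cumulative cost of the least-cost path between every site pair.

    A move between adjacent cells costs mean(cost_a, cost_b) * cell_size,
    times sqrt(2) for diagonal moves. Also returns the geometric length of
    each optimal path (steps * step length). Disconnected pairs get infinite
    distance and are flagged.
    """
    grid = cs.grid
    ii, jj, mc, dg, node_id = _grid_edges(grid.values)
    step = grid.cell_size * np.where(dg, SQRT2, 1.0)
    w = mc * step
    n_nodes = int(node_id.max()) + 1
    W = sparse.csr_matrix(
        (np.concatenate([w, w]),
         (np.concatenate([ii, jj]), np.concatenate([jj, ii]))),
        shape=(n_nodes, n_nodes))
    Ln = sparse.csr_matrix(
        (np.concatenate([step, step]),
         (np.concatenate([ii, jj]), np.concatenate([jj, ii]))),
        shape=(n_nodes, n_nodes))

    node_of, offsets = _snap_points(cs, pts)
    focal = np.array([node_id[node_of[lab]] for lab in pts.labels])
    dist, pred = dijkstra(W, indices=focal, return_predecessors=True)

    n = pts.n
    C = np.zeros((n, n))
    Plen = np.zeros((n, n))
    disconnected = []
    for a in range(n):
        for b in range(a + 1, n):
            d = dist[a, focal[b]]
            if not np.isfinite(d):
                disconnected.append((pts.labels[a], pts.labels[b]))
                C[a, b] = C[b, a] = np.inf
                Plen[a, b] = Plen[b, a] = np.inf
                continue
            C[a, b] = C[b, a] = d
            # walk predecessors to accumulate geometric length
            length = 0.0
            v = focal[b]
            while v != focal[a]:
                u = pred[a, v]
                length += Ln[u, v]
                v = u
            Plen[a, b] = Plen[b, a] = length
    return EffectiveDistanceResult(
        "cumulative_cost", PairwiseMatrix(list(pts.labels), C),
        path_length=PairwiseMatrix(list(pts.labels), Plen),
        snap_offsets=offsets, disconnected_pairs=disconnected)


def _laplacian(values: np.ndarray):
    """Sparse Laplacian of the landscape graph with edge conductance
    1 / (mean cell resistance), diagonals divided by sqrt(2)."""
    ii, jj, mc, dg, node_id = _grid_edges(values)
    cond = 1.0 / (mc * np.where(dg, SQRT2, 1.0))
    n = int(node_id.max()) + 1
    A = sparse.coo_matrix(
        (np.concatenate([cond, cond]),
         (np.concatenate([ii, jj]), np.concatenate([jj, ii]))),
        shape=(n, n)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    L = sparse.diags(deg) - A
    return L.tocsc(), node_id, (ii, jj, cond)


def resistance_distance(cs: CostSurface, pts: PointSet,
                        current_map: bool = False) -> EffectiveDistanceResult:
    """Pairwise effective resistance between sites on the landscape graph.

    Cell values are per-cell resistances; neighbouring cells are joined by a
    conductance 1/mean(r_a, r_b) (divided by sqrt(2) on diagonals). One focal
    node is grounded and the reduced Laplacian system solved once per focal
    node; R(s, t) = G_ss + G_tt - 2 G_st. Optionally accumulates a per-cell
    current map summed over all focal pairs (unit current injected per pair).
    """
    grid = cs.grid
    L, node_id, (ei, ej, cond) = _laplacian(grid.values)
    node_of, offsets = _snap_points(cs, pts)
    focal = np.array([node_id[node_of[lab]] for lab in pts.labels])
    n_nodes = L.shape[0]

    # connected-component check via one Dijkstra-free pass
    n_comp, comp = sparse.csgraph.connected_components(
        sparse.csr_matrix((cond, (ei, ej)), shape=(n_nodes, n_nodes)),
        directed=False)
    ground = int(focal[0])
    # solve only within the ground's component; pairs spanning components
    # are flagged as disconnected
    keep = (comp == comp[ground])
    keep[ground] = False
    reduced = L[keep][:, keep]
    reindex = np.cumsum(keep) - 1  # old id -> reduced id

    lu = None
    G = np.zeros((pts.n, n_nodes))  # grounded-inverse columns for focal sources
    solvable = comp[focal] == comp[ground]
    if solvable.any() and keep.any():
        lu = splu(reduced.tocsc())
    for a in range(pts.n):
        if focal[a] == ground or not solvable[a]:
            continue
        e = np.zeros(int(keep.sum()))
        e[reindex[focal[a]]] = 1.0
        x = lu.solve(e)
        full = np.zeros(n_nodes)
        full[keep] = x
        G[a] = full

    n = pts.n
    R = np.zeros((n, n))
    disconnected = []
    for a in range(n):
        for b in range(a + 1, n):
            if comp[focal[a]] != comp[focal[b]]:
                R[a, b] = R[b, a] = np.inf
                disconnected.append((pts.labels[a], pts.labels[b]))
                continue
            fa, fb = focal[a], focal[b]
            if fa == fb:
                continue
            if fa == ground:
                r = G[b, fb]
            elif fb == ground:
                r = G[a, fa]
            else:
                r = G[a, fa] + G[b, fb] - G[a, fb] - G[b, fa]
            R[a, b] = R[b, a] = r

    cmap = None
    if current_map:
        acc = np.zeros(n_nodes)
        for a in range(n):
            for b in range(a + 1, n):
                if comp[focal[a]] != comp[focal[b]] or focal[a] == focal[b]:
                    continue
                phi = G[a] - G[b]  # potentials for unit current a -> b (grounded)
                i_edge = cond * (phi[ei] - phi[ej])
                np.add.at(acc, ei, np.abs(i_edge) / 2.0)
                np.add.at(acc, ej, np.abs(i_edge) / 2.0)
        vals = np.full(grid.values.shape, np.nan)
        vals[np.isfinite(grid.values)] = acc
        cmap = grid.copy_with(vals)

    return EffectiveDistanceResult(
        "resistance", PairwiseMatrix(list(pts.labels), R),
        current_map=cmap, snap_offsets=offsets, disconnected_pairs=disconnected)


# ---------------------------------------------------------------------------
# cost-ratio optimization
# ---------------------------------------------------------------------------

def optimize_cost_ratio(layer: RasterSurface, favored_classes, ratios,
                        genetic: PairwiseMatrix, pts: PointSet,
                        n_perm: int = 10000, seed: int | None = None,
                        metric: str = "cumulative_cost"):
    """Mantel-r selection of the categorical cost ratio.

    For each (low, high) ratio the chosen effective distance is computed and
    correlated with the genetic matrix by a Mantel test; returns
    (best_ratio, table) where the table lists r and p per ratio.
    """
    from .matrix_models import mantel_test

    ratios = list(ratios)
    if not ratios:
        raise ValueError("no ratios supplied")
    rows = []
    rng = np.random.default_rng(seed)
    for low, high in ratios:
        if not low < high:
            raise ValueError(f"ratio {low}:{high} violates low < high")
        cs = reclassify_categorical(layer, favored_classes, (low, high))
        if metric == "cumulative_cost":
            eff = least_cost_distance(cs, pts)
        elif metric == "resistance":
            eff = resistance_distance(cs, pts)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        r, p = mantel_test(eff.matrix.reorder(genetic.labels), genetic,
                           n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
        rows.append({"low": low, "high": high, "mantel_r": r, "p": p})
    table = pd.DataFrame(rows)
    best = ratios[int(table["mantel_r"].idxmax())]
    return best, table
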