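"""Topological filtering (OMST), multilayer assembly, and network metrics.

Orthogonal minimal spanning trees (OMST) filter a dense weighted graph by
extracting successive edge-disjoint MSTs (on distances d = 1/w) and
keeping the aggregate that maximizes the quality function

    J = GE - Cost

where GE is the weighted global efficiency of the aggregate and Cost is
the fraction of total connection weight retained. The multilayer
participation coefficient (MPC) then quantifies, per node, how evenly its
retained connections spread across the coupling-mode layers:

    MPC_i = M/(M-1) * (1 - sum_layers (k_i[layer] / o_i)^2)

with M layers, binary degrees k and total degree o_i; 0 means all
connections in one layer, 1 means a perfectly even spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components, dijkstra

from .bands import coupling_modes
from .connectivity import SLFCG

#: Stop OMST extraction after this many consecutive declines of J.
OMST_PATIENCE = 5


# --------------------------------------------------------------------------
# global efficiency
# --------------------------------------------------------------------------


def global_efficiency(W: np.ndarray) -> float:
    """Weighted global efficiency: mean over ordered node pairs of the
    inverse shortest-path length on distances 1/w.

    Unreachable pairs contribute 0; a graph with < 2 nodes has GE 0.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        D = np.where(W > 0, 1.0 / W, 0.0)
    dist = dijkstra(csr_array(D), directed=False)
    np.fill_diagonal(dist, np.inf)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist), 1.0 / dist, 0.0)
    return float(inv.sum() / (n * (n - 1)))


# --------------------------------------------------------------------------
# OMST
# --------------------------------------------------------------------------


@dataclass
class OMSTResult:
    """Outcome of OMST filtering.

    ``selected_edges`` holds each round's (i, j) edge set (pairwise
    disjoint); ``J_curve`` the per-round (J, Cost) pairs for the
    aggregates of rounds 1..r; ``peak_round`` the 1-based round count
    maximizing J (first maximum on ties); ``W_filtered`` the input
    weights restricted to the edges of rounds 1..peak_round.
    """

    selected_edges: list[list[tuple[int, int]]]
    J_curve: list[tuple[float, float]]
    peak_round: int
    W_filtered: np.ndarray


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _check_connected(W: np.ndarray) -> None:
    n_comp, labels = connected_components(csr_array((W > 0).astype(float)), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"graph is disconnected ({n_comp} components, sizes {sizes.tolist()}); "
            "OMST requires a connected positive-weight graph"
        )


def _mst_edges(order: np.ndarray, ii: np.ndarray, jj: np.ndarray,
               available: np.ndarray, n: int) -> list[int] | None:
    """Kruskal over the available edges in the fixed deterministic order;
    returns edge indices of a spanning tree, or None if disconnected."""
    uf = _UnionFind(n)
    tree: list[int] = []
    for k in order:
        if not available[k]:
            continue
        if uf.union(int(ii[k]), int(jj[k])):
            tree.append(int(k))
            if len(tree) == n - 1:
                return tree
    return None


def omst_filter(W: np.ndarray, patience: int = OMST_PATIENCE) -> OMSTResult:
    """Filter a connected weighted graph by orthogonal MST rounds.

    Round r extracts the MST (distance 1/w; ties broken by lowest node
    index) of the graph restricted to edges not selected in earlier
    rounds. After each round, J = GE - Cost is evaluated on the aggregate
    of all rounds so far, with Cost the selected-weight fraction of the
    total weight. Extraction stops when the remaining edges no longer
    span the graph or when J has declined ``patience`` rounds in a row;
    the aggregate at the (first) argmax of J is returned.
    """
    W = np.asarray(W, dtype=float)
    if (W < 0).any():
        raise ValueError("weights must be non-negative")
    _check_connected(W)
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    pos = W[iu, ju] > 0
    ii, jj, ww = iu[pos], ju[pos], W[iu, ju][pos]
    total_weight = ww.sum()
    order = np.lexsort((jj, ii, 1.0 / ww))  # distance, then min node indices

    available = np.ones(ww.size, dtype=bool)
    rounds: list[list[tuple[int, int]]] = []
    J_curve: list[tuple[float, float]] = []
    agg = np.zeros_like(W)
    cost = 0.0
    declines = 0
    while True:
        tree = _mst_edges(order, ii, jj, available, n)
        if tree is None:
            break
        rounds.append([(int(ii[k]), int(jj[k])) for k in tree])
        for k in tree:
            available[k] = False
            agg[ii[k], jj[k]] = agg[jj[k], ii[k]] = W[ii[k], jj[k]]
        cost += ww[tree].sum() / total_weight
        J = global_efficiency(agg) - cost
        J_curve.append((float(J), float(cost)))
        if len(J_curve) > 1 and J < J_curve[-2][0]:
            declines += 1
            if declines >= patience:
                break
        else:
            declines = 0

    peak = int(np.argmax([j for j, _ in J_curve])) + 1
    W_filtered = np.zeros_like(W)
    for r in range(peak):
        for i, j in rounds[r]:
            W_filtered[i, j] = W_filtered[j, i] = W[i, j]
    return OMSTResult(
        selected_edges=rounds, J_curve=J_curve, peak_round=peak, W_filtered=W_filtered
    )


# --------------------------------------------------------------------------
# multilayer assembly
# --------------------------------------------------------------------------


@dataclass
class MLFCG:
    """The multilayer graph: the ordered 28 single-layer graphs plus a
    flattened (B*N) x (B*N) view with intra graphs on the diagonal
    blocks and the CFC graph of band pair (i, j) in off-diagonal block
    (i, j), mirrored (transposed) in (j, i)."""

    layers: list[SLFCG]
    flattened: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        modes = [g.mode for g in self.layers]
        bands = tuple(m.bands[0] for m in modes if m.kind == "intra")
        if any(b2.lo <= b1.lo for b1, b2 in zip(bands, bands[1:])):
            raise ValueError(
                "layers must be the full fixed-order mode set: intra layers "
                "must appear first in ascending band order"
            )
        expected = coupling_modes(bands)
        if len(bands) < 2 or modes != expected:
            raise ValueError(
                "layers must be the full fixed-order mode set "
                "(intra per band, then cross pairs in band order)"
            )
        n = self.layers[0].n_rois
        if any(g.n_rois != n for g in self.layers):
            raise ValueError("inconsistent ROI count across layers")
        B = len(bands)
        flat = np.zeros((B * n, B * n))
        by_mode = {g.mode.label: g.W for g in self.layers}
        for bi in range(B):
            flat[bi * n:(bi + 1) * n, bi * n:(bi + 1) * n] = by_mode[bands[bi].name]
            for bj in range(bi + 1, B):
                Wc = by_mode[f"{bands[bi].name}:{bands[bj].name}"]
                flat[bi * n:(bi + 1) * n, bj * n:(bj + 1) * n] = Wc
                flat[bj * n:(bj + 1) * n, bi * n:(bi + 1) * n] = Wc.T
        self.flattened = flat
        self._bands = bands
        self._n = n

    @property
    def n_rois(self) -> int:
        return self._n

    @property
    def n_bands(self) -> int:
        return len(self._bands)

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self._bands)


def assemble_mlfcg(slfcgs: Sequence[SLFCG]) -> MLFCG:
    """Assemble the ordered single-layer graphs into a multilayer graph."""
    return MLFCG(layers=list(slfcgs))


# --------------------------------------------------------------------------
# multilayer participation coefficient
# --------------------------------------------------------------------------


@dataclass
class MPCResult:
    per_node: np.ndarray  # MPC_i in [0, 1] per ROI
    global_mpc: float  # arithmetic mean of per_node


def mpc(layer_matrices: Sequence[np.ndarray], weighted: bool = False) -> MPCResult:
    """Multilayer participation coefficient from (filtered) layer matrices.

    By default uses binary degrees (count of retained edges per node per
    layer); ``weighted=True`` substitutes nodal strengths. A node with no
    retained connections in any layer gets MPC 0.
    """
    A = np.stack([np.asarray(L, dtype=float) for L in layer_matrices])  # M x N x N
    M = A.shape[0]
    if M < 2:
        raise ValueError("MPC needs at least 2 layers")
    dense = [m for m in range(M) if np.all(A[m][~np.eye(A.shape[1], dtype=bool)] > 0)]
    if dense:
        warnings.warn(
            f"{len(dense)} layer(s) are fully dense; MPC is intended for "
            "topologically filtered layers",
            stacklevel=2,
        )
    k = (A > 0).sum(axis=2).astype(float) if not weighted else A.sum(axis=2)  # M x N
    o = k.sum(axis=0)
    per_node = np.zeros(A.shape[1])
    active = o > 0
    frac = k[:, active] / o[active]
    per_node[active] = M / (M - 1) * (1.0 - (frac**2).sum(axis=0))
    return MPCResult(per_node=per_node, global_mpc=float(per_node.mean()))


# --------------------------------------------------------------------------
# comodulograms
# --------------------------------------------------------------------------


@dataclass
class Comodulogram:
    """Probability distribution of retained multilayer edges over the
    B x B band-pair table (diagonal = intra layers, upper off-diagonal =
    CFC layers); entries sum to 1."""

    PD: np.ndarray
    band_names: tuple[str, ...]


def comodulogram(
    omst_ml: OMSTResult | np.ndarray, n_rois: int, band_names: Sequence[str]
) -> Comodulogram:
    """Tabulate the fraction of OMST-retained flattened-multilayer edges
    falling in each coupling-mode layer.

    ``omst_ml`` is the OMST result of (or any filtered adjacency for) the
    flattened multilayer graph with ``len(band_names)`` band blocks of
    side ``n_rois``.
    """
    Wf = omst_ml.W_filtered if isinstance(omst_ml, OMSTResult) else np.asarray(omst_ml)
    B = len(band_names)
    if Wf.shape[0] != B * n_rois:
        raise ValueError(f"matrix side {Wf.shape[0]} != n_bands*n_rois = {B * n_rois}")
    iu, ju = np.nonzero(np.triu(Wf, k=1))
    if iu.size == 0:
        raise ValueError("no selected edges; comodulogram undefined")
    PD = np.zeros((B, B))
    bi, bj = iu // n_rois, ju // n_rois
    lo, hi = np.minimum(bi, bj), np.maximum(bi, bj)
    np.add.at(PD, (lo, hi), 1.0)
    PD /= PD.sum()
    return Comodulogram(PD=PD, band_names=tuple(band_names))


def group_average_comodulogram(tables: Sequence[Comodulogram]) -> Comodulogram:
    """Element-wise mean of subject comodulograms."""
    if not tables:
        raise ValueError("no comodulograms to average")
    names = tables[0].band_names
    if any(t.band_names != names for t in tables):
        raise ValueError("band layouts differ across subjects")
    return Comodulogram(PD=np.mean([t.PD for t in tables], axis=0), band_names=names)
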