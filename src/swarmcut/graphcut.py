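"""6-connected 3D graph construction and min-cut/max-flow segmentation.

The segmentation energy is

    E(labels) = sum_u D_u(label_u) + lambda * sum_{(u,v) in N6} B_uv * K_uv * [label_u != label_v]

with data costs D_u = -log Pr(x_u | label), Gaussian intensity affinity
K_uv = exp(-(I_u - I_v)^2 / (2 sigma^2)), and the swarm factor B_uv = 1 - tau_uv
from the ant-colony boundary-confidence field (B = 1 when the swarm stage is
disabled, which reduces the model to the classic seeded graph cut). Seeds and
quadrant-excluded voxels are hard-constrained through large finite terminal
weights. The pairwise energy is submodular, so the s-t min cut (solved with
igraph's max-flow) is the global optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph
import numpy as np

from .likelihood import LikelihoodField, data_cost
from .volume import CTVolume, SeedSet, SegmentationMask

__all__ = [
    "EnergyParams",
    "GraphSpec",
    "gaussian_affinity",
    "modulated_affinity",
    "build_graph",
    "solve_min_cut",
    "cut_energy",
    "segment_volume",
]


@dataclass(frozen=True)
class EnergyParams:
    """Energy weights: smoothness lambda, Gaussian scale sigma (HU)."""

    lam: float = 0.15
    sigma: float = 10.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class GraphSpec:
    """Explicit edge arrays of the s-t graph over a voxel grid.

    ``edges_u``/``edges_v`` are flat voxel indices of the 6-neighbour pairs
    with symmetric capacity ``n_weights``; ``source_cap``/``sink_cap`` are the
    per-voxel terminal capacities. ``hard_mask`` marks voxels whose terminal
    links are hard constraints (their data terms are excluded from energies).
    """

    shape: tuple[int, int, int]
    edges_u: np.ndarray
    edges_v: np.ndarray
    n_weights: np.ndarray
    source_cap: np.ndarray  # cut => voxel joins the background side
    sink_cap: np.ndarray
    hard_mask: np.ndarray
    cost_object: np.ndarray
    cost_background: np.ndarray


def gaussian_affinity(i_u, i_v, sigma: float):
    """Gaussian intensity affinity K = exp(-(I_u - I_v)^2 / (2 sigma^2)) in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = np.asarray(i_u, dtype=np.float64) - np.asarray(i_v, dtype=np.float64)
    out = np.exp(-(d * d) / (2.0 * sigma * sigma))
    return out if out.ndim else float(out)


def modulated_affinity(k, b):
    """Swarm-modulated boundary term K' = B * K."""
    return np.asarray(b, dtype=np.float64) * np.asarray(k, dtype=np.float64)


def _neighbor_pairs(shape: tuple[int, int, int]):
    """Flat-index (u, v, axis) arrays for all 6-neighbour pairs of a grid."""
    nz, nr, nc = shape
    flat = np.arange(nz * nr * nc, dtype=np.int64).reshape(shape)
    pairs = []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        u = flat[tuple(sl_a)].ravel()
        v = flat[tuple(sl_b)].ravel()
        pairs.append((u, v, np.full(u.shape, axis, dtype=np.int8)))
    return (
        np.concatenate([p[0] for p in pairs]),
        np.concatenate([p[1] for p in pairs]),
        np.concatenate([p[2] for p in pairs]),
    )


def _edge_boundary_factor(tau_volume: np.ndarray | None, eu, ev, axes) -> np.ndarray:
    """Per-edge B = 1 - tau_uv; in-slice edges use max(tau), inter-slice the mean."""
    if tau_volume is None:
        return np.ones(eu.shape, dtype=np.float64)
    t = tau_volume.ravel()
    tau_edge = np.where(axes == 0, 0.5 * (t[eu] + t[ev]), np.maximum(t[eu], t[ev]))
    return 1.0 - tau_edge


def build_graph(
    volume: CTVolume,
    likelihoods: LikelihoodField,
    seeds: SeedSet,
    params: EnergyParams = EnergyParams(),
    tau_volume: np.ndarray | None = None,
    exclusion: np.ndarray | None = None,
    eps_floor: float = 1e-6,
) -> GraphSpec:
    """Assemble n-link and t-link capacities for the modulated energy.

    Terminal convention: the source represents the object class, so the
    source-side capacity of voxel u is D_u(background) (cutting it assigns u
    to background) and the sink-side capacity is D_u(object). Object seeds get
    a hard source link; background seeds and excluded voxels a hard sink link.
    """
    shape = volume.shape
    if np.any(seeds.object_mask & (exclusion if exclusion is not None else False)):
        raise ValueError("object seeds conflict with the exclusion mask")

    inten = volume.intensities.ravel().astype(np.float64)
    eu, ev, axes = _neighbor_pairs(shape)
    k = gaussian_affinity(inten[eu], inten[ev], params.sigma)
    b = _edge_boundary_factor(tau_volume, eu, ev, axes)
    n_weights = params.lam * modulated_affinity(k, b)

    cost_obj = data_cost(likelihoods.pr_object, eps_floor).ravel()
    cost_bkg = data_cost(likelihoods.pr_background, eps_floor).ravel()
    source_cap = cost_bkg.copy()
    sink_cap = cost_obj.copy()

    hard = 10.0 * (max(cost_obj.max(), cost_bkg.max()) + params.lam * 6.0 * float(n_weights.max(initial=0.0)) + 1.0)
    obj_seed = seeds.object_mask.ravel()
    bkg_like = seeds.background_mask.ravel().copy()
    if exclusion is not None:
        bkg_like |= np.asarray(exclusion, dtype=bool).ravel()
    source_cap[obj_seed] = hard
    sink_cap[obj_seed] = 0.0
    source_cap[bkg_like] = 0.0
    sink_cap[bkg_like] = hard

    return GraphSpec(
        shape=shape,
        edges_u=eu,
        edges_v=ev,
        n_weights=n_weights,
        source_cap=source_cap,
        sink_cap=sink_cap,
        hard_mask=obj_seed | bkg_like,
        cost_object=cost_obj,
        cost_background=cost_bkg,
    )


def solve_min_cut(graph: GraphSpec, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> tuple[SegmentationMask, float]:
    """Globally optimal labelling via s-t max-flow; returns (mask, flow value)."""
    n_px = int(np.prod(graph.shape))
    source, sink = n_px, n_px + 1

    keep_n = graph.n_weights > 0
    keep_s = graph.source_cap > 0
    keep_t = graph.sink_cap > 0
    edges = np.concatenate(
        [
            np.column_stack([graph.edges_u[keep_n], graph.edges_v[keep_n]]),
            np.column_stack([np.full(keep_s.sum(), source), np.nonzero(keep_s)[0]]),
            np.column_stack([np.nonzero(keep_t)[0], np.full(keep_t.sum(), sink)]),
        ]
    )
    caps = np.concatenate([graph.n_weights[keep_n], graph.source_cap[keep_s], graph.sink_cap[keep_t]])

    g = igraph.Graph(n_px + 2, edges.tolist(), directed=False)
    cut = g.st_mincut(source, sink, capacity=caps.tolist())
    labels = np.zeros(n_px, dtype=bool)
    side0 = np.asarray(cut.partition[0])
    if source in cut.partition[0]:
        labels[side0[side0 < n_px]] = True
    else:
        side1 = np.asarray(cut.partition[1])
        labels[side1[side1 < n_px]] = True
    mask = SegmentationMask(labels.reshape(graph.shape), spacing, origin)
    return mask, float(cut.value)


def cut_energy(labels: np.ndarray, graph: GraphSpec) -> float:
    """Energy of a labelling: data terms (hard-constrained voxels excluded) + smoothness."""
    lab = np.asarray(labels, dtype=bool).ravel()
    if lab.size != int(np.prod(graph.shape)):
        raise ValueError("labelling not congruent with the graph")
    free = ~graph.hard_mask
    data = np.where(lab, graph.cost_object, graph.cost_background)[free].sum()
    boundary = graph.n_weights[lab[graph.edges_u] != lab[graph.edges_v]].sum()
    return float(data + boundary)


def segment_volume(
    volume: CTVolume,
    likelihoods: LikelihoodField,
    seeds: SeedSet,
    params: EnergyParams = EnergyParams(),
    tau_volume: np.ndarray | None = None,
    exclusion: np.ndarray | None = None,
) -> tuple[SegmentationMask, float, float]:
    """Build the graph, solve the cut and return (mask, flow, energy of the labelling)."""
    graph = build_graph(volume, likelihoods, seeds, params, tau_volume, exclusion)
    mask, flow = solve_min_cut(graph, volume.spacing, volume.origin)
    return mask, flow, cut_energy(mask.labels, graph)
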