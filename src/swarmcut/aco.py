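"""Variant ant colony optimization producing a per-pixel boundary-confidence field.

Ants random-walk on the 8-connected pixel lattice of an enhanced slice,
choosing the next pixel with probability proportional to tau^alpha * eta^beta
among non-tabu neighbours, where eta is heuristic edge evidence (local
intensity variation of the enhanced image) and tau the pheromone field. The
*variant* scheme uses selective updating:

* during the local iterations of a round the pheromone field is frozen —
  ants only record tours;
* at each global update the recorded best tours are reinforced,
  tau <- (1 - rho) * tau + rho, and every other pixel evaporates,
  tau <- (1 - phi) * tau;
* tau is clamped to [tau_min, tau_max] after every update, so the field is
  finite and stagnation-free.

The reinforced set is the round's elite: every tour recorded during the
round whose mean eta is at least ``elite_frac`` of the round's best tour
(ties keep the first found). Ants restart from fresh random positions each
local iteration, so the elite tours of a round cover the whole extent of the
strong-edge ridges rather than a single hot spot — a single elite tour of
n_steps pixels could never lift the pheromone statistics of a whole organ
contour. Tours with zero heuristic score are never reinforced, so on a
featureless slice the field simply evaporates down to tau_min.

The resulting tau is an edge-confidence map; the swarm factor B = 1 - tau
multiplies the Gaussian boundary term of the graph-cut energy, making cuts
along high-confidence boundaries cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "ACOParams",
    "heuristic_field",
    "run_variant_aco",
    "boundary_factor",
    "edge_tau",
]

TAU_MIN_DEFAULT = 0.001
TAU_MAX_DEFAULT = 0.999


@dataclass(frozen=True)
class ACOParams:
    """Variant-ACO tuning knobs.

    Defaults follow max-min ant-system practice for edge detection: heuristic
    information dominates pheromone (beta > alpha), evaporation/reinforcement
    rates are small for consistent trail change, and the pheromone is bounded
    in [0.001, 0.999].
    """

    alpha: float = 1.0
    beta: float = 2.0
    tau0: float = 1e-6
    phi: float = 0.2  # off-tour evaporation rate
    rho: float = 0.3  # best-tour reinforcement rate
    tau_min: float = TAU_MIN_DEFAULT
    tau_max: float = TAU_MAX_DEFAULT
    elite_frac: float = 0.5  # reinforce ant-best tours scoring >= elite_frac * best score
    n_ants: int | None = None  # default ceil(sqrt(rows * cols))
    n_steps: int = 40
    n_local: int = 4
    n_global: int = 10
    tabu_len: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.phi < 1 and 0 < self.rho < 1):
            raise ValueError("phi and rho must lie in (0, 1)")
        if not self.tau_min < self.tau_max:
            raise ValueError("tau_min must be below tau_max")
        if self.beta <= self.alpha:
            raise ValueError("beta > alpha is required (heuristic information dominates)")
        if self.n_steps <= 0 or self.n_local <= 0 or self.n_global <= 0:
            raise ValueError("n_steps, n_local and n_global must be positive")
        if self.n_ants is not None and self.n_ants <= 0:
            raise ValueError("n_ants must be positive")
        if not 0 < self.elite_frac <= 1:
            raise ValueError("elite_frac must lie in (0, 1]")


def heuristic_field(enhanced_slice: np.ndarray) -> np.ndarray:
    """Edge-evidence field eta in [0, 1] from 3x3 symmetric pair differences.

    eta(i, j) is the largest absolute difference over the four opposing pixel
    pairs (horizontal, vertical, both diagonals) around (i, j), normalized by
    its global maximum; a constant slice yields eta = 0 everywhere.
    """
    img = np.asarray(enhanced_slice, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("heuristic_field expects a 2D slice of at least 3x3")
    p = np.pad(img, 1, mode="edge")
    pairs = [
        np.abs(p[1:-1, 2:] - p[1:-1, :-2]),  # horizontal
        np.abs(p[2:, 1:-1] - p[:-2, 1:-1]),  # vertical
        np.abs(p[2:, 2:] - p[:-2, :-2]),  # main diagonal
        np.abs(p[2:, :-2] - p[:-2, 2:]),  # anti-diagonal
    ]
    eta = np.maximum.reduce(pairs)
    peak = eta.max()
    return eta / peak if peak > 0 else eta


_NEIGH = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)], dtype=np.int64
)


def run_variant_aco(
    enhanced_slice: np.ndarray,
    params: ACOParams = ACOParams(),
    observer: Callable[[str, np.ndarray], None] | None = None,
) -> np.ndarray:
    """Run the variant ACO on one slice and return the pheromone field tau.

    Deterministic for a fixed ``params.seed``. ``observer(stage, tau)`` is
    called with a copy of the field after initialization, after every local
    iteration and after every global update — test builds use it to assert the
    pheromone bounds and the selective-updating freeze.
    """
    eta = heuristic_field(enhanced_slice)
    nr, nc = eta.shape
    n_px = nr * nc
    n_ants = params.n_ants or int(np.ceil(np.sqrt(n_px)))
    rng = np.random.default_rng(params.seed)

    tau = np.full((nr, nc), max(params.tau0, params.tau_min), dtype=np.float64)
    if observer:
        observer("init", tau.copy())

    eta_flat = eta.ravel()
    eta_beta = eta_flat**params.beta

    for _g in range(params.n_global):
        tau_alpha_flat = tau.ravel() ** params.alpha  # frozen during local iterations
        attract = tau_alpha_flat * eta_beta
        round_tours: list[np.ndarray] = []
        round_scores: list[np.ndarray] = []
        for _l in range(params.n_local):
            pos_r = rng.integers(0, nr, size=n_ants)
            pos_c = rng.integers(0, nc, size=n_ants)
            tabu = np.full((n_ants, params.tabu_len), -1, dtype=np.int64)
            tabu[:, 0] = pos_r * nc + pos_c
            tabu_head = 1
            tours = np.empty((n_ants, params.n_steps + 1), dtype=np.int64)
            tours[:, 0] = tabu[:, 0]

            for s in range(params.n_steps):
                cand_r = pos_r[:, None] + _NEIGH[:, 0][None, :]
                cand_c = pos_c[:, None] + _NEIGH[:, 1][None, :]
                valid = (cand_r >= 0) & (cand_r < nr) & (cand_c >= 0) & (cand_c < nc)
                cand_flat = np.where(valid, cand_r * nc + cand_c, 0)
                w = np.where(valid, attract[cand_flat], 0.0)
                w[(cand_flat[:, :, None] == tabu[:, None, :]).any(axis=2) & valid] = 0.0

                totals = w.sum(axis=1)
                # zero-weight ants move uniformly among valid non-tabu neighbours
                fallback = valid & ~(cand_flat[:, :, None] == tabu[:, None, :]).any(axis=2)
                no_w = totals <= 0
                w[no_w] = fallback[no_w].astype(np.float64)
                totals = w.sum(axis=1)
                stuck = totals <= 0  # fully tabu-blocked: fall back to any valid neighbour
                if stuck.any():
                    w[stuck] = valid[stuck].astype(np.float64)
                    totals = w.sum(axis=1)

                cdf = np.cumsum(w, axis=1)
                u = rng.random(n_ants) * totals
                choice = (cdf < u[:, None]).sum(axis=1)
                nxt = cand_flat[np.arange(n_ants), choice]
                pos_r, pos_c = nxt // nc, nxt % nc
                tours[:, s + 1] = nxt
                tabu[:, tabu_head % params.tabu_len] = nxt
                tabu_head += 1

            round_tours.append(tours)
            round_scores.append(eta_flat[tours].mean(axis=1))
            if observer:
                observer("local", tau.copy())

        # global update: reinforce the round's elite tours (mean heuristic
        # score within elite_frac of the round's best), evaporate everywhere
        # else; zero-score tours carry no edge evidence and are never
        # reinforced
        all_tours = np.concatenate(round_tours)
        all_scores = np.concatenate(round_scores)
        reinforce = np.zeros(n_px, dtype=bool)
        cutoff = params.elite_frac * float(all_scores.max())
        for tour, score in zip(all_tours, all_scores):
            if score > 0 and score >= cutoff:
                reinforce[tour] = True
        flat = tau.ravel()
        flat[reinforce] = (1 - params.rho) * flat[reinforce] + params.rho
        flat[~reinforce] = (1 - params.phi) * flat[~reinforce]
        np.clip(flat, params.tau_min, params.tau_max, out=flat)
        if observer:
            observer("global", tau.copy())

    return tau


def boundary_factor(tau_field: np.ndarray) -> np.ndarray:
    """Swarm factor B = 1 - tau; high boundary confidence makes cuts cheap there."""
    return 1.0 - np.asarray(tau_field, dtype=np.float64)


def edge_tau(tau_volume: np.ndarray, u: tuple[int, int, int], v: tuple[int, int, int]) -> float:
    """Edge-level pheromone for a 6-neighbour voxel pair from per-slice tau fields.

    The pheromone is defined per pixel; an in-slice edge takes the max of its
    endpoints (an edge touching a confident boundary pixel is a boundary
    edge), an inter-slice edge the mean of the two slices' values.
    """
    u, v = tuple(int(x) for x in u), tuple(int(x) for x in v)
    diff = [abs(a - b) for a, b in zip(u, v)]
    if sum(diff) != 1:
        raise ValueError(f"{u} and {v} are not 6-neighbours")
    tu = float(tau_volume[u])
    tv = float(tau_volume[v])
    if diff[0] == 1:  # inter-slice
        return 0.5 * (tu + tv)
    return max(tu, tv)
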