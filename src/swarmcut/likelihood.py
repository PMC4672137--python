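"""Domain-knowledge data term: seed-anchored likelihood fields and t-link costs.

Two pieces of anatomical prior drive the per-voxel likelihoods Pr(x_u | omega):

1. *Intensity interval prior.* Contrast-enhanced liver parenchyma occupies a
   rough HU interval [low, high]. A normalized parabola over that interval
   (zero at the bounds, 1/4 at the midpoint) splits it into confident central
   intensities and "dubitable" margins near the bounds; the weight ``I_w``
   dampens the intensity penalty (q < 0) inside the confident band so that
   false edges within liver tissue cannot trap the expansion.

2. *Spatial connectivity prior.* The liver is one spatially continuous region,
   so the likelihood of a voxel is scored by the best path connecting it to a
   seed region: an exponential penalty on the squared deviation of the voxel's
   intensity from the running path-average intensity, relieved by the
   accumulated Euclidean path length in mm.

Path strength follows the fuzzy-connectedness convention: the strength of a
path is the weakest step along it, so the likelihood of voxel ``l`` reached
from a visited neighbour ``p`` is

    L(l) = min( L(p), exp( -I_w(l) * mu * (Int_l - IntBar_p)^2 / (dis(l, p) + Dis_p) ) )

with ``IntBar_l = (Int_l + IntBar_p) / 2`` and ``Dis_l = dis(l, p) + Dis_p``
on acceptance, and the maximum over incoming neighbours kept. The min makes
the likelihood non-increasing along every path — a voxel cannot become
liver-like again after the path has crossed an organ boundary. Seeds start at
likelihood 1 with ``IntBar = Int`` and ``Dis = delta_dis`` (a small positive
path-length offset that keeps the first step's denominator positive).

Expansion is level-wise and visit-once: the l-th front is the set of
unvisited 6-neighbours of the (l-1)-th front, and each voxel is scored the
first (and only) time the front reaches it, maximizing over its already
visited neighbours. Visit-once matters under noise: re-relaxing voxels to a
global best-path fixed point would let likelihood percolate through noise
along arbitrarily contorted paths and wash out the field's contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import CTVolume, SeedSet

__all__ = [
    "IntensityInterval",
    "ConnectivityParams",
    "LikelihoodField",
    "normalized_intensity",
    "intensity_weight",
    "interval_from_seeds",
    "propagate_likelihood",
    "compute_likelihood_field",
    "data_cost",
]

DEFAULT_THETA = (1.0 / 7.0) * (6.0 / 7.0)  # 6/49: confident band = central 3/4-ish of the interval


@dataclass(frozen=True)
class IntensityInterval:
    """HU interval prior with dubitable-band parameter.

    ``theta`` marks where the normalized parabola leaves the dubitable margin;
    with the default 6/49 the confident band spans fractional positions
    [1/7, 6/7] of [low, high]. ``q`` (< 0 by default) scales the exponent of
    the confident-band weight.
    """

    low: float
    high: float
    theta: float = DEFAULT_THETA
    q: float = -4.0

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"intensity interval requires low < high, got [{self.low}, {self.high}]")
        if not 0 < self.theta < 0.25:
            raise ValueError("theta must lie in (0, 1/4), the range of the normalized parabola")


@dataclass(frozen=True)
class ConnectivityParams:
    """Path-expansion scales: mu_object (mu1), mu_background (mu2), likelihood floor."""

    mu_object: float = 12.0
    mu_background: float = 8.0
    eps_floor: float = 1e-6
    delta_dis: float = 1.0  # mm; seed path-length offset

    def __post_init__(self) -> None:
        if self.mu_object <= 0 or self.mu_background <= 0:
            raise ValueError("expansion scales mu must be positive")
        if not 0 < self.eps_floor < 1:
            raise ValueError("eps_floor must lie in (0, 1)")
        if self.delta_dis <= 0:
            raise ValueError("delta_dis must be positive")


@dataclass(frozen=True)
class LikelihoodField:
    """Per-voxel Pr(x|object) and Pr(x|background), both in [eps_floor, 1]."""

    pr_object: np.ndarray
    pr_background: np.ndarray


def normalized_intensity(intensity, interval: IntensityInterval):
    """Normalized parabola over the HU interval: (I-low)(high-I)/(high-low)^2.

    Zero at and outside the bounds, maximal (1/4) at the interval midpoint.
    Accepts scalars or arrays.
    """
    i = np.asarray(intensity, dtype=float)
    span = interval.high - interval.low
    val = (i - interval.low) * (interval.high - i) / (span * span)
    val = np.clip(val, 0.0, 0.25)
    return val if val.ndim else float(val)


def intensity_weight(intensity, interval: IntensityInterval):
    """Intensity-prior weight I_w: 1 on the dubitable margins, exp(q * parabola) on the confident band.

    With q < 0 the confident central band damps the intensity-difference
    penalty of the path expansion, boosting Pr(x|object) on intensities that
    are confidently liver-like.
    """
    w = normalized_intensity(intensity, interval)
    w_arr = np.atleast_1d(np.asarray(w, dtype=float))
    dubitable = (w_arr > 0) & (w_arr < interval.theta)
    out = np.where(dubitable, 1.0, np.exp(interval.q * w_arr))
    return out if np.ndim(intensity) else float(out[0])


def interval_from_seeds(volume: CTVolume, object_mask: np.ndarray, n_std: float = 3.0, **kw) -> IntensityInterval:
    """Estimate the HU interval as mean +/- n_std * std of the object-seed intensities."""
    vals = volume.intensities[object_mask]
    if vals.size == 0:
        raise ValueError("cannot estimate intensity interval from empty seeds")
    mu, sd = float(vals.mean()), float(vals.std())
    sd = max(sd, 1.0)  # degenerate constant seeds
    return IntensityInterval(mu - n_std * sd, mu + n_std * sd, **kw)


_NEIGHBOR_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def propagate_likelihood(
    volume: CTVolume,
    seed_mask: np.ndarray,
    mu: float,
    interval: IntensityInterval | None = None,
    eps_floor: float = 1e-6,
    delta_dis: float = 1.0,
    max_sweeps: int | None = None,
) -> np.ndarray:
    """Seed-anchored likelihood by level-wise visit-once front expansion.

    Each level assigns, synchronously, every unvisited voxel adjacent to the
    visited set: the voxel takes the best candidate over its visited
    6-neighbours (weakest-step path strength, deterministic neighbour-order
    tie-break) together with the winning predecessor's running path state
    (average intensity, aggregate mm distance). Synchronous levels make the
    result independent of seed enumeration order.

    When ``interval`` is None (background expansion) the intensity weight is
    identically 1.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if seed_mask.shape != volume.shape:
        raise ValueError("seed mask not congruent with volume")
    if not seed_mask.any():
        raise ValueError("seed set is empty")
    if mu <= 0:
        raise ValueError("mu must be positive")

    inten = volume.intensities.astype(np.float64)
    iw = intensity_weight(inten, interval) if interval is not None else None

    visited = seed_mask.copy()
    like = np.where(seed_mask, 1.0, 0.0)
    intbar = inten.copy()
    dis = np.full(volume.shape, float(delta_dis))
    spacing = volume.spacing

    if max_sweeps is None:
        max_sweeps = sum(volume.shape) + 2

    for _ in range(max_sweeps):
        best = np.full(volume.shape, -np.inf)
        best_ib = np.zeros(volume.shape)
        best_dis = np.zeros(volume.shape)
        for off in _NEIGHBOR_OFFSETS:
            # predecessor grid shifted by -off supplies candidates at each voxel
            src = tuple(slice(None if o <= 0 else o, None if o >= 0 else o) for o in off)
            dst = tuple(slice(None if o >= 0 else -o, None if o <= 0 else -o) for o in off)
            step = spacing[int(np.argmax(np.abs(off)))]

            diff = inten[dst] - intbar[src]
            denom = step + dis[src]
            iw_dst = iw[dst] if iw is not None else 1.0
            cand = np.exp(-iw_dst * mu * diff * diff / denom)
            cand = np.minimum(cand, like[src])  # weakest-step path strength
            cand = np.where(visited[src] & ~visited[dst], cand, -np.inf)

            win = cand > best[dst]
            if win.any():
                b = best[dst]
                b[win] = cand[win]
                best[dst] = b
                bi = best_ib[dst]
                bi[win] = 0.5 * (inten[dst][win] + intbar[src][win])
                best_ib[dst] = bi
                bd = best_dis[dst]
                bd[win] = step + dis[src][win]
                best_dis[dst] = bd

        frontier = best > -np.inf
        if not frontier.any():
            break
        like[frontier] = best[frontier]
        intbar[frontier] = best_ib[frontier]
        dis[frontier] = best_dis[frontier]
        visited |= frontier

    return np.clip(like, eps_floor, 1.0)


def compute_likelihood_field(
    volume: CTVolume,
    seeds: SeedSet,
    params: ConnectivityParams | None = None,
    interval: IntensityInterval | None = None,
    use_intensity_weight: bool = True,
) -> LikelihoodField:
    """Object and background likelihood fields from a seed set.

    The object expansion applies the intensity-prior weight (unless disabled,
    which yields the plain connectivity data term); the background expansion
    always uses I_w = 1, since the interval prior is liver-specific. If no
    explicit interval is given it is estimated from the object seeds.
    """
    params = params or ConnectivityParams()
    seeds.require_nonempty()
    if interval is None and use_intensity_weight:
        interval = interval_from_seeds(volume, seeds.object_mask)
    pr_obj = propagate_likelihood(
        volume,
        seeds.object_mask,
        params.mu_object,
        interval if use_intensity_weight else None,
        params.eps_floor,
        params.delta_dis,
    )
    pr_bkg = propagate_likelihood(
        volume, seeds.background_mask, params.mu_background, None, params.eps_floor, params.delta_dis
    )
    return LikelihoodField(pr_obj, pr_bkg)


def data_cost(probabilities: np.ndarray, eps_floor: float = 1e-6) -> np.ndarray:
    """t-link cost -log Pr, finite everywhere thanks to the likelihood floor."""
    return -np.log(np.clip(probabilities, eps_floor, 1.0))
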