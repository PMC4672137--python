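import math

import numpy as np
import pytest

import swarmcut as sc
from swarmcut.likelihood import (
    ConnectivityParams,
    IntensityInterval,
    compute_likelihood_field,
    data_cost,
    intensity_weight,
    interval_from_seeds,
    normalized_intensity,
    propagate_likelihood,
)

_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def reference_expansion(inten, seed_mask, mu, spacing=(1, 1, 1), delta=1.0, eps=1e-6):
    """Independent scalar implementation of the level-wise visit-once expansion."""
    shape = inten.shape
    visited = {tuple(c) for c in np.argwhere(seed_mask)}
    like = {c: 1.0 for c in visited}
    intbar = {c: float(inten[c]) for c in visited}
    dis = {c: float(delta) for c in visited}
    while True:
        frontier = {}
        cells = set()
        for c in visited:
            for off in _OFFSETS:
                n = tuple(np.add(c, off))
                if all(0 <= n[a] < shape[a] for a in range(3)) and n not in visited:
                    cells.add(n)
        if not cells:
            break
        for cell in cells:
            best = None
            for off in _OFFSETS:
                p = tuple(np.subtract(cell, off))
                if not all(0 <= p[a] < shape[a] for a in range(3)) or p not in visited:
                    continue
                step = spacing[int(np.argmax(np.abs(off)))]
                cand = min(
                    like[p],
                    math.exp(-mu * (float(inten[cell]) - intbar[p]) ** 2 / (step + dis[p])),
                )
                if best is None or cand > best[0]:
                    best = (cand, 0.5 * (float(inten[cell]) + intbar[p]), step + dis[p])
            frontier[cell] = best
        for cell, (l, ib, d) in frontier.items():
            like[cell], intbar[cell], dis[cell] = l, ib, d
        visited |= set(frontier)
    out = np.full(shape, 0.0)
    for c, l in like.items():
        out[c] = l
    return np.clip(out, eps, 1.0)


class TestIntervalWeights:
    def test_parabola_roots_and_vertex(self):
        iv = IntensityInterval(0.0, 100.0)
        assert normalized_intensity(0.0, iv) == 0.0
        assert normalized_intensity(100.0, iv) == 0.0
        assert normalized_intensity(50.0, iv) == pytest.approx(0.25)
        assert normalized_intensity(-50.0, iv) == 0.0  # outside the interval

    def test_theta_marks_band_edges_at_sevenths(self):
        # x(1-x) = 6/49 has roots exactly at fractional positions 1/7 and 6/7
        iv = IntensityInterval(0.0, 7.0)
        assert normalized_intensity(1.0, iv) == pytest.approx(iv.theta)
        assert normalized_intensity(6.0, iv) == pytest.approx(iv.theta)
        assert iv.theta == pytest.approx(6.0 / 49.0)

    def test_invalid_intervals(self):
        with pytest.raises(ValueError):
            IntensityInterval(10.0, 10.0)
        with pytest.raises(ValueError):
            IntensityInterval(0.0, 1.0, theta=0.3)

    def test_weight_branches(self):
        iv = IntensityInterval(0.0, 1.0, q=-4.0)
        # dubitable margin (0 < parabola < theta) -> weight 1
        assert intensity_weight(0.05, iv) == 1.0
        # at the bound the parabola is 0: strict inequality puts it on exp(q*0) = 1
        assert intensity_weight(0.0, iv) == 1.0
        # confident centre: parabola = 1/4 -> exp(-4/4) = 1/e
        assert intensity_weight(0.5, iv) == pytest.approx(math.exp(-1.0))

    def test_interval_from_seeds_spans_three_sigma(self):
        vol = sc.CTVolume(np.full((2, 2, 2), 110.0) + np.arange(8).reshape(2, 2, 2))
        iv = interval_from_seeds(vol, np.ones((2, 2, 2), bool))
        vals = vol.intensities.ravel()
        assert iv.low == pytest.approx(vals.mean() - 3 * max(vals.std(), 1.0))
        assert iv.high == pytest.approx(vals.mean() + 3 * max(vals.std(), 1.0))


class TestPropagation:
    def test_uniform_volume_gives_unit_likelihood(self):
        vol = sc.CTVolume(np.full((4, 5, 6), 80.0))
        seeds = np.zeros((4, 5, 6), bool)
        seeds[2, 2, 3] = True
        like = propagate_likelihood(vol, seeds, mu=12.0)
        np.testing.assert_allclose(like, 1.0)

    def test_three_voxel_chain_matches_hand_computation(self):
        inten = np.array([[[100.0, 100.0, 160.0]]])
        seeds = np.zeros((1, 1, 3), bool)
        seeds[0, 0, 0] = True
        mu = 1e-3  # keep the hand value above the floor
        like = propagate_likelihood(sc.CTVolume(inten), seeds, mu=mu)
        assert like[0, 0, 1] == pytest.approx(1.0)
        assert like[0, 0, 2] == pytest.approx(math.exp(-mu * 60.0**2 / (1.0 + 2.0)))

    def test_harsh_step_floors(self):
        inten = np.array([[[100.0, 100.0, 160.0]]])
        seeds = np.zeros((1, 1, 3), bool)
        seeds[0, 0, 0] = True
        like = propagate_likelihood(sc.CTVolume(inten), seeds, mu=12.0, eps_floor=1e-6)
        assert like[0, 0, 2] == pytest.approx(1e-6)

    def test_non_increasing_along_monotone_ramp(self):
        inten = np.linspace(0, 90, 10).reshape(1, 1, 10)
        seeds = np.zeros((1, 1, 10), bool)
        seeds[0, 0, 0] = True
        like = propagate_likelihood(sc.CTVolume(inten), seeds, mu=0.05)
        assert np.all(np.diff(like[0, 0]) <= 1e-12)

    def test_matches_scalar_reference_on_small_grids(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            inten = rng.normal(100.0, 20.0, size=(2, 3, 3))
            seeds = np.zeros((2, 3, 3), bool)
            seeds[tuple(rng.integers(0, s) for s in (2, 3, 3))] = True
            seeds[tuple(rng.integers(0, s) for s in (2, 3, 3))] = True
            got = propagate_likelihood(sc.CTVolume(inten), seeds, mu=0.05)
            want = reference_expansion(inten, seeds, mu=0.05)
            np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(3)
        inten = rng.normal(100.0, 15.0, size=(4, 5, 6))
        seeds = np.zeros((4, 5, 6), bool)
        seeds[1, 2, 3] = True
        base = propagate_likelihood(sc.CTVolume(inten), seeds, mu=0.1)
        flipped = propagate_likelihood(sc.CTVolume(inten[::-1].copy()), seeds[::-1].copy(), mu=0.1)
        np.testing.assert_allclose(flipped[::-1], base)

    def test_bounds_respected(self, noisy_phantom):
        vol, _, seeds = noisy_phantom
        field = compute_likelihood_field(vol, seeds)
        for arr in (field.pr_object, field.pr_background):
            assert arr.min() >= 1e-6 and arr.max() <= 1.0
        assert np.all(field.pr_object[seeds.object_mask] == 1.0)
        assert np.all(field.pr_background[seeds.background_mask] == 1.0)

    def test_empty_seeds_rejected(self):
        vol = sc.CTVolume(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            propagate_likelihood(vol, np.zeros((2, 2, 2), bool), mu=1.0)


class TestClassification:
    def test_argmax_recovers_well_separated_classes(self, clean_phantom):
        vol, truth, seeds = clean_phantom
        field = compute_likelihood_field(vol, seeds)
        predicted = field.pr_object > field.pr_background
        assert (predicted == truth).mean() >= 0.99


class TestDataCost:
    def test_closed_forms(self):
        assert data_cost(np.array(1.0)) == 0.0
        assert data_cost(np.array(math.exp(-1.0))) == pytest.approx(1.0)
        assert data_cost(np.array(0.0), eps_floor=1e-6) == pytest.approx(-math.log(1e-6))
        assert np.isfinite(data_cost(np.zeros((3, 3)))).all()


class TestParams:
    def test_connectivity_validation(self):
        with pytest.raises(ValueError):
            ConnectivityParams(mu_object=-1.0)
        with pytest.raises(ValueError):
            ConnectivityParams(eps_floor=2.0)
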