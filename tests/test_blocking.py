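"""Pair-correlation maps and the flow-axis depletion test."""

import math
import warnings

import numpy as np
import pytest

from flowadhesion import (
    FieldPoints,
    ParameterError,
    ShadowModel,
    SimulationConfig,
    flow_axis_depletion_index,
    pair_correlation_map,
    permutation_test,
    radial_profile,
    simulate_adhesion,
    uniform_hard_core_field,
)

SCALE = 0.61


def brute_force_map(fields, r_max, mode="unordered", border_margin=None):
    """Independent O(n^2) all-pairs reimplementation of the map."""
    if border_margin is None:
        border_margin = float(r_max)
    side = 2 * r_max + 1
    counts = np.zeros((side, side))
    for f in fields:
        n = len(f)
        for i in range(n):
            xi, yi = f.x_px[i], f.y_px[i]
            if not (
                border_margin <= xi <= f.width_px - 1 - border_margin
                and border_margin <= yi <= f.height_px - 1 - border_margin
            ):
                continue
            for j in range(n):
                if j == i:
                    continue
                if mode == "time_ordered" and not f.attach_times_s[j] > f.attach_times_s[i]:
                    continue
                dx = f.x_px[j] - xi
                dy = f.y_px[j] - yi
                if dx == 0 and dy == 0:
                    continue
                ix, iy = int(round(dx)), int(round(dy))
                if ix == 0 and iy == 0:
                    continue
                if ix * ix + iy * iy > r_max * r_max:
                    continue
                counts[iy + r_max, ix + r_max] += 1
    if mode == "unordered":
        counts = counts + counts[::-1, ::-1]
    total = counts.sum()
    return counts / total if total > 0 else counts


def uniform_fields(n_fields, n_cells, side_um, rng, min_dist=2.0):
    fields = []
    for child in rng.spawn(n_fields):
        pts = uniform_hard_core_field(n_cells, side_um, side_um, min_dist, child)
        px = pts / SCALE
        dim = side_um / SCALE
        fields.append(FieldPoints(px[:, 0], px[:, 1], dim, dim))
    return fields


def test_two_point_field():
    """A single pair separated by (10, 0) px gives two mirror bins of 0.5."""
    f = FieldPoints(np.array([60.0, 70.0]), np.array([60.0, 60.0]), 200, 200)
    m = pair_correlation_map(f, r_max=50)
    nz = np.argwhere(m.density > 0)
    assert len(nz) == 2
    r = m.r_max
    assert m.density[r, r + 10] == 0.5
    assert m.density[r, r - 10] == 0.5


def test_normalization_and_disc_support(rng):
    fields = uniform_fields(2, 400, 300, rng)
    m = pair_correlation_map(fields, r_max=50)
    assert m.density.sum() == pytest.approx(1.0, abs=1e-12)
    dx, dy = m.bin_centers()
    outside = np.hypot(dx, dy) > m.r_max
    assert (m.density[outside] == 0).all()


def test_unordered_map_centro_symmetric(rng):
    fields = uniform_fields(2, 300, 300, rng)
    m = pair_correlation_map(fields, r_max=50)
    assert (m.density == m.density[::-1, ::-1]).all()


def test_matches_brute_force_oracle(rng):
    """Production (k-d tree) map is bit-identical to the O(n^2) loop."""
    pts = rng.uniform(0, 200, size=(150, 2))
    times = rng.uniform(0, 1800, size=150)
    f = FieldPoints(pts[:, 0], pts[:, 1], 200, 200, attach_times_s=times)
    for mode in ("unordered", "time_ordered"):
        m = pair_correlation_map(f, r_max=50, mode=mode)
        oracle = brute_force_map([f], 50, mode=mode)
        assert np.array_equal(m.density, oracle)


def test_time_ordered_map_sums_to_one(rng):
    pts = rng.uniform(0, 300, size=(100, 2))
    f = FieldPoints(pts[:, 0], pts[:, 1], 300, 300, attach_times_s=np.arange(100.0))
    m = pair_correlation_map(f, r_max=50, mode="time_ordered")
    assert m.density.sum() == pytest.approx(1.0, abs=1e-12)


def test_uniform_fields_approach_flat_density(rng):
    """Mean in-disc bin -> 1/(pi R^2); max bin stays below 4e-4 at R=50."""
    fields = uniform_fields(10, 3721, 610, rng)
    m = pair_correlation_map(fields, r_max=50)
    assert m.n_pairs >= 1_000_000
    dx, dy = m.bin_centers()
    in_disc = (np.hypot(dx, dy) <= 50) & (np.hypot(dx, dy) > 4)  # beyond hard core
    level = 1.0 / (math.pi * 50**2)
    assert m.density[in_disc].mean() == pytest.approx(level, rel=0.05)
    assert m.density.max() <= 4.0e-4


def test_empty_reference_set_rejected():
    f = FieldPoints(np.array([1.0, 2.0]), np.array([1.0, 2.0]), 60, 60)
    with pytest.raises(ParameterError, match="reference"):
        pair_correlation_map(f, r_max=50)


class TestRadialProfile:
    def test_uniform_profile_is_flat(self, rng):
        fields = uniform_fields(6, 3721, 610, rng)
        m = pair_correlation_map(fields, r_max=50)
        prof = radial_profile(m, ring_width=5)
        outer = prof[prof.r_inner >= 5]
        level = 1.0 / (math.pi * 50**2)
        # each ring within 3 Poisson standard errors of the uniform level
        for _, row in outer.iterrows():
            ring_pairs = row.mean_density * row.n_bins * m.n_pairs
            se = math.sqrt(max(ring_pairs, 1)) / (row.n_bins * m.n_pairs)
            assert abs(row.mean_density - level) < 3 * se + 1e-6

    def test_hard_core_ring_depleted(self, rng):
        fields = uniform_fields(4, 1000, 300, rng, min_dist=3.0)
        m = pair_correlation_map(fields, r_max=50)
        prof = radial_profile(m, ring_width=2)
        inner = prof[prof.r_outer <= 4].mean_density
        outer = prof[prof.r_inner >= 10].mean_density
        assert inner.mean() < 0.3 * outer.mean()

    def test_single_pair_occupies_one_ring(self):
        f = FieldPoints(np.array([60.0, 70.0]), np.array([60.0, 60.0]), 200, 200)
        m = pair_correlation_map(f, r_max=50)
        prof = radial_profile(m, ring_width=5)
        assert (prof.mean_density > 0).sum() == 1

    def test_ring_width_validated(self, rng):
        fields = uniform_fields(1, 100, 200, rng)
        m = pair_correlation_map(fields, r_max=50)
        with pytest.raises(ParameterError):
            radial_profile(m, ring_width=0.5)


class TestDepletionIndex:
    def test_uniform_map_index_near_one(self, rng):
        fields = uniform_fields(10, 3721, 610, rng)
        m = pair_correlation_map(fields, r_max=50)
        res = flow_axis_depletion_index(m, r_s=34)
        assert 0.9 <= res.index <= 1.1

    def test_zeroed_cone_gives_zero_index(self, rng):
        fields = uniform_fields(2, 500, 300, rng)
        m = pair_correlation_map(fields, r_max=50)
        dx, dy = m.bin_centers()
        r = np.hypot(dx, dy)
        with np.errstate(invalid="ignore"):
            cos_ang = np.where(r > 0, dx / r, 0.0)
        cone = (np.abs(cos_ang) >= math.cos(math.radians(30.0))) & (r <= 34)
        density = m.density.copy()
        density[cone] = 0.0
        m2 = type(m)(density=density, r_max=m.r_max, mode=m.mode, n_pairs=m.n_pairs)
        assert flow_axis_depletion_index(m2, r_s=34).index == 0.0

    def test_shadowed_simulation_shows_depletion(self):
        shadow = ShadowModel(enabled=True, length_um=21.0, halfwidth_um=1.5)
        fields = []
        for seed in range(4):
            cfg = SimulationConfig(rng_seed=500 + seed, arrival_rate=600.0, shadow=shadow)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sim = simulate_adhesion(cfg)
            last = sim.frames[-1]
            dim = cfg.field_width_um / SCALE
            fields.append(
                FieldPoints(last[:, 0] / SCALE, last[:, 1] / SCALE, dim, dim, last[:, 2])
            )
        m = pair_correlation_map(fields, r_max=50, mode="time_ordered")
        res = flow_axis_depletion_index(m, r_s=34)
        assert res.index < 1.0


class TestPermutationTest:
    def test_p_floor_with_99_permutations(self, rng):
        """Strong depletion with n_perm=99 gives exactly p = 1/100."""
        # synthetic displacements: uniform ring with the downstream cone removed
        n = 4000
        ang = rng.uniform(math.radians(35), 2 * math.pi - math.radians(35), n)
        r = rng.uniform(5, 30, n)
        x = 100 + r * np.cos(ang)
        y = 100 + r * np.sin(ang)
        xs = np.concatenate([[100.0], x])
        ys = np.concatenate([[100.0], y])
        times = np.arange(float(n + 1))
        f = FieldPoints(xs, ys, 200, 200, attach_times_s=times)
        res = permutation_test(
            f, r_max=50, mode="time_ordered", r_s=34, n_permutations=99, seed=1,
            border_margin=50,
        )
        assert res.p_value == pytest.approx(0.01, abs=1e-12)

    def test_calibration_without_shadow(self, rng):
        """No-blocking fields: p > 0.05 in >= 90% of 20 seeded runs."""
        ok = 0
        for child in rng.spawn(20):
            pts = uniform_hard_core_field(930, 305, 305, 2.0, child)
            f = FieldPoints(pts[:, 0] / SCALE, pts[:, 1] / SCALE, 500, 500)
            res = permutation_test(f, r_s=34, n_permutations=199, seed=child)
            ok += res.p_value > 0.05
        assert ok >= 18

    def test_power_with_shadow_on(self):
        """10 shadowed fields: depletion detected at p < 0.01."""
        shadow = ShadowModel(enabled=True, length_um=21.0, halfwidth_um=1.5)
        fields = []
        for seed in range(10):
            cfg = SimulationConfig(rng_seed=600 + seed, arrival_rate=600.0, shadow=shadow)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sim = simulate_adhesion(cfg)
            last = sim.frames[-1]
            dim = cfg.field_width_um / SCALE
            fields.append(
                FieldPoints(last[:, 0] / SCALE, last[:, 1] / SCALE, dim, dim, last[:, 2])
            )
        res = permutation_test(
            fields, mode="time_ordered", r_s=34, n_permutations=199, seed=7
        )
        assert res.index < 1.0
        assert res.p_value < 0.01

    def test_low_pair_warning(self, rng):
        pts = rng.uniform(45, 75, size=(6, 2))
        f = FieldPoints(pts[:, 0], pts[:, 1], 120, 120, attach_times_s=np.arange(6.0))
        with pytest.warns(UserWarning, match="unreliable"):
            res = permutation_test(f, r_max=20, r_s=20, n_permutations=99, seed=0, border_margin=20)
        assert res.low_pair_caveat
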