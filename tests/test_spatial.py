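"""Anchor selection, correction-surface construction, and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rppanorm import (
    AnchorLattice,
    AnchorSelectionError,
    ExteriorQueryError,
    SimulationConfig,
    SpotRole,
    apply_correction,
    assemble_lattice,
    bilinear_interpolate,
    build_surface,
    cellwise_bilinear,
    compute_reference,
    constant_field,
    extrapolate_nearest,
    normalize_slide,
    select_anchors,
    simulate_slide,
    spline_surface,
)
from rppanorm.spatial import Anchor, _spline_evaluate
from conftest import make_slide


def set_control_intensities(slide, set_id, values):
    """Overwrite one positive-control set's intensities in dilution order."""
    mask = slide.spots["sample_id"] == set_id
    sub = slide.spots[mask].sort_values("dilution_step")
    slide.spots.loc[sub.index, "intensity"] = np.asarray(values, dtype=float)
    return sub


class TestSelectAnchors:
    def test_median_of_monotone_series(self, default_layout):
        slide = make_slide(default_layout, np.ones(default_layout.n_spots))
        sub = set_control_intensities(
            slide, "PC_r01c1s1", [100, 50, 25, 12.5, 6.25])
        anchors = {a.set_id: a for a in select_anchors(slide)}
        a = anchors["PC_r01c1s1"]
        assert a.pci == 25
        third = sub.iloc[2]
        assert (a.row, a.col) == (int(third["row"]), int(third["col"]))

    def test_median_anchored_at_attaining_spot(self, default_layout):
        slide = make_slide(default_layout, np.ones(default_layout.n_spots))
        sub = set_control_intensities(slide, "PC_r01c1s1", [40, 10, 30, 20, 50])
        a = {x.set_id: x for x in select_anchors(slide)}["PC_r01c1s1"]
        assert a.pci == 30
        holder = sub[np.isclose(
            slide.spots.loc[sub.index, "intensity"], 30)].iloc[0]
        assert (a.row, a.col) == (int(holder["row"]), int(holder["col"]))

    def test_even_count_takes_lower_median(self, default_layout):
        slide = make_slide(default_layout, np.ones(default_layout.n_spots))
        sub = set_control_intensities(slide, "PC_r01c1s1", [40, 10, 30, 20, 50])
        slide.spots.loc[sub.index[1], "valid"] = False  # drop the 10
        a = {x.set_id: x for x in select_anchors(slide)}["PC_r01c1s1"]
        assert a.pci == 30  # lower median of (20, 30, 40, 50)

    def test_constant_controls_give_constant_anchors(self, uniform_slide):
        anchors = select_anchors(uniform_slide)
        assert len(anchors) == 96
        assert all(a.pci == 1000.0 for a in anchors)

    def test_fixed_dilution_policy(self, default_layout):
        slide = make_slide(default_layout, np.ones(default_layout.n_spots))
        set_control_intensities(slide, "PC_r01c1s1", [100, 50, 25, 12.5, 6.25])
        a = {x.set_id: x
             for x in select_anchors(slide, policy="fixed:1")}["PC_r01c1s1"]
        assert a.pci == 100

    def test_dead_set_is_an_error_naming_it(self, default_layout):
        slide = make_slide(default_layout, np.ones(default_layout.n_spots))
        mask = slide.spots["sample_id"] == "PC_r05c2s2"
        slide.spots.loc[mask, "valid"] = False
        with pytest.raises(AnchorSelectionError, match="PC_r05c2s2"):
            select_anchors(slide)


class TestReference:
    def test_mean_examples(self):
        mk = lambda v: Anchor(1, 1, v, "s", 1, 1)
        assert compute_reference([mk(10), mk(20), mk(30)]) == 20
        assert compute_reference([mk(7.0)]) == 7.0
        with pytest.raises(AnchorSelectionError):
            compute_reference([])

    def test_mean_matches_summation_oracle(self):
        rng = np.random.default_rng(42)
        vals = rng.lognormal(8, 0.4, size=96)
        anchors = [Anchor(1, 1, v, f"s{i}", 1, i) for i, v in enumerate(vals)]
        direct = sum(vals) / len(vals)
        assert compute_reference(anchors) == pytest.approx(direct, rel=1e-12)


def unit_lattice(values):
    return AnchorLattice(rows=np.array([0.0, 1.0]), cols=np.array([0.0, 1.0]),
                         values=np.asarray(values, dtype=float))


class TestBilinear:
    def test_cell_centre_closed_form(self):
        # corners 1,2,3,4 row-major; closed form at the centre: mean = 2.5
        lat = unit_lattice([[1.0, 2.0], [3.0, 4.0]])
        assert bilinear_interpolate(lat, 0.5, 0.5) == pytest.approx(2.5)

    def test_corner_knot_property(self):
        lat = unit_lattice([[1.0, 2.0], [3.0, 4.0]])
        for (r, c), v in zip([(0, 0), (0, 1), (1, 0), (1, 1)], [1, 2, 3, 4]):
            assert bilinear_interpolate(lat, r, c) == pytest.approx(v)

    def test_constant_corners(self):
        lat = unit_lattice([[3.3] * 2] * 2)
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 1, size=(20, 2))
        np.testing.assert_allclose(
            bilinear_interpolate(lat, pts[:, 0], pts[:, 1]), 3.3)

    def test_exterior_signals(self):
        lat = unit_lattice([[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ExteriorQueryError):
            bilinear_interpolate(lat, -0.5, 0.5)

    @given(
        corners=st.lists(st.floats(0.1, 100.0), min_size=4, max_size=4),
        r=st.floats(0.0, 1.0), c=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_bounded_by_corners(self, corners, r, c):
        lat = unit_lattice(np.array(corners).reshape(2, 2))
        v = float(bilinear_interpolate(lat, r, c))
        assert min(corners) - 1e-9 <= v <= max(corners) + 1e-9


class TestNearestExtrapolation:
    def test_axis_aligned_clamp(self):
        lat = unit_lattice([[1.0, 2.0], [3.0, 4.0]])
        # directly above the top edge -> value on the edge below
        assert extrapolate_nearest(lat, -1.0, 0.5) == pytest.approx(
            bilinear_interpolate(lat, 0.0, 0.5))

    def test_interior_consistency(self):
        lat = unit_lattice([[1.0, 2.0], [3.0, 4.0]])
        assert extrapolate_nearest(lat, 0.3, 0.7) == pytest.approx(
            float(bilinear_interpolate(lat, 0.3, 0.7)))

    def test_matches_brute_force_nearest_search(self, toy_layout):
        """50 seeded exterior queries vs exhaustive nearest-covered-point."""
        rng = np.random.default_rng(11)
        slide = make_slide(toy_layout, rng=rng)
        surf = build_surface(slide, policy="fixed:3")
        lat = surf.lattice
        r0, r1, c0, c1 = lat.bounds
        covered = [(r, c)
                   for r in range(int(r0), int(r1) + 1)
                   for c in range(int(c0), int(c1) + 1)]
        queries = []
        while len(queries) < 50:
            q = (int(rng.integers(1, toy_layout.n_rows + 1)),
                 int(rng.integers(1, toy_layout.n_cols + 1)))
            if not lat.contains(*q):
                queries.append(q)
        for (qr, qc) in queries:
            best = min(covered,
                       key=lambda p: ((p[0] - qr) ** 2 + (p[1] - qc) ** 2,
                                      p[0], p[1]))
            expected = float(bilinear_interpolate(lat, *best))
            got = float(extrapolate_nearest(lat, qr, qc))
            assert got == pytest.approx(expected, rel=1e-12)


class TestSurface:
    def test_uniform_controls_identity(self, uniform_slide):
        surf = build_surface(uniform_slide)
        np.testing.assert_allclose(surf.cf, 1.0, rtol=1e-12)
        norm = apply_correction(uniform_slide, surf)
        np.testing.assert_allclose(
            norm.corrected, uniform_slide.spots["intensity"], rtol=1e-12)

    def test_scale_equivariance(self, default_layout):
        slide = make_slide(default_layout, rng=np.random.default_rng(3))
        scaled = make_slide(default_layout,
                            slide.spots["intensity"].to_numpy() * 2.0)
        s1, s2 = build_surface(slide), build_surface(scaled)
        np.testing.assert_allclose(s2.cf, s1.cf, rtol=1e-12)
        n1 = apply_correction(slide, s1)
        n2 = apply_correction(scaled, s2)
        np.testing.assert_allclose(n2.corrected, 2.0 * n1.corrected, rtol=1e-12)

    def test_knot_property_at_lattice_nodes(self, default_layout):
        slide = make_slide(default_layout, rng=np.random.default_rng(5))
        surf = build_surface(slide)
        lat = surf.lattice
        rr, cc = np.meshgrid(lat.rows, lat.cols, indexing="ij")
        np.testing.assert_allclose(
            bilinear_interpolate(lat, rr.ravel(), cc.ravel()),
            lat.values.ravel(), rtol=1e-12)

    def test_anchor_spots_correct_to_reference(self, default_layout):
        """Jitter-free anchors divided by their own CF land on <PCI>."""
        cfg = SimulationConfig(layout=default_layout, noise_sigma_log=0.0,
                               bias=cellwise_bilinear(default_layout, seed=9))
        slide, _ = simulate_slide(cfg, seed=9)
        norm = normalize_slide(slide)
        idx = slide.spots.set_index(["row", "col"]).index
        pos = {(a.row, a.col) for a in norm.surface.anchors}
        at_anchor = np.array([p in pos for p in idx])
        np.testing.assert_allclose(norm.corrected[at_anchor],
                                   norm.surface.reference, rtol=1e-9)

    def test_cellwise_bias_recovered_exactly(self, default_layout):
        cfg = SimulationConfig(layout=default_layout, noise_sigma_log=0.0,
                               bias=cellwise_bilinear(default_layout, seed=21))
        slide, truth = simulate_slide(cfg, seed=21)
        surf = build_surface(slide)
        np.testing.assert_allclose(surf.cf, truth.bias, rtol=1e-9)
        norm = apply_correction(slide, surf)
        np.testing.assert_allclose(norm.corrected, truth.true_intensity,
                                   rtol=1e-9)

    def test_clamping_bounds_and_logging(self, default_layout):
        slide = make_slide(default_layout, np.ones(default_layout.n_spots))
        # one dead region: crush an entire control set far below the rest
        set_control_intensities(slide, "PC_r01c1s1", [1e-4] * 5)
        surf = build_surface(slide, clamp_bounds=(0.5, 2.0))
        assert surf.n_clamped > 0
        assert surf.cf.min() >= 0.5 and surf.cf.max() <= 2.0
        assert surf.cf_raw.min() < 0.5

    def test_invalid_spots_still_corrected(self, default_layout):
        slide = make_slide(default_layout, rng=np.random.default_rng(2))
        slide.spots.loc[0, "valid"] = False
        norm = normalize_slide(slide)
        assert np.isfinite(norm.corrected[0])
        assert not norm.slide.spots.loc[0, "valid"]

    def test_coverage_mismatch_is_error(self, default_layout, toy_layout):
        surf = build_surface(make_slide(toy_layout))
        with pytest.raises(ValueError, match="cover"):
            apply_correction(make_slide(default_layout), surf)


class TestSpline:
    def test_constant_field_gives_unit_cf(self, uniform_slide):
        surf = spline_surface(uniform_slide)
        assert surf.method == "spline"
        np.testing.assert_allclose(surf.cf, 1.0, rtol=1e-9)

    def test_knot_property(self, default_layout):
        slide = make_slide(default_layout, rng=np.random.default_rng(8))
        surf = build_surface(slide, method="spline")
        lat = surf.lattice
        rr, cc = np.meshgrid(lat.rows, lat.cols, indexing="ij")
        np.testing.assert_allclose(
            _spline_evaluate(lat, rr.ravel(), cc.ravel()),
            lat.values.ravel(), rtol=1e-9)

    def test_reproduces_bicubic_polynomial(self):
        """An interpolating bicubic spline is exact on cubic surfaces."""
        rows = np.linspace(0.0, 10.0, 6)
        cols = np.linspace(0.0, 8.0, 5)
        poly = lambda r, c: (1 + 0.1 * r + 0.02 * r**2 - 0.001 * r**3) * \
            (2 + 0.05 * c - 0.01 * c**2 + 0.002 * c**3)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        lat = AnchorLattice(rows=rows, cols=cols, values=poly(rr, cc))
        rng = np.random.default_rng(4)
        qr = rng.uniform(0, 10, 200)
        qc = rng.uniform(0, 8, 200)
        np.testing.assert_allclose(_spline_evaluate(lat, qr, qc),
                                   poly(qr, qc), rtol=1e-8)

    def test_small_lattice_falls_back_to_bilinear(self, toy_layout):
        slide = make_slide(toy_layout)
        with pytest.warns(UserWarning, match="falling back"):
            surf = build_surface(slide, method="spline")
        assert surf.method == "bilinear"


class TestLatticeAssembly:
    def test_incomplete_lattice_rejected(self):
        anchors = [Anchor(1, 1, 1.0, "a", 1, 1), Anchor(1, 5, 1.0, "b", 1, 2),
                   Anchor(5, 1, 1.0, "c", 2, 1)]
        with pytest.raises(AnchorSelectionError, match="lattice"):
            assemble_lattice(anchors)

    def test_jittered_positions_averaged(self):
        # column positions jitter +/-1 around 1 and 5; lines use the means
        anchors = [
            Anchor(1, 1, 1.0, "a", 1, 1), Anchor(1, 5, 2.0, "b", 1, 2),
            Anchor(5, 2, 3.0, "c", 2, 1), Anchor(5, 4, 4.0, "d", 2, 2),
        ]
        lat = assemble_lattice(anchors)
        np.testing.assert_allclose(lat.rows, [1.0, 5.0])
        np.testing.assert_allclose(lat.cols, [1.5, 4.5])
        np.testing.assert_allclose(lat.values, [[1, 2], [3, 4]])
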