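import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smaddyn.imagequant import (CellMeasurement, Kymograph, MaskError,
                                RadialProfile, expression_domain, measure_cells,
                                normalize_channel, profiles_to_kymograph,
                                radial_profile, restriction_time,
                                segment_fixture, track_front, LabeledImage)
from smaddyn.synth import RenderParams, render_cell_field


def _uniform_cell_image(nuc=30.0, cyt=20.0, bg=10.0):
    """One square 'cell': 4x4 nucleus, 2-px cytoplasm frame, background."""
    img = np.full((16, 16), bg)
    nuclear = np.zeros((16, 16), dtype=np.int32)
    cyto = np.zeros((16, 16), dtype=np.int32)
    nuclear[6:10, 6:10] = 1
    cyto[4:12, 4:12] = 1
    cyto[nuclear > 0] = 0
    img[cyto > 0] = cyt
    img[nuclear > 0] = nuc
    background = (nuclear == 0) & (cyto == 0)
    return LabeledImage(intensity={"signal": img}, nuclear_labels=nuclear,
                        cyto_labels=cyto, background_mask=background,
                        pixel_size=1.0)


class TestMeasureCells:
    def test_background_subtracted_ratio(self):
        cells = measure_cells(_uniform_cell_image(30, 20, 10))
        assert len(cells) == 1
        assert cells[0].nc_ratio == pytest.approx(2.0)

    def test_equal_nuc_cyt_gives_unity(self):
        cells = measure_cells(_uniform_cell_image(25, 25, 0))
        assert cells[0].nc_ratio == pytest.approx(1.0)

    @given(offset=st.floats(-5.0, 50.0), scale=st.floats(0.1, 10.0))
    @settings(max_examples=40, deadline=None)
    def test_offset_and_scale_invariance(self, offset, scale):
        """Background subtraction cancels offsets; the ratio cancels gains."""
        base = _uniform_cell_image(30, 20, 10)
        transformed = LabeledImage(
            intensity={"signal": scale * base.intensity["signal"] + offset},
            nuclear_labels=base.nuclear_labels, cyto_labels=base.cyto_labels,
            background_mask=base.background_mask, pixel_size=1.0)
        r0 = measure_cells(base)[0].nc_ratio
        r1 = measure_cells(transformed)[0].nc_ratio
        assert r1 == pytest.approx(r0, rel=1e-9)

    def test_nonpositive_cytoplasm_excluded_with_warning(self):
        img = _uniform_cell_image(nuc=30, cyt=5, bg=10)  # cyt below background
        with pytest.warns(UserWarning, match="excluded 1"):
            cells = measure_cells(img)
        assert cells == []

    def test_empty_background_raises(self):
        img = _uniform_cell_image()
        img.background_mask = np.zeros_like(img.background_mask)
        with pytest.raises(MaskError, match="background"):
            measure_cells(img)

    def test_rendered_field_recovered_within_two_percent(self):
        """Generator closure: 200 noisy cells, known ratio 1.5."""
        rp = RenderParams(shape=(512, 512), n_cells=200)
        images, masks, truth = render_cell_field([1.5] * 200, rp, seed=4)
        img = LabeledImage(intensity=images, pixel_size=1.0, **masks)
        cells = measure_cells(img, channel="signal")
        assert len(cells) == 200
        mean_ratio = np.mean([c.nc_ratio for c in cells])
        assert mean_ratio == pytest.approx(1.5, rel=0.02)


def _cells_at(radii_values, angle=0.3):
    out = []
    for i, (r, v) in enumerate(radii_values, start=1):
        x = 400 + r * math.cos(angle + i)
        y = 400 + r * math.sin(angle + i)
        out.append(CellMeasurement(cell_id=i, nuc_mean=0, cyt_mean=0, bg_mean=0,
                                   nc_ratio=v, centroid=(x, y)))
    return out


class TestRadialProfile:
    def test_constant_field_constant_profile(self):
        cells = _cells_at([(r, 1.7) for r in (15, 55, 95, 135, 175)])
        prof = radial_profile(cells, center=(400, 400), bin_width=40,
                              colony_radius=200)
        filled = np.isfinite(prof.values)
        assert np.allclose(prof.values[filled], 1.7)

    def test_two_population_step(self):
        cells = _cells_at([(r, 1.0) for r in (10, 50, 90, 130)]
                          + [(r, 2.0) for r in (170, 190)])
        prof = radial_profile(cells, center=(400, 400), bin_width=40,
                              colony_radius=200)
        assert np.allclose(prof.values[:4], 1.0)
        assert prof.values[4] == pytest.approx(2.0)

    def test_single_cell_single_bin(self):
        prof = radial_profile(_cells_at([(50, 1.2)]), center=(400, 400),
                              bin_width=40, colony_radius=200)
        assert np.isfinite(prof.values).sum() == 1
        assert prof.n_cells_per_bin.sum() == 1

    def test_empty_bins_are_missing_not_zero(self):
        prof = radial_profile(_cells_at([(50, 1.2)]), center=(400, 400),
                              bin_width=40, colony_radius=200)
        assert np.isnan(prof.values[0])

    def test_rotation_invariance(self):
        """A radially symmetric colony profiles identically after rotation."""
        rng = np.random.default_rng(0)
        radii = rng.uniform(5, 340, 400)
        values = 1.0 + 1.0 / (1.0 + np.exp(-(radii - 300) / 10))

        def profile(theta0):
            angles = rng2 + theta0
            cells = [CellMeasurement(cell_id=i, nuc_mean=0, cyt_mean=0,
                                     bg_mean=0, nc_ratio=v,
                                     centroid=(400 + r * math.cos(a),
                                               400 + r * math.sin(a)))
                     for i, (r, v, a) in enumerate(zip(radii, values, angles))]
            return radial_profile(cells, center=(400, 400), bin_width=20,
                                  colony_radius=350)

        rng2 = rng.uniform(0, 2 * math.pi, 400)
        p0 = profile(0.0)
        p1 = profile(1.234)
        np.testing.assert_allclose(p0.values, p1.values, rtol=0.02)


class TestNormalization:
    def _kym(self, mat, **kw):
        mat = np.asarray(mat, dtype=float)
        return Kymograph(r_centers=np.arange(mat.shape[1]) * 20.0 + 10.0,
                         t=np.arange(mat.shape[0], dtype=float), matrix=mat, **kw)

    def test_minmax_row(self):
        out = normalize_channel(self._kym([[1.0, 3.0, 5.0]]), "minmax")
        np.testing.assert_allclose(out.matrix[0], [0.0, 0.5, 1.0])

    def test_minmax_idempotent(self):
        once = normalize_channel(self._kym([[1.0, 3.0, 5.0], [2.0, 2.5, 4.0]]),
                                 "minmax")
        twice = normalize_channel(once, "minmax")
        np.testing.assert_allclose(once.matrix, twice.matrix)

    def test_minmax_constant_row_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="constant row"):
            out = normalize_channel(self._kym([[2.0, 2.0, 2.0]]), "minmax")
        np.testing.assert_allclose(out.matrix[0], 0.0)

    def test_bra_rule_divides_by_final_row_max(self):
        out = normalize_channel(self._kym([[1.0, 2.0], [2.0, 4.0]]), "bra_rule")
        assert out.matrix[-1].max() == pytest.approx(1.0)
        np.testing.assert_allclose(out.matrix, [[0.25, 0.5], [0.5, 1.0]])

    def test_smad4_rule_interior_reference(self):
        # pSMAD1 half-max sits at r = 300 um; SMAD4 interior max (2.0) at 250
        r = np.arange(10.0, 350.0, 20.0)
        psmad1 = 1.0 / (1.0 + np.exp(-(r - 300) / 5.0))
        smad4 = np.where(r > 320, 3.0, np.where(np.isclose(r, 250.0), 2.0, 1.0))
        aux = Kymograph(r_centers=r, t=np.array([0.0]), matrix=psmad1[None, :])
        kym = Kymograph(r_centers=r, t=np.array([0.0]), matrix=smad4[None, :])
        out = normalize_channel(kym, "smad4_rule", auxiliary=aux)
        i250 = int(np.argmin(np.abs(r - 250.0)))
        assert out.matrix[0, i250] == pytest.approx(1.0)

    def test_smad4_rule_requires_auxiliary(self):
        with pytest.raises(ValueError, match="auxiliary"):
            normalize_channel(self._kym([[1.0, 2.0]]), "smad4_rule")

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            normalize_channel(self._kym([[1.0, 2.0]]), "zscore")


def _front_kym(shift_per_frame, n_frames=30, noise=0.0, seed=0):
    """Logistic front translated inward by a fixed amount per frame."""
    r = np.arange(10.0, 350.0, 20.0)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_frames):
        c = 300.0 - shift_per_frame * i
        row = 1.0 / (1.0 + np.exp(-(r - c) / 9.0))
        rows.append(row + rng.normal(0, noise, r.shape))
    return Kymograph(r_centers=r, t=np.arange(n_frames, dtype=float),
                     matrix=np.array(rows), meta={"colony_radius": 350.0})


class TestFrontTracking:
    def test_static_profile_zero_velocity(self):
        kym = _front_kym(0.0)
        ft = track_front(kym, window=(5.0, 25.0))
        assert ft.velocity == pytest.approx(0.0, abs=1e-9)
        assert math.isnan(ft.onset_time)

    def test_exact_translation_speed_recovered(self):
        # window spans several 20-um bin periods so the interpolation wobble
        # of the sampled logistic averages out of the fitted slope
        kym = _front_kym(7.0)
        ft = track_front(kym, window=(2.0, 26.0))
        assert ft.velocity == pytest.approx(7.0, rel=0.01)

    def test_onset_requires_prior_edge_presence(self):
        kym = _front_kym(7.0)
        ft = track_front(kym, window=(2.0, 6.0))
        # front starts at 300 um (within one bin of the 315 um edge zone) and
        # departs past 295 um after the first ~0.7 hr of motion
        assert ft.onset_time == pytest.approx(1.0, abs=1.0)

    def test_rows_without_crossing_are_missing(self):
        kym = _front_kym(0.0)
        kym.matrix[3] = 0.9  # uniformly high: no 0.5 crossing
        ft = track_front(kym, window=(5.0, 25.0))
        assert math.isnan(ft.r_half[3])
        assert np.isfinite(np.delete(ft.r_half, 3)).all()


class TestRestrictionAndDomain:
    def test_restriction_time_of_programmed_shutdown(self):
        r = np.arange(10.0, 350.0, 20.0)
        t = np.arange(0.0, 25.0, 1.0)
        band = 1.0 / (1.0 + np.exp(-(r - 300) / 9.0))
        interior = np.exp(-t / 5.0)
        mat = np.maximum(interior[:, None], band[None, :])
        kym = Kymograph(r_centers=r, t=t, matrix=mat,
                        meta={"colony_radius": 350.0})
        # interior/edge crosses 0.5 when exp(-t/5) = 0.5 -> t = 3.47
        assert restriction_time(kym) == pytest.approx(4.0, abs=1.0)

    def test_constant_profile_spans_colony(self):
        prof = RadialProfile(r_centers=np.arange(10.0, 350.0, 20.0),
                             values=np.full(17, 2.0),
                             n_cells_per_bin=np.ones(17))
        domain = expression_domain(prof)
        assert domain[0] == 0.0
        assert domain[1] == pytest.approx(330.0)

    def test_triangular_profile_boundary_at_twenty_percent(self):
        r = np.linspace(0, 350, 141)
        prof = RadialProfile(r_centers=r, values=r / 350.0,
                             n_cells_per_bin=np.ones_like(r))
        domain = expression_domain(prof, threshold_fraction=0.20)
        assert domain[0] == pytest.approx(70.0, abs=1.0)

    def test_zero_profile_flagged_empty(self):
        prof = RadialProfile(r_centers=np.arange(5), values=np.zeros(5),
                             n_cells_per_bin=np.ones(5))
        with pytest.warns(UserWarning, match="no positive"):
            assert expression_domain(prof) is None


class TestSegmentation:
    def test_counts_well_separated_nuclei(self):
        rp = RenderParams(shape=(256, 256), n_cells=25, poisson_noise=False,
                          read_noise_sd=0.0)
        images, _masks, truth = render_cell_field([1.5] * 25, rp, seed=9)
        img = segment_fixture(images)
        assert len(img.labels) == 25

    def test_blank_image_no_labels_no_error(self):
        images = {"dapi": np.zeros((64, 64)), "signal": np.zeros((64, 64))}
        img = segment_fixture(images)
        assert len(img.labels) == 0

    def test_touching_nuclei_split_by_watershed(self):
        img = np.zeros((40, 40))
        yy, xx = np.mgrid[0:40, 0:40]
        img[(yy - 20) ** 2 + (xx - 15) ** 2 <= 25] = 100.0
        img[(yy - 20) ** 2 + (xx - 24) ** 2 <= 25] = 100.0  # touching pair
        seg = segment_fixture({"dapi": img}, seed_min_distance=4)
        assert len(seg.labels) == 2

    def test_measurement_pipeline_on_segmented_render(self):
        rp = RenderParams(shape=(256, 256), n_cells=30, poisson_noise=False,
                          read_noise_sd=0.0)
        images, _m, truth = render_cell_field([2.0] * 30, rp, seed=2)
        seg = segment_fixture(images)
        cells = measure_cells(seg, channel="signal")
        assert len(cells) == 30
        ratios = [c.nc_ratio for c in cells]
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.02)
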