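"""ROI scheme, relative differences, group statistics, MLD screen."""

import dataclasses

import numpy as np
import pytest

import muacsim as m
from muacsim import regional as reg
from muacsim.attenuation import LungMask
from muacsim.errors import GeometryError, InputError


@pytest.fixture(scope="module")
def lung_mask(small_phantom):
    return LungMask(small_phantom.lung_mask)


@pytest.fixture(scope="module")
def rois(lung_mask, small_phantom):
    return m.place_rois(lung_mask, small_phantom.spacing_mm)


class TestROIPlacement:
    def test_exactly_twelve_rois(self, rois):
        assert len(rois) == 12
        combos = {(r.side, r.level, r.position) for r in rois}
        assert len(combos) == 12

    def test_all_roi_voxels_inside_mask(self, rois, lung_mask, small_phantom):
        for roi in rois:
            rr, cc = reg.roi_voxels(roi, lung_mask.mask.shape[1:],
                                    small_phantom.spacing_mm)
            assert lung_mask.mask[roi.slice_index][rr, cc].all()

    def test_symmetric_phantom_gives_mirrored_centers(self, rois, lung_mask):
        n = lung_mask.mask.shape[2]
        by_key = {(r.side, r.level, r.position): r for r in rois}
        for level in reg.LEVELS:
            for pos in reg.POSITIONS:
                left = by_key[("left", level, pos)]
                right = by_key[("right", level, pos)]
                assert left.center_vox[0] == right.center_vox[0]
                assert left.center_vox[1] == pytest.approx(
                    n - 1 - right.center_vox[1], abs=1.0)

    def test_tiny_lung_raises_placement_error(self):
        mask = np.zeros((1, 40, 40), dtype=bool)
        mask[0, 18:21, 8:10] = True   # "left" blob, far too small for 10 mm
        mask[0, 18:21, 30:32] = True
        with pytest.raises(GeometryError):
            m.place_rois(LungMask(mask), spacing_mm=2.6)


class TestROIMean:
    def test_constant_image(self, rois, small_phantom):
        img = np.full(small_phantom.hu_volume.shape, 3.14)
        for roi in rois[:3]:
            assert m.roi_mean(img, roi, small_phantom.spacing_mm) \
                == pytest.approx(3.14)

    def test_matches_voxel_loop_brute_force(self, rois, small_phantom, rng):
        img = rng.random(small_phantom.hu_volume.shape)
        roi = rois[5]
        rr, cc = reg.roi_voxels(roi, img.shape[1:], small_phantom.spacing_mm)
        total, count = 0.0, 0
        for r, c in zip(rr, cc):
            total += img[roi.slice_index, r, c]
            count += 1
        assert m.roi_mean(img, roi, small_phantom.spacing_mm) \
            == pytest.approx(total / count)

    def test_posterior_roi_reads_posterior_lung_density(self, rois,
                                                        small_phantom):
        posterior = [r for r in rois if r.position == "posterior"]
        for roi in posterior:
            hu = m.roi_mean(small_phantom.hu_volume, roi,
                            small_phantom.spacing_mm)
            assert hu == pytest.approx(-685.0, abs=25.0)

    def test_out_of_bounds_roi_rejected(self, small_phantom):
        roi = reg.ROISpec("left", "hilum", "anterior", 0, (1.0, 1.0), 10.0)
        with pytest.raises(GeometryError):
            m.roi_mean(small_phantom.hu_volume, roi, small_phantom.spacing_mm)


class TestRelativeDifference:
    @pytest.mark.parametrize("x, ref, expected", [
        (0.47, 0.47, 0.0),
        (0.42, 0.47, -10.638297872340425),
        (0.94, 0.47, 100.0),
    ])
    def test_formula(self, x, ref, expected):
        assert m.relative_difference(x, ref) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(InputError):
            m.relative_difference(0.4, 0.0)


class TestRegionalSummary:
    @staticmethod
    def _measurements(values):
        """Build a full 12-ROI set with given per-position CTAC SUVs."""
        out = []
        for side in reg.SIDES:
            for level in reg.LEVELS:
                for pos in reg.POSITIONS:
                    suv_ref = values[pos]
                    out.append(m.ROIMeasurement(
                        roi=reg.ROISpec(side, level, pos, 0, (10.0, 10.0)),
                        suv_mean={"CTAC": suv_ref, "MRAC": suv_ref * 0.9},
                        hu_mean=-700.0))
        return out

    def test_identical_rois_give_zero_spread(self):
        rep = m.regional_summary(self._measurements(
            {"anterior": 0.4, "middle": 0.4, "posterior": 0.4}))
        for pos in reg.POSITIONS:
            mean, sd = rep.suv_mean_sd(pos, "CTAC")
            assert (mean, sd) == (0.4, 0.0)
            relmean, relsd = rep.reldiff_mean_sd(pos, "MRAC")
            assert relmean == pytest.approx(-10.0)
            assert relsd == pytest.approx(0.0)
            assert np.all(rep.reldiff_by_region[pos]["CTAC"] == 0.0)

    def test_hand_built_fixture_matches_arithmetic(self):
        meas = self._measurements(
            {"anterior": 0.3, "middle": 0.4, "posterior": 0.5})
        # perturb one anterior ROI to create spread
        meas[0].suv_mean = {"CTAC": 0.5, "MRAC": 0.4}
        rep = m.regional_summary(meas)
        vals = [0.5, 0.3, 0.3, 0.3]  # anterior CTAC per (side, level)
        assert rep.suv_mean_sd("anterior", "CTAC")[0] \
            == pytest.approx(np.mean(vals))
        assert rep.suv_mean_sd("anterior", "CTAC")[1] \
            == pytest.approx(np.std(vals, ddof=1))
        rel = [(0.4 - 0.5) / 0.5 * 100] + [-10.0] * 3
        assert rep.reldiff_mean_sd("anterior", "MRAC")[0] \
            == pytest.approx(np.mean(rel))
        assert rep.ap_suv_gradient("CTAC") == pytest.approx(0.5 - 0.35)

    def test_incomplete_roi_set_rejected(self):
        meas = self._measurements(
            {"anterior": 0.3, "middle": 0.4, "posterior": 0.5})[:7]
        with pytest.raises(InputError):
            m.regional_summary(meas)


class TestCompareGroups:
    def test_identical_groups_adjusted_p_is_one(self):
        cmp = m.compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert cmp.anova_p == pytest.approx(1.0, abs=1e-9) or cmp.anova_p > 0.99
        assert cmp.pairwise_p[("a", "b")] == 1.0

    def test_f_statistic_matches_textbook_formula(self):
        groups = {"g1": np.array([1.0, 2, 3, 4, 5]),
                  "g2": np.array([2.0, 3, 4, 5, 6]),
                  "g3": np.array([4.0, 5, 6, 7, 8])}
        data = np.concatenate(list(groups.values()))
        grand = data.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups.values())
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
        f_hand = (ssb / 2) / (ssw / 12)
        cmp = m.compare_groups(groups)
        assert cmp.anova_f == pytest.approx(f_hand, rel=1e-6)

    def test_bonferroni_factor_equals_number_of_pairs(self):
        from scipy import stats
        groups = {"a": np.array([1.0, 2, 3]), "b": np.array([2.0, 3, 4]),
                  "c": np.array([10.0, 11, 12])}
        cmp = m.compare_groups(groups)
        raw = stats.ttest_ind(groups["a"], groups["b"]).pvalue
        assert cmp.pairwise_p[("a", "b")] == pytest.approx(
            min(1.0, raw * 3), rel=1e-9)

    def test_degenerate_variance_unequal_means(self):
        cmp = m.compare_groups({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert cmp.anova_p == 0.0
        assert cmp.pairwise_p[("a", "b")] == 0.0

    def test_significance_ranking_matches_permutation_oracle(self, rng):
        """The ANOVA p-value ranks a clearly separated fixture as more
        significant than an overlapping one, in agreement with a
        permutation test on the F statistic."""
        def perm_p(groups, n_perm=2000):
            from scipy import stats
            f_obs = stats.f_oneway(*groups).statistic
            data = np.concatenate(groups)
            sizes = [len(g) for g in groups]
            count = 0
            for _ in range(n_perm):
                rng.shuffle(data)
                parts = np.split(data, np.cumsum(sizes)[:-1])
                if stats.f_oneway(*parts).statistic >= f_obs:
                    count += 1
            return (count + 1) / (n_perm + 1)

        separated = [rng.normal(0, 1, 8), rng.normal(4, 1, 8)]
        overlapping = [rng.normal(0, 1, 8), rng.normal(0.3, 1, 8)]
        p_sep = m.compare_groups({"a": separated[0], "b": separated[1]}).anova_p
        p_ovl = m.compare_groups({"a": overlapping[0],
                                  "b": overlapping[1]}).anova_p
        assert p_sep < p_ovl
        assert (perm_p(separated) < perm_p(overlapping)) == (p_sep < p_ovl)


class TestMLDScreen:
    def test_healthy_phantom_flags_nothing(self, small_phantom, lung_mask):
        report = m.mld_screen(small_phantom.hu_volume, lung_mask)
        assert len(report.segments) == 6
        assert report.n_flagged == 0
        names = {(s.lung, s.segment) for s in report.segments}
        assert len(names) == 6

    def test_emphysematous_lung_flags_three_segments(self, small_phantom,
                                                     lung_mask):
        from muacsim import phantom as ph
        hu = small_phantom.hu_volume.copy()
        hu[small_phantom.label_volume == ph.LUNG_LEFT] = -980.0
        report = m.mld_screen(hu, lung_mask)
        flagged = [s for s in report.segments if s.emphysema_flag]
        assert len(flagged) == 3
        assert all(s.lung == "left" for s in flagged)

    def test_cutoff_is_strict(self, small_phantom, lung_mask):
        hu = np.where(small_phantom.lung_mask, -950.0,
                      small_phantom.hu_volume)
        report = m.mld_screen(hu, lung_mask)
        assert report.n_flagged == 0
        hu2 = np.where(small_phantom.lung_mask, -950.0 - 1e-9,
                       small_phantom.hu_volume)
        assert m.mld_screen(hu2, lung_mask).n_flagged == 6

    def test_multislice_uses_craniocaudal_axis(self, small_phantom_config):
        cfg = dataclasses.replace(small_phantom_config, n_slices=6)
        phantom = m.generate_thorax_phantom(cfg)
        mask = LungMask(phantom.lung_mask)
        hu = phantom.hu_volume.copy()
        hu[:2][phantom.lung_mask[:2]] = -990.0  # upper third pathologic
        report = m.mld_screen(hu, mask)
        flagged = {(s.lung, s.segment) for s in report.segments
                   if s.emphysema_flag}
        assert flagged == {("left", "upper"), ("right", "upper")}
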