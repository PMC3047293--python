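import numpy as np
import pytest

import sfindex as s
from sfindex.hemifield import REGION_IDS
from sfindex.io_model import ValidationError


class TestRegionMap:
    @pytest.mark.parametrize("laterality", ["right", "left"])
    def test_ten_disjoint_mirror_paired_clusters_cover_grid(self, laterality):
        rmap = s.default_regions(laterality)
        assert len(rmap.regions) == 10
        all_points = [p for pts in rmap.regions.values() for p in pts]
        assert len(all_points) == 52
        assert set(all_points) == set(s.grid_24_2(laterality))
        for r in REGION_IDS:
            sup = rmap.points(r, "superior")
            inf = rmap.points(r, "inferior")
            assert 3 <= len(sup) <= 6
            assert {s.FieldLocation(p.x, -p.y) for p in sup} == set(inf)

    def test_documented_region_sizes(self):
        rmap = s.default_regions("right")
        assert len(rmap.points(1, "superior")) == 3
        assert len(rmap.points(4, "superior")) == 6

    def test_hemifields_respect_horizontal_meridian(self):
        rmap = s.default_regions("right")
        for r in REGION_IDS:
            assert all(p.y > 0 for p in rmap.points(r, "superior"))
            assert all(p.y < 0 for p in rmap.points(r, "inferior"))


class TestPointScore:
    def test_cap_and_reference_values(self):
        assert s.point_score(0.999) == 100.0
        assert s.point_score(1.0) == 100.0
        assert s.point_score(0.0) == pytest.approx(0.1)
        assert s.point_score(0.9) == pytest.approx(1.0)

    def test_monotone_and_capped(self):
        xs = np.linspace(0, 1, 101)
        ys = [s.point_score(x) for x in xs]
        assert all(b >= a for a, b in zip(ys, ys[1:]))
        assert max(ys) == 100.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            s.point_score(1.1)
        with pytest.raises(ValueError):
            s.point_score(-0.01)


class TestRegionScore:
    def test_maximum_scores_by_region_size(self, sfi_result_factory):
        res = sfi_result_factory(value=0.999)
        rmap = s.default_regions("right")
        assert s.region_score(res, rmap.points(1, "superior")) == 300.0
        assert s.region_score(res, rmap.points(4, "superior")) == 600.0

    def test_floor_score(self, sfi_result_factory):
        res = sfi_result_factory(value=0.0)
        rmap = s.default_regions("right")
        assert s.region_score(res, rmap.points(1, "superior")) == pytest.approx(0.3)

    def test_bounds_for_all_regions(self, sfi_result_factory):
        rmap = s.default_regions("right")
        lo = s.region_scores(sfi_result_factory(value=0.0), rmap)
        hi = s.region_scores(sfi_result_factory(value=1.0), rmap)
        for (r, h), pts in rmap.regions.items():
            assert lo[(r, h)] == pytest.approx(0.1 * len(pts))
            assert hi[(r, h)] == pytest.approx(100.0 * len(pts))

    def test_missing_point_rejected(self, sfi_result_factory):
        res = sfi_result_factory(value=0.5)
        del res.values[s.FieldLocation(3, 15)]
        rmap = s.default_regions("right")
        with pytest.raises(ValidationError):
            s.region_score(res, rmap.points(3, "superior"))


class TestHtStatistics:
    def test_symmetric_field_has_zero_differences(self, sfi_result_factory):
        res = sfi_result_factory(value=0.37)
        diffs, total = s.ht_statistics(res, s.default_regions("right"))
        assert np.allclose(diffs, 0.0)

    def test_superior_only_damage_arithmetic(self, sfi_result_factory):
        """Superior SFI 0.9 (point score 1.0) vs inferior 0 (0.1): each paired
        difference is 0.9 per point."""
        rmap = s.default_regions("right")
        sup_vals = {
            p: 0.9 for r in REGION_IDS for p in rmap.points(r, "superior")
        }
        res = sfi_result_factory(value=0.0, values=sup_vals)
        diffs, total = s.ht_statistics(res, rmap)
        sizes = np.array([len(rmap.points(r, "superior")) for r in REGION_IDS])
        assert np.allclose(diffs, 0.9 * sizes)

    def test_all_zero_total_counts_points(self, sfi_result_factory):
        _, total = s.ht_statistics(
            sfi_result_factory(value=0.0), s.default_regions("right")
        )
        assert total == pytest.approx(52 * 0.1)


class TestHtReference:
    def test_six_samples_of_cohort_size(self, fitted_model):
        ref = fitted_model.ht_reference
        assert len(ref.diffs) == 5
        assert all(c.n == 500 for c in ref.diffs)
        assert ref.total.n == 500

    def test_refit_is_deterministic_and_permutation_invariant(
        self, reference_cohort, right_model, right_linkage, right_regions
    ):
        results = [
            s.score_eye(r, right_model, right_linkage) for r in reference_cohort[:60]
        ]
        a = s.fit_ht_reference(results, right_regions)
        b = s.fit_ht_reference(results[::-1], right_regions)
        for k in range(5):
            assert np.array_equal(a.diffs[k].sample, b.diffs[k].sample)
        assert np.array_equal(a.total.sample, b.total.sample)

    def test_insufficient_eyes_rejected(
        self, reference_cohort, right_model, right_linkage, right_regions
    ):
        results = [
            s.score_eye(r, right_model, right_linkage) for r in reference_cohort[:5]
        ]
        with pytest.raises(ValidationError):
            s.fit_ht_reference(results, right_regions)


class TestHtSummary:
    def test_median_difference_is_unremarkable(self, fitted_model):
        ref = fitted_model.ht_reference
        diffs = np.array([float(np.median(ref.diffs[k].sample)) for k in range(5)])
        total = float(np.median(ref.total.sample))
        out = s.ht_summary(diffs, total, ref)
        for k in range(5):
            assert out.abnormality_probs[f"diff_{k + 1}"] < 0.05

    def test_extreme_difference_hits_rank_bound(self, fitted_model):
        ref = fitted_model.ht_reference
        n = ref.diffs[0].n
        diffs = np.zeros(5)
        diffs[0] = ref.diffs[0].sample.max() + 1000.0
        total = float(np.median(ref.total.sample))
        out = s.ht_summary(diffs, total, ref)
        # two-sided extremity of the n/(n+1) clamp: (n-1)/(n+1), never 1
        assert out.abnormality_probs["diff_1"] == pytest.approx((n - 1) / (n + 1))
        assert out.summary < 1.0

    def test_summary_is_max_and_argmax_reported(self, fitted_model):
        ref = fitted_model.ht_reference
        diffs = np.array([0.0, 0.0, ref.diffs[2].sample.max() + 10, 0.0, 0.0])
        out = s.ht_summary(diffs, float(ref.total.sample.max() - 1e-9), ref)
        assert out.summary == max(out.abnormality_probs.values())
        assert out.argmax_statistic in out.abnormality_probs

    def test_monotone_under_growing_superior_damage(
        self, fitted_model, right_regions, sfi_result_factory
    ):
        ref = fitted_model.ht_reference
        summaries = []
        for level in (0.0, 0.3, 0.6, 0.9):
            sup_vals = {
                p: level
                for r in REGION_IDS
                for p in right_regions.points(r, "superior")
            }
            res = sfi_result_factory(value=0.0, values=sup_vals)
            out = s.score_eye_ht(res, right_regions, ref)
            summaries.append(out.summary)
        assert all(b >= a for a, b in zip(summaries, summaries[1:]))

    def test_one_sided_option(self, fitted_model):
        ref = fitted_model.ht_reference
        diffs = np.array([float(ref.diffs[k].sample.min()) - 5 for k in range(5)])
        total = float(np.median(ref.total.sample))
        two = s.ht_summary(diffs, total, ref, two_sided=True)
        one = s.ht_summary(diffs, total, ref, two_sided=False)
        # strongly negative differences are extreme two-sided, bland one-sided
        assert two.abnormality_probs["diff_1"] > 0.9
        assert one.abnormality_probs["diff_1"] < 0.1
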