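"""Dead-time correction, plane alignment, accumulation, ROI ratios."""

import numpy as np
import pytest

from littertrace import nanosims, synthetic
from littertrace.nanosims import (
    IonImageStack,
    accumulate,
    align_planes,
    dead_time_correct,
    dead_time_forward,
    ratio_map,
    roi_ratios,
)


class TestDeadTime:
    def test_zero_counts_unchanged(self):
        assert dead_time_correct(0.0) == 0.0

    def test_hand_evaluated_example(self):
        # 1000 counts, 1 ms dwell, 44 ns dead time: 1000 / (1 - 0.044)
        assert dead_time_correct(1000.0) == pytest.approx(1000.0 / 0.956, rel=1e-12)

    def test_forward_inverse_round_trip(self):
        n_true = np.array([0.0, 1.0, 50.0, 500.0, 5000.0, 2e4])
        back = dead_time_correct(dead_time_forward(n_true))
        assert np.allclose(back, n_true, rtol=1e-9)

    def test_monotone_never_below_measured(self):
        n = np.linspace(0, 2e4, 50)
        corrected = dead_time_correct(n)
        assert np.all(corrected >= n)
        assert np.all((corrected > n) == (n > 0))

    def test_saturation_names_pixel(self):
        counts = np.zeros((1, 2, 2))
        counts[0, 1, 0] = 1e3 / 44e-9 * 1e-3  # exactly at saturation
        with pytest.raises(ValueError, match=r"\(0, 1, 0\)"):
            dead_time_correct(counts)


def _stack_from(planes_12c14n, extra=None):
    counts = {"12C14N": np.asarray(planes_12c14n)}
    if extra:
        counts.update(extra)
    return IonImageStack(counts=counts)


class TestAlignment:
    def test_identical_planes_zero_shifts(self, rng):
        base = rng.poisson(50.0, size=(16, 16))
        stack = _stack_from(np.stack([base] * 5))
        aligned = align_planes(stack)
        assert aligned.shifts == [(0, 0)] * 5

    def test_injected_drift_recovered(self, scenario):
        stack, _, truth = synthetic.gen_ion_stacks(scenario, seed=2, drift=True)
        aligned = align_planes(stack, max_shift=5)
        # recovered shifts undo the injected ones
        recovered = [(-dy, -dx) for dy, dx in aligned.shifts]
        assert recovered == [tuple(s) for s in truth["shifts"]]

    def test_shift_beyond_window_warns(self, rng):
        base = np.zeros((24, 24))
        base[8:14, 8:14] = 200.0
        shifted = nanosims._shift_int(base, 6, 0)
        stack = _stack_from(np.stack([base, shifted]))
        with pytest.warns(UserWarning, match="search bound"):
            aligned = align_planes(stack, max_shift=3)
        assert max(abs(s) for s in aligned.shifts[1]) <= 3

    def test_all_zero_plane_skipped(self, rng):
        base = rng.poisson(30.0, size=(12, 12)).astype(float)
        stack = _stack_from(np.stack([base, np.zeros_like(base), base]))
        with pytest.warns(UserWarning, match="all-zero"):
            aligned = align_planes(stack)
        assert aligned.shifts[1] == (0, 0)

    def test_single_plane_rejected(self):
        stack = _stack_from(np.ones((1, 8, 8)))
        with pytest.raises(ValueError, match="2 planes"):
            align_planes(stack)

    def test_agrees_with_phase_correlation_oracle(self, rng):
        # independent registration route: skimage phase correlation
        from skimage.registration import phase_cross_correlation

        base = rng.poisson(200.0, size=(32, 32)).astype(float)
        for true_shift in [(2, -1), (-3, 2), (0, 3)]:
            shifted = nanosims._shift_int(base, *true_shift)
            stack = _stack_from(np.stack([base, shifted]))
            aligned = align_planes(stack, max_shift=5)
            oracle, _, _ = phase_cross_correlation(base, shifted, upsample_factor=1)
            assert aligned.shifts[1] == (-true_shift[0], -true_shift[1])
            assert tuple(int(v) for v in oracle) == (-true_shift[0], -true_shift[1])


class TestAccumulate:
    def test_identical_planes_sum(self):
        stack = _stack_from(np.full((40, 4, 4), 3.0))
        assert np.all(accumulate(stack)["12C14N"] == 120.0)

    def test_permutation_invariant(self, rng):
        planes = rng.poisson(20.0, size=(10, 8, 8)).astype(float)
        a = accumulate(_stack_from(planes))["12C14N"]
        b = accumulate(_stack_from(planes[::-1].copy()))["12C14N"]
        assert np.array_equal(a, b)

    def test_poisson_mean_within_3se(self, rng):
        lam, n_planes = 50.0, 40
        planes = rng.poisson(lam, size=(n_planes, 32, 32)).astype(float)
        acc = accumulate(_stack_from(planes))["12C14N"]
        se = np.sqrt(n_planes * lam / acc.size)
        assert abs(acc.mean() - n_planes * lam) < 3 * se


class TestRoiRatios:
    def test_no_13c_gives_zero_not_enriched(self):
        images = {"12C": np.full((4, 4), 100.0), "13C": np.zeros((4, 4)), "12C14N": np.full((4, 4), 10.0)}
        r = roi_ratios(images, np.ones((4, 4), bool))
        assert r.c13_ratio == 0.0
        assert not r.enriched

    def test_empty_mask_rejected(self):
        images = {"12C": np.ones((4, 4)), "13C": np.ones((4, 4))}
        with pytest.raises(ValueError, match="empty"):
            roi_ratios(images, np.zeros((4, 4), bool))

    def test_missing_denominator_reported_missing(self):
        images = {"12C": np.zeros((2, 2)), "13C": np.zeros((2, 2))}
        r = roi_ratios(images, np.ones((2, 2), bool))
        assert r.c13_ratio is None and r.c13_se is None

    def test_pooled_equals_count_weighted_pixel_mean(self, rng):
        # algebraic identity: sum(13C)/sum(12C+13C) equals the mean of
        # per-pixel ratios weighted by per-pixel total counts
        c12 = rng.poisson(80.0, size=(16, 16)).astype(float) + 1
        c13 = rng.poisson(2.0, size=(16, 16)).astype(float)
        images = {"12C": c12, "13C": c13}
        mask = np.ones((16, 16), bool)
        r = roi_ratios(images, mask)
        w = c12 + c13
        weighted = np.sum(w * (c13 / w)) / np.sum(w)
        assert r.c13_ratio == pytest.approx(weighted, rel=1e-12)

    def test_labeled_roi_recovered_within_3se(self, rng):
        images = synthetic.simulate_roi_counts(0.030, rng=rng)
        r = roi_ratios(images, np.ones(200, bool))
        assert abs(r.c13_ratio - 0.030) <= 3 * r.c13_se
        assert r.enriched

    def test_natural_abundance_rarely_enriched(self, rng):
        flags = []
        for _ in range(100):
            images = synthetic.simulate_roi_counts(0.011, rng=rng)
            flags.append(roi_ratios(images, np.ones(200, bool)).enriched)
        assert np.mean(flags) <= 0.01

    def test_generator_rois_recovered(self, ion_bundle):
        stack, masks, truth = ion_bundle
        images = accumulate(nanosims.correct_stack(stack))
        for region in ("hyphae", "bacteria", "EPS"):
            r = roi_ratios(images, masks[region], label=region)
            af = truth["atom_fraction"][region]
            assert abs(r.c13_ratio - af) <= 3 * r.c13_se
            assert r.enriched


class TestRatioMap:
    def test_uniform_images_uniform_map(self):
        images = {"12C": np.full((8, 8), 500.0), "13C": np.full((8, 8), 10.0)}
        m = ratio_map(images)
        assert np.allclose(m, 10.0 / 510.0)

    def test_infinite_floor_masks_everything(self):
        images = {"12C": np.full((8, 8), 500.0), "13C": np.full((8, 8), 10.0)}
        m = ratio_map(images, count_floor=np.inf)
        assert np.all(np.isnan(m))

    def test_two_region_means_within_3se(self, ion_bundle):
        stack, masks, truth = ion_bundle
        images = accumulate(nanosims.correct_stack(stack))
        m = ratio_map(images, count_floor=20)
        for region in ("hyphae", "POM"):
            vals = m[masks[region]]
            af = truth["atom_fraction"][region]
            total = (images["12C"] + images["13C"])[masks[region]].sum()
            se = np.sqrt(af * (1 - af) / total)
            assert abs(np.nanmean(vals) - af) <= 4 * se


class TestStackIO:
    def test_tiff_round_trip(self, tmp_path, scenario):
        stack, _, _ = synthetic.gen_ion_stacks(scenario, seed=5)
        nanosims.write_stack_dir(stack, tmp_path)
        back = nanosims.read_stack_dir(tmp_path)
        for sp in stack.counts:
            assert np.array_equal(back.counts[sp], stack.counts[sp])
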