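import warnings

import numpy as np
import pytest

from wmdamage import (
    LevelSelectionRules,
    TissueMaskSet,
    dice,
    flair_histogram_threshold,
    fuse_rg,
    gaussian_cluster,
    intensity_stats,
    minimum_variance_quantise,
    segment_cluster_threshold,
    segment_mcmxxxvi,
    select_tissue_levels,
    split_intense_less,
)
from wmdamage.metric import IntensityStats


class TestFuseRG:
    def test_ramp_spans_unit_interval(self):
        vol = np.linspace(0, 100, 4 * 4 * 4).reshape(4, 4, 4)
        mask = np.ones((4, 4, 4), bool)
        fused = fuse_rg(vol, vol.copy(), mask)
        assert fused.red.min() == 0.0 and fused.red.max() == 1.0

    def test_identical_inputs_give_equal_channels(self, rng):
        vol = rng.uniform(0, 50, (5, 5, 5))
        mask = rng.random((5, 5, 5)) > 0.3
        fused = fuse_rg(vol, vol, mask)
        np.testing.assert_array_equal(fused.red[mask], fused.green[mask])

    def test_matches_per_volume_normalisation_oracle(self, rng):
        a = rng.uniform(-10, 90, (5, 5, 5))
        b = rng.uniform(5, 500, (5, 5, 5))
        mask = rng.random((5, 5, 5)) > 0.4
        fused = fuse_rg(a, b, mask)
        for vol, channel in ((a, fused.red), (b, fused.green)):
            vals = vol[mask]
            expected = (vals - vals.min()) / (vals.max() - vals.min())
            np.testing.assert_allclose(channel[mask], expected, atol=1e-12)

    def test_constant_volume_errors(self):
        mask = np.ones((3, 3, 3), bool)
        with pytest.raises(ValueError, match="constant"):
            fuse_rg(np.ones((3, 3, 3)), np.arange(27.0).reshape(3, 3, 3), mask)


class TestMinimumVarianceQuantise:
    @staticmethod
    def _image_from_colours(colours):
        """Build a fused image whose in-mask colours are exactly `colours`."""
        from wmdamage.segmentation import FusedColourImage

        n = len(colours)
        shape = (n, 1, 1)
        red = np.asarray([c[0] for c in colours], float).reshape(shape)
        green = np.asarray([c[1] for c in colours], float).reshape(shape)
        return FusedColourImage(red=red, green=green, mask=np.ones(shape, bool))

    def test_exactly_k_colours_quantised_losslessly(self):
        colours = [(0.0, 0.0), (0.2, 0.9), (0.8, 0.1), (1.0, 1.0)] * 10
        quant = minimum_variance_quantise(self._image_from_colours(colours), k=4)
        assert quant.within_variance == pytest.approx(0.0, abs=1e-20)
        # one colour per level
        for j in range(4):
            level_colours = {
                colours[i] for i in range(len(colours))
                if quant.labels.ravel()[i] == j
            }
            assert len(level_colours) == 1

    def test_k1_centroid_is_colour_mean(self, rng):
        colours = [tuple(c) for c in rng.random((50, 2))]
        quant = minimum_variance_quantise(self._image_from_colours(colours), k=1)
        np.testing.assert_allclose(
            quant.centroids[0], np.mean(colours, axis=0), atol=1e-12
        )

    def test_beats_uniform_grid_partition_oracle(self, rng):
        """k=4 quantisation achieves no more within-level variance than a
        fixed 2x2 uniform partition of the RG square."""
        colours = rng.random((200, 2))
        img = self._image_from_colours([tuple(c) for c in colours])
        quant = minimum_variance_quantise(img, k=4)
        cells = (colours[:, 0] >= 0.5).astype(int) * 2 + (colours[:, 1] >= 0.5).astype(int)
        grid_var = sum(
            float(((colours[cells == c] - colours[cells == c].mean(axis=0)) ** 2).sum())
            for c in np.unique(cells)
        )
        assert quant.within_variance <= grid_var + 1e-12

    def test_within_variance_nonincreasing_in_k(self, rng):
        colours = rng.random((300, 2))
        img = self._image_from_colours([tuple(c) for c in colours])
        variances = [
            minimum_variance_quantise(img, k).within_variance for k in range(1, 7)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(variances, variances[1:]))

    def test_competitive_with_kmeans_oracle(self, rng):
        """The quantiser's within-level variance is close to (or better
        than) the inertia of a multi-start k-means on the same colours."""
        from sklearn.cluster import KMeans

        colours = np.vstack([
            rng.normal((0.2, 0.2), 0.05, (150, 2)),
            rng.normal((0.7, 0.4), 0.05, (100, 2)),
            rng.normal((0.5, 0.9), 0.05, (50, 2)),
        ])
        img = self._image_from_colours([tuple(c) for c in colours])
        quant = minimum_variance_quantise(img, k=3)
        km = KMeans(n_clusters=3, n_init=10, random_state=0).fit(colours)
        assert quant.within_variance <= 1.05 * km.inertia_

    def test_k_exceeding_distinct_colours_errors(self):
        img = self._image_from_colours([(0.1, 0.1), (0.9, 0.9)] * 5)
        with pytest.raises(ValueError, match="distinct"):
            minimum_variance_quantise(img, k=3)


class TestSelectTissueLevels:
    @staticmethod
    def _three_tissue_image(rng, noise=0.01):
        """CSF-like, WM-like and lesion-like blocks in two channels."""
        shape = (12, 12, 12)
        truth = np.zeros(shape, int)  # 0 csf, 1 wm, 2 lesion
        truth[:, :, 4:] = 1
        truth[3:6, 3:6, 6:9] = 2
        means_a = np.array([0.1, 0.6, 0.7])   # red source
        means_b = np.array([0.05, 0.5, 0.95])  # green (FLAIR-like) source
        vol_a = means_a[truth] + rng.normal(0, noise, shape)
        vol_b = means_b[truth] + rng.normal(0, noise, shape)
        return vol_a, vol_b, truth

    def test_recovers_three_tissues(self, rng):
        vol_a, vol_b, truth = self._three_tissue_image(rng)
        mask = np.ones(truth.shape, bool)
        fused = fuse_rg(vol_a, vol_b, mask)
        quant = minimum_variance_quantise(fused, k=3)
        wm, intense, less = select_tissue_levels(quant, fused)
        assert dice(wm, truth == 1) >= 0.9
        assert dice(intense | less, truth == 2) >= 0.9

    def test_no_lesion_image_gives_empty_wmh(self, rng):
        vol_a, vol_b, truth = self._three_tissue_image(rng)
        mask = truth != 2  # exclude the lesion block entirely
        fused = fuse_rg(vol_a, vol_b, mask)
        quant = minimum_variance_quantise(fused, k=2)
        _, intense, less = select_tissue_levels(quant, fused)
        assert not (intense | less).any()

    def test_union_of_compartments_is_total(self, rng):
        vol_a, vol_b, truth = self._three_tissue_image(rng)
        fused = fuse_rg(vol_a, vol_b, np.ones(truth.shape, bool))
        quant = minimum_variance_quantise(fused, k=3)
        wm, intense, less = select_tissue_levels(quant, fused)
        assert not np.any(intense & less)
        assert not np.any(wm & (intense | less))


class TestGaussianCluster:
    def test_two_separated_clusters_high_accuracy(self, rng):
        shape = (10, 10, 10)
        truth = rng.random(shape) > 0.5
        chan = {
            "a": np.where(truth, 10.0, 0.0) + rng.normal(0, 0.5, shape),
            "b": np.where(truth, 0.0, 8.0) + rng.normal(0, 0.5, shape),
        }
        res = gaussian_cluster(chan, np.ones(shape, bool), k=2, seed=0)
        labels = res.labels[res.mask]
        t = truth[res.mask]
        acc = max(np.mean(labels == t), np.mean(labels == ~t))
        assert acc >= 0.99

    def test_posteriors_sum_to_one(self, small_phantom):
        _, scan, truth = small_phantom
        brain = truth.masks.icv & ~truth.cortex
        res = gaussian_cluster(scan.channels(), brain, k=4, seed=0)
        sums = res.posteriors.sum(axis=0)[brain]
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_nawm_dice_on_phantom(self, small_phantom):
        _, scan, truth = small_phantom
        brain = truth.masks.icv & ~truth.cortex
        res = gaussian_cluster(scan.channels(), brain, k=4, seed=0)
        assert dice(res.nawm_mask, truth.masks.nawm) >= 0.85

    def test_em_loglik_nondecreasing(self, rng):
        """EM's objective never decreases: tracked across warm-started
        single-iteration refits of the same mixture."""
        from sklearn.mixture import GaussianMixture

        X = np.concatenate([
            rng.normal(0, 1, (300, 2)),
            rng.normal(4, 1.5, (300, 2)),
            rng.normal((8, 0), 1, (300, 2)),
        ])
        gm = GaussianMixture(n_components=3, covariance_type="diag",
                             warm_start=True, max_iter=1, tol=0.0,
                             random_state=0)
        bounds = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(25):
                gm.fit(X)
                bounds.append(gm.lower_bound_)
        assert all(b >= a - 1e-10 for a, b in zip(bounds, bounds[1:]))

    def test_small_mask_rejected(self, rng):
        chan = {"a": rng.random((3, 3, 3))}
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, :2] = True
        with pytest.raises(ValueError, match="voxels"):
            gaussian_cluster(chan, mask, k=2)


class TestFlairThreshold:
    def test_noiseless_phantom_recovered_exactly(self, noiseless_phantom):
        spec, scan, truth = noiseless_phantom
        brain = truth.masks.icv & ~truth.cortex
        stats = intensity_stats(scan.flair, truth.masks.nawm)
        with pytest.warns(UserWarning, match="SD is 0"):
            mask = flair_histogram_threshold(scan.flair, brain, stats, k_sd=3.0)
        assert np.array_equal(mask, truth.masks.wmh_total)

    def test_all_below_threshold_gives_empty_mask(self):
        flair = np.full((5, 5, 5), 50.0)
        stats = IntensityStats(mean=100.0, sd=5.0, min=90.0, max=110.0, n=100)
        mask = flair_histogram_threshold(flair, np.ones((5, 5, 5), bool), stats)
        assert not mask.any()

    def test_monotone_in_k_sd(self, default_phantom):
        _, scan, truth = default_phantom
        brain = truth.masks.icv & ~truth.cortex
        stats = intensity_stats(scan.flair, truth.masks.nawm)
        prev = None
        for k_sd in (1.0, 2.0, 3.0, 4.0, 5.0):
            mask = flair_histogram_threshold(scan.flair, brain, stats, k_sd=k_sd)
            if prev is not None:
                assert not np.any(mask & ~prev)  # raising k_sd never adds voxels
            prev = mask

    def test_zero_k_sd_on_contrastless_image_takes_nearly_everything(self, rng):
        """With no WMH/NAWM contrast and k_sd = 0 the threshold sits at the
        NAWM mean and about half the noise is selected — the rule is only
        meaningful with a positive margin."""
        shape = (10, 10, 10)
        flair = rng.normal(100.0, 5.0, shape)
        brain = np.ones(shape, bool)
        stats = intensity_stats(flair, brain)
        mask = flair_histogram_threshold(flair, brain, stats, k_sd=0.0)
        assert 0.4 <= mask.mean() <= 0.6

    def test_exclusion_mask_removes_voxels(self, default_phantom):
        _, scan, truth = default_phantom
        brain = truth.masks.icv & ~truth.cortex
        stats = intensity_stats(scan.flair, truth.masks.nawm)
        full = flair_histogram_threshold(scan.flair, brain, stats)
        excl = flair_histogram_threshold(scan.flair, brain, stats, exclusion=full)
        assert not excl.any()

    def test_intense_split_partitions_wmh(self, default_phantom):
        _, scan, truth = default_phantom
        stats = intensity_stats(scan.flair, truth.masks.nawm)
        wmh = truth.masks.wmh_total
        intense, less = split_intense_less(scan.flair, wmh, stats, k_sd_intense=5.0)
        assert np.array_equal(intense | less, wmh)
        assert not np.any(intense & less)


class TestPipelines:
    def test_mcmxxxvi_outputs_valid_maskset(self, default_phantom):
        _, scan, truth = default_phantom
        brain = truth.masks.icv & ~truth.cortex
        masks = segment_mcmxxxvi(scan, brain, k=4)
        assert isinstance(masks, TissueMaskSet)
        assert dice(masks.wmh_total, truth.masks.wmh_total) >= 0.9
        assert dice(masks.nawm, truth.masks.nawm) >= 0.9

    def test_cluster_threshold_outputs_valid_maskset(self, small_phantom):
        _, scan, truth = small_phantom
        brain = truth.masks.icv & ~truth.cortex
        masks = segment_cluster_threshold(scan, brain, seed=0)
        assert isinstance(masks, TissueMaskSet)
        assert dice(masks.wmh_total, truth.masks.wmh_total) >= 0.9
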