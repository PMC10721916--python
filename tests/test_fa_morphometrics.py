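"""Adhesion segmentation, equivalent-ellipse moments, context features and
the maturity classifier."""

import numpy as np
import pandas as pd
import pytest

from catchquant._angles import axial_difference
from catchquant.fa_morphometrics import (
    classify_fa_maturity,
    cytoplasm_mask,
    fa_context_features,
    fa_morphometrics,
    segment_fas,
)
from catchquant.synth import FaSpec, SceneSpec, gen_fret_scene, gen_maturity_features
from catchquant.workflows import random_fa_layout


def _moment_oracle(xs, ys):
    """Brute-force per-pixel central moments (independent of the implementation)."""
    n = len(xs)
    cx = sum(xs) / n
    cy = sum(ys) / n
    u20 = sum((x - cx) ** 2 for x in xs) / n
    u02 = sum((y - cy) ** 2 for y in ys) / n
    u11 = sum((x - cx) * (y - cy) for x, y in zip(xs, ys)) / n
    return cx, cy, u20, u02, u11


class TestMorphometrics:
    def test_moments_match_pixel_oracle(self):
        rng = np.random.default_rng(0)
        labels = np.zeros((40, 40), dtype=int)
        labels[5:20, 8:30] = (rng.random((15, 22)) < 0.6).astype(int)
        rec = fa_morphometrics(labels).iloc[0]
        ys, xs = np.nonzero(labels)
        cx, cy, u20, u02, u11 = _moment_oracle(list(xs.astype(float)), list(ys.astype(float)))
        for name, val in [("cx", cx), ("cy", cy), ("u20", u20), ("u02", u02), ("u11", u11)]:
            assert rec[name] == pytest.approx(val, abs=1e-9)
        disc = np.sqrt((u20 - u02) ** 2 + 4 * u11**2)
        assert rec["fa_major"] == pytest.approx(2 * np.sqrt(2 * (u20 + u02 + disc)), abs=1e-9)

    def test_disk_has_unit_axis_ratio_and_degenerate_orientation(self):
        yy, xx = np.mgrid[0:41, 0:41]
        labels = ((xx - 20) ** 2 + (yy - 20) ** 2 <= 15**2).astype(int)
        rec = fa_morphometrics(labels).iloc[0]
        assert rec["axis_ratio"] == pytest.approx(1.0, abs=0.02)
        assert rec["degenerate_orientation"]

    @pytest.mark.parametrize("angle_deg", range(-85, 90, 5))
    @pytest.mark.parametrize("ratio", [1.5, 2.0, 3.0])
    def test_rendered_ellipse_recovery(self, angle_deg, ratio):
        major = 30.0
        fa = FaSpec(center=(55, 55), axes=(major, major / ratio), orientation=np.radians(angle_deg))
        _, truth = gen_fret_scene(SceneSpec(shape=(110, 110), fas=[fa], poisson_noise=False,
                                            read_noise_sd=0.0))
        rec = fa_morphometrics(truth["labels"]).iloc[0]
        assert np.degrees(axial_difference(rec["orientation"], fa.orientation)) < 2.0
        assert rec["axis_ratio"] == pytest.approx(ratio, rel=0.05)
        assert rec["fa_major"] == pytest.approx(major, rel=0.05)

    def test_ninety_degree_rotation_equivariance(self):
        rng = np.random.default_rng(1)
        labels = np.zeros((50, 50), dtype=int)
        labels[10:20, 5:40] = (rng.random((10, 35)) < 0.7).astype(int)
        rec = fa_morphometrics(labels).iloc[0]
        rot = fa_morphometrics(np.rot90(labels)).iloc[0]
        assert rot["axis_ratio"] == pytest.approx(rec["axis_ratio"], rel=1e-9)
        assert np.degrees(
            axial_difference(rot["orientation"], rec["orientation"])
        ) == pytest.approx(90.0, abs=1e-6)

    def test_translation_invariance(self):
        labels = np.zeros((60, 60), dtype=int)
        labels[10:16, 10:30] = 1
        a = fa_morphometrics(labels).iloc[0]
        b = fa_morphometrics(np.roll(labels, (17, 13), axis=(0, 1))).iloc[0]
        for col in ("axis_ratio", "orientation", "fa_major", "fa_minor"):
            assert b[col] == pytest.approx(a[col], abs=1e-9)

    def test_single_pixel_flagged(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[4, 4] = 1
        rec = fa_morphometrics(labels).iloc[0]
        assert rec["fa_major"] == rec["fa_minor"] == 1.0
        assert rec["degenerate_orientation"]


class TestSegmentation:
    def test_blank_image_has_no_labels(self):
        assert segment_fas(np.zeros((64, 64))).max() == 0

    def test_recovers_all_planted_adhesions(self):
        rng = np.random.default_rng(4)
        fas = random_fa_layout(rng, n_fas=7)
        triplet, truth = gen_fret_scene(SceneSpec(fas=fas, seed=21))
        labels = segment_fas(triplet.acceptor, truth["cell_mask"])
        found = fa_morphometrics(labels)
        matched = 0
        for _, row in truth["fa_table"].iterrows():
            d = np.hypot(found["cx"] - row["cx"], found["cy"] - row["cy"])
            if d.min() < 3.0:
                matched += 1
        assert matched == len(fas)
        assert labels.max() == len(fas)

    def test_centroids_within_one_pixel(self):
        rng = np.random.default_rng(4)
        fas = random_fa_layout(rng, n_fas=7)
        triplet, truth = gen_fret_scene(SceneSpec(fas=fas, seed=22))
        labels = segment_fas(triplet.acceptor, truth["cell_mask"])
        found = fa_morphometrics(labels)
        for _, row in truth["fa_table"].iterrows():
            d = np.hypot(found["cx"] - row["cx"], found["cy"] - row["cy"])
            assert d.min() < 1.0

    def test_touching_adhesions_with_distinct_peaks_split(self):
        yy, xx = np.mgrid[0:80, 0:80]
        img = 8000 * np.exp(-((xx - 32) ** 2 + (yy - 40) ** 2) / (2 * 5.0**2))
        img += 8000 * np.exp(-((xx - 50) ** 2 + (yy - 40) ** 2) / (2 * 5.0**2))
        labels = segment_fas(img)
        assert labels.max() == 2


class TestCytoplasmMask:
    def test_no_adhesions_gives_whole_cell(self):
        cell = np.zeros((50, 50), dtype=bool)
        cell[5:45, 5:45] = True
        np.testing.assert_array_equal(cytoplasm_mask(np.zeros((50, 50), int), cell), cell)

    def test_central_adhesion_excluded_with_margin(self):
        yy, xx = np.mgrid[0:201, 0:201]
        r = np.hypot(xx - 100, yy - 100)
        cell = r <= 100
        labels = (r <= 5).astype(int)
        cyto = cytoplasm_mask(labels, cell, dilation_radius=10)
        assert not cyto[r <= 14.5].any()
        assert cyto[(r >= 17) & (r <= 99)].all()

    def test_never_overlaps_dilated_adhesions(self):
        rng = np.random.default_rng(5)
        fas = random_fa_layout(rng, n_fas=5)
        triplet, truth = gen_fret_scene(SceneSpec(fas=fas, seed=9))
        labels = segment_fas(triplet.acceptor, truth["cell_mask"])
        cyto = cytoplasm_mask(labels, truth["cell_mask"])
        assert not (cyto & (labels > 0)).any()


class TestContextFeatures:
    def _records(self, centroids, orientations=None):
        k = len(centroids)
        orientations = orientations if orientations is not None else np.zeros(k)
        return pd.DataFrame(
            {"id": np.arange(1, k + 1), "area": 50, "axis_ratio": 2.0,
             "cx": [c[0] for c in centroids], "cy": [c[1] for c in centroids],
             "orientation": orientations}
        )

    def test_parallel_adhesions_have_zero_relative_orientation(self):
        cell = np.ones((100, 100), dtype=bool)
        rec = self._records([(20, 20), (40, 40), (60, 20), (30, 60), (70, 70)],
                            np.full(5, 0.6))
        feats = fa_context_features(rec, cell)
        np.testing.assert_allclose(feats["theta_relative"], 0.0, atol=1e-12)

    def test_collinear_middle_adhesion_d4fa(self):
        cell = np.ones((40, 40), dtype=bool)
        rec = self._records([(10 + i, 20) for i in range(5)])
        feats = fa_context_features(rec, cell)
        assert feats["d4fa"].iloc[2] == pytest.approx(1.5)  # (1+1+2+2)/4

    def test_edge_and_center_distance_limits(self):
        # cell centroid is the mean of adhesion centroids: place them so it
        # coincides with one adhesion and falls far from the boundary one
        yy, xx = np.mgrid[0:101, 0:101]
        cell = np.hypot(xx - 50, yy - 50) <= 45
        feats = fa_context_features(self._records([(50, 50), (30, 50), (70, 50)]), cell)
        assert feats["d_nce"].iloc[0] == pytest.approx(1.0)  # at the centroid
        feats = fa_context_features(self._records([(94, 50), (6, 50)]), cell)
        assert feats["d_nce"].iloc[0] == pytest.approx(0.0, abs=0.04)  # on the boundary

    def test_d_nce_always_in_unit_interval(self):
        rng = np.random.default_rng(6)
        yy, xx = np.mgrid[0:80, 0:80]
        cell = np.hypot(xx - 40, yy - 40) <= 35
        pts = [(rng.uniform(10, 70), rng.uniform(10, 70)) for _ in range(12)]
        feats = fa_context_features(self._records(pts), cell)
        assert ((feats["d_nce"] >= 0) & (feats["d_nce"] <= 1)).all()


class TestMaturityClassifier:
    def test_separable_training_set_fits_perfectly(self):
        features, labels = gen_maturity_features(n_per_class=60, seed=1)
        pred, model = classify_fa_maturity(features, labels=labels, seed=0)
        assert (pred == labels).mean() == 1.0 or (pred == labels).mean() > 0.97

    def test_heldout_accuracy(self):
        features, labels = gen_maturity_features(n_per_class=150, seed=2)
        n_train = int(0.8 * len(labels))
        _, model = classify_fa_maturity(features.iloc[:n_train], labels=labels[:n_train], seed=0)
        pred, _ = classify_fa_maturity(features.iloc[n_train:], model=model)
        assert (pred == labels[n_train:]).mean() >= 0.9

    def test_training_is_deterministic(self):
        features, labels = gen_maturity_features(n_per_class=50, seed=3)
        p1, _ = classify_fa_maturity(features, labels=labels, seed=5)
        p2, _ = classify_fa_maturity(features, labels=labels, seed=5)
        assert (p1 == p2).all()

    def test_single_class_rejected(self):
        features, labels = gen_maturity_features(n_per_class=20, seed=4)
        with pytest.raises(ValueError, match="single class"):
            classify_fa_maturity(features[labels == "SF"], labels=labels[labels == "SF"])

    def test_missing_feature_column_rejected(self):
        features, labels = gen_maturity_features(n_per_class=20, seed=5)
        with pytest.raises(ValueError, match="missing"):
            classify_fa_maturity(features.drop(columns=["d4fa"]), labels=labels)
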