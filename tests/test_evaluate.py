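"""Realism statistics against closed forms and hand tallies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermavec import evaluate
from dermavec.evaluate import (
    default_features,
    frechet_feature_distance,
    frechet_from_features,
    radial_bin_counts,
    radial_power_spectrum,
    rgb_histograms,
    saturation_luminance,
    score_assessment,
    summarize_scores,
)


def _const_image(value, size=8):
    return np.full((size, size, 3), value, dtype=np.uint8)


class TestHistograms:
    def test_all_black_image(self):
        h = rgb_histograms([_const_image(0, 2)])
        assert h[0, 0] == 4 and h[0, 1:].sum() == 0

    def test_uniform_value_concentrates_in_one_bin(self):
        h = rgb_histograms([_const_image(128, 4)])
        assert np.all(h[:, 128] == 16)
        assert h.sum() == 3 * 16

    def test_hand_tallied_pair_of_images(self):
        a = np.zeros((2, 2, 3), dtype=np.uint8)
        a[0, 0] = (10, 20, 30)
        b = np.full((2, 2, 3), 255, dtype=np.uint8)
        h = rgb_histograms([a, b])
        assert h[0, 10] == 1 and h[1, 20] == 1 and h[2, 30] == 1
        assert np.all(h[:, 0] == 3)
        assert np.all(h[:, 255] == 4)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 4))
    def test_mass_conservation(self, seed, n_images):
        rng = np.random.default_rng(seed)
        imgs = [rng.integers(0, 256, (6, 6, 3), dtype=np.uint8) for _ in range(n_images)]
        h = rgb_histograms(imgs)
        assert np.all(h.sum(axis=1) == n_images * 36)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            rgb_histograms([])


class TestRadialSpectrum:
    def test_constant_image_all_power_in_dc(self):
        freq, power = radial_power_spectrum([_const_image(77, 16)])
        assert power[0] > 0
        assert np.all(power[1:] < 1e-9 * power[0])

    def test_sinusoid_concentrates_in_its_radial_bin(self):
        k = 5
        x = np.arange(64)
        wave = 127.5 + 80 * np.sin(2 * np.pi * k * x / 64)
        img = np.clip(np.rint(wave), 0, 255).astype(np.uint8)
        img = np.repeat(img[None, :], 64, axis=0)[..., None].repeat(3, axis=-1)
        freq, power = radial_power_spectrum([img])
        counts = radial_bin_counts(64)
        summed = power * counts
        assert summed[k] / summed[1:].sum() > 0.99

    def test_white_noise_profile_approximately_flat(self):
        rng = np.random.default_rng(0)
        imgs = [rng.integers(0, 256, (32, 32, 3), dtype=np.uint8) for _ in range(500)]
        _, power = radial_power_spectrum(imgs)
        profile = power[1:]
        assert profile.std() / profile.mean() < 0.2

    def test_parseval_identity(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        _, power = radial_power_spectrum([img], truncate=False)
        counts = radial_bin_counts(16, truncate=False)
        total_spectral = float((power * counts).sum())
        gray = evaluate._grayscale(img)
        assert total_spectral == pytest.approx(float((gray**2).sum()), rel=1e-6)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            radial_power_spectrum([np.zeros((8, 12, 3), dtype=np.uint8)])


class TestSaturationLuminance:
    def test_gray_image_has_zero_saturation(self):
        sl = saturation_luminance([_const_image(100)])
        assert sl[0, 0] == 0.0
        assert sl[0, 1] == pytest.approx(100 / 255)

    def test_pure_red_saturated_and_bright(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        img[..., 0] = 255
        sl = saturation_luminance([img])
        assert sl[0] == pytest.approx([1.0, 1.0])

    def test_half_red_half_gray_closed_form(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0] = (255, 0, 0)   # saturation 1, value 1
        img[1] = (51, 51, 51)  # saturation 0, value 0.2
        sl = saturation_luminance([img])
        assert sl[0, 0] == pytest.approx(0.5)
        assert sl[0, 1] == pytest.approx((1.0 + 0.2) / 2)


class TestFrechet:
    def test_univariate_gaussian_closed_form(self):
        # two-point samples with exact sample moments under ddof=1:
        # a: mean 0, sd 1; b: mean 3, sd 2
        a = np.array([[-1.0], [1.0]]) / np.sqrt(2.0)
        b = np.array([[3.0 - np.sqrt(2.0)], [3.0 + np.sqrt(2.0)]])
        d = frechet_from_features(a, b)
        assert d == pytest.approx((0 - 3) ** 2 + (1 - 2) ** 2, abs=1e-6)

    def test_identical_sets_distance_zero(self):
        rng = np.random.default_rng(1)
        imgs = [rng.integers(0, 256, (16, 16, 3), dtype=np.uint8) for _ in range(30)]
        assert frechet_feature_distance(imgs, imgs) == pytest.approx(0.0, abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a = [rng.integers(0, 256, (16, 16, 3), dtype=np.uint8) for _ in range(25)]
        b = [rng.integers(100, 200, (16, 16, 3), dtype=np.uint8) for _ in range(25)]
        assert frechet_feature_distance(a, b) == pytest.approx(
            frechet_feature_distance(b, a), rel=1e-9
        )

    def test_nonnegative_and_regularized_on_degenerate_covariance(self):
        # constant feature sets give singular covariances; shrinkage handles it
        fa = np.ones((5, 3))
        fb = np.full((5, 3), 2.0)
        d = frechet_from_features(fa, fb)
        assert d >= 0.0
        assert d == pytest.approx(3.0, abs=1e-3)  # ||mu diff||^2 = 3

    def test_default_features_shape(self):
        rng = np.random.default_rng(0)
        imgs = [rng.integers(0, 256, (32, 32, 3), dtype=np.uint8) for _ in range(4)]
        assert default_features(imgs).shape == (4, 16)


class TestAssessment:
    @staticmethod
    def _records(rows):
        return pd.DataFrame(
            rows, columns=["image_id", "true_source", "rater_id", "verdict"]
        )

    def test_perfect_rater(self):
        rec = self._records(
            [("i1", "real", "A", "real"), ("i2", "generated", "A", "generated")]
        )
        out = score_assessment(rec)
        pooled = out[out.rater_id == "pooled"].iloc[0]
        assert pooled.real_accuracy == 1.0
        assert pooled.generated_accuracy == 1.0
        assert pooled.generated_judged_real == 0.0

    def test_half_of_generated_judged_real(self):
        rows = []
        for rater in "ABC":
            rows.append((f"g1", "generated", rater, "real"))
            rows.append((f"g2", "generated", rater, "generated"))
        out = score_assessment(self._records(rows))
        pooled = out[out.rater_id == "pooled"].iloc[0]
        assert pooled.generated_accuracy == 0.5
        assert pooled.generated_judged_real == 0.5

    def test_hand_built_twelve_record_table(self):
        rows = [
            ("r1", "real", "A", "real"), ("r2", "real", "A", "generated"),
            ("g1", "generated", "A", "generated"), ("g2", "generated", "A", "generated"),
            ("r1", "real", "B", "real"), ("r2", "real", "B", "real"),
            ("g1", "generated", "B", "real"), ("g2", "generated", "B", "generated"),
            ("r1", "real", "C", "generated"), ("r2", "real", "C", "generated"),
            ("g1", "generated", "C", "real"), ("g2", "generated", "C", "real"),
        ]
        out = score_assessment(self._records(rows))
        pooled = out[out.rater_id == "pooled"].iloc[0]
        assert pooled.real_accuracy == pytest.approx(3 / 6)
        assert pooled.generated_accuracy == pytest.approx(3 / 6)
        a = out[out.rater_id == "A"].iloc[0]
        assert a.real_accuracy == pytest.approx(0.5)
        assert a.generated_accuracy == pytest.approx(1.0)

    def test_accuracy_plus_missrate_is_one_per_rater(self):
        rng = np.random.default_rng(7)
        rows = [
            (f"i{i}", src, rater, rng.choice(["real", "generated"]))
            for i in range(6)
            for src in ("real", "generated")
            for rater in "AB"
        ]
        out = score_assessment(self._records(rows))
        assert np.allclose(out.generated_accuracy + out.generated_judged_real, 1.0)

    def test_unknown_verdict_rejected(self):
        rec = self._records([("i1", "real", "A", "maybe")])
        with pytest.raises(ValueError, match="verdict"):
            score_assessment(rec)


class TestScoreSummaries:
    def test_zero_variance_group(self):
        labels = pd.DataFrame(
            {
                "image_id": ["a", "a", "b", "b"],
                "erythema": [3, 3, 3, 3],
                "scale": [2, 2, 2, 2],
                "rater_id": ["r0", "r1", "r0", "r1"],
            }
        )
        out = summarize_scores(labels, (["a", "b"], ["a"]))
        severe = out[out.group == "severe"].iloc[0]
        assert severe.erythema_mean == 3.0 and severe.erythema_sem == 0.0

    def test_two_point_sem_closed_form(self):
        labels = pd.DataFrame(
            {
                "image_id": ["a", "b", "c"],
                "erythema": [2, 4, 2],
                "scale": [1, 1, 1],
                "rater_id": ["r0"] * 3,
            }
        )
        out = summarize_scores(labels, (["a", "b"], ["c"]))
        severe = out[out.group == "severe"].iloc[0]
        assert severe.erythema_mean == 3.0
        assert severe.erythema_sem == pytest.approx(1.0)  # sd=sqrt(2), n=2

    def test_group_sizes_echoed(self):
        n_sev, n_mod = 153, 151
        ids = [f"i{k}" for k in range(n_sev + n_mod)]
        labels = pd.DataFrame(
            {"image_id": ids, "erythema": 2, "scale": 2, "rater_id": "r0"}
        )
        out = summarize_scores(labels, (ids[:n_sev], ids[n_sev:]))
        assert list(out.n) == [n_sev, n_mod]

    def test_unlabeled_image_rejected(self):
        labels = pd.DataFrame(
            {"image_id": ["a"], "erythema": [1], "scale": [1], "rater_id": ["r"]}
        )
        with pytest.raises(ValueError, match="no labels"):
            summarize_scores(labels, (["a"], ["zzz"]))
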