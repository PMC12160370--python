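"""Lab color statistics, masked GLCM texture, tabular preprocessing, kappa."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skimage.color import rgb2lab

from tonguedx.features_traditional import (
    FeatureTable,
    fleiss_kappa,
    glcm_features,
    lab_stats,
    one_hot,
    one_hot_decode,
    standardize,
    validate_binary,
)
from tonguedx.features_traditional import _angle_offset, _cooccurrence, _glcm_stats, _quantize


def full_mask(h, w):
    return np.ones((h, w), dtype=bool)


class TestLabStats:
    def test_white_region_hits_the_white_point(self):
        img = np.full((8, 8, 3), 255, dtype=np.uint8)
        s = lab_stats(img, full_mask(8, 8))
        assert s.mean_L == pytest.approx(100.0, abs=1e-6)
        assert abs(s.mean_a) < 0.6 and abs(s.mean_b) < 0.6

    def test_constant_color_has_zero_std(self):
        img = np.full((8, 8, 3), (120, 60, 200), dtype=np.uint8)
        s = lab_stats(img, full_mask(8, 8))
        assert s.std_L == pytest.approx(0.0, abs=1e-9)
        assert s.std_a == pytest.approx(0.0, abs=1e-9)
        assert s.std_b == pytest.approx(0.0, abs=1e-9)

    def test_mid_gray_is_achromatic(self):
        img = np.full((8, 8, 3), 119, dtype=np.uint8)
        s = lab_stats(img, full_mask(8, 8))
        assert abs(s.mean_a) < 0.6 and abs(s.mean_b) < 0.6
        assert 0.0 < s.mean_L < 100.0

    def test_agrees_with_reference_conversion_on_srgb_corners(self):
        corners = [
            (255, 0, 0), (0, 255, 0), (0, 0, 255),
            (255, 255, 0), (255, 0, 255), (0, 255, 255),
            (0, 0, 0), (255, 255, 255),
        ]
        for rgb in corners:
            img = np.full((4, 4, 3), rgb, dtype=np.uint8)
            s = lab_stats(img, full_mask(4, 4))
            ref = rgb2lab(np.array(rgb, float)[None, None] / 255.0)[0, 0]
            assert abs(s.mean_L - ref[0]) < 0.5
            assert abs(s.mean_a - ref[1]) < 0.5
            assert abs(s.mean_b - ref[2]) < 0.5

    def test_statistics_use_masked_pixels_only(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        img[:4] = 255
        mask = np.zeros((8, 8), dtype=bool)
        mask[:4] = True
        assert lab_stats(img, mask).mean_L == pytest.approx(100.0, abs=1e-6)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lab_stats(np.zeros((4, 4, 3), dtype=np.uint8), np.zeros((4, 4), bool))


def glcm_oracle(gray, mask, distances, angles, levels):
    """Independent double-loop pair-counting oracle."""
    lo, hi = gray[mask].min(), gray[mask].max()
    if hi <= lo:
        q = np.zeros_like(gray, dtype=int)
    else:
        q = np.clip(np.floor((gray - lo) / (hi - lo) * levels).astype(int), 0, levels - 1)
    h, w = gray.shape
    stats = []
    for d in distances:
        for ang in angles:
            th = np.deg2rad(ang)
            dr, dc = -int(round(d * np.sin(th))), int(round(d * np.cos(th)))
            P = np.zeros((levels, levels))
            for r in range(h):
                for c in range(w):
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                        P[q[r, c], q[r2, c2]] += 1
            P = P + P.T
            if P.sum() == 0:
                continue
            P = P / P.sum()
            stats.append(_glcm_stats(P))
    return {k: np.mean([s[k] for s in stats]) for k in stats[0]}


class TestGLCM:
    def test_uniform_region_degenerates_to_single_cell(self):
        img = np.full((8, 8, 3), 77, dtype=np.uint8)
        g = glcm_features(img, full_mask(8, 8))
        assert g.asm == 1.0 and g.contrast == 0.0 and g.homogeneity == 1.0

    def test_checkerboard_by_hand(self):
        """2x2 symmetric matrix has only (0,1)/(1,0) cells: contrast 1, ASM 0.5."""
        cb = (np.indices((8, 8)).sum(axis=0) % 2).astype(float)
        g = glcm_features(cb, full_mask(8, 8), distances=(1,), angles=(0.0,), levels=2)
        assert g.contrast == pytest.approx(1.0, abs=1e-12)
        assert g.asm == pytest.approx(0.5, abs=1e-12)
        assert g.correlation == pytest.approx(-1.0, abs=1e-12)

    def test_matches_double_loop_oracle_on_random_masked_patches(self, rng):
        for _ in range(30):
            gray = rng.random((8, 8))
            mask = rng.random((8, 8)) > 0.3
            if mask.sum() < 4:
                continue
            mine = glcm_features(gray, mask, levels=8)
            ref = glcm_oracle(gray, mask, (1,), (0.0, 45.0, 90.0, 135.0), 8)
            for k, v in ref.items():
                assert getattr(mine, k) == pytest.approx(v, abs=1e-10)

    def test_matches_skimage_on_full_frame(self):
        """Cross-check against the scikit-image GLCM on an unmasked patch."""
        from skimage.feature import graycomatrix, graycoprops

        rng = np.random.default_rng(3)
        q = rng.integers(0, 8, (12, 12)).astype(np.uint8)
        P = graycomatrix(q, [1], [0.0], levels=8, symmetric=True, normed=True)[:, :, 0, 0]
        mask = full_mask(12, 12)
        mine = _cooccurrence(_quantize(q.astype(float), mask, 8), mask, *(_angle_offset(1, 0.0)), 8)
        assert np.allclose(mine, P, atol=1e-12)
        stats = _glcm_stats(P)
        assert stats["contrast"] == pytest.approx(
            graycoprops(P[:, :, None, None], "contrast")[0, 0]
        )
        assert stats["asm"] == pytest.approx(graycoprops(P[:, :, None, None], "ASM")[0, 0])

    def test_too_small_mask_and_levels_rejected(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        m = np.zeros((4, 4), bool)
        m[0, 0] = True
        with pytest.raises(ValueError, match="2 pixels"):
            glcm_features(img, m)
        with pytest.raises(ValueError, match="levels"):
            glcm_features(img, full_mask(4, 4), levels=1)


class TestOneHot:
    def test_basic_expansion(self):
        col = pd.Series(["red", "pale", "red"], name="tongue_color")
        enc = one_hot(col)
        assert list(enc.columns) == ["tongue_color=pale", "tongue_color=red"]
        assert enc.values.tolist() == [[0, 1], [1, 0], [0, 1]]
        assert (enc.sum(axis=1) == 1).all()

    def test_single_category_gives_all_ones_column(self):
        enc = one_hot(pd.Series(["thin", "thin"], name="coating"))
        assert enc.shape == (2, 1)
        assert (enc == 1).all().all()

    def test_unseen_category_rejected_by_name(self):
        with pytest.raises(ValueError, match="purple"):
            one_hot(pd.Series(["red", "purple"], name="c"), vocabulary=["red", "pale"])

    @given(st.lists(st.sampled_from(["a", "b", "c", "d"]), min_size=1, max_size=20))
    @settings(max_examples=40, derandomize=True)
    def test_round_trip_decodes_original_labels(self, labels):
        col = pd.Series(labels, name="x")
        assert one_hot_decode(one_hot(col), "x").tolist() == labels


class TestStandardize:
    def make_table(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, 4.0], "b": [10.0, 10.0, 10.0, 10.0], "s": [0, 1, 0, 1]},
            index=list("wxyz"),
        )
        return FeatureTable(df, {"a": "continuous", "b": "continuous", "s": "binary"})

    def test_full_fit_zero_mean_unit_sd(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            out, _ = standardize(self.make_table())
        assert abs(out.values["a"].mean()) < 1e-9
        assert out.values["a"].std(ddof=0) == pytest.approx(1.0)
        assert (out.values["b"] == 0.0).all()  # constant column centered

    def test_heldout_rows_use_training_parameters(self):
        # fit on w, x: mean 1.5, sd 0.5 -> y maps to (3 - 1.5) / 0.5 = 3
        with pytest.warns(UserWarning):
            out, params = standardize(self.make_table(), fit_ids=["w", "x"])
        assert params.mean["a"] == 1.5
        assert out.values.loc["y", "a"] == pytest.approx(3.0)
        assert out.values.loc["z", "a"] == pytest.approx(5.0)

    def test_leakage_guard_fit_unchanged_by_other_rows(self):
        t1 = self.make_table()
        t2 = self.make_table()
        t2.values.loc["z", "a"] = 1000.0  # perturb a non-fit row
        with pytest.warns(UserWarning):
            _, p1 = standardize(t1, fit_ids=["w", "x"])
        with pytest.warns(UserWarning):
            _, p2 = standardize(t2, fit_ids=["w", "x"])
        assert p1.mean.equals(p2.mean) and p1.std.equals(p2.std)

    def test_binary_columns_untouched(self):
        with pytest.warns(UserWarning):
            out, _ = standardize(self.make_table())
        assert out.values["s"].tolist() == [0, 1, 0, 1]

    def test_empty_fit_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            standardize(self.make_table(), fit_ids=[])


class TestValidateBinary:
    def test_mode_imputation(self):
        t = FeatureTable(pd.DataFrame({"b": [1.0, 0.0, np.nan, 1.0]}), {"b": "binary"})
        out, audit = validate_binary(t)
        assert out.values["b"].tolist() == [1, 0, 1, 1]
        assert audit.imputed == {"b": 1}

    def test_out_of_set_value_replaced_and_flagged(self):
        t = FeatureTable(pd.DataFrame({"b": [0, 0, 1, 2]}), {"b": "binary"})
        out, audit = validate_binary(t, default=0)
        assert out.values["b"].tolist() == [0, 0, 1, 0]
        assert audit.out_of_set == {"b": [2]}

    def test_clean_column_passes_through_with_empty_report(self):
        t = FeatureTable(pd.DataFrame({"b": [0, 1, 1]}), {"b": "binary"})
        out, audit = validate_binary(t)
        assert out.values["b"].tolist() == [0, 1, 1]
        assert not audit.imputed and not audit.out_of_set

    def test_all_missing_column_rejected(self):
        t = FeatureTable(pd.DataFrame({"b": [np.nan, np.nan]}), {"b": "binary"})
        with pytest.raises(ValueError, match="no observed"):
            validate_binary(t)


class TestAnnotationRecord:
    def test_valid_record_round_trips(self):
        from tonguedx.features_traditional import AnnotationRecord

        r = AnnotationRecord("pale", "enlarged", "white", "greasy")
        assert r.as_dict()["tongue_color"] == "pale"

    def test_out_of_vocabulary_label_rejected(self):
        from tonguedx.features_traditional import AnnotationRecord

        with pytest.raises(ValueError, match="vocabulary"):
            AnnotationRecord("green", "normal", "white", "thin")

    def test_records_encode_through_one_hot(self):
        from tonguedx.features_traditional import ANNOTATION_VOCABULARY, AnnotationRecord

        records = [
            AnnotationRecord("pale", "enlarged", "white", "greasy"),
            AnnotationRecord("red", "normal", "yellow", "thin"),
        ]
        col = pd.Series([r.tongue_color for r in records], name="tongue_color")
        enc = one_hot(col, vocabulary=list(ANNOTATION_VOCABULARY["tongue_color"]))
        assert enc.shape == (2, 5)
        assert (enc.sum(axis=1) == 1).all()


class TestFleissKappa:
    def test_perfect_agreement_is_one(self):
        ratings = np.array([["a"] * 3, ["b"] * 3, ["a"] * 3, ["b"] * 3])
        assert fleiss_kappa(ratings) == pytest.approx(1.0)

    def test_random_ratings_near_zero(self):
        rng = np.random.default_rng(1)
        ratings = rng.choice(["x", "y"], size=(200, 3))
        assert abs(fleiss_kappa(ratings)) < 0.1

    def test_ten_item_table_matches_hand_formula(self):
        rng = np.random.default_rng(4)
        ratings = rng.choice(["p", "q", "r"], size=(10, 3))
        # hand computation of the chance-corrected agreement
        cats = sorted({c for row in ratings for c in row})
        counts = np.array([[list(row).count(c) for c in cats] for row in ratings])
        n = 3
        p_i = ((counts**2).sum(axis=1) - n) / (n * (n - 1))
        p_bar = p_i.mean()
        p_j = counts.sum(axis=0) / counts.sum()
        p_e = (p_j**2).sum()
        expected = (p_bar - p_e) / (1 - p_e)
        assert fleiss_kappa(ratings) == pytest.approx(expected, abs=1e-12)

    def test_single_category_everywhere_is_nan_with_warning(self):
        ratings = np.array([["a"] * 3] * 5)
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(fleiss_kappa(ratings))

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.array([["a", "b"]]))
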