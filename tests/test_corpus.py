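"""Synthetic corpus generation: distortions, scoring, manifests."""

import numpy as np
import pytest
from scipy import stats

from ctiqa.corpus import (
    CT_IQA_RANGE,
    DistortionSpec,
    MixtureConfig,
    NATURAL_MOS_RANGE,
    ScoreRange,
    apply_distortion,
    assign_quality,
    build_source_corpus,
    build_target_corpus,
    distortion_type_bank,
    generate_pristine,
    rescale_score,
    severity_mse_curve,
    DISTORTION_KINDS,
)


class TestGeneratePristine:
    def test_contract_target(self):
        imgs = generate_pristine("target", 3, 64, seed=0)
        assert len(imgs) == 3
        for im in imgs:
            assert im.shape == (64, 64)
            assert im.min() >= 0.0 and im.max() <= 1.0

    def test_determinism(self):
        a = generate_pristine("source", 4, 32, seed=5)
        b = generate_pristine("source", 4, 32, seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_textures_pairwise_distinct(self):
        imgs = generate_pristine("source", 81, 64, seed=1)
        # spot-check pairwise MSE > 0 over a deterministic subset plus all
        # consecutive pairs (full 81x81 comparison is redundant)
        for i in range(len(imgs) - 1):
            assert np.mean((imgs[i] - imgs[i + 1]) ** 2) > 0
        for i in range(0, 81, 9):
            for j in range(i + 9, 81, 9):
                assert np.mean((imgs[i] - imgs[j]) ** 2) > 0

    def test_size_minimum_rejected(self):
        with pytest.raises(ValueError, match="minimum"):
            generate_pristine("target", 1, 8, seed=0)

    def test_unknown_domain(self):
        with pytest.raises(ValueError, match="domain"):
            generate_pristine("natural", 1, 64, seed=0)


class TestApplyDistortion:
    def test_zero_severity_is_identity(self, phantom64):
        for kind in DISTORTION_KINDS:
            out = apply_distortion(phantom64, DistortionSpec(kind, 0.0, seed=3))
            np.testing.assert_array_equal(out, phantom64)

    @pytest.mark.parametrize("kind", DISTORTION_KINDS)
    def test_mse_monotone_in_level(self, phantom64, kind):
        curve = severity_mse_curve(phantom64, kind, seed=9)
        assert curve[0] > 0
        assert np.all(np.diff(curve) >= -1e-15)

    def test_noise_mse_strictly_increasing(self, phantom64):
        curve = severity_mse_curve(phantom64, "gaussian_noise", seed=9)
        assert np.all(np.diff(curve) > 0)

    def test_blur_preserves_mean(self, phantom64):
        out = apply_distortion(phantom64, DistortionSpec("gaussian_blur", 2.0))
        assert abs(out.mean() - phantom64.mean()) < 1e-6

    def test_blur_matches_dense_convolution_oracle(self):
        # independent oracle: explicit dense convolution with a truncated,
        # normalized Gaussian kernel under symmetric (half-sample) padding
        rng = np.random.default_rng(0)
        img = rng.random((24, 24))
        sigma = 1.1  # level-1 blur
        out = apply_distortion(img, DistortionSpec("gaussian_blur", 1.0))
        radius = int(4 * sigma + 0.5)
        xs = np.arange(-radius, radius + 1)
        k1 = np.exp(-(xs**2) / (2 * sigma**2))
        k1 /= k1.sum()
        pad = np.pad(img, radius, mode="symmetric")
        tmp = np.array([np.convolve(row, k1, mode="valid") for row in pad])
        dense = np.array(
            [np.convolve(col, k1, mode="valid") for col in tmp.T]
        ).T
        np.testing.assert_allclose(out, np.clip(dense, 0, 1), atol=1e-10)

    def test_same_spec_is_deterministic(self, phantom64):
        spec = DistortionSpec("gaussian_noise", 3.0, seed=21)
        np.testing.assert_array_equal(
            apply_distortion(phantom64, spec), apply_distortion(phantom64, spec)
        )

    def test_output_clipped(self, phantom64):
        out = apply_distortion(phantom64, DistortionSpec("gaussian_noise", 5.0, seed=1))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="supported"):
            DistortionSpec("speckle", 1.0)

    def test_level_out_of_range(self):
        with pytest.raises(ValueError, match="level"):
            DistortionSpec("gaussian_noise", 6.0)


class TestAssignQuality:
    def test_endpoints(self):
        top = assign_quality(DistortionSpec("gaussian_noise", 0.0), jitter_sd=0.0)
        bottom = assign_quality(DistortionSpec("gaussian_noise", 5.0), jitter_sd=0.0)
        assert top == 4.0
        assert bottom == 0.0

    def test_linear_map_values(self):
        scores = [
            assign_quality(DistortionSpec("gaussian_blur", float(l)), jitter_sd=0.0)
            for l in range(1, 6)
        ]
        np.testing.assert_allclose(scores, [3.2, 2.4, 1.6, 0.8, 0.0])

    def test_strictly_decreasing_and_rank_perfect(self):
        levels = np.arange(0, 6, dtype=float)
        scores = [
            assign_quality(DistortionSpec("contrast_scale", l), jitter_sd=0.0)
            for l in levels
        ]
        assert np.all(np.diff(scores) < 0)
        assert stats.spearmanr(levels, scores).statistic == -1.0

    def test_jitter_clipped_to_range(self):
        s = assign_quality(
            DistortionSpec("gaussian_noise", 0.0, seed=3), jitter_sd=5.0, seed=3
        )
        assert 0.0 <= s <= 4.0

    def test_negative_jitter_sd_rejected(self):
        with pytest.raises(ValueError):
            assign_quality(DistortionSpec("gaussian_noise", 1.0), jitter_sd=-0.1)


class TestRescaleScore:
    @pytest.mark.parametrize(
        "v,expected", [(5.0, 4.0), (1.0, 0.0), (3.0, 2.0)]
    )
    def test_natural_to_ct(self, v, expected):
        assert rescale_score(v, NATURAL_MOS_RANGE, CT_IQA_RANGE) == pytest.approx(
            expected
        )

    def test_order_preserved(self):
        vals = [1.0, 2.2, 3.7, 5.0]
        out = [rescale_score(v, NATURAL_MOS_RANGE, CT_IQA_RANGE) for v in vals]
        assert out == sorted(out)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            rescale_score(5.5, NATURAL_MOS_RANGE, CT_IQA_RANGE)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            ScoreRange(2.0, 2.0)


class TestSourceCorpus:
    @pytest.mark.parametrize(
        "np_,nt,nl,expected", [(1, 1, 1, 1), (4, 3, 5, 60), (2, 3, 2, 12)]
    )
    def test_combinatorial_cardinality(self, np_, nt, nl, expected):
        m = build_source_corpus(np_, nt, nl, size=32, seed=0, jitter_sd=0.0)
        assert len(m) == expected

    def test_bank_exhausted_rejected(self):
        with pytest.raises(ValueError, match="bank"):
            build_source_corpus(1, 26, 5, size=32, seed=0)

    def test_type_bank_labels_unique(self):
        bank = distortion_type_bank(25)
        labels = [b[0] for b in bank]
        assert len(set(labels)) == 25

    def test_scores_within_range(self, small_source_corpus):
        for r in small_source_corpus.records:
            assert 0.0 <= r.score <= 4.0

    def test_regeneration_hash_identical(self):
        a = build_source_corpus(2, 2, 2, size=32, seed=3)
        b = build_source_corpus(2, 2, 2, size=32, seed=3)
        assert a.content_hash() == b.content_hash()

    def test_config_echoed(self, small_source_corpus):
        cfg = small_source_corpus.generator_config
        assert cfg["n_pristine"] == 2 and cfg["n_types"] == 3

    def test_generator_config_round_numbers(self):
        with pytest.raises(ValueError):
            build_source_corpus(0, 1, 1, size=32, seed=0)


class TestTargetCorpus:
    def test_cardinality_and_determinism(self):
        a = build_target_corpus(40, 32, seed=2, mixture=MixtureConfig(jitter_sd=0.0))
        b = build_target_corpus(40, 32, seed=2, mixture=MixtureConfig(jitter_sd=0.0))
        assert len(a) == 40
        assert a.content_hash() == b.content_hash()

    def test_all_unit_bins_populated(self, small_target_corpus):
        bins = {int(min(r.score, 3.999)) for r in small_target_corpus.records}
        assert bins == {0, 1, 2, 3}

    def test_mixture_sizes(self, small_target_corpus):
        sizes = {len(r.distortions) for r in small_target_corpus.records}
        assert sizes <= {2, 3} and sizes  # default: combined artifacts

    def test_score_is_mean_of_component_scores(self, small_target_corpus):
        # jitter-free: record score must equal the severity-linear mean
        for r in small_target_corpus.records:
            per_kind = [4.0 * (1.0 - d.level / d.n_levels) for d in r.distortions]
            assert r.score == pytest.approx(np.mean(per_kind), abs=1e-9)

    def test_splits_cover_all_bins(self):
        m = build_target_corpus(200, 32, seed=0, mixture=MixtureConfig(jitter_sd=0.0))
        for split in ("train", "val", "test"):
            sub = m.subset(split)
            assert len(sub) > 0
            bins = {int(min(r.score, 3.999)) for r in sub.records}
            assert bins == {0, 1, 2, 3}, split
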