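import numpy as np
import pytest

from glimpsetrf.phonemes import (
    FEATURE_NAMES,
    GlimpseRatios,
    PhonemeTier,
    PhonemeInterval,
    build_phonetic_regressors,
    binary_feature_matrix,
    compute_glimpse_ratios,
    read_alignment_tsv,
    read_textgrid,
    shuffle_feature_mapping,
    shuffle_word_onsets,
    word_onset_regressor,
    write_alignment_tsv,
)
from glimpsetrf.spectrogram import BandSpectrogram

from conftest import make_tier


def spec_of(values, rate=100.0):
    values = np.asarray(values, dtype=float)
    centers = np.geomspace(100, 4000, values.shape[1])
    return BandSpectrogram(values, centers, rate)


class TestGlimpseRatios:
    def test_toy_count_by_hand(self):
        # 2 frames x 2 bands, threshold 0 dB: cells (2>=1) and (4>=1) glimpse
        talker = spec_of([[2, 1], [4, 1]])
        background = spec_of([[1, 2], [1, 2]])
        tier = make_tier([("pa", 0.0, 0.02, 0)])
        r = compute_glimpse_ratios(talker, background, tier, 0.0)
        assert r.ratio_glimpse[0] == pytest.approx(0.5)
        assert r.ratio_mask[0] == pytest.approx(0.5)

    def test_silence_background_fully_glimpsed(self, rng):
        talker = spec_of(rng.random((10, 5)) + 0.1)
        background = spec_of(np.zeros((10, 5)))
        tier = make_tier([("pa", 0.0, 0.1, 0)])
        r = compute_glimpse_ratios(talker, background, tier, 0.0)
        assert r.ratio_glimpse[0] == 1.0
        r = compute_glimpse_ratios(talker, background, tier, -20.0)
        assert r.ratio_glimpse[0] == 1.0

    def test_equal_energy_is_glimpsed_at_zero_db(self, rng):
        v = rng.random((10, 4)) + 0.5
        tier = make_tier([("pa", 0.0, 0.1, 0)])
        r = compute_glimpse_ratios(spec_of(v), spec_of(v), tier, 0.0)
        assert r.ratio_glimpse[0] == 1.0  # >= comparison

    def test_monotone_in_threshold_and_limits(self, rng):
        talker = spec_of(rng.random((30, 20)) + 0.05)
        background = spec_of(rng.random((30, 20)) + 0.05)
        tier = make_tier([("pa", 0.0, 0.15, 0), ("pb", 0.15, 0.3, 1)])
        thresholds = np.arange(-30, 31, 3.0)
        prev = np.ones(2) * np.inf
        for th in thresholds:
            r = compute_glimpse_ratios(talker, background, tier, th).ratio_glimpse
            assert np.all(r <= prev + 1e-12)
            prev = r
        assert np.all(compute_glimpse_ratios(talker, background, tier, -200.0)
                      .ratio_glimpse == 1.0)
        assert np.all(compute_glimpse_ratios(talker, background, tier, 200.0)
                      .ratio_glimpse == 0.0)

    def test_db_to_linear_conventions(self):
        # amplitude ratio 0.7: flips at 20*log10(0.7) = -3.1 dB under the
        # magnitude convention and at 10*log10(0.7) = -1.55 dB under the
        # power convention (factor 10^(dB/10))
        talker = spec_of(np.full((10, 2), 0.7))
        background = spec_of(np.ones((10, 2)))
        tier = make_tier([("pa", 0.0, 0.1, 0)])
        get = lambda db, sc: compute_glimpse_ratios(
            talker, background, tier, db, scale=sc).ratio_glimpse[0]
        assert get(-3.0, "magnitude") == 0.0 and get(-3.2, "magnitude") == 1.0
        assert get(-1.5, "power") == 0.0 and get(-1.6, "power") == 1.0

    def test_interval_outside_range_raises(self):
        talker = spec_of(np.ones((5, 2)))
        tier = make_tier([("pa", 0.0, 0.2, 0)])
        with pytest.raises(ValueError, match="outside"):
            compute_glimpse_ratios(talker, talker, tier, 0.0)


class TestPhoneticRegressors:
    def test_fully_glimpsed_equals_binary_matrix(self, toy_tier, toy_fmap):
        ratios = GlimpseRatios(np.ones(3), 0.0)
        reg = build_phonetic_regressors(toy_tier, toy_fmap, ratios)
        assert np.array_equal(reg["glimpsed"],
                              binary_feature_matrix(toy_tier, toy_fmap))
        assert np.all(reg["masked"] == 0)

    def test_b_phoneme_quarter_glimpsed(self, arpabet):
        # a single 100 ms /B/ with glimpse ratio 0.25 at 100 Hz
        tier = make_tier([("B", 0.0, 0.1, 0)])
        reg = build_phonetic_regressors(
            tier, arpabet, GlimpseRatios(np.array([0.25]), -4.0))
        b_features = {"bilabial", "plosive", "voiced", "consonantal",
                      "obstruent", "anterior"}
        for i, name in enumerate(FEATURE_NAMES):
            expect_g = 0.25 if name in b_features else 0.0
            expect_m = 0.75 if name in b_features else 0.0
            assert np.allclose(reg["glimpsed"][:10, i], expect_g)
            assert np.allclose(reg["masked"][:10, i], expect_m)

    def test_glimpsed_plus_masked_reconstructs_binary(self, toy_tier, toy_fmap, rng):
        ratios = GlimpseRatios(rng.random(3), -4.0)
        reg = build_phonetic_regressors(toy_tier, toy_fmap, ratios)
        binary = binary_feature_matrix(toy_tier, toy_fmap)
        assert np.allclose(reg["glimpsed"] + reg["masked"], binary)
        # column mass equals frames of phonemes carrying the feature
        assert np.allclose((reg["glimpsed"] + reg["masked"]).sum(axis=0),
                           binary.sum(axis=0))

    def test_onset_impulses_carry_ratios(self, toy_tier, toy_fmap):
        ratios = GlimpseRatios(np.array([0.2, 0.9, 0.5]), -4.0)
        reg = build_phonetic_regressors(toy_tier, toy_fmap, ratios)
        assert reg["glimpsed_onsets"][:, 0].sum() == pytest.approx(1.6)
        assert reg["glimpsed_onsets"][0, 0] == 0.2
        assert reg["masked_onsets"][10, 0] == pytest.approx(0.1)
        assert np.count_nonzero(reg["glimpsed_onsets"]) == 3

    def test_unknown_label_raises_with_name(self, toy_tier, toy_fmap):
        bad = make_tier([("zz", 0.0, 0.1, 0)])
        with pytest.raises(KeyError, match="zz"):
            build_phonetic_regressors(bad, toy_fmap, GlimpseRatios(np.ones(1), 0.0))


class TestWordOnsets:
    def test_one_impulse_per_word(self, toy_tier):
        out = word_onset_regressor(toy_tier)
        assert out.sum() == 2
        assert out[0, 0] == 1.0 and out[20, 0] == 1.0

    def test_single_phoneme_utterance(self):
        tier = make_tier([("pa", 0.0, 0.08, 0)])
        out = word_onset_regressor(tier)
        assert out.sum() == 1 and out[0, 0] == 1.0

    def test_shuffled_onsets_one_per_word_on_phoneme_starts(self, toy_tier):
        out = shuffle_word_onsets(toy_tier, seed=4)
        assert out.sum() == 2
        assert set(np.flatnonzero(out[:, 0])) <= {0, 10, 20}
        # monophonemic words are forced to the true onset
        tier = make_tier([("pa", 0.0, 0.1, 0), ("pb", 0.1, 0.2, 1)])
        assert np.array_equal(shuffle_word_onsets(tier, seed=0),
                              word_onset_regressor(tier))


class TestFeatureMapShuffle:
    def test_reproducible_and_preserves_vector_multiset(self, arpabet):
        a = shuffle_feature_mapping(arpabet, seed=2)
        b = shuffle_feature_mapping(arpabet, seed=2)
        assert all(np.array_equal(a.mapping[k], b.mapping[k]) for k in a.mapping)
        orig = sorted(tuple(v) for v in arpabet.mapping.values())
        assert sorted(tuple(v) for v in a.mapping.values()) == orig

    def test_different_seeds_differ(self, arpabet):
        a = shuffle_feature_mapping(arpabet, seed=1)
        b = shuffle_feature_mapping(arpabet, seed=2)
        assert any(not np.array_equal(a.mapping[k], b.mapping[k]) for k in a.mapping)

    def test_column_sums_change_on_toy_tier(self, toy_tier, toy_fmap):
        # a permutation may be the identity by chance; over several seeds at
        # least one shuffle must rearrange the matrix
        orig = binary_feature_matrix(toy_tier, toy_fmap)
        news = [binary_feature_matrix(toy_tier,
                                      shuffle_feature_mapping(toy_fmap, seed=s))
                for s in range(5)]
        assert any(not np.array_equal(orig, n) for n in news)
        shuffled = shuffle_feature_mapping(toy_fmap, seed=0)
        # total mass is preserved only in the multiset sense
        assert np.allclose(np.sort([v.sum() for v in toy_fmap.mapping.values()]),
                           np.sort([v.sum() for v in shuffled.mapping.values()]))


class TestTierValidationAndIO:
    def test_rejects_overlap_and_reversed(self):
        with pytest.raises(ValueError):
            make_tier([("pa", 0.0, 0.2, 0), ("pb", 0.1, 0.3, 0)])
        with pytest.raises(ValueError):
            make_tier([("pa", 0.2, 0.1, 0)])

    def test_tsv_round_trip(self, toy_tier, tmp_path):
        path = tmp_path / "tier.tsv"
        write_alignment_tsv(toy_tier, path)
        back = read_alignment_tsv(path)
        assert back.labels == toy_tier.labels
        assert back.n_words == toy_tier.n_words
        assert back.intervals[1].start_s == pytest.approx(0.1)

    def test_textgrid_reader(self, tmp_path):
        tg = """File type = "ooTextFile"
Object class = "TextGrid"
xmin = 0
xmax = 0.3
tiers? <exists>
size = 2
item []:
    item [1]:
        class = "IntervalTier"
        name = "phones"
        xmin = 0
        xmax = 0.3
        intervals: size = 3
        intervals [1]:
            xmin = 0.0
            xmax = 0.1
            text = "b"
        intervals [2]:
            xmin = 0.1
            xmax = 0.2
            text = "iy"
        intervals [3]:
            xmin = 0.2
            xmax = 0.3
            text = "sp"
    item [2]:
        class = "IntervalTier"
        name = "words"
        xmin = 0
        xmax = 0.3
        intervals: size = 2
        intervals [1]:
            xmin = 0.0
            xmax = 0.2
            text = "be"
        intervals [2]:
            xmin = 0.2
            xmax = 0.3
            text = ""
"""
        path = tmp_path / "a.TextGrid"
        path.write_text(tg)
        tier = read_textgrid(path)
        assert tier.labels == ["B", "IY"]
        assert tier.intervals[0].word_index == tier.intervals[1].word_index
        assert tier.total_duration_s == pytest.approx(0.3)
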