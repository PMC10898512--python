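"""Temporal generalization, confusion matrices, visibility split and exclusions."""

import numpy as np
import pytest

from vividness import (
    EmbeddingSpec,
    apply_min_trial_exclusion,
    binarize_visibility_by_median,
    binary_stimulus_decode,
    confusion_over_time,
    generate_meg_dataset,
    temporal_generalization,
)
from vividness.simulate import CONTENT_VISIBILITY_WEIGHT, _raised_cosine


def test_within_tgm_on_null_data_sits_at_chance(behavior):
    rec = generate_meg_dataset(behavior, EmbeddingSpec("null"), 12, seed=21,
                               epoch_ms=(-200, 0))
    tgm = temporal_generalization(rec, rec.labels["pas"].to_numpy(), "within", seed=0)
    assert tgm.chance == 0.25
    assert abs(tgm.accuracy.mean() - 0.25) < 0.02
    assert tgm.accuracy.shape == (rec.time_ms.size,) * 2


def test_cross_decoding_never_trains_on_test_stimulus(behavior):
    rec = generate_meg_dataset(behavior, EmbeddingSpec("null"), 8, seed=22,
                               epoch_ms=(-200, -100))
    mask = (rec.labels["stimulus"] == "square").to_numpy()
    with pytest.raises(ValueError, match="disjoint"):
        temporal_generalization(rec, rec.labels["pas"].to_numpy(), "cross", mask, mask)
    # overlapping-stimulus subsets are caught even when index-disjoint
    half = mask.copy()
    half[np.flatnonzero(mask)[::2]] = False
    with pytest.raises(AssertionError):
        temporal_generalization(rec, rec.labels["pas"].to_numpy(), "cross",
                                half, mask & ~half)


def test_graded_code_generalizes_across_stimuli(behavior):
    spec = EmbeddingSpec("abstract_graded", snr=2.0, window=(100, 400))
    rec = generate_meg_dataset(behavior, spec, 24, seed=23, epoch_ms=(-200, 500))
    y = rec.labels["pas"].to_numpy()
    mask = (rec.labels["stimulus"] == "square").to_numpy()
    tgm = temporal_generalization(rec, y, "cross", mask, ~mask, seed=1)
    win = (rec.time_ms >= 150) & (rec.time_ms <= 350)
    assert np.diag(tgm.accuracy)[win].mean() > 0.5
    assert np.diag(tgm.accuracy)[rec.time_ms < 0].mean() < 0.35


def test_content_specific_code_fails_to_transfer(behavior):
    spec = EmbeddingSpec("specific_graded", snr=2.0, window=(100, 400))
    rec = generate_meg_dataset(behavior, spec, 24, seed=24, epoch_ms=(-200, 500))
    y = rec.labels["pas"].to_numpy()
    mask = (rec.labels["stimulus"] == "square").to_numpy()
    win = (rec.time_ms >= 150) & (rec.time_ms <= 350)
    within = temporal_generalization(rec, y, "within", mask, mask, seed=1)
    cross = temporal_generalization(rec, y, "cross", mask, ~mask, seed=1)
    assert np.diag(within.accuracy)[win].mean() > 0.5
    assert np.diag(cross.accuracy)[win].mean() < 0.35


def test_confusion_rows_normalised_and_neighbour_structured(behavior):
    spec = EmbeddingSpec("abstract_graded", snr=0.7, window=(100, 400))
    rec = generate_meg_dataset(behavior, spec, 24, seed=25, epoch_ms=(100, 400))
    conf = confusion_over_time(rec, rec.labels["pas"].to_numpy(), seed=2)
    assert conf.shape[1:] == (4, 4)
    assert np.allclose(conf.sum(axis=2), 1.0, atol=1e-10)
    # graded code: NE confused with WG more than with ACE, more than with CE
    mean_conf = conf.mean(axis=0)
    assert mean_conf[0, 1] > mean_conf[0, 2] > mean_conf[0, 3]


def test_stimulus_decoding_tracks_content_visibility(behavior):
    spec = EmbeddingSpec("null")
    rec = generate_meg_dataset(behavior, spec, 20, noise_sd=1.0, seed=26,
                               epoch_ms=(-200, 500))
    rng = np.random.default_rng(0)
    pat = rng.standard_normal(20)
    pat -= pat.mean()
    pat /= np.linalg.norm(pat)
    env = _raised_cosine(rec.time_ms, (100, 400))
    sign = np.where(rec.labels["stimulus"] == "square", 1.0, -1.0)
    w = rec.labels["pas"].map(CONTENT_VISIBILITY_WEIGHT).to_numpy()
    rec.data += (3.0 * sign * w)[:, None, None] * pat[None, :, None] * env[None, None, :]
    hi = binary_stimulus_decode(rec, "high", seed=3)
    lo = binary_stimulus_decode(rec, "low", seed=3)
    win = (rec.time_ms >= 150) & (rec.time_ms <= 350)
    assert hi[win].mean() > 0.9
    assert abs(lo[win].mean() - 0.5) < 0.12


def test_stimulus_decoding_input_validation(behavior):
    rec = generate_meg_dataset(behavior, EmbeddingSpec("null"), 8, seed=27,
                               epoch_ms=(-200, -150))
    with pytest.raises(ValueError):
        binary_stimulus_decode(rec, "medium")


@pytest.mark.parametrize(
    "ratings,low,high",
    [
        ([2, 2, 3, 4, 4], {2}, {3, 4}),          # odd n, median 3
        ([2, 2, 3, 3, 4, 4, 4, 4], {2, 3}, {4}),  # half {2,3}, half {4} -> median 3.5
        ([3, 3, 3], set(), {3}),                  # identical ratings -> all high
    ],
)
def test_median_split_convention(ratings, low, high):
    out = binarize_visibility_by_median(np.array(ratings))
    assert set(np.array(ratings)[out == "low"]) == low
    assert set(np.array(ratings)[out == "high"]) == high


@pytest.mark.parametrize(
    "counts,keep",
    [
        ((63, 25, 61, 28), True),   # typical post-split cell counts
        ((63, 9, 61, 28), False),   # one cell just below threshold
        ((10, 10, 10, 10), True),   # threshold is inclusive
    ],
)
def test_min_trial_exclusion_rule(counts, keep):
    animacy = np.repeat(["animate", "animate", "inanimate", "inanimate"], counts)
    vis = np.repeat(["high", "low", "high", "low"], counts)
    assert apply_min_trial_exclusion(animacy, vis, 10) is keep
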