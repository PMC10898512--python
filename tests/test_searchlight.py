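"""Searchlight geometry and decoding, ROI voxel selection and content decoding."""

import numpy as np
import pytest

from vividness import (
    RegionSpec,
    binarize_visibility_by_median,
    generate_fmri_dataset,
    roi_content_decode,
    roi_top_voxels,
    searchlight_decode,
    searchlight_offsets,
    simulate_fmri_behavior,
)
from vividness.searchlight import AccuracyMap
from vividness.simulate import default_mask


def test_radius_4_sphere_holds_257_voxels():
    offs = searchlight_offsets(4)
    assert offs.shape == (257, 3)


def test_radius_0_is_just_the_center():
    assert searchlight_offsets(0).tolist() == [[0, 0, 0]]


def test_offsets_match_brute_force_lattice_scan():
    r = 2
    brute = [(x, y, z)
             for x in range(-r, r + 1) for y in range(-r, r + 1)
             for z in range(-r, r + 1) if x * x + y * y + z * z <= r * r]
    assert [tuple(o) for o in searchlight_offsets(r)] == sorted(brute)


def _visibility_volume(noise_sd, seed=0, n_trials=120, amplitude=3.0, code="visibility_invariant"):
    trials = simulate_fmri_behavior(n_trials, seed=seed)
    shape = (9, 9, 9)
    mask = default_mask(shape)
    region = RegionSpec("vis", code=code, center=(4, 4, 4), radius=1.5,
                        amplitude=amplitude)
    vol = generate_fmri_dataset(trials, [region], shape, mask, noise_sd=noise_sd,
                                seed=seed + 1)
    vis = binarize_visibility_by_median(trials["pas"].to_numpy())
    return vol, vis, region


def test_noiseless_region_cross_decodes_perfectly():
    vol, vis, region = _visibility_volume(noise_sd=0.0)
    for direction in ("cross_first_to_second", "cross_second_to_first"):
        amap = searchlight_decode(vol, vis, direction, radius_voxels=1, seed=0)
        for ijk in region.voxel_indices(vol.mask.shape):
            assert amap.values[tuple(ijk)] == 1.0


def test_null_volume_accuracy_centers_on_chance():
    trials = simulate_fmri_behavior(120, seed=5)
    shape = (9, 9, 9)
    mask = default_mask(shape)
    vol = generate_fmri_dataset(trials, [], shape, mask, noise_sd=1.0, seed=6)
    vis = binarize_visibility_by_median(trials["pas"].to_numpy())
    amap = searchlight_decode(vol, vis, "within_first", radius_voxels=2, seed=1)
    vals = amap.in_mask()
    assert abs(vals.mean() - 0.5) < 0.02
    assert np.isnan(amap.values[0, 0, 0])  # outside the mask


def test_roi_top_voxels_returns_best_ranked_set():
    mask = default_mask((8, 8, 8))
    rng = np.random.default_rng(7)
    vals = np.full(mask.shape, np.nan)
    vals[mask] = rng.random(int(mask.sum()))
    amap = AccuracyMap(vals, mask, "within_first")
    roi = np.zeros_like(mask)
    roi[3:6, 3:6, 3:6] = True
    roi &= mask
    top = roi_top_voxels([amap], roi, n=5)
    assert top.size == 5
    roi_flat = np.flatnonzero(roi[mask])
    acc = vals[mask]
    excluded = np.setdiff1d(roi_flat, top)
    assert acc[top].min() >= acc[excluded].max()
    # undersized ROI returns everything
    small = np.zeros_like(mask)
    small[4, 4, 4] = True
    assert roi_top_voxels([amap], small & mask, n=5).size == 1


def test_roi_content_decoding_works_only_at_high_visibility():
    trials = simulate_fmri_behavior(200, seed=8)
    shape = (9, 9, 9)
    mask = default_mask(shape)
    region = RegionSpec("content", code="content", center=(4, 4, 4), radius=1.5,
                        amplitude=3.0)
    vol = generate_fmri_dataset(trials, [region], shape, mask, noise_sd=1.0, seed=9)
    vis = binarize_visibility_by_median(trials["pas"].to_numpy())
    flat_index = np.flatnonzero(mask.ravel())
    region_cols = np.searchsorted(
        flat_index, np.ravel_multi_index(region.voxel_indices(shape).T, shape))
    acc = roi_content_decode(vol, region_cols, vis, seed=2)
    assert acc["high"] > 0.8
    assert abs(acc["low"] - 0.5) < 0.15


def test_label_permutation_destroys_roi_decoding():
    trials = simulate_fmri_behavior(200, seed=10)
    shape = (9, 9, 9)
    mask = default_mask(shape)
    region = RegionSpec("content", code="content", center=(4, 4, 4), radius=1.5,
                        amplitude=3.0)
    vol = generate_fmri_dataset(trials, [region], shape, mask, noise_sd=1.0, seed=11)
    rng = np.random.default_rng(3)
    vol.labels["stimulus"] = rng.permutation(vol.labels["stimulus"].to_numpy())
    vis = binarize_visibility_by_median(trials["pas"].to_numpy())
    cols = np.arange(20)
    accs = [roi_content_decode(vol, cols, vis, seed=s)["high"] for s in range(8)]
    assert abs(np.mean(accs) - 0.5) < 0.1


def test_within_exceeds_cross_for_content_specific_code():
    vol, vis, region = _visibility_volume(noise_sd=1.0, seed=12, n_trials=160,
                                          code="visibility_specific")
    within = searchlight_decode(vol, vis, "within_first", radius_voxels=1, seed=2)
    cross = searchlight_decode(vol, vis, "cross_first_to_second", radius_voxels=1, seed=2)
    cells = region.voxel_indices(vol.mask.shape)
    w = np.mean([within.values[tuple(c)] for c in cells])
    c = np.mean([cross.values[tuple(c)] for c in cells])
    assert w > c + 0.1
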