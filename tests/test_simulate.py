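"""Synthetic MEG/fMRI generators: shapes, determinism, planted geometry."""

import numpy as np
import pandas as pd
import pytest

from vividness import (
    EmbeddingSpec,
    RegionSpec,
    build_model_rdm,
    compute_neural_rdm_series,
    estimate_condition_patterns,
    generate_fmri_dataset,
    generate_meg_dataset,
    kendall_tau_lower,
    simulate_bold_and_estimate_betas,
    simulate_fmri_behavior,
)
from vividness.simulate import default_mask, scheme_pattern, _orthonormal_patterns


def test_epoch_has_551_samples_for_full_window(behavior):
    rec = generate_meg_dataset(behavior, EmbeddingSpec("null"), n_sensors=10, seed=0)
    assert rec.data.shape == (len(behavior), 10, 551)
    assert rec.time_ms[0] == -200.0 and rec.time_ms[-1] == 2000.0
    assert np.allclose(np.diff(rec.time_ms), 4.0)


def test_generation_is_bitwise_reproducible(behavior):
    spec = EmbeddingSpec("abstract_graded", snr=1.0, window=(0.0, 150.0))
    a = generate_meg_dataset(behavior, spec, 12, seed=4, epoch_ms=(-200, 200))
    b = generate_meg_dataset(behavior, spec, 12, seed=4, epoch_ms=(-200, 200))
    assert np.array_equal(a.data, b.data)


def test_window_outside_epoch_rejected(behavior):
    spec = EmbeddingSpec("abstract_graded", window=(100.0, 900.0))
    with pytest.raises(ValueError, match="window"):
        generate_meg_dataset(behavior, spec, 10, seed=0, epoch_ms=(-200, 600))


def test_graded_pattern_distances_monotone_in_rating_difference():
    # at infinite SNR the pairwise Pearson distance of the planted patterns is
    # an exactly monotone function of |delta PAS|, identical across stimuli
    basis = _orthonormal_patterns(30, 6, np.random.default_rng(0))
    pats = {(s, r): scheme_pattern("abstract_graded", basis, s, r)
            for s in (0, 1) for r in (1, 2, 3, 4)}
    def dist(a, b):
        pa, pb = pats[a][0], pats[b][0]
        pa, pb = pa - pa.mean(), pb - pb.mean()
        return 1 - pa @ pb / (np.linalg.norm(pa) * np.linalg.norm(pb))
    for s1 in (0, 1):
        for s2 in (0, 1):
            d = [dist((s1, 1), (s2, 1 + k)) for k in range(4)]
            assert np.allclose(d[0], 0.0, atol=1e-12)
            assert all(d[k + 1] > d[k] + 1e-9 for k in range(3))
    # content-invariance: distances do not depend on the stimulus pairing
    assert np.isclose(dist((0, 1), (0, 3)), dist((0, 1), (1, 3)), atol=1e-12)


@pytest.mark.parametrize("scheme,model", [
    ("abstract_graded", "abstract_graded"),
    ("abstract_discrete", "abstract_discrete"),
    ("specific_graded", "specific_graded"),
])
def test_noiseless_neural_rdm_attains_model_tau_maximum(behavior, scheme, model):
    spec = EmbeddingSpec(scheme, snr=2.0, window=(100.0, 400.0))
    rec = generate_meg_dataset(behavior, spec, 24, noise_sd=0.0, seed=5,
                               epoch_ms=(-200, 600))
    series = compute_neural_rdm_series(estimate_condition_patterns(rec))
    t_peak = np.argmin(np.abs(rec.time_ms - 250.0))
    m = build_model_rdm(model)
    tau = kendall_tau_lower(series.values[t_peak], m)
    assert tau == pytest.approx(kendall_tau_lower(m, m), abs=1e-12)


def test_ar1_noise_has_requested_autocorrelation(behavior):
    rec = generate_meg_dataset(behavior.head(40), EmbeddingSpec("null"), 20,
                               noise_sd=1.0, noise_ar1=0.7, seed=8,
                               epoch_ms=(-200, 600))
    x = rec.data.reshape(-1, rec.data.shape[-1])
    lag1 = np.mean([np.corrcoef(r[:-1], r[1:])[0, 1] for r in x[:200]])
    assert abs(lag1 - 0.7) < 0.05


def test_prestim_offset_only_before_zero(behavior):
    spec = EmbeddingSpec("null", snr=0.0, prestim_offset_gain=2.0)
    rec = generate_meg_dataset(behavior, spec, 15, noise_sd=0.0, seed=1,
                               epoch_ms=(-200, 200))
    pre = rec.data[:, :, rec.time_ms < 0]
    post = rec.data[:, :, rec.time_ms >= 0]
    assert np.abs(pre).max() > 0 and np.abs(post).max() == 0
    # offset scales with the PAS rating
    norms = np.linalg.norm(pre[:, :, 0], axis=1)
    pas = rec.labels["pas"].to_numpy()
    assert np.allclose(norms, 2.0 * pas, atol=1e-10)


# --- fMRI -----------------------------------------------------------------


def _fmri_setup(seed=0, n_trials=96):
    trials = simulate_fmri_behavior(n_trials, seed=seed)
    shape = (10, 10, 10)
    mask = default_mask(shape)
    region = RegionSpec("vis", code="visibility_invariant", center=(5, 5, 5),
                        radius=1.5, amplitude=2.0)
    return trials, shape, mask, region


def test_fmri_betas_shape_and_determinism():
    trials, shape, mask, region = _fmri_setup()
    a = generate_fmri_dataset(trials, [region], shape, mask, seed=3)
    b = generate_fmri_dataset(trials, [region], shape, mask, seed=3)
    assert a.betas.shape == (len(trials), int(mask.sum()))
    assert np.array_equal(a.betas, b.betas)


def test_region_outside_mask_rejected():
    trials, shape, mask, _ = _fmri_setup()
    bad = RegionSpec("edge", code="visibility_invariant", center=(0, 0, 0), radius=1)
    with pytest.raises(ValueError, match="outside the mask"):
        generate_fmri_dataset(trials, [bad], shape, mask, seed=0)


def test_visibility_region_signal_scales_with_rating():
    trials, shape, mask, region = _fmri_setup()
    vol = generate_fmri_dataset(trials, [region], shape, mask, noise_sd=0.0, seed=3)
    norms = np.linalg.norm(vol.betas, axis=1)
    pas = trials["pas"].to_numpy()
    w = (pas - 1) / 3.0
    assert np.allclose(norms, 2.0 * w, atol=1e-10)


def test_content_region_distinguishes_animacy_only_when_visible():
    trials, shape, mask, _ = _fmri_setup(n_trials=200)
    region = RegionSpec("content", code="content", center=(5, 5, 5), radius=1.5,
                        amplitude=2.0)
    vol = generate_fmri_dataset(trials, [region], shape, mask, noise_sd=0.0, seed=3)
    code = pd.Categorical(trials["stimulus"]).codes
    hi = trials["pas"].to_numpy() == 4
    lo = trials["pas"].to_numpy() <= 2
    d_hi = np.linalg.norm(vol.betas[hi & (code == 0)].mean(0)
                          - vol.betas[hi & (code == 1)].mean(0))
    d_lo = np.linalg.norm(vol.betas[lo & (code == 0)].mean(0)
                          - vol.betas[lo & (code == 1)].mean(0))
    assert d_hi > 10 * d_lo


# --- forward BOLD + trialwise GLM ------------------------------------------


def _true_volume(n_trials=12, seed=0):
    trials, shape, mask, region = _fmri_setup(seed=seed, n_trials=n_trials)
    return generate_fmri_dataset(trials, [region], shape, mask, noise_sd=0.0, seed=seed)


def test_noiseless_beta_recovery_is_exact():
    vol = _true_volume()
    onsets = 8.0 * np.arange(vol.betas.shape[0])
    rec = simulate_bold_and_estimate_betas(vol, onsets, tr_s=1.0, noise_sd=0.0)
    assert np.allclose(rec.betas, vol.betas, atol=1e-6)


def test_beta_recovery_error_grows_with_noise():
    vol = _true_volume()
    onsets = 4.0 * np.arange(vol.betas.shape[0])
    rmse = []
    for sd in (0.5, 1.0, 2.0):
        rec = simulate_bold_and_estimate_betas(vol, onsets, tr_s=1.0, noise_sd=sd, seed=42)
        rmse.append(np.sqrt(np.mean((rec.betas - vol.betas) ** 2)))
    assert rmse[0] < rmse[1] < rmse[2]


def test_zero_amplitude_trials_recover_near_zero_betas():
    vol = _true_volume()
    vol.betas[:] = 0.0
    onsets = 6.0 * np.arange(vol.betas.shape[0])
    rec = simulate_bold_and_estimate_betas(vol, onsets, tr_s=1.0, noise_sd=0.5, seed=1)
    assert np.abs(rec.betas.mean()) < 3 * 0.5 / np.sqrt(rec.betas.size)


def test_duplicate_onsets_rejected():
    vol = _true_volume(n_trials=3)
    with pytest.raises(ValueError, match="onsets"):
        simulate_bold_and_estimate_betas(vol, np.array([0.0, 8.0, 8.0]), tr_s=1.0)
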