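"""End-to-end synthetic scenarios reproducing each figure-level analysis.

Each scenario simulates a cohort of subjects with a known representational
code, runs the corresponding analysis chain, performs group inference, and
writes TSV/JSON outputs plus a machine-readable run report.  Scenarios:

- ``meg-rsa``: model-RDM RSA with shuffled controls, paired model tests, MDS.
- ``meg-tgm``: within/cross temporal generalization of PAS decoding with
  cluster tests against chance and cross-vs-within comparisons.
- ``meg-stimulus``: binary stimulus decoding in low/high-visibility groups.
- ``fmri-searchlight``: visibility searchlight in all four directions with the
  permute-then-bootstrap group null, FDR, averaged-cross and cross-minus-
  within tests.
- ``fmri-roi``: content decoding on the top visibility-decoding ROI voxels,
  split by visibility.

Two named profiles exist: ``full`` mirrors the reference analysis parameters
(epoch -200..2000 ms, 1,000 cluster permutations, 1,000 shuffle permutations,
25 x 10,000 searchlight null, radius-4 searchlights); ``reduced`` (default)
shrinks cohort and problem sizes so every scenario completes in minutes on a
single CPU.  All randomness derives from one master seed via a counter
scheme, so re-running a config reproduces every output bitwise.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decoding import (
    apply_min_trial_exclusion,
    binarize_visibility_by_median,
    binary_stimulus_decode,
    temporal_generalization,
)
from .inference import cluster_permutation_test, fdr_bh, paired_cluster_permutation, searchlight_group_test
from .preprocess import baseline_correct
from .rdm import build_model_rdm, shuffle_blend_rdms
from .rsa import (
    average_shuffled_tau,
    classical_mds,
    compare_models,
    compute_neural_rdm_series,
    estimate_condition_patterns,
    smooth_rdm_series,
)
from .searchlight import searchlight_decode
from .simulate import (
    EmbeddingSpec,
    RegionSpec,
    default_mask,
    generate_fmri_dataset,
    generate_meg_dataset,
    simulate_fmri_behavior,
)
from .staircase import PsychometricModel, simulate_behavior

__all__ = ["SCENARIOS", "validate_config", "run_scenario", "stage_seed"]

SCENARIOS = ("meg-rsa", "meg-tgm", "meg-stimulus", "fmri-searchlight", "fmri-roi")

_COMMON_DEFAULTS: dict = {
    "profile": "reduced",
    "seed": 0,
    "n_subjects": 15,
    "snr": 1.0,
    "scheme": "abstract_graded",
    "n_folds": 5,
    "cluster_alpha": 0.05,
    "n_perm": 1000,
}

# analysis parameters mirror the reference values; the reduced profile
# shrinks only problem sizes, never the statistical conventions
_SCENARIO_DEFAULTS: dict[str, dict] = {
    "meg-rsa": {
        "n_sensors": 50, "n_blocks": 11, "trials_per_block": 72,
        "epoch_ms": (-200.0, 2000.0), "window_ms": (100.0, 800.0),
        "kernel_ms": 60.0, "n_shuffle": 1000,
    },
    "meg-tgm": {
        "n_sensors": 50, "n_blocks": 11, "trials_per_block": 72,
        "epoch_ms": (-200.0, 2000.0), "window_ms": (100.0, 800.0),
        "smooth_samples": 7,
    },
    "meg-stimulus": {
        "n_sensors": 50, "n_blocks": 11, "trials_per_block": 72,
        "epoch_ms": (-200.0, 2000.0), "window_ms": (100.0, 800.0),
        "smooth_samples": 7, "stimulus_snr": 1.0,
    },
    "fmri-searchlight": {
        "n_trials": 184, "grid_shape": (16, 16, 16), "radius": 4,
        "shrinkage": 0.2, "n_label_perm": 25, "n_boot": 10000,
        "fdr_q": 0.01, "noise_sd": 1.0, "region_amplitude": 3.0,
        "min_per_cell": 10, "cohort": "content_invariant",
    },
    "fmri-roi": {
        "n_trials": 184, "grid_shape": (16, 16, 16), "radius": 4,
        "shrinkage": 0.2, "n_top_voxels": 200, "noise_sd": 1.0,
        "region_amplitude": 3.0, "min_per_cell": 10,
    },
}

_REDUCED_OVERRIDES: dict[str, dict] = {
    "meg-rsa": {
        "n_subjects": 8, "n_blocks": 6, "trials_per_block": 48,
        "epoch_ms": (-200.0, 800.0), "n_shuffle": 200, "n_perm": 500,
    },
    "meg-tgm": {
        "n_subjects": 8, "n_blocks": 6, "trials_per_block": 48,
        "epoch_ms": (-200.0, 600.0), "window_ms": (100.0, 500.0),
        "n_sensors": 30, "n_perm": 500,
    },
    "meg-stimulus": {
        "n_subjects": 8, "n_blocks": 6, "trials_per_block": 48,
        "epoch_ms": (-200.0, 800.0), "n_sensors": 30, "n_perm": 500,
    },
    "fmri-searchlight": {
        "n_subjects": 8, "n_trials": 120, "grid_shape": (10, 10, 10),
        "radius": 2, "n_label_perm": 10, "n_boot": 2000,
    },
    "fmri-roi": {
        "n_subjects": 8, "n_trials": 160, "grid_shape": (10, 10, 10),
        "radius": 2, "n_top_voxels": 30,
    },
}


def stage_seed(master_seed: int, stage: int, unit: int = 0) -> int:
    """Deterministic per-stage seed derivation (documented counter scheme)."""
    return int((master_seed * 1_000_003 + stage * 10_007 + unit) % (2**31 - 1))


def validate_config(config: dict) -> dict:
    """Fill defaults, apply the profile's size overrides, reject unknown keys.

    Explicit keys in ``config`` always win over profile overrides; the report
    records every deviation from the full-profile (reference) defaults.
    """
    if "scenario" not in config:
        raise ValueError("config must name a 'scenario'")
    scenario = config["scenario"]
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    defaults = {**_COMMON_DEFAULTS, **_SCENARIO_DEFAULTS[scenario]}
    allowed = set(defaults) | {"scenario"}
    errors = [f"unknown config key {k!r}" for k in config if k not in allowed]
    if errors:
        raise ValueError("; ".join(errors))
    profile = config.get("profile", defaults["profile"])
    if profile not in ("reduced", "full"):
        raise ValueError(f"unknown profile {profile!r}")
    merged = dict(defaults)
    if profile == "reduced":
        merged.update(_REDUCED_OVERRIDES[scenario])
    merged.update(config)
    if merged.get("radius", 1) < 0:
        raise ValueError("config key 'radius' must be non-negative")
    if merged["n_perm"] < 1:
        raise ValueError("config key 'n_perm' must be >= 1")
    full = {**_COMMON_DEFAULTS, **_SCENARIO_DEFAULTS[scenario], "scenario": scenario}
    merged["deviations_from_full"] = sorted(
        k for k in merged if k in full and merged[k] != full[k] and k != "profile"
    )
    return merged


def _simulate_meg_subject(cfg: dict, subject: int, scheme: str | None = None,
                          stimulus_snr: float = 0.0) -> "object":
    behav = simulate_behavior(
        PsychometricModel(),
        n_blocks=cfg["n_blocks"],
        trials_per_block=cfg["trials_per_block"],
        seed=stage_seed(cfg["seed"], 1, subject),
    )
    spec = EmbeddingSpec(scheme or cfg["scheme"], snr=cfg["snr"], window=cfg["window_ms"])
    rec = generate_meg_dataset(
        behav, spec, n_sensors=cfg["n_sensors"],
        seed=stage_seed(cfg["seed"], 2, subject),
        epoch_ms=tuple(cfg["epoch_ms"]), subject_id=f"S{subject:02d}",
    )
    if stimulus_snr:
        # add a visibility-scaled stimulus-identity pattern for content decoding
        rng = np.random.default_rng(stage_seed(cfg["seed"], 3, subject))
        pat = rng.standard_normal(cfg["n_sensors"])
        pat -= pat.mean()
        pat /= np.linalg.norm(pat)
        from .simulate import _raised_cosine, CONTENT_VISIBILITY_WEIGHT
        env = _raised_cosine(rec.time_ms, tuple(cfg["window_ms"]))
        sign = np.where(behav["stimulus"] == behav["stimulus"].iloc[0], 1.0, -1.0)
        w = behav["pas"].map(CONTENT_VISIBILITY_WEIGHT).to_numpy()
        rec.data += (stimulus_snr * sign * w)[:, None, None] * pat[None, :, None] * env[None, None, :]
    return baseline_correct(rec)


def _winning_model(group_tau: dict[str, np.ndarray], window_mask: np.ndarray) -> str:
    """Model with the largest group-mean tau inside the embedding window."""
    scores = {k: float(v.mean(axis=0)[window_mask].mean()) for k, v in group_tau.items()}
    return max(scores, key=scores.get)


def _run_meg_rsa(cfg: dict, out: Path) -> dict:
    kinds = ["abstract_graded", "abstract_discrete", "specific_graded"]
    models = [build_model_rdm(k) for k in kinds]
    all_fits, mean_rdms = [], []
    for s in range(cfg["n_subjects"]):
        rec = _simulate_meg_subject(cfg, s)
        series = smooth_rdm_series(
            compute_neural_rdm_series(estimate_condition_patterns(rec)),
            kernel_ms=cfg["kernel_ms"],
        )
        fits = compare_models(series, models, subject_id=rec.subject_id)
        pairs = shuffle_blend_rdms(cfg["n_shuffle"], seed=stage_seed(cfg["seed"], 4, s))
        shuffled = average_shuffled_tau(series, pairs)
        shuffled["subject_id"] = rec.subject_id
        all_fits.append(pd.concat([fits, shuffled], ignore_index=True))
        window = (series.time_ms >= cfg["window_ms"][0]) & (series.time_ms <= cfg["window_ms"][1])
        mean_rdms.append(series.values[window].mean(axis=0))
    fits = pd.concat(all_fits, ignore_index=True)
    fits.to_csv(out / "model_fits.tsv", sep="\t", index=False)

    time_ms = np.sort(fits["time_ms"].unique())
    group_tau = {
        kind: fits[fits["model"] == kind].pivot(index="subject_id", columns="time_ms",
                                                values="tau").to_numpy()
        for kind in kinds + ["shuffled_discrete", "shuffled_graded"]
    }
    tests = {
        kind: cluster_permutation_test(taus, 0.0, cfg["n_perm"], cfg["cluster_alpha"],
                                       "greater", seed=stage_seed(cfg["seed"], 5, i))
        for i, (kind, taus) in enumerate(group_tau.items())
    }
    paired = {
        f"abstract_graded_vs_{other}": paired_cluster_permutation(
            group_tau["abstract_graded"], group_tau[other], cfg["n_perm"],
            cfg["cluster_alpha"], "two-sided", seed=stage_seed(cfg["seed"], 6, i))
        for i, other in enumerate(["abstract_discrete", "specific_graded"])
    }
    coords = classical_mds(np.mean(mean_rdms, axis=0), k=2)
    pd.DataFrame(coords, columns=[f"dim{i+1}" for i in range(coords.shape[1])]).to_csv(
        out / "mds_coordinates.tsv", sep="\t", index=False)

    window_mask = (time_ms >= cfg["window_ms"][0]) & (time_ms <= cfg["window_ms"][1])
    summary = {
        "winning_model": _winning_model({k: group_tau[k] for k in kinds}, window_mask),
        "significant_models": [k for k, t in tests.items() if t.any_significant],
        "paired_tests": {name: {"significant": t.any_significant,
                                "min_p": min((c.p for c in t.clusters), default=1.0)}
                         for name, t in paired.items()},
        "cluster_extents_ms": {
            kind: [[float(time_ms[m.mask][0]), float(time_ms[m.mask][-1])]
                   for m in t.clusters if m.p < 0.05]
            for kind, t in tests.items()
        },
    }
    return summary


def _run_meg_tgm(cfg: dict, out: Path) -> dict:
    directions = {}
    for s in range(cfg["n_subjects"]):
        rec = _simulate_meg_subject(cfg, s)
        y = rec.labels["pas"].to_numpy()
        stims = sorted(rec.labels["stimulus"].unique())
        mask_a = (rec.labels["stimulus"] == stims[0]).to_numpy()
        mask_b = ~mask_a
        sd = stage_seed(cfg["seed"], 7, s)
        runs = {
            "within_a": temporal_generalization(rec, y, "within", mask_a, mask_a,
                                                cfg["n_folds"], "auto",
                                                cfg["smooth_samples"], sd),
            "within_b": temporal_generalization(rec, y, "within", mask_b, mask_b,
                                                cfg["n_folds"], "auto",
                                                cfg["smooth_samples"], sd + 1),
            "cross_a_to_b": temporal_generalization(rec, y, "cross", mask_a, mask_b,
                                                    cfg["n_folds"], "auto",
                                                    cfg["smooth_samples"], sd + 2),
            "cross_b_to_a": temporal_generalization(rec, y, "cross", mask_b, mask_a,
                                                    cfg["n_folds"], "auto",
                                                    cfg["smooth_samples"], sd + 3),
        }
        for name, tgm in runs.items():
            directions.setdefault(name, []).append(tgm.accuracy)
        time_ms = rec.time_ms
    arrays = {k: np.stack(v) for k, v in directions.items()}
    long = []
    for name, arr in arrays.items():
        mean = arr.mean(axis=0)
        t_idx, te_idx = np.meshgrid(np.arange(mean.shape[0]), np.arange(mean.shape[1]),
                                    indexing="ij")
        long.append(pd.DataFrame({
            "train_ms": time_ms[t_idx.ravel()], "test_ms": time_ms[te_idx.ravel()],
            "accuracy": mean.ravel(), "direction": name,
        }))
    pd.concat(long, ignore_index=True).to_csv(out / "tgm_group_mean.tsv", sep="\t", index=False)

    chance = 0.25
    vs_chance = {
        name: cluster_permutation_test(arr, chance, cfg["n_perm"], cfg["cluster_alpha"],
                                       "greater", seed=stage_seed(cfg["seed"], 8, i))
        for i, (name, arr) in enumerate(arrays.items())
    }
    cross_vs_within = {
        "a": paired_cluster_permutation(arrays["cross_a_to_b"], arrays["within_a"],
                                        cfg["n_perm"], cfg["cluster_alpha"], "two-sided",
                                        seed=stage_seed(cfg["seed"], 9, 0)),
        "b": paired_cluster_permutation(arrays["cross_b_to_a"], arrays["within_b"],
                                        cfg["n_perm"], cfg["cluster_alpha"], "two-sided",
                                        seed=stage_seed(cfg["seed"], 9, 1)),
    }
    return {
        "above_chance": {k: t.any_significant for k, t in vs_chance.items()},
        "cross_vs_within_significant": {k: t.any_significant for k, t in cross_vs_within.items()},
        "mean_peak_accuracy": {k: float(arr.mean(axis=0).max()) for k, arr in arrays.items()},
    }


def _run_meg_stimulus(cfg: dict, out: Path) -> dict:
    accs = {"low": [], "high": []}
    for s in range(cfg["n_subjects"]):
        rec = _simulate_meg_subject(cfg, s, scheme="null",
                                    stimulus_snr=cfg["stimulus_snr"])
        for group in ("low", "high"):
            accs[group].append(binary_stimulus_decode(
                rec, group, cfg["n_folds"], "auto", cfg["smooth_samples"],
                seed=stage_seed(cfg["seed"], 10, s)))
        time_ms = rec.time_ms
    arrays = {k: np.stack(v) for k, v in accs.items()}
    pd.DataFrame({
        "time_ms": np.tile(time_ms, 2),
        "group": np.repeat(["low", "high"], time_ms.size),
        "accuracy": np.concatenate([arrays["low"].mean(0), arrays["high"].mean(0)]),
    }).to_csv(out / "stimulus_decoding.tsv", sep="\t", index=False)
    tests = {
        g: cluster_permutation_test(arrays[g], 0.5, cfg["n_perm"], cfg["cluster_alpha"],
                                    "greater", seed=stage_seed(cfg["seed"], 11, i))
        for i, g in enumerate(("low", "high"))
    }
    return {
        "above_chance": {g: t.any_significant for g, t in tests.items()},
        "peak_accuracy": {g: float(arrays[g].mean(0).max()) for g in arrays},
    }


def _fmri_regions(cfg: dict, mask: np.ndarray) -> list[RegionSpec]:
    shape = np.asarray(cfg["grid_shape"])
    r = max(1, int(min(shape) * 0.12))
    out = []
    for name, code, frac in (("visibility", "visibility_invariant", 0.38),
                             ("content", "content", 0.62)):
        center = tuple((shape * frac).astype(int))
        sphere = RegionSpec(name, code="none", center=center, radius=r)
        ijk = sphere.voxel_indices(mask.shape)
        ijk = ijk[mask[ijk[:, 0], ijk[:, 1], ijk[:, 2]]]  # clip to the brain mask
        out.append(RegionSpec(name, code=code, voxels=ijk, center=center, radius=r,
                              amplitude=cfg["region_amplitude"]))
    return out


def _simulate_fmri_subject(cfg: dict, subject: int, cohort: str = "roi"):
    """One subject's behaviour + beta volume, or None if excluded.

    ``cohort`` picks the planted regions: ``content_invariant`` (a single
    visibility-invariant region; cross and within visibility decoding should
    not differ), ``content_specific`` (a visibility-specific region with a
    separate pattern per animacy class; within should exceed cross), or
    ``roi`` (visibility-invariant plus a visibility-scaled content region,
    the configuration for ROI content decoding).
    """
    behav = simulate_fmri_behavior(cfg["n_trials"], seed=stage_seed(cfg["seed"], 12, subject))
    vis = binarize_visibility_by_median(behav["pas"].to_numpy())
    if not apply_min_trial_exclusion(behav["stimulus"].to_numpy(), vis, cfg["min_per_cell"]):
        return None
    mask = default_mask(tuple(cfg["grid_shape"]))
    regions = _fmri_regions(cfg, mask)
    if cohort == "content_invariant":
        regions = [r for r in regions if r.code == "visibility_invariant"]
    elif cohort == "content_specific":
        vis_region = next(r for r in regions if r.code == "visibility_invariant")
        regions = [RegionSpec(vis_region.name, code="visibility_specific",
                              voxels=vis_region.voxels, center=vis_region.center,
                              radius=vis_region.radius, amplitude=vis_region.amplitude)]
    elif cohort != "roi":
        raise ValueError(f"unknown cohort {cohort!r}")
    vol = generate_fmri_dataset(behav, regions, tuple(cfg["grid_shape"]), mask,
                                cfg["noise_sd"], seed=stage_seed(cfg["seed"], 13, subject))
    return vol, vis


def _run_fmri_searchlight(cfg: dict, out: Path) -> dict:
    cross_dirs = ("cross_first_to_second", "cross_second_to_first")
    within_dirs = ("within_first", "within_second")
    obs = {d: [] for d in cross_dirs + within_dirs}
    perm = {d: [] for d in cross_dirs + within_dirs}
    n_included = 0
    for s in range(cfg["n_subjects"]):
        sim = _simulate_fmri_subject(cfg, s, cohort=cfg["cohort"])
        if sim is None:
            continue
        vol, vis = sim
        n_included += 1
        rng = np.random.default_rng(stage_seed(cfg["seed"], 14, s))
        for d in cross_dirs + within_dirs:
            obs[d].append(searchlight_decode(vol, vis, d, cfg["radius"], cfg["shrinkage"],
                                             cfg["n_folds"],
                                             seed=stage_seed(cfg["seed"], 15, s)).in_mask())
            p_maps = []
            for p in range(cfg["n_label_perm"]):
                y_perm = rng.permutation(vis)
                p_maps.append(searchlight_decode(vol, y_perm, d, cfg["radius"],
                                                 cfg["shrinkage"], cfg["n_folds"],
                                                 seed=stage_seed(cfg["seed"], 16, s * 100 + p)
                                                 ).in_mask())
            perm[d].append(np.stack(p_maps))
    if n_included < 2:
        raise RuntimeError("fewer than 2 subjects survived the trial-count exclusion")
    obs_arr = {d: np.stack(v) for d, v in obs.items()}
    perm_arr = {d: np.stack(v) for d, v in perm.items()}

    # averaged cross map vs averaged null
    obs_cross = np.mean([obs_arr[d] for d in cross_dirs], axis=0)
    perm_cross = np.mean([perm_arr[d] for d in cross_dirs], axis=0)
    p_cross = searchlight_group_test(obs_cross, perm_cross, cfg["n_boot"],
                                     seed=stage_seed(cfg["seed"], 17, 0))
    sig_cross = fdr_bh(p_cross, cfg["fdr_q"])

    # cross-minus-within difference propagated through the bootstrap
    obs_within = np.mean([obs_arr[d] for d in within_dirs], axis=0)
    perm_within = np.mean([perm_arr[d] for d in within_dirs], axis=0)
    p_diff_hi = searchlight_group_test(obs_cross - obs_within, perm_cross - perm_within,
                                       cfg["n_boot"], seed=stage_seed(cfg["seed"], 17, 1))
    p_diff_lo = searchlight_group_test(obs_within - obs_cross, perm_within - perm_cross,
                                       cfg["n_boot"], seed=stage_seed(cfg["seed"], 17, 2))
    p_diff = np.minimum(1.0, 2 * np.minimum(p_diff_hi, p_diff_lo))  # two-sided
    sig_diff = fdr_bh(p_diff, cfg["fdr_q"])

    np.savetxt(out / "p_cross.tsv", p_cross, delimiter="\t")
    np.savetxt(out / "p_cross_minus_within.tsv", p_diff, delimiter="\t")
    return {
        "n_subjects_included": n_included,
        "n_voxels": int(p_cross.size),
        "n_significant_cross": int(sig_cross.sum()),
        "n_significant_cross_minus_within": int(sig_diff.sum()),
        "mean_cross_accuracy": float(obs_cross.mean()),
        "mean_within_accuracy": float(obs_within.mean()),
    }


def _run_fmri_roi(cfg: dict, out: Path) -> dict:
    from .searchlight import roi_content_decode, roi_top_voxels
    rows = []
    for s in range(cfg["n_subjects"]):
        sim = _simulate_fmri_subject(cfg, s, cohort="roi")
        if sim is None:
            continue
        vol, vis = sim
        maps = [searchlight_decode(vol, vis, d, cfg["radius"], cfg["shrinkage"],
                                   cfg["n_folds"], seed=stage_seed(cfg["seed"], 18, s))
                for d in ("within_first", "within_second",
                          "cross_first_to_second", "cross_second_to_first")]
        # synthetic ROI masks centred on the planted regions
        regions = _fmri_regions(cfg, vol.mask)
        for region in regions:
            roi = np.zeros(vol.mask.shape, dtype=bool)
            ijk = RegionSpec(region.name, code="none", center=region.center,
                             radius=region.radius + 1).voxel_indices(vol.mask.shape)
            roi[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
            roi &= vol.mask
            voxels = roi_top_voxels(maps, roi, cfg["n_top_voxels"])
            acc = roi_content_decode(vol, voxels, vis, cfg["n_folds"], cfg["shrinkage"],
                                     seed=stage_seed(cfg["seed"], 19, s))
            for split, a in acc.items():
                rows.append({"subject": s, "roi": region.name, "visibility": split,
                             "accuracy": a})
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "roi_content_decoding.tsv", sep="\t", index=False)
    summary = {}
    for (roi, split), grp in frame.groupby(["roi", "visibility"]):
        summary[f"{roi}_{split}"] = float(grp["accuracy"].mean())
    return {"mean_accuracy": summary, "n_subjects_included": int(frame["subject"].nunique())}


_RUNNERS = {
    "meg-rsa": _run_meg_rsa,
    "meg-tgm": _run_meg_tgm,
    "meg-stimulus": _run_meg_stimulus,
    "fmri-searchlight": _run_fmri_searchlight,
    "fmri-roi": _run_fmri_roi,
}


def run_scenario(config: dict, out_dir: str | Path) -> dict:
    """Validate the config, run the scenario, write outputs and a run report."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps({k: v for k, v in cfg.items()}, sort_keys=True, default=str)
    summary = _RUNNERS[cfg["scenario"]](cfg, out)
    report = {
        "scenario": cfg["scenario"],
        "package_version": __version__,
        "master_seed": cfg["seed"],
        "config": json.loads(cfg_json),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "summary": summary,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=2, default=str)
    return report
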