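"""Synthetic MEG-like and fMRI-like datasets with known representational geometry.

The generators plant one of four candidate vividness codes into noise:

``abstract_graded``
    One code shared by both stimuli whose sensor pattern rotates along an arc
    with PAS level (30 degrees per level) and whose amplitude grows linearly
    with PAS.  Because Pearson distance between zero-mean unit patterns is
    ``1 - cos(angle)``, the noiseless condition geometry is *exactly* graded:
    distance is a strictly increasing function of the rating difference and
    identical across stimuli.  A pure amplitude code would be invisible to a
    correlation distance (scaling leaves correlation at 1), so the graded
    codes here are angular with an amplitude gain on top.
``abstract_discrete``
    Four mutually orthogonal patterns, one per PAS level, shared by both
    stimuli: every pair of different ratings is equally dissimilar.
``specific_graded``
    The same 30-degree arc construction but in a separate (orthogonal)
    sensor-space plane per stimulus, so the largest within-stimulus distance
    (90 degrees) equals the cross-stimulus distance -- the noiseless geometry
    matches the specific-graded model RDM rank-for-rank.
``null``
    No rating-dependent signal.

Optional confounds: a contrast-proportional pattern (to exercise the
contrast-regression control) and a PAS-proportional prestimulus offset (to
exercise the no-baseline-correction analysis).  All patterns are zero-mean
orthonormal columns (QR of centred Gaussian draws), so planted geometries are
exact up to noise.

The fMRI generator plants visibility and content codes into spherical regions
of a masked voxel grid as per-trial beta amplitudes; a forward BOLD
simulation with a canonical double-gamma HRF and trialwise GLM recovery is
provided to validate the beta-series route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import gamma as gamma_dist

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingSpec",
    "EpochedRecording",
    "RegionSpec",
    "TrialBetaVolume",
    "generate_meg_dataset",
    "generate_fmri_dataset",
    "simulate_bold_and_estimate_betas",
]

SFREQ_HZ = 250.0
DT_MS = 1000.0 / SFREQ_HZ

SCHEMES = ("abstract_graded", "abstract_discrete", "specific_graded", "null")

#: angular separation between neighbouring PAS-level patterns (radians).
#: pi/6 per level puts ratings 1..4 on a quarter arc, so the maximal graded
#: distance (1 - cos 90deg = 1) equals the distance between orthogonal planes.
ARC_STEP_RAD = np.pi / 6.0

#: relative amplitude per PAS level for graded codes (linear in level).
GRADED_AMPLITUDE = {1: 0.25, 2: 0.5, 3: 0.75, 4: 1.0}


@dataclass(frozen=True)
class EmbeddingSpec:
    """What to plant into a synthetic MEG recording.

    ``snr`` is the ratio of the peak signal-pattern norm to the sensor noise
    standard deviation.  ``window`` (ms) bounds a raised-cosine temporal
    envelope.  ``contrast_gain`` adds a contrast-proportional pattern;
    ``prestim_offset_gain`` adds a PAS-proportional constant before 0 ms.
    ``seed`` optionally fixes the pattern draw independently of the noise.
    """

    scheme: str = "abstract_graded"
    snr: float = 1.0
    window: tuple[float, float] = (100.0, 800.0)
    contrast_gain: float = 0.0
    prestim_offset_gain: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown embedding scheme {self.scheme!r}; choose from {SCHEMES}")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")


@dataclass
class EpochedRecording:
    """Epoched sensor data: ``data`` is trials x sensors x samples.

    ``time_ms`` is uniform at 250 Hz; ``labels`` is the trial table aligned
    row-for-row with the first axis of ``data``.
    """

    data: np.ndarray
    time_ms: np.ndarray
    labels: pd.DataFrame
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.labels):
            raise ValueError("labels row count must equal trial count")
        if self.data.shape[2] != self.time_ms.size:
            raise ValueError("time axis length must equal sample count")
        dt = np.diff(self.time_ms)
        if dt.size and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("time axis must be strictly increasing and uniform")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EpochedRecording":
        return EpochedRecording(
            self.data.copy(), self.time_ms.copy(), self.labels.copy(), self.subject_id
        )


@dataclass(frozen=True)
class RegionSpec:
    """An informative region of the fMRI voxel grid.

    ``code`` is one of ``visibility_invariant`` (same visibility pattern for
    both animacy classes), ``visibility_specific`` (separate pattern per
    class), ``content`` (animate-vs-inanimate pattern whose strength grows
    with visibility), or ``none``.  Voxels are given either as
    ``(center, radius)`` in 0-based voxel indices or as an explicit ``(n, 3)``
    index array.
    """

    name: str
    code: str = "visibility_invariant"
    center: tuple[int, int, int] | None = None
    radius: float | None = None
    voxels: np.ndarray | None = None
    amplitude: float = 1.0

    def voxel_indices(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        if self.voxels is not None:
            return np.asarray(self.voxels, dtype=int)
        if self.center is None or self.radius is None:
            raise ValueError(f"region {self.name!r} needs either voxels or center+radius")
        offs = _sphere_offsets(self.radius)
        ijk = np.asarray(self.center, dtype=int) + offs
        ok = np.all((ijk >= 0) & (ijk < np.asarray(grid_shape)), axis=1)
        return ijk[ok]


@dataclass
class TrialBetaVolume:
    """Trialwise beta estimates on a masked 3D voxel grid.

    ``betas`` is trials x V where V counts the True voxels of ``mask`` in
    C-order; ``affine`` follows the NIfTI convention.
    """

    betas: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if self.betas.shape[1] != int(self.mask.sum()):
            raise ValueError("beta columns must match in-mask voxel count")
        if self.betas.shape[0] != len(self.labels):
            raise ValueError("labels row count must equal trial count")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def to_grid(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a length-V vector back onto the 3D grid."""
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.mask] = values
        return out


def _sphere_offsets(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def _orthonormal_patterns(n_sensors: int, n_patterns: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean orthonormal columns (n_sensors x n_patterns)."""
    if n_sensors < n_patterns + 1:
        raise ValueError("need more sensors than requested patterns")
    raw = rng.standard_normal((n_sensors, n_patterns))
    raw -= raw.mean(axis=0, keepdims=True)
    q, r = np.linalg.qr(raw)
    # fix sign for reproducibility across BLAS implementations
    q *= np.sign(np.diag(r))
    return q


def _raised_cosine(time_ms: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    on, off = window
    env = np.zeros_like(time_ms)
    inside = (time_ms >= on) & (time_ms <= off)
    env[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (time_ms[inside] - on) / (off - on)))
    return env


def scheme_pattern(scheme: str, basis: np.ndarray, stimulus: int, pas: int) -> tuple[np.ndarray, float]:
    """Unit pattern and relative amplitude for one condition under a scheme.

    ``basis`` holds >= 4 zero-mean orthonormal sensor columns; ``stimulus`` is
    0/1 and ``pas`` 1..4.
    """
    if scheme == "abstract_graded":
        theta = (pas - 1) * ARC_STEP_RAD
        return np.cos(theta) * basis[:, 0] + np.sin(theta) * basis[:, 1], GRADED_AMPLITUDE[pas]
    if scheme == "abstract_discrete":
        return basis[:, pas - 1], 1.0
    if scheme == "specific_graded":
        u, v = (basis[:, 0], basis[:, 1]) if stimulus == 0 else (basis[:, 2], basis[:, 3])
        theta = (pas - 1) * ARC_STEP_RAD
        return np.cos(theta) * u + np.sin(theta) * v, GRADED_AMPLITUDE[pas]
    raise ValueError(f"scheme {scheme!r} has no condition pattern")


def generate_meg_dataset(
    trials: pd.DataFrame,
    embedding: EmbeddingSpec,
    n_sensors: int = 50,
    noise_sd: float = 1.0,
    noise_ar1: float = 0.0,
    seed: int = 0,
    epoch_ms: tuple[float, float] = (-200.0, 2000.0),
    subject_id: str = "S00",
) -> EpochedRecording:
    """Epoched sensor recordings carrying the requested vividness code.

    Data are ``sum(code patterns x envelopes) + noise``; the peak planted
    pattern norm is ``embedding.snr * noise_sd``.  Noise is Gaussian across
    sensors, optionally AR(1) along time with coefficient ``noise_ar1``
    (stationary unit marginal variance before scaling).  The epoch spans
    ``epoch_ms`` inclusive at 250 Hz (551 samples for -200..2000 ms).
    Deterministic given ``seed`` (and ``embedding.seed`` for the patterns).
    """
    if len(trials) == 0:
        raise ValueError("trial table is empty")
    start, end = epoch_ms
    n_samples = int(round((end - start) / DT_MS)) + 1
    time_ms = start + DT_MS * np.arange(n_samples)
    uses_envelope = (embedding.scheme != "null" and embedding.snr > 0) or embedding.contrast_gain
    if uses_envelope:
        on, off = embedding.window
        if on < time_ms[0] or off > time_ms[-1] or on >= off:
            raise ValueError("embedding window must lie within the epoch")

    rng = np.random.default_rng(seed)
    pattern_rng = rng if embedding.seed is None else np.random.default_rng(embedding.seed)
    basis = _orthonormal_patterns(n_sensors, 6, pattern_rng)

    n_trials = len(trials)
    noise = rng.standard_normal((n_trials, n_sensors, n_samples))
    if noise_ar1:
        rho = float(noise_ar1)
        innov = noise * np.sqrt(1.0 - rho**2)
        innov[..., 0] = noise[..., 0]
        noise = lfilter([1.0], [1.0, -rho], innov, axis=-1)
    data = noise_sd * noise

    stim_codes = pd.Categorical(trials["stimulus"]).codes
    pas = trials["pas"].to_numpy()
    env = _raised_cosine(time_ms, embedding.window)
    # snr is relative to the noise floor; with zero noise it is the absolute amplitude
    amp = embedding.snr * noise_sd if noise_sd > 0 else embedding.snr

    if embedding.scheme != "null" and amp > 0:
        for (s, r), idx in pd.DataFrame({"s": stim_codes, "r": pas}).groupby(["s", "r"]).groups.items():
            pattern, rel = scheme_pattern(embedding.scheme, basis, int(s), int(r))
            data[list(idx)] += amp * rel * pattern[None, :, None] * env[None, None, :]

    if embedding.contrast_gain:
        c = trials["contrast"].to_numpy(dtype=float)
        data += (embedding.contrast_gain * c)[:, None, None] * basis[:, 4][None, :, None] * env[None, None, :]

    if embedding.prestim_offset_gain:
        pre = (time_ms < 0).astype(float)
        data += (embedding.prestim_offset_gain * pas)[:, None, None] * basis[:, 5][None, :, None] * pre[None, None, :]

    return EpochedRecording(data, time_ms, trials.reset_index(drop=True), subject_id)


#: visibility weight per rating: signal strength grows linearly from zero.
VISIBILITY_WEIGHT = {1: 0.0, 2: 1.0 / 3.0, 3: 2.0 / 3.0, 4: 1.0}

#: content-signal weight per rating: stimulus identity is essentially
#: unavailable below the awareness threshold (no experience / weak glimpse)
#: and rises steeply with a clear percept.
CONTENT_VISIBILITY_WEIGHT = {1: 0.0, 2: 0.1, 3: 0.7, 4: 1.0}


def simulate_fmri_behavior(
    n_trials: int = 184,
    seed: int = 0,
    vis_probs: tuple[float, float, float, float] = (0.1, 0.2, 0.35, 0.35),
    stimuli: tuple[str, str] = ("animate", "inanimate"),
) -> pd.DataFrame:
    """Trial table for the masked-object fMRI session.

    Animacy is balanced and randomly ordered; the 4-level visibility rating
    is drawn i.i.d. from ``vis_probs``, whose default skews toward higher
    ratings the way un-staircased visibility reports do (making the
    median-split machinery do real work).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    half = n_trials // 2
    stim = np.array([stimuli[0]] * half + [stimuli[1]] * (n_trials - half))
    rng.shuffle(stim)
    pas = rng.choice([1, 2, 3, 4], size=n_trials, p=vis_probs)
    return pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "stimulus": stim,
        "contrast": np.nan,
        "correct": True,
        "pas": pas,
        "block": 1 + np.arange(n_trials) * 4 // max(n_trials, 1),
    })


def default_mask(grid_shape: tuple[int, int, int] = (16, 16, 16), margin: int = 1) -> np.ndarray:
    """Ellipsoidal brain-like mask inside the grid."""
    ax = [np.linspace(-1.0, 1.0, n) for n in grid_shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    scale = 1.0 - margin / max(grid_shape)
    return gx**2 + gy**2 + gz**2 <= scale**2


def generate_fmri_dataset(
    trials: pd.DataFrame,
    regions: list[RegionSpec],
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    mask: np.ndarray | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    affine: np.ndarray | None = None,
) -> TrialBetaVolume:
    """Trialwise beta volumes with planted visibility/content regions.

    Per trial, in-mask betas are the sum of region contributions plus iid
    Gaussian voxel noise.  ``visibility_invariant`` regions carry a fixed
    voxel pattern scaled by the visibility weight regardless of animacy;
    ``content`` regions carry an animate-vs-inanimate (+/-) pattern whose
    amplitude also scales with visibility (content is decodable only when
    visibility is high); ``visibility_specific`` regions use a separate
    visibility pattern per animacy class.  Deterministic given ``seed``.
    """
    if mask is None:
        mask = default_mask(grid_shape)
    if mask.shape != tuple(grid_shape):
        raise ValueError("mask shape must equal grid_shape")
    if affine is None:
        affine = np.eye(4)
    rng = np.random.default_rng(seed)
    flat_index = -np.ones(grid_shape, dtype=int)
    flat_index[mask] = np.arange(int(mask.sum()))

    n_trials = len(trials)
    v = int(mask.sum())
    betas = noise_sd * rng.standard_normal((n_trials, v))

    vis = trials["pas"].to_numpy()
    stim_codes = pd.Categorical(trials["stimulus"]).codes  # 0 = first class alphabetically
    w = np.array([VISIBILITY_WEIGHT[int(r)] for r in vis])

    for region in regions:
        ijk = region.voxel_indices(grid_shape)
        cols = flat_index[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
        if np.any(cols < 0):
            raise ValueError(f"region {region.name!r} lies partly outside the mask")
        if region.code == "none":
            continue
        pattern = rng.standard_normal(cols.size)
        pattern -= pattern.mean()
        pattern /= np.linalg.norm(pattern)
        if region.code == "visibility_invariant":
            betas[:, cols] += region.amplitude * w[:, None] * pattern[None, :]
        elif region.code == "content":
            sign = np.where(stim_codes == 0, 1.0, -1.0)
            wc = np.array([CONTENT_VISIBILITY_WEIGHT[int(r)] for r in vis])
            betas[:, cols] += region.amplitude * (wc * sign)[:, None] * pattern[None, :]
        elif region.code == "visibility_specific":
            pattern2 = rng.standard_normal(cols.size)
            pattern2 -= pattern2.mean()
            pattern2 /= np.linalg.norm(pattern2)
            pat = np.where((stim_codes == 0)[:, None], pattern[None, :], pattern2[None, :])
            betas[:, cols] += region.amplitude * w[:, None] * pat
        else:
            raise ValueError(f"unknown region code {region.code!r}")

    return TrialBetaVolume(betas, mask, affine, trials.reset_index(drop=True))


def canonical_hrf(t_s: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                  ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak-normalised."""
    t = np.asarray(t_s, dtype=float)
    h = gamma_dist.pdf(t, peak) - ratio * gamma_dist.pdf(t, undershoot)
    h[t < 0] = 0.0
    peak_val = h.max()
    return h / peak_val if peak_val > 0 else h


def simulate_bold_and_estimate_betas(
    true_vol: TrialBetaVolume,
    onsets_s: np.ndarray,
    tr_s: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    hrf_kwargs: dict | None = None,
) -> TrialBetaVolume:
    """Forward-simulate BOLD and recover trialwise betas by least squares.

    Each voxel's time series is the sum over trials of the trial's true
    amplitude times the canonical HRF shifted to the trial onset, plus
    Gaussian noise.  Betas are re-estimated with one regressor per trial plus
    an intercept; with well-separated onsets and no noise the recovery is
    exact up to numerical precision.
    """
    onsets = np.asarray(onsets_s, dtype=float)
    if tr_s <= 0:
        raise ValueError("TR must be positive")
    if np.any(np.diff(onsets) < 0):
        raise ValueError("onsets must be sorted")
    if np.any(np.diff(onsets) == 0):
        raise ValueError("overlapping identical onsets")
    if onsets.size != true_vol.betas.shape[0]:
        raise ValueError("one onset per trial required")

    n_scans = int(np.ceil((onsets[-1] + 32.0) / tr_s)) + 1
    scan_t = tr_s * np.arange(n_scans)
    design = np.stack([canonical_hrf(scan_t - on, **(hrf_kwargs or {})) for on in onsets], axis=1)
    X = np.column_stack([design, np.ones(n_scans)])

    rng = np.random.default_rng(seed)
    Y = design @ true_vol.betas
    if noise_sd:
        Y += noise_sd * rng.standard_normal(Y.shape)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return TrialBetaVolume(coef[:-1], true_vol.mask, true_vol.affine, true_vol.labels.copy())
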