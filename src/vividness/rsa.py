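"""Representational similarity analysis over epoched sensor data.

Per time point: estimate one pattern per condition (dummy-coded OLS, which for
a one-hot design equals the condition mean across trials), compute the 8x8
Pearson-distance neural RDM over sensors, smooth each RDM cell across time
with a 60 ms uniform kernel, and rank-correlate the strictly-lower triangle
(28 cells, diagonal excluded) of the neural RDM against each model RDM with
Kendall's tau.

Tau-a is the default (pair-count normalisation ``n(n-1)/2``), the convention
for comparing model RDMs with tied values; tau-b (tie-corrected
denominator) is available as an option.  Rank correlation makes every
analysis invariant to monotone transforms of a model's values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .preprocess import boxcar_smooth
from .rdm import ModelRDM, N_CONDITIONS, condition_order
from .simulate import DT_MS, EpochedRecording

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionPatterns",
    "NeuralRDMSeries",
    "estimate_condition_patterns",
    "compute_neural_rdm_series",
    "smooth_rdm_series",
    "kendall_tau_lower",
    "compare_models",
    "average_shuffled_tau",
    "classical_mds",
]


@dataclass
class ConditionPatterns:
    """Condition x sensor x sample coefficient array with its condition order."""

    coefficients: np.ndarray
    conditions: list[str]
    time_ms: np.ndarray

    def __post_init__(self) -> None:
        if self.coefficients.shape[0] != len(self.conditions):
            raise ValueError("one coefficient row per condition required")


@dataclass
class NeuralRDMSeries:
    """Per-sample 8x8 Pearson-distance matrices (values in [0, 2])."""

    values: np.ndarray  # (n_samples, 8, 8)
    time_ms: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[1:] != (N_CONDITIONS, N_CONDITIONS):
            raise ValueError("values must be (n_samples, 8, 8)")


def estimate_condition_patterns(
    rec: EpochedRecording,
    stimuli: tuple[str, str] | None = None,
) -> ConditionPatterns:
    """Per-condition response patterns from dummy-coded least squares.

    The design has one one-hot indicator per condition and no intercept, so
    the coefficients are exactly the per-condition trial means at every
    (sensor, sample).  Raises if any of the 8 conditions has no trials.
    """
    labels = rec.labels
    if stimuli is None:
        stimuli = tuple(sorted(labels["stimulus"].unique()))
    conditions = condition_order(stimuli)
    coeffs = np.empty((N_CONDITIONS, rec.data.shape[1], rec.data.shape[2]))
    i = 0
    for s in stimuli:
        for r in (1, 2, 3, 4):
            sel = ((labels["stimulus"] == s) & (labels["pas"] == r)).to_numpy()
            if not sel.any():
                raise ValueError(f"condition {s}-PAS{r} has no trials")
            coeffs[i] = rec.data[sel].mean(axis=0)
            i += 1
    return ConditionPatterns(coeffs, conditions, rec.time_ms.copy())


def compute_neural_rdm_series(patterns: ConditionPatterns) -> NeuralRDMSeries:
    """Per-sample Pearson distance (1 - r over sensors) between condition patterns.

    A zero-variance pattern has no defined correlation with anything; its
    off-diagonal distances are set to the neutral value 1 and the event is
    logged.
    """
    coeffs = patterns.coefficients
    if coeffs.shape[1] < 2:
        raise ValueError("need at least 2 sensors")
    x = coeffs - coeffs.mean(axis=1, keepdims=True)  # centre over sensors
    norms = np.linalg.norm(x, axis=1)  # (8, T)
    degenerate = norms < 1e-300
    if degenerate.any():
        logger.info("zero-variance pattern at %d (condition, sample) cells; "
                    "distances set to 1", int(degenerate.sum()))
    safe = np.where(degenerate, 1.0, norms)
    xn = x / safe[:, None, :]
    corr = np.einsum("ist,jst->tij", xn, xn)
    dist = 1.0 - corr
    # neutral distance for degenerate patterns, exact zero diagonal
    bad = degenerate.T  # (T, 8)
    dist = np.where(bad[:, :, None] | bad[:, None, :], 1.0, dist)
    idx = np.arange(N_CONDITIONS)
    dist[:, idx, idx] = 0.0
    return NeuralRDMSeries(dist, patterns.time_ms.copy())


def smooth_rdm_series(
    series: NeuralRDMSeries, kernel_ms: float = 60.0, edge: str = "truncate"
) -> NeuralRDMSeries:
    """Convolve each RDM cell across time with a uniform kernel (default 60 ms = 15 samples)."""
    size = max(int(round(kernel_ms / DT_MS)), 1)
    return NeuralRDMSeries(boxcar_smooth(series.values, size, axis=0, edge=edge),
                           series.time_ms.copy())


def _lower(values: np.ndarray) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    if a.ndim == 2:
        return a[np.tril_indices(a.shape[0], -1)]
    return a.ravel()


def kendall_tau_lower(rdm_a, rdm_b, variant: str = "a") -> float:
    """Kendall rank correlation of two RDM lower triangles (diagonal excluded).

    Accepts square matrices (strictly-lower triangles are extracted),
    ``ModelRDM`` instances or flat vectors.  ``variant='a'`` (default) uses
    the pair-count denominator ``n(n-1)/2``; ``variant='b'`` is the
    tie-corrected statistic.  A constant input carries no rank information
    and yields 0 (logged).
    """
    x = _lower(rdm_a.values if isinstance(rdm_a, ModelRDM) else rdm_a)
    y = _lower(rdm_b.values if isinstance(rdm_b, ModelRDM) else rdm_b)
    if x.size != y.size:
        raise ValueError("RDMs must have matching dimensions")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.info("constant RDM passed to kendall_tau_lower; returning 0")
        return 0.0
    if variant == "b":
        return float(kendalltau(x, y).statistic)
    if variant != "a":
        raise ValueError("variant must be 'a' or 'b'")
    n = x.size
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, 1)
    return float(np.sum(sx[iu] * sy[iu]) / (n * (n - 1) / 2))


def _tau_batch(X: np.ndarray, y: np.ndarray, variant: str = "a") -> np.ndarray:
    """Kendall tau of each row of ``X`` (N x 28) against ``y`` (28,).

    Same statistics as :func:`kendall_tau_lower`; constant rows (or a
    constant ``y``) contribute no concordant/discordant pairs and come out
    as 0.
    """
    n = y.size
    iu, ju = np.triu_indices(n, 1)
    n_pairs = iu.size
    sy = np.sign(y[iu] - y[ju])
    sx = np.sign(X[:, iu] - X[:, ju])
    num = sx @ sy
    if variant == "a":
        return num / n_pairs
    ties_x = np.sum(sx == 0, axis=1)
    ties_y = np.sum(sy == 0)
    denom = np.sqrt((n_pairs - ties_x).astype(float) * (n_pairs - ties_y))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)


def _tau_a_batch(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return _tau_batch(X, y, "a")


def average_shuffled_tau(
    series: NeuralRDMSeries,
    pairs: list[tuple[ModelRDM, ModelRDM]],
) -> pd.DataFrame:
    """Permutation-averaged tau time courses for the shuffled control RDMs.

    For every (shuffled_discrete, shuffled_graded) pair the neural RDM series
    is rank-correlated per time point, and the tau values are averaged over
    all permutations, giving one control time course per family.
    """
    tril = np.tril_indices(N_CONDITIONS, -1)
    neural = series.values[:, tril[0], tril[1]]  # (T, 28)
    acc = {"shuffled_discrete": 0.0, "shuffled_graded": 0.0}
    for disc, grad in pairs:
        acc["shuffled_discrete"] += _tau_a_batch(neural, disc.lower_triangle())
        acc["shuffled_graded"] += _tau_a_batch(neural, grad.lower_triangle())
    frames = [
        pd.DataFrame({"time_ms": series.time_ms, "model": kind, "tau": total / len(pairs)})
        for kind, total in acc.items()
    ]
    return pd.concat(frames, ignore_index=True)


def compare_models(
    series: NeuralRDMSeries,
    models: list[ModelRDM],
    variant: str = "a",
    subject_id: str = "S00",
) -> pd.DataFrame:
    """Per-sample Kendall tau between the neural RDM series and each model.

    Returns a long-format frame (time_ms, model, tau, subject_id).  A uniform
    model (constant lower triangle, i.e. the specific-discrete null) cannot
    be rank-correlated and is rejected; it is compared only implicitly, as
    the tau = 0 reference of the other models.
    """
    if not models:
        raise ValueError("no models given")
    if variant not in ("a", "b"):
        raise ValueError("variant must be 'a' or 'b'")
    for m in models:
        if np.ptp(m.lower_triangle()) == 0:
            raise ValueError(
                f"model {m.kind!r} has a uniform lower triangle; a rank correlation "
                "against it is undefined — it serves only as the implicit tau=0 null"
            )
    tril = np.tril_indices(N_CONDITIONS, -1)
    neural = series.values[:, tril[0], tril[1]]
    frames = []
    for m in models:
        taus = _tau_batch(neural, m.lower_triangle(), variant=variant)
        frames.append(pd.DataFrame({
            "time_ms": series.time_ms, "model": m.kind, "tau": taus,
            "subject_id": subject_id,
        }))
    return pd.concat(frames, ignore_index=True)


def classical_mds(rdm, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling of a dissimilarity matrix.

    Double-centres the squared dissimilarities, eigendecomposes, and returns
    coordinates built from the top-``k`` positive eigenvalues.  If fewer than
    ``k`` eigenvalues are positive, fewer dimensions are returned (logged).
    Orientation (sign/rotation) is arbitrary, as for any MDS embedding.
    """
    d = np.asarray(rdm.values if isinstance(rdm, ModelRDM) else rdm, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("RDM must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("RDM must be symmetric with zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-12 * max(abs(eigval[0]), 1.0)
    n_pos = int(np.sum(eigval > tol))
    if n_pos < k:
        logger.info("classical_mds: only %d positive eigenvalues; returning %d dims",
                    n_pos, n_pos)
    k_eff = min(k, n_pos)
    return eigvec[:, :k_eff] * np.sqrt(eigval[:k_eff])
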