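"""Group-level nonparametric inference.

Cluster-based sign-flip permutation tests over one or two time dimensions
(FieldTrip-style): a one-sample t statistic is computed per point, points
exceeding the cluster-forming threshold are grouped by adjacency
(4-connectivity in 2D), each cluster is summarised by the sum of its
t-values, and the observed cluster statistics are compared with the maximum
cluster statistic across whole-map subject sign flips.  Paired comparisons
swap the two conditions within subjects, which is equivalent to sign-flipping
the within-subject differences.

For searchlight maps, a Stelzer-style permute-then-bootstrap null is used:
each subject contributes a small set of label-permuted accuracy maps, and
bootstrap samples draw one permuted map per subject and average, giving a
group-mean null distribution per voxel; voxelwise p-values are then corrected
with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Cluster",
    "ClusterTestResult",
    "cluster_permutation_test",
    "paired_cluster_permutation",
    "searchlight_group_test",
    "fdr_bh",
]

_STRUCTURE_2D = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class Cluster:
    """A connected suprathreshold region with its summed-t statistic and p-value."""

    mask: np.ndarray
    stat: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    t_obs: np.ndarray
    n_perm: int
    cluster_alpha: float
    tail: str
    null_max: np.ndarray = field(repr=False, default=None)

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        out = np.zeros_like(self.t_obs, dtype=bool)
        for c in self.clusters:
            if c.p < alpha:
                out |= c.mask
        return out

    @property
    def any_significant(self) -> bool:
        return any(c.p < 0.05 for c in self.clusters)


def _t_from_signs(signs: np.ndarray, x: np.ndarray) -> np.ndarray:
    """One-sample t maps for sign-flipped data, vectorised over permutations.

    ``signs`` is (P, S), ``x`` is (S, M).  Sign flips change the mean but not
    the per-point sum of squares, so the t statistic follows from the flipped
    mean alone.
    """
    n = x.shape[0]
    ss = np.einsum("sm,sm->m", x, x)
    means = signs @ x / n
    var = np.maximum(ss[None, :] - n * means**2, 0.0) / (n - 1)
    se = np.sqrt(var / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, means / se, 0.0)
    return t


def _find_clusters(t_map: np.ndarray, threshold: float, negative: bool = False):
    """Maximal connected components above threshold (or below -threshold)."""
    supra = t_map < -threshold if negative else t_map > threshold
    structure = _STRUCTURE_2D if t_map.ndim == 2 else np.ones(3, dtype=bool)
    if t_map.ndim == 2:
        labeled, n = ndimage.label(supra, structure=structure)
    else:
        labeled, n = ndimage.label(supra, structure=structure)
    out = []
    for i in range(1, n + 1):
        m = labeled == i
        out.append((m, float(t_map[m].sum())))
    return out


def _max_cluster_stat(t_map: np.ndarray, threshold: float, two_sided: bool) -> float:
    stats_ = [abs(s) for _, s in _find_clusters(t_map, threshold)]
    if two_sided:
        stats_ += [abs(s) for _, s in _find_clusters(t_map, threshold, negative=True)]
    return max(stats_, default=0.0)


def cluster_permutation_test(
    values: np.ndarray,
    null_value: float = 0.0,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    tail: str = "greater",
    seed: int = 0,
    _perm_stat=None,
) -> ClusterTestResult:
    """Cluster-based one-sample sign-flip permutation test.

    ``values`` is subjects x time (1D clustering by temporal adjacency) or
    subjects x time x time (2D clustering, 4-connectivity).  Points whose
    one-sample t against ``null_value`` passes the ``cluster_alpha`` threshold
    form clusters; the cluster statistic is the sum of t.  The null is the
    maximum cluster statistic over whole-map per-subject sign flips, and
    cluster p-values use the (1 + exceedances) / (1 + n_perm) convention, so
    they are never 0.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError("tail must be 'greater', 'less' or 'two-sided'")
    x = np.asarray(values, dtype=float) - null_value
    if x.ndim not in (2, 3):
        raise ValueError("values must be (subjects, time) or (subjects, time, time)")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if tail == "less":
        res = cluster_permutation_test(-values, -null_value, n_perm, cluster_alpha,
                                       "greater", seed, _perm_stat)
        res.tail = "less"
        res.t_obs = -res.t_obs
        for c in res.clusters:
            c.stat = -c.stat
        return res

    shape = x.shape[1:]
    n_sub = x.shape[0]
    xf = x.reshape(n_sub, -1)
    two_sided = tail == "two-sided"
    p_point = cluster_alpha / 2 if two_sided else cluster_alpha
    t_crit = stats.t.ppf(1 - p_point, df=n_sub - 1)

    t_obs = _t_from_signs(np.ones((1, n_sub)), xf)[0].reshape(shape)
    observed = _find_clusters(t_obs, t_crit)
    if two_sided:
        observed += _find_clusters(t_obs, t_crit, negative=True)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    done = 0
    while done < n_perm:
        chunk = min(256, n_perm - done)
        if _perm_stat is None:
            signs = rng.choice([-1.0, 1.0], size=(chunk, n_sub))
            t_perm = _t_from_signs(signs, xf)
        else:
            t_perm = _perm_stat(rng, chunk, xf)
        for i in range(chunk):
            null_max[done + i] = _max_cluster_stat(t_perm[i].reshape(shape), t_crit, two_sided)
        done += chunk

    clusters = [
        Cluster(m, s, float((1 + np.sum(null_max >= abs(s))) / (1 + n_perm)))
        for m, s in observed
    ]
    return ClusterTestResult(clusters, t_obs, n_perm, cluster_alpha, tail, null_max)


def paired_cluster_permutation(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    tail: str = "two-sided",
    seed: int = 0,
) -> ClusterTestResult:
    """Paired cluster permutation test between two matched condition series.

    The observed statistic is the paired t (a vs b) per point.  Each
    permutation randomly swaps the two conditions within whole subjects and
    recomputes the paired t; this is the exchangeability-preserving analogue
    of sign-flipping the per-subject differences, and agrees with
    ``cluster_permutation_test`` applied to ``a - b``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have matching shapes")

    def perm_stat(rng: np.random.Generator, chunk: int, diff_flat: np.ndarray) -> np.ndarray:
        n_sub = a.shape[0]
        out = np.empty((chunk, diff_flat.shape[1]))
        af, bf = a.reshape(n_sub, -1), b.reshape(n_sub, -1)
        for i in range(chunk):
            swap = rng.random(n_sub) < 0.5
            a_p = np.where(swap[:, None], bf, af)
            b_p = np.where(swap[:, None], af, bf)
            out[i] = _t_from_signs(np.ones((1, n_sub)), a_p - b_p)[0]
        return out

    return cluster_permutation_test(
        a - b, 0.0, n_perm, cluster_alpha, tail, seed, _perm_stat=perm_stat
    )


def searchlight_group_test(
    observed_maps: np.ndarray,
    permuted_maps: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Voxelwise p-values from a permute-then-bootstrap group null.

    ``observed_maps`` is subjects x voxels; ``permuted_maps`` is subjects x
    n_perm x voxels (label-permuted decoding maps, 25 per subject in the
    reference analysis).  Each of ``n_boot`` bootstrap samples draws one
    permuted map per subject uniformly at random and averages across
    subjects; the voxel p-value is (1 + #{bootstrap mean >= observed group
    mean}) / (1 + n_boot).

    To test an averaged cross-direction map, average the observed and the
    permuted maps over directions before calling.  For the cross-minus-within
    difference test, pass per-subject difference maps (cross - within, with
    permuted maps differenced at matched permutation indices) so the
    difference propagates through the bootstrap.
    """
    obs = np.asarray(observed_maps, dtype=float)
    perm = np.asarray(permuted_maps, dtype=float)
    if obs.ndim != 2 or perm.ndim != 3:
        raise ValueError("expected observed (S, V) and permuted (S, P, V)")
    n_sub, n_vox = obs.shape
    if perm.shape[0] != n_sub or perm.shape[2] != n_vox:
        raise ValueError("permuted maps do not match observed maps")
    rng = np.random.default_rng(seed)
    obs_mean = obs.mean(axis=0)
    exceed = np.zeros(n_vox, dtype=np.int64)
    done = 0
    while done < n_boot:
        chunk = min(2000, n_boot - done)
        acc = np.zeros((chunk, n_vox))
        for s in range(n_sub):
            draws = rng.integers(0, perm.shape[1], size=chunk)
            acc += perm[s, draws, :]
        acc /= n_sub
        exceed += np.sum(acc >= obs_mean[None, :], axis=0)
        done += chunk
    return (1 + exceed) / (1 + n_boot)


def fdr_bh(pvals: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at level ``q``."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)
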