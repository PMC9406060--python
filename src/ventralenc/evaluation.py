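"""Model evaluation statistics for voxelwise encoding.

Prediction accuracy is the per-voxel Pearson correlation rho between
measured and predicted validation responses. A voxel counts as
"effectively encoded" when rho exceeds a validity threshold derived from a
shuffle null: sample correspondence is permuted many times, the null
correlation recomputed, and the (1 - alpha) order statistic taken per
voxel. The conventional global threshold is rho = 0.27 (alpha = 0.001 with
1000 shuffles at n = 120); for a standard-normal null this quantile is
approximately z_{1-alpha} / sqrt(n - 1), i.e. 3.09/sqrt(119) ~ 0.283.

Model comparisons use (a) Top-K average accuracy over the K best-predicted
voxels, (b) the advantage proportion — the share of jointly valid voxels a
model predicts better — against a coin-flip randomization null, and (c)
best-encoded-voxel proportions, assigning each voxel that at least one
model encodes validly to its argmax-accuracy model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AccuracyVector",
    "AdvantageResult",
    "pearson_accuracy",
    "permutation_threshold",
    "topk_average_accuracy",
    "advantage_analysis",
    "best_encoded_proportions",
    "DEFAULT_THRESHOLD",
]

#: Conventional global validity threshold (alpha = 0.001 shuffle null at n=120).
DEFAULT_THRESHOLD = 0.27

_TIE_EPS = 1e-12


@dataclass
class AccuracyVector:
    """Per-voxel prediction accuracies with a validity threshold.

    ``rho`` is NaN where the correlation is undefined (zero variance);
    ``defined`` marks finite entries and ``valid`` marks defined entries
    strictly above the threshold.
    """

    rho: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=np.float64)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.rho)

    @property
    def valid(self) -> np.ndarray:
        return self.defined & (self.rho > self.threshold)

    @property
    def n_voxels(self) -> int:
        return self.rho.shape[0]

    def mean_defined(self) -> float:
        if not self.defined.any():
            raise ValueError("no voxel has a defined accuracy")
        return float(np.mean(self.rho[self.defined]))


@dataclass
class AdvantageResult:
    """Pairwise model comparison over jointly valid voxels."""

    label_a: str
    label_b: str
    n_joint: int
    n_ties: int
    prop_a: float  # share of non-tied joint voxels where A wins
    prop_b: float
    null_cutoff: float  # (1 - alpha) quantile of the coin-flip null
    alpha: float
    significant: bool
    hist_edges: np.ndarray = field(repr=False, default=None)
    hist_counts: np.ndarray = field(repr=False, default=None)


def _columnwise_pearson(measured: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Pearson rho per column; NaN where either column has zero variance."""
    mc = measured - measured.mean(axis=0)
    pc = predicted - predicted.mean(axis=0)
    vm = np.einsum("ij,ij->j", mc, mc)
    vp = np.einsum("ij,ij->j", pc, pc)
    cov = np.einsum("ij,ij->j", mc, pc)
    denom = np.sqrt(vm * vp)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    return rho


def pearson_accuracy(
    measured: np.ndarray,
    predicted: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
) -> AccuracyVector:
    """Columnwise Pearson correlation between measured and predicted
    responses (samples x voxels). Zero-variance columns are flagged
    undefined (NaN), never silently zeroed."""
    measured = np.atleast_2d(np.asarray(measured, dtype=np.float64))
    predicted = np.atleast_2d(np.asarray(predicted, dtype=np.float64))
    if measured.shape != predicted.shape:
        raise ValueError(f"shape mismatch: measured {measured.shape} vs predicted {predicted.shape}")
    if measured.shape[0] < 3:
        raise ValueError("need at least 3 samples for a meaningful correlation")
    rho = _columnwise_pearson(measured, predicted)
    return AccuracyVector(rho=rho, threshold=threshold, n_samples=measured.shape[0])


def _null_quantile_index(n_perm: int, alpha: float) -> int:
    """k such that the k-th largest of n_perm null draws estimates the
    (1 - alpha) quantile: k = floor(alpha * n_perm) + 1. With 1000 draws at
    alpha = 0.001 this is the 2nd-largest value, a conservative order
    statistic (the empirical 99.9th percentile of 1000 draws would be the
    maximum, which is noisy)."""
    return int(np.floor(alpha * n_perm)) + 1


def permutation_threshold(
    measured: np.ndarray,
    predicted: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.001,
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> dict:
    """Shuffle-null validity thresholds.

    Permutes the sample correspondence ``n_perm`` times, recomputes the
    per-voxel correlation each time, and returns the per-voxel (1 - alpha)
    null quantile plus a global threshold (median of the per-voxel
    quantiles over defined voxels). Voxels with undefined correlation are
    excluded.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    measured = np.atleast_2d(np.asarray(measured, dtype=np.float64))
    predicted = np.atleast_2d(np.asarray(predicted, dtype=np.float64))
    if measured.shape != predicted.shape:
        raise ValueError("measured/predicted shape mismatch")
    n = measured.shape[0]
    mc = measured - measured.mean(axis=0)
    pc = predicted - predicted.mean(axis=0)
    sm = np.sqrt(np.einsum("ij,ij->j", mc, mc))
    sp = np.sqrt(np.einsum("ij,ij->j", pc, pc))
    defined = (sm > 0) & (sp > 0)
    zm = np.where(defined, mc / np.where(sm > 0, sm, 1.0), 0.0)
    zp = np.where(defined, pc / np.where(sp > 0, sp, 1.0), 0.0)
    null = np.empty((n_perm, measured.shape[1]))
    # chunked vectorized shuffles: argsort of uniforms = uniform permutation
    chunk = max(1, min(n_perm, int(2**22 // max(n, 1))))
    for lo in range(0, n_perm, chunk):
        hi = min(lo + chunk, n_perm)
        perms = np.argsort(rng.random((hi - lo, n)), axis=1)
        null[lo:hi] = np.einsum("tij,ij->tj", zm[perms], zp)
    k = min(_null_quantile_index(n_perm, alpha), n_perm)
    part = np.partition(null, n_perm - k, axis=0)
    per_voxel = np.where(defined, part[n_perm - k], np.nan)
    if defined.any():
        global_threshold = float(np.median(per_voxel[defined]))
    else:
        global_threshold = float("nan")
    return {
        "per_voxel": per_voxel,
        "global": global_threshold,
        "defined": defined,
        "n_perm": n_perm,
        "alpha": alpha,
        "order_statistic": k,
    }


def topk_average_accuracy(acc: AccuracyVector, k: int = 300) -> float:
    """Mean accuracy of the k best-predicted voxels (defined voxels only).

    With fewer than k defined voxels, the mean of all of them is returned
    with a warning."""
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = acc.rho[acc.defined]
    if vals.size == 0:
        raise ValueError("no voxel has a defined accuracy")
    if vals.size < k:
        warnings.warn(
            f"only {vals.size} defined voxels for Top-{k}; averaging all",
            stacklevel=2,
        )
        return float(vals.mean())
    top = np.partition(vals, vals.size - k)[vals.size - k :]
    return float(top.mean())


def advantage_analysis(
    acc_a: AccuracyVector,
    acc_b: AccuracyVector,
    threshold: float | None = None,
    n_perm: int = 1000,
    alpha: float = 0.001,
    *,
    labels: tuple[str, str] = ("A", "B"),
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    hist_range: tuple[float, float] = (-0.5, 0.5),
    hist_width: float = 0.05,
) -> AdvantageResult:
    """Advantage of model A over model B on jointly valid voxels.

    Restricts to voxels valid under both models, computes the share of
    non-tied voxels where A's accuracy is higher, and calibrates it
    against a coin-flip null: each voxel's (a, b) pair is swapped with
    probability 0.5, n_perm times, and the (1 - alpha) order statistic of
    the null advantage is the significance cutoff.
    """
    if acc_a.n_voxels != acc_b.n_voxels:
        raise ValueError("accuracy vectors cover different voxel sets")
    if rng is None:
        rng = np.random.default_rng(seed)
    thr_a = acc_a.threshold if threshold is None else threshold
    thr_b = acc_b.threshold if threshold is None else threshold
    joint = (
        acc_a.defined & acc_b.defined & (acc_a.rho > thr_a) & (acc_b.rho > thr_b)
    )
    n_joint = int(joint.sum())
    if n_joint == 0:
        raise ValueError("no voxel is valid under both models")
    a = acc_a.rho[joint]
    b = acc_b.rho[joint]
    diff = a - b
    ties = np.abs(diff) < _TIE_EPS
    n_ties = int(ties.sum())
    n_eff = n_joint - n_ties
    if n_eff > 0:
        prop_a = float(np.sum(diff > 0) / n_eff)
        prop_b = 1.0 - prop_a
    else:
        prop_a = prop_b = float("nan")
    # Coin-flip null: swapping a voxel's pair flips the sign of its diff.
    signs = np.sign(diff[~ties])
    flips = rng.random((n_perm, n_eff)) < 0.5 if n_eff else np.zeros((n_perm, 0), bool)
    null_prop = np.mean(np.where(flips, -signs, signs) > 0, axis=1) if n_eff else np.full(n_perm, np.nan)
    k = min(_null_quantile_index(n_perm, alpha), n_perm)
    cutoff = float(np.partition(null_prop, n_perm - k)[n_perm - k]) if n_eff else float("nan")
    edges = np.arange(hist_range[0], hist_range[1] + hist_width / 2, hist_width)
    counts, edges = np.histogram(diff, bins=edges)
    return AdvantageResult(
        label_a=labels[0],
        label_b=labels[1],
        n_joint=n_joint,
        n_ties=n_ties,
        prop_a=prop_a,
        prop_b=prop_b,
        null_cutoff=cutoff,
        alpha=alpha,
        significant=bool(n_eff and prop_a > cutoff),
        hist_edges=edges,
        hist_counts=counts,
    )


def best_encoded_proportions(
    models: dict[str, AccuracyVector],
    threshold: float | None = None,
) -> dict[str, float]:
    """Proportion of voxels best encoded by each model.

    A voxel is included when it is valid under at least one model; it is
    assigned to the model with the highest accuracy there (exact ties go
    to the earlier-listed model). Proportions sum to 1 over included
    voxels.
    """
    if len(models) < 1:
        raise ValueError("need at least one model")
    labels = list(models)
    n_vox = {acc.n_voxels for acc in models.values()}
    if len(n_vox) != 1:
        raise ValueError("models cover different voxel sets")
    rho = np.stack([models[l].rho for l in labels], axis=0)
    if threshold is None:
        valid = np.stack([models[l].valid for l in labels], axis=0)
    else:
        valid = np.isfinite(rho) & (rho > threshold)
    included = valid.any(axis=0)
    if not included.any():
        raise ValueError("no voxel is valid under any model")
    scores = np.where(np.isfinite(rho), rho, -np.inf)[:, included]
    winners = np.argmax(scores, axis=0)  # argmax takes the first on ties
    n_inc = int(included.sum())
    return {l: float(np.sum(winners == i) / n_inc) for i, l in enumerate(labels)}
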