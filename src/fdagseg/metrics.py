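"""Segmentation metrics (ASA, UE, MAE) and Friedman/Nemenyi rank tests.

ASA (achievable segmentation accuracy) is the fraction of pixels labeled
correctly when every superpixel adopts the ground-truth segment it
overlaps most; UE (undersegmentation error) is the normalized leakage of
superpixels across ground-truth boundaries.  Both are 0..1; ASA = 1 and
UE = 0 exactly when every superpixel lies inside one ground-truth
segment.

The Friedman test compares several methods over repeated samples using
within-sample ranks; the post-hoc Nemenyi test declares two methods
significantly different when their average ranks differ by at least the
critical distance CD = q_alpha * sqrt(nm (nm + 1) / (6 ns)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2, rankdata

__all__ = [
    "NemenyiConfig",
    "SaliencyMaps",
    "asa",
    "undersegmentation_error",
    "best_over_ground_truths",
    "mae",
    "friedman_test",
    "nemenyi_critical_distance",
    "Q_ALPHA_05",
]

#: Two-tailed Nemenyi critical values at alpha = 0.05 for k = 2..10
#: compared groups (studentized range statistic divided by sqrt(2)).
Q_ALPHA_05: dict[int, float] = {
    2: 1.960,
    3: 2.343,
    4: 2.569,
    5: 2.728,
    6: 2.850,
    7: 2.949,
    8: 3.031,
    9: 3.102,
    10: 3.164,
}


@dataclass(frozen=True)
class NemenyiConfig:
    """Inputs of the Nemenyi critical distance.

    n_methods : number of compared methods (>= 2)
    n_samples : number of samples (images) ranked (>= 1)
    q_alpha   : critical value of the Nemenyi statistic; defaults to the
                built-in alpha = 0.05 table entry for ``n_methods``.
    """

    n_methods: int
    n_samples: int
    q_alpha: float | None = None

    def __post_init__(self) -> None:
        if self.n_methods < 2:
            raise ValueError("need at least 2 methods")
        if self.n_samples < 1:
            raise ValueError("need at least 1 sample")
        if self.q_alpha is None:
            if self.n_methods not in Q_ALPHA_05:
                raise ValueError(
                    "no built-in q_alpha for this method count; pass q_alpha"
                )
            object.__setattr__(self, "q_alpha", Q_ALPHA_05[self.n_methods])
        elif self.q_alpha <= 0:
            raise ValueError("q_alpha must be positive")


@dataclass(frozen=True)
class SaliencyMaps:
    """A predicted and a reference saliency map, both in [0, 1]."""

    predicted: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.predicted, dtype=float)
        r = np.asarray(self.reference, dtype=float)
        if p.shape != r.shape:
            raise ValueError("maps must be co-registered")
        for name, m in (("predicted", p), ("reference", r)):
            if m.min() < 0 or m.max() > 1:
                raise ValueError(f"{name} map values must lie in [0, 1]")
        object.__setattr__(self, "predicted", p)
        object.__setattr__(self, "reference", r)


def _overlap_matrix(labels: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """Contingency counts: rows = superpixels, cols = GT segments."""
    labels = np.asarray(labels).ravel()
    gt = np.asarray(gt).ravel()
    _, li = np.unique(labels, return_inverse=True)
    _, gi = np.unique(gt, return_inverse=True)
    n_l, n_g = li.max() + 1, gi.max() + 1
    counts = np.bincount(li * n_g + gi, minlength=n_l * n_g)
    return counts.reshape(n_l, n_g)


def asa(labels: np.ndarray, gt: np.ndarray) -> float:
    """Achievable segmentation accuracy of a superpixel map against GT.

    Each superpixel adopts the GT segment of largest overlap; ASA is the
    fraction of pixels labeled correctly under that assignment.
    """
    if np.shape(labels) != np.shape(gt):
        raise ValueError("label map and ground truth must have the same shape")
    overlap = _overlap_matrix(labels, gt)
    return float(overlap.max(axis=1).sum() / overlap.sum())


def undersegmentation_error(labels: np.ndarray, gt: np.ndarray) -> float:
    """Undersegmentation error: normalized leakage across GT boundaries.

    For each GT segment G, every superpixel S overlapping it contributes
    min(|S ∩ G|, |S \\ G|); the sum is normalized by the total pixel
    count.
    """
    if np.shape(labels) != np.shape(gt):
        raise ValueError("label map and ground truth must have the same shape")
    overlap = _overlap_matrix(labels, gt)
    sizes = overlap.sum(axis=1, keepdims=True)
    leak = np.minimum(overlap, sizes - overlap)
    leak[overlap == 0] = 0
    return float(leak.sum() / overlap.sum())


def best_over_ground_truths(
    labels: np.ndarray, gts: Sequence[np.ndarray]
) -> tuple[float, float]:
    """Best ASA (max) and best UE (min) over several annotations,
    selected independently."""
    if len(gts) == 0:
        raise ValueError("need at least one ground-truth map")
    asas = [asa(labels, g) for g in gts]
    ues = [undersegmentation_error(labels, g) for g in gts]
    return max(asas), min(ues)


def mae(maps: SaliencyMaps) -> float:
    """Mean absolute per-pixel difference between the two maps."""
    return float(np.abs(maps.predicted - maps.reference).mean())


def friedman_test(
    scores: np.ndarray, larger_is_better: bool = True
) -> tuple[float, float, np.ndarray]:
    """Friedman rank test over an (n_samples x n_methods) score table.

    Each sample's methods are ranked 1 (best) to nm (worst), with
    average ranks on ties; "best" means largest score when
    ``larger_is_better`` else smallest.  Returns the chi-square
    statistic with nm - 1 degrees of freedom, its upper-tail p-value,
    and the per-method average ranks.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("expected an n_samples x n_methods table")
    ns, nm = scores.shape
    if nm < 2:
        raise ValueError("need at least 2 methods")
    if np.isnan(scores).any():
        raise ValueError("score table must have no missing entries")
    oriented = -scores if larger_is_better else scores
    ranks = rankdata(oriented, axis=1)
    avg = ranks.mean(axis=0)
    stat = 12.0 * ns / (nm * (nm + 1)) * ((avg - (nm + 1) / 2.0) ** 2).sum()
    p = float(chi2.sf(stat, df=nm - 1))
    return float(stat), p, avg


def nemenyi_critical_distance(config: NemenyiConfig) -> float:
    """Nemenyi critical distance, rounded to 4 decimals for reporting."""
    nm, ns = config.n_methods, config.n_samples
    cd = config.q_alpha * np.sqrt(nm * (nm + 1) / (6.0 * ns))
    return round(float(cd), 4)
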