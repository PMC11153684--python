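"""Overlap scoring between a binary truth image and a real-valued prediction.

The soft classifier score is one minus the mean squared voxel difference,

    d_s(I1, I2) = 1 - sum((I1 - I2)^2) / (x * y * z),

and the hard score binarizes the prediction at a threshold zeta (strictly
greater-than) before applying d_s.  For inputs valued in [0, 1] both scores lie
in [0, 1].  Cohort summaries report mean and sample (n-1) standard deviation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy import ndimage

__all__ = [
    "soft_score",
    "hard_score",
    "cohort_summary",
    "ScoreReport",
    "dice",
    "metastasis_truth_mask",
    "localization_percentiles",
    "localization_summary",
    "default_zeta",
]


def _check_shapes(i1, i2):
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    if i1.shape != i2.shape:
        raise ValueError(f"shape mismatch: {i1.shape} vs {i2.shape}")
    return i1, i2


def soft_score(I1, I2) -> float:
    """d_s(I1, I2) = 1 - mean squared voxel difference."""
    i1, i2 = _check_shapes(I1, I2)
    return float(1.0 - np.sum((i1 - i2) ** 2) / i1.size)


def hard_score(I1, I2, zeta: float) -> float:
    """d_h(I1, I2, zeta) = d_s on the prediction binarized at alpha > zeta."""
    i1, i2 = _check_shapes(I1, I2)
    return soft_score(i1, (i2 > zeta).astype(float))


def default_zeta(n_grid_points: int) -> float:
    """Uniform-probability baseline threshold 1/|Omega|."""
    if n_grid_points < 1:
        raise ValueError("need at least one grid point")
    return 1.0 / n_grid_points


@dataclass
class ScoreReport:
    per_case: pd.DataFrame
    mean_soft: float
    std_soft: float
    mean_hard: float
    std_hard: float
    zeta: float | None = None

    def to_csv(self, path) -> None:
        self.per_case.to_csv(path, index=False)

    def summary(self) -> str:
        return (
            f"hard {self.mean_hard:.4f} +/- {self.std_hard:.4f}, "
            f"soft {self.mean_soft:.4f} +/- {self.std_soft:.4f}"
        )


def cohort_summary(scores, zeta: float | None = None) -> ScoreReport:
    """Per-case table plus MEAN +/- STD over (soft, hard) score pairs."""
    scores = list(scores)
    if not scores:
        raise ValueError("empty cohort")
    df = pd.DataFrame(scores, columns=["soft", "hard"])
    df.insert(0, "case", np.arange(1, len(df) + 1))
    std_soft = float(df["soft"].std(ddof=1)) if len(df) > 1 else 0.0
    std_hard = float(df["hard"].std(ddof=1)) if len(df) > 1 else 0.0
    return ScoreReport(
        per_case=df,
        mean_soft=float(df["soft"].mean()),
        std_soft=std_soft,
        mean_hard=float(df["hard"].mean()),
        std_hard=std_hard,
        zeta=zeta,
    )


def dice(a, b) -> float:
    """Dice overlap 2|A.B| / (|A| + |B|); 1.0 for two empty masks."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def metastasis_truth_mask(met_mask, dilation: int = 1) -> np.ndarray:
    """Ground-truth binary image I1: planted voxels dilated to absorb
    rasterization error (dilation radius in voxels, 0 disables)."""
    mask = np.asarray(met_mask).astype(bool)
    if dilation > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, iterations=dilation)
    return mask


def localization_percentiles(heatmap, truth_mask) -> np.ndarray:
    """Percentile rank (0-100) of the heatmap value at each truth voxel.

    The value at a truth voxel is taken at its nearest grid point; ranks are
    computed among the *nonzero* grid values (mid-rank for ties).  Empty result
    if the truth mask is empty or the heatmap has no support.
    """
    truth = np.asarray(truth_mask).astype(bool)
    nonzero = np.sort(heatmap.nonzero_grid_values())
    voxels = np.argwhere(truth)
    if voxels.size == 0 or nonzero.size == 0:
        return np.array([])
    ranks = []
    for vox in voxels:
        v = heatmap.nearest_grid_value(vox)
        lo = np.searchsorted(nonzero, v, side="left")
        hi = np.searchsorted(nonzero, v, side="right")
        ranks.append(100.0 * (lo + 0.5 * (hi - lo)) / nonzero.size)
    return np.array(ranks)


def localization_summary(cases) -> dict:
    """Pooled localization of planted sites across (heatmap, truth_mask) cases.

    Two complementary views of how strongly the heatmap concentrates on the
    planted sites:

    * ``mean_truth_value`` vs ``nonzero_p80``: the mean heatmap value at truth
      voxels against the 80th-percentile value of the pooled nonzero grid
      values (an enrichment-in-value statement; heatmaps are L1-normalized so
      values pool on a common scale);
    * ``mean_percentile``: the mean percentile rank of truth-voxel values among
      each case's nonzero grid values.
    """
    truth_vals: list[float] = []
    nonzero: list[float] = []
    ranks: list[float] = []
    for hm, truth in cases:
        truth = np.asarray(truth).astype(bool)
        nonzero.extend(hm.nonzero_grid_values())
        truth_vals.extend(hm.nearest_grid_value(v) for v in np.argwhere(truth))
        ranks.extend(localization_percentiles(hm, truth))
    if not truth_vals or not nonzero:
        raise ValueError("need at least one truth voxel and one nonzero grid value")
    mean_truth = float(np.mean(truth_vals))
    p80 = float(np.quantile(nonzero, 0.8))
    return {
        "mean_truth_value": mean_truth,
        "nonzero_p80": p80,
        "enrichment": mean_truth / p80 if p80 > 0 else np.inf,
        "mean_percentile": float(np.mean(ranks)),
        "n_truth_voxels": len(truth_vals),
    }
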