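"""Low-plex spot counting and summary statistics.

Covers the quantities used to benchmark a ligation-based in situ assay:
the true discovery rate of a matched/junction-mismatched probe pair,
sensitivity relative to single-molecule FISH, the coefficient of variation
between probes tiling one transcript, and correlation of spot counts with
bulk expression values.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats
from skimage.feature import peak_local_max
from skimage.restoration import rolling_ball

__all__ = [
    "count_spots",
    "tdr",
    "sensitivity",
    "probe_cov",
    "expression_correlation",
]


def count_spots(
    image_stack: np.ndarray,
    rolling_ball_radius: float = 10.0,
    smooth: bool = True,
    threshold_k: float = 3.0,
    min_distance: int = 3,
) -> int:
    """Count punctate spots in a single-channel image or z-stack.

    The stack is maximum-projected in Z, background-subtracted with a
    rolling ball of the given radius (10 for amplicons, 2 for smFISH
    puncta), optionally box-smoothed, and spots are local maxima above an
    adaptive threshold (background mean + ``threshold_k`` standard
    deviations) separated by at least ``min_distance`` pixels.
    """
    img = np.asarray(image_stack, dtype=np.float64)
    if img.size == 0:
        return 0
    if img.ndim == 3:
        img = img.max(axis=0)
    elif img.ndim != 2:
        raise ValueError(f"expected 2D image or 3D stack, got shape {img.shape}")
    if not np.any(img):
        return 0
    background = rolling_ball(img, radius=rolling_ball_radius)
    sub = np.maximum(img - background, 0.0)
    if smooth:
        sub = ndimage.uniform_filter(sub, size=3)
    thresh = sub.mean() + threshold_k * sub.std()
    if not np.any(sub > thresh):
        return 0
    peaks = peak_local_max(
        sub, min_distance=min_distance, threshold_abs=thresh,
        exclude_border=False,
    )
    return len(peaks)


def tdr(matched_mean: float, mismatched_mean: float) -> float:
    """True discovery rate, (M / (M + MM)) x 100, in percent.

    M is the mean spot count per cell of the perfectly matched probe and MM
    that of its single-base ligation-junction mismatch control. A matched
    mean of 99 spots/cell against a mismatched mean of 1 gives 99%.
    """
    if matched_mean < 0 or mismatched_mean < 0:
        raise ValueError("mean counts must be non-negative")
    total = matched_mean + mismatched_mean
    if total == 0:
        raise ValueError("TDR undefined when both means are zero")
    return matched_mean / total * 100.0


def sensitivity(assay_counts, smfish_counts) -> float:
    """Detection sensitivity vs smFISH, in percent.

    Mean spots/cell of the ligation assay divided by the mean spots/cell of
    single-molecule FISH for the same gene, x 100.
    """
    ours = float(np.mean(assay_counts))
    ref = float(np.mean(smfish_counts))
    if ref <= 0:
        raise ValueError("smFISH mean must be positive")
    return ours / ref * 100.0


def probe_cov(per_probe_mean_counts) -> float:
    """Coefficient of variation between probes on one transcript, in percent.

    Sample (n-1) standard deviation divided by the mean, x 100.
    """
    x = np.asarray(per_probe_mean_counts, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 probes")
    mean = x.mean()
    if mean == 0:
        raise ValueError("COV undefined for zero mean")
    return x.std(ddof=1) / mean * 100.0


def expression_correlation(
    spot_means, reference_values, log_transform: bool = False
) -> float:
    """Pearson correlation between spot counts and bulk expression values."""
    x = np.asarray(spot_means, dtype=float)
    y = np.asarray(reference_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of at least 3 genes")
    if log_transform:
        x = np.log1p(x)
        y = np.log1p(y)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the vectors")
    r, _ = stats.pearsonr(x, y)
    return float(r)
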