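"""Uncertainty-versus-distance analysis.

Each response voxel contributes one (uncertainty, distance) pair: the
uncertainty sampled at the voxel itself, and the Euclidean distance in mm
from the voxel center to the nearest tract-mask foreground voxel (0 inside
the mask).  Pairs are summarized in an equal-width joint histogram on the
distance axis with per-bin mean/std, a pooled Spearman rank correlation,
and an ordinary-least-squares linear trend.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .ensemble import UncertaintyMap, sample_at_mask
from .ntms import ClassifiedResponseMask
from .volumes import BinaryMask, Volume, require_same_grid

logger = logging.getLogger(__name__)

__all__ = [
    "distance_map",
    "pair_uncertainty_distance",
    "JointHistogram",
    "joint_histogram",
    "spearman",
    "linear_trend",
]

DEFAULT_N_BINS = 30


def distance_map(tract: BinaryMask) -> Volume:
    """Euclidean distance (mm) from each voxel to the nearest tract voxel.

    Honours anisotropic spacing; exactly 0 on foreground.  An empty tract
    mask is an error (the distance would be undefined everywhere).
    """
    if tract.foreground_count == 0:
        raise ValueError("distance map of an empty tract mask is undefined")
    dist = ndimage.distance_transform_edt(tract.data == 0, sampling=tract.spacing)
    return Volume(dist, tract.affine)


def pair_uncertainty_distance(
    unc: UncertaintyMap | Volume,
    dist: Volume,
    responses: ClassifiedResponseMask | BinaryMask,
) -> np.ndarray:
    """(u, d) pairs at the response voxels, lexicographic voxel order.

    Returns an (n, 2) array; n may be 0 for an empty response mask.
    """
    uvol = unc.volume if isinstance(unc, UncertaintyMap) else unc
    mask = responses.mask if isinstance(responses, ClassifiedResponseMask) else responses
    require_same_grid(uvol, dist, "uncertainty/distance pairing")
    u = sample_at_mask(uvol, mask)
    d = sample_at_mask(dist, mask)
    return np.column_stack([u, d]) if len(u) else np.empty((0, 2))


@dataclass
class JointHistogram:
    """Equal-width distance-axis histogram with per-bin uncertainty stats."""

    bin_edges: np.ndarray  # length n_bins + 1, strictly increasing
    counts: np.ndarray  # ints, sum == number of pairs
    means: np.ndarray  # NaN for empty bins
    stds: np.ndarray  # population std; 0 for singleton bins, NaN for empty
    n_pairs: int = field(default=0)

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_mm": self.bin_edges[:-1],
                "bin_hi_mm": self.bin_edges[1:],
                "count": self.counts,
                "mean_unc": self.means,
                "std_unc": self.stds,
            }
        )

    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def joint_histogram(pairs: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> JointHistogram:
    """Bin (u, d) pairs into equal-width distance bins on [0, max d].

    Bins are right-open except the last, which is right-closed so the
    maximum distance lands in the final bin.  Per-bin statistics are the
    mean and population std of u; empty bins carry NaN.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) == 0:
        raise ValueError("pairs must be a nonempty (n, 2) array of (u, d)")
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    u, d = pairs[:, 0], pairs[:, 1]
    dmax = float(d.max())
    if dmax <= 0:
        logger.warning("all distances are 0 — degenerate single-bin histogram")
        edges = np.array([0.0, 1.0])
        n_bins = 1
    else:
        edges = np.linspace(0.0, dmax, n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.full(n_bins, np.nan)
    stds = np.full(n_bins, np.nan)
    for b in range(n_bins):
        vals = u[idx == b]
        if len(vals):
            means[b] = vals.mean()
            stds[b] = vals.std(ddof=0)
    return JointHistogram(edges, counts, means, stds, n_pairs=len(pairs))


def spearman(pairs: np.ndarray, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rank correlation between u and d with its two-sided p.

    Ties receive average ranks; rho is the Pearson correlation of the rank
    vectors.  For n <= ``exact_max_n`` the p-value is computed by exact
    permutation of one margin; above that the t-approximation is used.
    """
    pairs = np.asarray(pairs, dtype=float)
    if len(pairs) < 3:
        raise ValueError(f"spearman needs at least 3 pairs, got {len(pairs)}")
    u, d = pairs[:, 0], pairs[:, 1]
    if np.ptp(u) == 0 or np.ptp(d) == 0:
        raise ValueError("spearman is undefined when either coordinate has zero variance")
    rho = float(stats.spearmanr(u, d).statistic)
    n = len(pairs)
    if n <= exact_max_n:
        ru = stats.rankdata(u)
        rd = stats.rankdata(d)
        obs = abs(np.corrcoef(ru, rd)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(ru[list(perm)], rd)[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        p = count / total
    else:
        p = float(stats.spearmanr(u, d).pvalue)
    return rho, float(p)


def linear_trend(pairs: np.ndarray) -> tuple[float, float]:
    """Ordinary-least-squares fit of u on d: returns (slope, intercept)."""
    pairs = np.asarray(pairs, dtype=float)
    if len(pairs) < 2:
        raise ValueError("linear trend needs at least 2 pairs")
    u, d = pairs[:, 0], pairs[:, 1]
    if np.ptp(d) == 0:
        raise ValueError("linear trend is undefined for a degenerate distance axis")
    slope, intercept = np.polyfit(d, u, 1)
    return float(slope), float(intercept)


def binned_spearman(hist: JointHistogram) -> tuple[float, float] | None:
    """Spearman over (bin center, bin mean) points — the display-level variant.

    Returns None when fewer than 3 nonempty bins exist.
    """
    centers = hist.bin_centers()
    keep = ~np.isnan(hist.means)
    if keep.sum() < 3 or np.ptp(hist.means[keep]) == 0:
        return None
    return spearman(np.column_stack([hist.means[keep], centers[keep]]))
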