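"""Discrimination coefficient, support-recovery metrics and the exact
one-tailed binomial test used for the behavioural outcome counts.

The discrimination coefficient compares a processor image ``h`` against
binary shape templates by normalized correlation:

    C_i = (h^T s_i) / (||h||_2 ||s_i||_2),
    r   = C_sample / C_alternative,
    R   = 20 log10(r)   [dB].

R > 0 means the image overlaps the correct sample's shape more than the
alternative's.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

SIGNIFICANCE_ALPHA = 0.01   # reporting default for the binomial test


@dataclass(frozen=True)
class DiscriminationResult:
    c_sample: float
    c_alt: float
    ratio: float
    r_db: float


def _as_nonneg_vector(x, name: str) -> np.ndarray:
    v = np.asarray(getattr(x, "values", getattr(x, "h", x)), float).ravel()
    if np.any(v < 0):
        raise ValueError(f"{name} must be non-negative (processor images "
                         "and masks are magnitudes)")
    return v


def overlap_coefficient(h, mask) -> float:
    """Normalized correlation of an image with a binary shape template."""
    hv = _as_nonneg_vector(h, "h")
    sv = _as_nonneg_vector(mask, "mask")
    if hv.shape != sv.shape:
        raise ValueError("image and mask must live on the same grid")
    hn, sn = np.linalg.norm(hv), np.linalg.norm(sv)
    if hn == 0 or sn == 0:
        raise ValueError("zero-norm input: overlap undefined")
    return float(hv @ sv / (hn * sn))


def discrimination(h, sample_mask, alt_mask) -> DiscriminationResult:
    """Discrimination coefficient R (dB) of an image for sample vs
    alternative shape templates."""
    c_s = overlap_coefficient(h, sample_mask)
    c_a = overlap_coefficient(h, alt_mask)
    if c_a == 0:
        raise ZeroDivisionError(
            "alternative overlap is zero: discrimination is unbounded")
    r = c_s / c_a
    return DiscriminationResult(c_s, c_a, r, float(20.0 * np.log10(r)))


@dataclass(frozen=True)
class SupportMetrics:
    precision: float        # NaN when no voxel is declared active
    recall: float
    threshold: float
    defined: bool


def support_metrics(h, truth_mask, threshold: float = 0.1) -> SupportMetrics:
    """Precision/recall of the active-voxel set against a truth mask.

    A voxel is declared active iff ``h >= threshold * max(h)``.  An
    all-zero image yields recall 0 and undefined (NaN) precision.
    """
    hv = _as_nonneg_vector(h, "h")
    tv = _as_nonneg_vector(truth_mask, "truth").astype(bool)
    if hv.shape != tv.shape:
        raise ValueError("image and truth mask must share the grid")
    peak = hv.max()
    if peak == 0:
        warnings.warn("all-zero image: precision undefined")
        return SupportMetrics(float("nan"), 0.0, threshold, False)
    active = hv >= threshold * peak
    tp = int(np.sum(active & tv))
    precision = tp / int(active.sum()) if active.any() else float("nan")
    recall = tp / int(tv.sum()) if tv.any() else float("nan")
    return SupportMetrics(float(precision), float(recall), threshold, True)


def binomial_tail_p(successes: int, trials: int, chance: float) -> float:
    """Exact one-tailed (upper) binomial tail probability
    ``P(X >= successes)`` for X ~ Binomial(trials, chance)."""
    if not (0 <= successes <= trials):
        raise ValueError("need 0 <= successes <= trials")
    if not (0.0 < chance < 1.0):
        raise ValueError("chance probability must be in (0, 1)")
    return float(stats.binomtest(successes, trials, chance,
                                 alternative="greater").pvalue)


def binomial_tail_p_exact(successes: int, trials: int,
                          chance_num: int, chance_den: int) -> float:
    """Independent exact-rational summation oracle for the binomial tail."""
    from fractions import Fraction
    p = Fraction(chance_num, chance_den)
    total = Fraction(0)
    for j in range(successes, trials + 1):
        total += (math.comb(trials, j) * p ** j
                  * (1 - p) ** (trials - j))
    return float(total)


def off_target_variance(h: np.ndarray, h_reference: np.ndarray,
                        target_mask) -> float:
    """Mean squared deviation of the image from a noise-free reference over
    the off-target voxels — the background-noise level of the image."""
    hv = np.asarray(h, float).ravel()
    rv = np.asarray(h_reference, float).ravel()
    tv = _as_nonneg_vector(target_mask, "target").astype(bool)
    off = ~tv
    if not off.any():
        raise ValueError("no off-target voxels")
    d = hv[off] - rv[off]
    return float(np.mean(d ** 2))
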