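"""Distributional diagnostics and relative-entropy feature ranking.

Before the capacity regressor is trained, the two tap-test features are
checked for approximate normality on the log scale (skewness/kurtosis
thresholds appropriate for large samples) and ranked by how well each one
separates the healthy and sick classes, via the Kullback–Leibler divergence
between class-conditional histograms, stratified by the number of on-screen
objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import FeatureRow

#: Acceptability thresholds for near-normality in large samples (n > 300):
#: |skewness| < 2 and |Pearson kurtosis| < 7.
SKEW_LIMIT = 2.0
KURT_LIMIT = 7.0
MIN_N_FOR_THRESHOLDS = 300


class DegenerateSampleError(ValueError):
    """Sample too small or with zero variance for the requested statistic."""


class StratificationError(ValueError):
    """A class-conditional comparison was requested on a single-class stratum."""


@dataclass(frozen=True)
class NormalityReport:
    gamma: float   # sample skewness (adjusted Fisher–Pearson)
    kappa: float   # sample kurtosis, Pearson convention (normal -> 3)
    n: int
    acceptable: bool


def skewness(sample: Sequence[float]) -> float:
    """Adjusted Fisher–Pearson sample skewness."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise DegenerateSampleError(f"skewness needs n >= 3, got n={x.size}")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("skewness undefined for a zero-variance sample")
    return float(sps.skew(x, bias=False))


def kurtosis(sample: Sequence[float]) -> float:
    """Sample kurtosis in the Pearson (non-excess) convention: normal data -> 3."""
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise DegenerateSampleError(f"kurtosis needs n >= 4, got n={x.size}")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("kurtosis undefined for a zero-variance sample")
    return float(sps.kurtosis(x, fisher=False, bias=False))


def normality_acceptable(gamma: float, kappa: float, n: int) -> bool:
    """Large-sample acceptability rule: n > 300 and |gamma| < 2 and |kappa| < 7."""
    if n <= 0:
        raise DegenerateSampleError(f"sample size must be positive, got {n}")
    return n > MIN_N_FOR_THRESHOLDS and abs(gamma) < SKEW_LIMIT and abs(kappa) < KURT_LIMIT


def normality_report(sample: Sequence[float]) -> NormalityReport:
    x = np.asarray(sample, dtype=float)
    g, k = skewness(x), kurtosis(x)
    return NormalityReport(gamma=g, kappa=k, n=int(x.size),
                           acceptable=normality_acceptable(g, k, int(x.size)))


def kl_divergence_bits(
    p_counts: np.ndarray, q_counts: np.ndarray, alpha: float = 0.5
) -> float:
    """KL divergence D(P||Q) in bits between two histograms over shared bins.

    ``alpha`` is an additive (pseudo-count) smoothing per bin; with
    ``alpha=0`` empty Q-bins with P mass make the divergence infinite.
    """
    p = np.asarray(p_counts, dtype=float) + alpha
    q = np.asarray(q_counts, dtype=float) + alpha
    if p.shape != q.shape:
        raise ValueError("histograms must share their binning")
    p /= p.sum()
    q /= q.sum()
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def kl_feature_ranking(
    rows: Iterable[FeatureRow],
    feature: str,
    stratum: int,
    bins: int = 20,
    alpha: float = 0.5,
    symmetrized: bool = False,
) -> float:
    """Class-separation score of one feature within one object-count stratum.

    Builds class-conditional histograms (healthy = P, sick = Q) of the
    feature over ``bins`` equal-width bins spanning the pooled range and
    returns D(P||Q) in bits (or the symmetrized Jeffreys divergence).
    """
    if feature not in ("rt", "delta", "log_rt", "log_delta"):
        raise ValueError(f"unknown feature {feature!r}")
    vals = {0: [], 1: []}
    for r in rows:
        if r.n_objects == stratum:
            vals[r.is_sick].append(getattr(r, feature))
    if not vals[0] or not vals[1]:
        raise StratificationError(
            f"stratum nC={stratum} must contain both classes "
            f"(healthy n={len(vals[0])}, sick n={len(vals[1])})"
        )
    pooled = np.concatenate([vals[0], vals[1]])
    edges = np.histogram_bin_edges(pooled, bins=bins)
    p_counts, _ = np.histogram(vals[0], bins=edges)
    q_counts, _ = np.histogram(vals[1], bins=edges)
    d = kl_divergence_bits(p_counts, q_counts, alpha=alpha)
    if symmetrized:
        d = d + kl_divergence_bits(q_counts, p_counts, alpha=alpha)
    return d


def rank_features(
    rows: Sequence[FeatureRow],
    features: Sequence[str] = ("rt", "delta"),
    strata: Sequence[int] = (2, 3, 5),
    bins: int = 20,
    alpha: float = 0.5,
) -> pd.DataFrame:
    """Divergence table (feature x stratum), exportable to CSV.

    Columns: ``feature``, ``n_objects``, ``kl_bits``.
    """
    out = [
        {"feature": f, "n_objects": s,
         "kl_bits": kl_feature_ranking(rows, f, s, bins=bins, alpha=alpha)}
        for f in features
        for s in strata
    ]
    return pd.DataFrame(out)
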