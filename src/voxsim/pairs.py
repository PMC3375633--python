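"""Pairwise gene samples: features, labels, subsets, splits and the R-curve.

Every unordered pair of genes becomes one sample.  Its feature vector is
the element-wise absolute difference of the two genes' map descriptors,
with three pair-level statistics (Pearson R between the two maps, its
two-sided p-value, and their Euclidean distance) inserted after the voxel
segment.  Its label is the genes' functional similarity from the ontology
module.  Pair generation streams: per-gene descriptors are computed once
and pairs are yielded one at a time, so memory stays linear in the number
of genes rather than quadratic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .layout import FeatureLayout, LayoutError, pair_layout_of
from .maps import ExpressionMap, MapDescriptor, map_descriptor
from .mask import GridMask, enumerate_neighbor_pairs
from .ontology import AnnotationSet, OntologyGraph, binarize_label, gene_pair_similarity

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairStatistics:
    """Pearson R, its two-sided p-value and the Euclidean distance.

    R and P are NaN sentinels when either input has zero variance.
    """

    r: float
    p: float
    d_euclid: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


@dataclass(frozen=True)
class PairSample:
    """One unordered gene pair: features V, similarity label, optional class."""

    gene_a: str
    gene_b: str
    features: np.ndarray
    label: float
    klass: int | None = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("a pair must join two distinct genes")
        if self.gene_a > self.gene_b:
            raise ValueError("pair genes must be in lexicographic order")


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/test index sets drawn with a recorded seed."""

    train: np.ndarray
    test: np.ndarray
    seed: int


def pair_count(n: int) -> int:
    """Closed-form number of unordered pairs of n genes: n(n-1)/2."""
    return n * (n - 1) // 2


def pair_statistics(x: np.ndarray, y: np.ndarray) -> PairStatistics:
    """Pearson R (with two-sided p from the t distribution) and Euclidean distance.

    The p-value is the probability of |R| at least as large under the null
    of zero correlation, via ``t = R sqrt((n-2)/(1-R^2))`` with n-2 df.
    Zero-variance inputs leave R and P undefined (NaN); the distance is
    always computed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 values for a p-value")
    d = float(np.linalg.norm(x - y))
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return PairStatistics(math.nan, math.nan, d)
    r, p = sps.pearsonr(x, y)
    return PairStatistics(float(r), float(p), d)


def build_pair_features(
    w1: MapDescriptor, w2: MapDescriptor, pair_stats: PairStatistics
) -> tuple[np.ndarray, FeatureLayout]:
    """V = |W1 - W2| on the per-gene segments, with (R, P, dE) spliced in.

    Undefined statistics enter the feature vector as 0 (their slots stay
    comparable across samples); the pair is still flagged by the caller.
    """
    if w1.layout != w2.layout:
        raise LayoutError("pair members have different descriptor layouts")
    layout = pair_layout_of(w1.layout)
    diff = np.abs(w1.values - w2.values)
    stats_slice = layout.slice("stats")
    out = np.empty(layout.total)
    out[: stats_slice.start] = diff[: stats_slice.start]
    out[stats_slice] = [
        0.0 if math.isnan(pair_stats.r) else pair_stats.r,
        0.0 if math.isnan(pair_stats.p) else pair_stats.p,
        pair_stats.d_euclid,
    ]
    out[stats_slice.stop :] = diff[stats_slice.start :]
    return out, layout


def build_dataset(
    genes: Sequence[tuple[ExpressionMap, AnnotationSet]],
    mask: GridMask,
    graph: OntologyGraph,
    level: int = 3,
    wavelet_name: str = "haar",
    mode: str = "symmetric",
    stats_domain: str = "voxels",
    class_threshold: float | None = None,
) -> Iterator[PairSample]:
    """Stream all C(n, 2) pair samples, each unordered pair exactly once.

    Per-gene descriptors are computed once up front; pairs are then yielded
    lazily so memory is O(genes), not O(pairs).  ``stats_domain`` selects
    the vectors on which R/P/dE are computed: the raw voxel values
    (``"voxels"``) or the wavelet coefficients (``"wavelet"``).  When
    ``class_threshold`` is given each sample also carries the binarized
    class label.
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to form pairs")
    if stats_domain not in ("voxels", "wavelet"):
        raise ValueError(f"unknown stats_domain {stats_domain!r}")
    order = sorted(range(len(genes)), key=lambda i: genes[i][0].gene_id)
    pairs = enumerate_neighbor_pairs(mask)
    descriptors = [
        map_descriptor(genes[i][0], mask, pairs, level, wavelet_name, mode) for i in order
    ]
    stat_vectors = [d.segment(stats_domain) for d in descriptors]
    annotations = [genes[i][1] for i in order]
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            ps = pair_statistics(stat_vectors[a], stat_vectors[b])
            if not ps.defined:
                logger.info(
                    "pair (%s, %s): undefined correlation (constant map)",
                    descriptors[a].gene_id,
                    descriptors[b].gene_id,
                )
            features, _ = build_pair_features(descriptors[a], descriptors[b], ps)
            label = gene_pair_similarity(annotations[a], annotations[b], graph)
            klass = None if class_threshold is None else binarize_label(label, class_threshold)
            yield PairSample(
                descriptors[a].gene_id, descriptors[b].gene_id, features, label, klass
            )


def samples_to_arrays(
    samples: Iterable[PairSample],
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Materialize a sample stream as (X, labels, pair ids)."""
    feats, labels, ids = [], [], []
    for s in samples:
        feats.append(s.features)
        labels.append(s.label)
        ids.append((s.gene_a, s.gene_b))
    return np.asarray(feats), np.asarray(labels), ids


def restrict_by_correlation(
    samples: Iterable[PairSample],
    layout: FeatureLayout,
    rho: float = 0.7,
) -> Iterator[PairSample]:
    """Keep samples whose R slot strictly exceeds rho (undefined R dropped)."""
    r_index = layout.offset("stats")
    for s in samples:
        if s.features[r_index] > rho:
            yield s


def binned_similarity_curve(
    r_values: np.ndarray,
    labels: np.ndarray,
    bin_width: float = 0.1,
    lo: float = -1.0,
    hi: float = 1.0,
) -> pd.DataFrame:
    """Mean functional similarity per correlation bin (the R-vs-similarity curve).

    Bins are left-closed right-open over [lo, hi), with the last bin closed
    at ``hi``.  Empty bins carry count 0 and NaN mean.  NaN R values are
    excluded.
    """
    r_values = np.asarray(r_values, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_bins = (hi - lo) / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide the range evenly")
    n_bins = int(round(n_bins))
    keep = ~np.isnan(r_values)
    r_values, labels = r_values[keep], labels[keep]
    idx = np.floor((r_values - lo) / bin_width).astype(int)
    idx = np.where((r_values == hi), n_bins - 1, idx)  # closed last bin
    valid = (idx >= 0) & (idx < n_bins)
    idx, labels = idx[valid], labels[valid]
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=labels, minlength=n_bins)
    means = np.divide(sums, counts, out=np.full(n_bins, np.nan), where=counts > 0)
    left = lo + bin_width * np.arange(n_bins)
    return pd.DataFrame(
        {
            "bin_left": left,
            "bin_right": left + bin_width,
            "count": counts,
            "mean_label": means,
        }
    )


def r_label_arrays(
    samples: Iterable[PairSample], layout: FeatureLayout
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Collect (R, label, gene pair) from a stream without keeping features."""
    r_index = layout.offset("stats")
    rs, labels, ids = [], [], []
    for s in samples:
        rs.append(s.features[r_index])
        labels.append(s.label)
        ids.append((s.gene_a, s.gene_b))
    return np.asarray(rs), np.asarray(labels), ids


def curve_from_samples(
    samples: Iterable[PairSample], layout: FeatureLayout, bin_width: float = 0.1
) -> pd.DataFrame:
    """R-vs-similarity curve from a sample stream (R read from the stats slot).

    R slots stored as exactly 0 are treated as undefined-sentinel
    replacements only when flagged upstream; here every finite slot value
    participates.
    """
    rs, labels, _ = r_label_arrays(samples, layout)
    return binned_similarity_curve(rs, labels, bin_width)


@dataclass(frozen=True)
class TrendCheck:
    """Statistical monotonicity check of the high-correlation curve tail.

    Pair samples sharing a gene are dependent, so standard errors use the
    number of distinct genes in a bin (the independent units) rather than
    the pair count.  ``no_significant_decrease`` holds when no adjacent-bin
    drop exceeds ``z`` standard errors of the difference (non-decreasing up
    to sampling noise); ``rises`` when the last high-R bin's mean exceeds
    the mean label of all pairs below ``r_min`` by more than ``z`` standard
    errors.
    """

    bin_left: np.ndarray
    counts: np.ndarray
    means: np.ndarray
    baseline_mean: float
    no_significant_decrease: bool
    rises: bool


def high_r_trend(
    r_values: np.ndarray,
    labels: np.ndarray,
    gene_pairs: Sequence[tuple[str, str]] | None = None,
    r_min: float = 0.6,
    bin_width: float = 0.1,
    z: float = 2.576,
) -> TrendCheck:
    """Evaluate the mean-similarity trend over the bins with R >= r_min.

    ``z`` defaults to the two-sided 99% normal quantile.
    """
    r_values = np.asarray(r_values, dtype=float)
    labels = np.asarray(labels, dtype=float)
    finite = ~np.isnan(r_values)
    r_values, labels = r_values[finite], labels[finite]
    if gene_pairs is not None:
        gene_pairs = [p for p, k in zip(gene_pairs, finite) if k]

    def _stats(mask: np.ndarray) -> tuple[float, float]:
        vals = labels[mask]
        if gene_pairs is not None:
            units = len({g for p, k in zip(gene_pairs, mask) if k for g in p})
        else:
            units = vals.size
        return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(units))

    high = r_values >= r_min
    low = ~high
    n_bins = int(round((1.0 - r_min) / bin_width))
    idx = np.minimum(np.floor((r_values - r_min) / bin_width).astype(int), n_bins - 1)
    lefts, counts, means, ses = [], [], [], []
    for b in range(n_bins):
        mask = high & (idx == b)
        if mask.sum() < 2:  # no standard error from < 2 samples
            continue
        mean, se = _stats(mask)
        lefts.append(r_min + b * bin_width)
        counts.append(int(mask.sum()))
        means.append(mean)
        ses.append(se)
    means_a = np.asarray(means)
    ses_a = np.asarray(ses)
    base_mean, base_se = _stats(low) if low.sum() >= 2 else (math.nan, math.nan)
    if len(means) < 2:
        return TrendCheck(
            np.asarray(lefts), np.asarray(counts), means_a, base_mean, False, False
        )
    diffs = np.diff(means_a)
    se_diff = np.sqrt(ses_a[:-1] ** 2 + ses_a[1:] ** 2)
    no_drop = bool(np.all(diffs >= -z * se_diff))
    rise = bool(
        not math.isnan(base_mean)
        and means_a[-1] - base_mean > z * math.hypot(base_se, ses_a[-1])
    )
    return TrendCheck(
        np.asarray(lefts), np.asarray(counts), means_a, base_mean, no_drop, rise
    )


def train_test_split(n_samples: int, fraction: float, seed: int) -> DatasetSplit:
    """Random disjoint split; |train| = round-half-up(fraction * n)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if n_samples < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(math.floor(fraction * n_samples + 0.5))
    n_train = min(max(n_train, 1), n_samples - 1)
    perm = np.random.default_rng(seed).permutation(n_samples)
    return DatasetSplit(np.sort(perm[:n_train]), np.sort(perm[n_train:]), seed)
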