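"""Rarefaction, feature filtering, alpha diversity, dissimilarities, dispersion.

All metrics are computed directly from their definitions on integer count
tables: inverse Simpson 1/sum(p_i^2), richness as the number of features with
count >= 1, asymmetric shared-OTU percentages, Bray-Curtis dissimilarity
sum|x-y|/sum(x+y), and Anderson-style distance-to-centroid dispersion in the
principal-coordinate embedding (negative-eigenvalue axes retained and
subtracted).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .tables_io import CountTable

__all__ = [
    "DistanceMatrix",
    "filter_rare_features",
    "rarefy",
    "inverse_simpson",
    "richness",
    "shared_fraction",
    "bray_curtis",
    "euclidean",
    "centroid_distances",
]

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal over sample ids."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if (np.diag(self.d) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be nonnegative")

    def subset(self, sample_ids) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.d[np.ix_(idx, idx)])


def filter_rare_features(t: CountTable, min_total_reads: int) -> CountTable:
    """Drop features whose dataset-wide total is below ``min_total_reads``.

    The threshold applies to the sum over all samples; samples are retained
    even if they end up all-zero.
    """
    if min_total_reads < 0:
        raise ValueError("min_total_reads must be >= 0")
    totals = t.counts.sum(axis=0)
    keep = totals >= min_total_reads
    if not keep.any():
        log.warning("all %d features fall below the %d-read threshold", t.n_features, min_total_reads)
    features = [f for f, k in zip(t.features, keep) if k]
    tax = None
    if t.feature_taxonomy is not None:
        tax = {f: t.feature_taxonomy[f] for f in features if f in t.feature_taxonomy}
    return CountTable(
        samples=list(t.samples),
        features=features,
        counts=t.counts[:, keep],
        feature_taxonomy=tax,
    )


def rarefy(t: CountTable, depth: int, seed: int) -> tuple[CountTable, list[str]]:
    """Subsample each sample to ``depth`` reads without replacement.

    Draws follow the multivariate hypergeometric distribution (a single draw
    per sample, not an average over draws). Samples whose total is below the
    depth are dropped and returned in the second element.

    Returns (rarefied table, list of dropped sample ids).
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = t.counts.sum(axis=1)
    kept_rows = []
    kept_samples = []
    dropped = []
    for i, s in enumerate(t.samples):
        if totals[i] < depth:
            dropped.append(s)
            continue
        if totals[i] == depth:
            kept_rows.append(t.counts[i].copy())
        else:
            kept_rows.append(rng.multivariate_hypergeometric(t.counts[i], depth))
        kept_samples.append(s)
    if dropped:
        log.warning("rarefy: dropped %d sample(s) under depth %d: %s", len(dropped), depth, dropped)
    counts = np.vstack(kept_rows) if kept_rows else np.empty((0, t.n_features), dtype=np.int64)
    return (
        CountTable(
            samples=kept_samples,
            features=list(t.features),
            counts=counts,
            feature_taxonomy=t.feature_taxonomy,
        ),
        dropped,
    )


def inverse_simpson(counts) -> float:
    """Inverse Simpson index 1 / sum(p_i^2) of one sample's counts."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("inverse Simpson undefined for an all-zero sample")
    p = c / total
    return float(1.0 / np.sum(p * p))


def richness(counts) -> int:
    """Number of features present (count >= 1)."""
    return int(np.count_nonzero(np.asarray(counts)))


def shared_fraction(a, b) -> float:
    """Percentage of a's present features also present in b.

    Asymmetric: the denominator is the first argument's richness. This is the
    contrast under which patients (hosting a subset of family taxa) share a
    higher percentage toward relatives than relatives share toward them.
    """
    pa = np.asarray(a) > 0
    pb = np.asarray(b) > 0
    na = int(pa.sum())
    if na == 0:
        raise ValueError("shared_fraction undefined: first sample has zero richness")
    return 100.0 * int((pa & pb).sum()) / na


def bray_curtis(t: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity: sum|x-y| / sum(x+y)."""
    if t.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = t.counts.astype(float)
    totals = x.sum(axis=1)
    if (totals == 0).any():
        zero = [s for s, tt in zip(t.samples, totals) if tt == 0]
        raise ValueError(f"Bray-Curtis undefined for all-zero sample(s): {zero}")
    n = t.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
        denom = totals[i] + totals[i + 1 :]
        d[i, i + 1 :] = diff / denom
    d = d + d.T
    return DistanceMatrix(list(t.samples), d)


def euclidean(m: np.ndarray, ids=None) -> DistanceMatrix:
    """Pairwise Euclidean distances over rows of a real matrix."""
    m = np.asarray(m, dtype=float)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    sq = np.sum(m * m, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (m @ m.T)
    np.fill_diagonal(d2, 0.0)
    d = np.sqrt(np.clip(d2, 0.0, None))
    if ids is None:
        ids = [str(i) for i in range(m.shape[0])]
    return DistanceMatrix(list(ids), d)


def _pcoa_axes(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate axes of a distance matrix.

    Returns (real_coords, imag_coords): coordinates on positive- and
    negative-eigenvalue axes respectively (each scaled by sqrt(|eigenvalue|)).
    Non-Euclidean distance matrices produce nonempty imaginary axes.
    """
    n = d.shape[0]
    a = -0.5 * d * d
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    tol = 1e-9 * max(1.0, np.abs(vals).max())
    pos = vals > tol
    neg = vals < -tol
    real = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return real, imag


def centroid_distances(d: DistanceMatrix, groups) -> np.ndarray:
    """Per-sample distance to its group centroid (multivariate dispersion).

    The distance matrix is embedded by principal coordinates keeping
    negative-eigenvalue axes; the squared distance to the group centroid is the
    real-axis part minus the imaginary-axis part, floored at zero before the
    square root. For a Euclidean-embeddable matrix this equals the plain
    distance to the centroid in the embedding.
    """
    groups = np.asarray(groups)
    if len(groups) != len(d.ids):
        raise ValueError("every sample must be labeled")
    real, imag = _pcoa_axes(d.d)
    out = np.zeros(len(d.ids))
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() == 1:
            warnings.warn(f"group {g!r} has a single sample; its dispersion is 0")
            out[mask] = 0.0
            continue
        cr = real[mask].mean(axis=0)
        ci = imag[mask].mean(axis=0)
        sq = ((real[mask] - cr) ** 2).sum(axis=1) - ((imag[mask] - ci) ** 2).sum(axis=1)
        out[mask] = np.sqrt(np.clip(sq, 0.0, None))
    return out
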