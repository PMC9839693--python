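"""Enterotype discovery and distance-matrix hypothesis tests.

Partitioning around medoids (BUILD + SWAP) on an arbitrary distance matrix,
average-silhouette selection of the number of community types, the exact
2x2 Fisher association of cluster membership with case status (conditional-MLE
odds ratio, exact CI), random-forest ranking of cluster-defining taxa, and
PERMANOVA (pseudo-F with label-permutation p, +1 convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import silhouette_samples

from .diversity import DistanceMatrix
from .tables_io import CountTable

__all__ = [
    "EnterotypeResult",
    "FisherResult",
    "PermanovaResult",
    "pam",
    "select_k",
    "fisher_exact_2x2",
    "rank_cluster_features",
    "permanova",
]

log = logging.getLogger(__name__)


@dataclass
class EnterotypeResult:
    k: int
    labels: np.ndarray  # cluster ids in {1..k}, one per sample
    medoids: list[str]
    avg_silhouette: float
    per_sample_silhouette: np.ndarray
    cost: float  # total within-cluster distance to medoids


def _assignment_cost(d: np.ndarray, medoids: np.ndarray) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def _build_medoids(dm: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD seeding: first medoid minimizes total distance, each
    subsequent one maximizes the drop in total assignment cost."""
    medoids = [int(np.argmin(dm.sum(axis=0)))]
    while len(medoids) < k:
        cur = dm[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - dm, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return np.array(sorted(medoids))


def _swap_to_local_optimum(dm: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Best-improvement SWAP: apply the single (medoid, non-medoid) exchange
    with the largest cost drop until none improves. Cost is nonincreasing per
    swap and the loop terminates."""
    n = dm.shape[0]
    medoids = np.array(sorted(medoids))
    cost = _assignment_cost(dm, medoids)
    while True:
        best = (0.0, None)
        med_set = set(medoids.tolist())
        for mi in range(len(medoids)):
            for h in range(n):
                if h in med_set:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                c = _assignment_cost(dm, trial)
                if cost - c > best[0] + 1e-12:
                    best = (cost - c, (mi, h))
        if best[1] is None:
            return medoids, cost
        mi, h = best[1]
        medoids[mi] = h
        medoids = np.array(sorted(medoids))
        cost -= best[0]


def pam(d: DistanceMatrix, k: int, seed: int = 0, n_starts: int = 10) -> EnterotypeResult:
    """Partitioning around medoids: BUILD + SWAP with seeded restarts.

    The classic greedy BUILD seeding followed by best-improvement SWAP is a
    local search and can miss the optimal medoid set even at small n, so the
    SWAP phase is additionally restarted from ``n_starts - 1`` seeded random
    medoid subsets and the lowest-cost local optimum wins (ties broken toward
    the BUILD start). Deterministic given ``seed``.
    """
    n = len(d.ids)
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n, got k={k}, n={n}")
    dm = d.d
    medoids, cost = _swap_to_local_optimum(dm, _build_medoids(dm, k))
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_starts - 1)):
        start = rng.choice(n, size=k, replace=False)
        med_r, cost_r = _swap_to_local_optimum(dm, start)
        if cost_r < cost - 1e-12:
            medoids, cost = med_r, cost_r
    labels = np.argmin(dm[:, medoids], axis=1) + 1
    if len(np.unique(labels)) < k:
        # a medoid can lose all its members on ties; keep the medoid itself
        for ci, m in enumerate(medoids):
            labels[m] = ci + 1
    sil = silhouette_samples(dm, labels, metric="precomputed")
    return EnterotypeResult(
        k=k,
        labels=labels,
        medoids=[d.ids[m] for m in medoids],
        avg_silhouette=float(sil.mean()),
        per_sample_silhouette=sil,
        cost=_assignment_cost(dm, medoids),
    )


def select_k(d: DistanceMatrix, k_range=range(2, 7), seed: int = 0) -> int:
    """Pick k maximizing average silhouette width; ties break to the smallest k.

    A warning is raised when the winning silhouette falls below 0.25,
    indicating no convincing cluster structure.
    """
    ks = [int(k) for k in k_range]
    if not ks:
        raise ValueError("empty k range")
    n = len(d.ids)
    if any(not 2 <= k <= n - 1 for k in ks):
        raise ValueError("k range must lie within [2, n-1]")
    best_k, best_s = None, -np.inf
    for k in sorted(ks):
        s = pam(d, k, seed=seed).avg_silhouette
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_s < 0.25:
        warnings.warn(f"select_k: weak cluster structure (avg silhouette {best_s:.3f} < 0.25)")
    return best_k


@dataclass
class FisherResult:
    table: np.ndarray
    p: float
    odds_ratio: float  # conditional MLE
    ci_low: float
    ci_high: float


def fisher_exact_2x2(table) -> FisherResult:
    """Exact two-sided Fisher test on a 2x2 table.

    p is the sum of hypergeometric probabilities of tables (margins fixed) no
    more probable than the observed one; the odds ratio is the conditional MLE
    under the noncentral hypergeometric likelihood with an exact 95% CI by
    inverting the conditional test. Degenerate margins raise.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("Fisher test undefined with a zero margin")
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    orr = stats.contingency.odds_ratio(t, kind="conditional")
    ci = orr.confidence_interval(confidence_level=0.95)
    return FisherResult(
        table=t,
        p=p,
        odds_ratio=float(orr.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )


def rank_cluster_features(
    t: CountTable,
    labels,
    seed: int = 0,
    n_estimators: int = 500,
    n_repeats: int = 10,
):
    """Rank features by permutation importance for separating the clusters.

    Fits an out-of-bag-validated random forest (500 trees, sqrt(m) features per
    split) on relative abundances, then scores each feature by mean accuracy
    drop under column permutation. Returns a list of
    (feature, importance, marks_cluster) sorted by decreasing importance, where
    ``marks_cluster`` is the cluster with the higher median relative abundance.
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    if (counts < 2).any():
        raise ValueError("every cluster needs at least 2 samples")
    x = t.counts.astype(float)
    totals = x.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    x = x / totals
    rf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(x, labels)
    imp = permutation_importance(rf, x, labels, n_repeats=n_repeats, random_state=seed, n_jobs=1)
    order = np.argsort(-imp.importances_mean)
    ranked = []
    for j in order:
        medians = {int(u): float(np.median(x[labels == u, j])) for u in uniq}
        marks = max(medians, key=medians.get)
        ranked.append((t.features[j], float(imp.importances_mean[j]), marks))
    log.info("rank_cluster_features: OOB accuracy %.3f", rf.oob_score_)
    return ranked


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    df_between: int
    n_perm: int


def _permanova_f(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R2 from a squared distance matrix and group labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    uniq = np.unique(groups)
    for g in uniq:
        idx = np.flatnonzero(groups == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    k = len(uniq)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    r2 = ss_between / ss_total
    return f, r2


def permanova(
    d: DistanceMatrix, groups, n_perm: int = 9999, seed: int = 0, exhaustive: bool = False
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    SS_total = (1/n) sum_{i<j} d_ij^2; SS_within sums (1/n_g) sum_{i<j in g}
    d_ij^2 over groups; pseudo-F = (SS_between/(k-1)) / (SS_within/(n-k)).
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) under whole-label permutation.
    With ``exhaustive=True`` every distinct label arrangement is evaluated
    instead and p is the exact fraction with F >= F_obs (the identity
    arrangement included, so p > 0); only sensible for small n.
    """
    groups = np.asarray(groups)
    n = len(d.ids)
    if len(groups) != n:
        raise ValueError("every sample must be labeled")
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    d2 = d.d * d.d
    f_obs, r2 = _permanova_f(d2, groups)
    if exhaustive:
        from itertools import permutations

        seen = set()
        count = 0
        for perm in permutations(range(n)):
            labels = tuple(groups[list(perm)])
            if labels in seen:
                continue
            seen.add(labels)
            f_p, _ = _permanova_f(d2, np.asarray(labels))
            if f_p >= f_obs - 1e-12:
                count += 1
        p = count / len(seen)
        n_used = len(seen)
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            f_p, _ = _permanova_f(d2, groups[rng.permutation(n)])
            if f_p >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
        n_used = n_perm
    return PermanovaResult(
        pseudo_F=float(f_obs),
        R2=float(r2),
        p=float(p),
        df_between=len(uniq) - 1,
        n_perm=n_used,
    )
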