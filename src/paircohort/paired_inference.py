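"""Random-pairing permutation inference for ambiguous patient-relative pairings.

In a household case-control design each patient may have zero, one, or several
eligible relative samples (a sample is eligible when it was collected within a
window, by default 90 days, of the patient's sample). Rather than discarding
the ambiguity, the test repeatedly draws one eligible relative per patient
uniformly at random, computes an ordinary two-sided paired t-test over the
resulting patient-minus-relative differences, and reports the arithmetic means
of the per-draw statistics (t, p, difference, and the 95% CI bounds) across
permutations. Patients with no eligible relative are excluded, so df is fixed
at n_pairs - 1 for every draw.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables_io import CohortMetadata

__all__ = [
    "PairGraph",
    "PairedTestResult",
    "build_pair_graph",
    "paired_t",
    "permutation_paired_test",
    "welch_t",
    "fdr_bh",
]

log = logging.getLogger(__name__)


@dataclass
class PairGraph:
    """Eligible patient-relative pairings within the date window.

    ``eligible`` maps each patient sample id to a list of
    (relative sample id, absolute date gap in days) tuples. Patients with no
    eligible relative are listed in ``excluded_patients``.
    """

    patients: list[str]
    eligible: dict[str, list[tuple[str, int]]]
    window_days: int
    excluded_patients: list[str] = field(default_factory=list)
    shared_relatives: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.patients)


def build_pair_graph(meta: CohortMetadata, window_days: int = 90) -> PairGraph:
    """Enumerate eligible pairs: same family, |date gap| <= window_days.

    Relative samples collected more than ``window_days`` after or before the
    patient's sample are excluded. Patients left with no eligible relative are
    excluded from paired analyses and recorded. A relative sample eligible for
    two patients (shared household) stays eligible for both; draws are
    independent per patient.
    """
    df = meta.table
    dates = {s: meta.date_of(s) for s in meta.samples}
    patients_df = df[df["role"] == "patient"]
    relatives_df = df[df["role"] == "relative"]
    eligible: dict[str, list[tuple[str, int]]] = {}
    excluded: list[str] = []
    rel_use: dict[str, int] = {}
    for _, prow in patients_df.iterrows():
        pid = str(prow["sample_id"])
        fam = prow["family_id"]
        cands = []
        for _, rrow in relatives_df.iterrows():
            if rrow["family_id"] != fam:
                continue
            rid = str(rrow["sample_id"])
            gap = abs((dates[pid] - dates[rid]).days)
            if gap <= window_days:
                cands.append((rid, gap))
        cands.sort()
        if cands:
            eligible[pid] = cands
            for rid, _ in cands:
                rel_use[rid] = rel_use.get(rid, 0) + 1
        else:
            excluded.append(pid)
    shared = sorted(r for r, k in rel_use.items() if k > 1)
    if excluded:
        log.info("build_pair_graph: %d patient(s) without eligible relative: %s", len(excluded), excluded)
    return PairGraph(
        patients=sorted(eligible),
        eligible=eligible,
        window_days=window_days,
        excluded_patients=sorted(excluded),
        shared_relatives=shared,
    )


@dataclass
class PairedTestResult:
    """Across-permutation means of the paired t statistics for one endpoint."""

    endpoint: str
    n_pairs: int
    df: int
    mean_t: float
    mean_p: float
    mean_diff: float
    mean_ci_low: float
    mean_ci_high: float
    n_permutations: int
    seed: int
    q: float = float("nan")
    # CI of the mean difference across permutations (secondary; the canonical
    # interval is the mean of the per-permutation bounds above)
    ci_of_mean_low: float = float("nan")
    ci_of_mean_high: float = float("nan")
    dropped_patients: list[str] = field(default_factory=list)


def _t_rows(diffs: np.ndarray) -> tuple[np.ndarray, ...]:
    """Row-wise paired t statistics for a (n_rows, n) matrix of differences."""
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / np.where(se > 0, se, 1.0), np.where(mean == 0, 0.0, np.sign(mean) * np.inf))
    dfree = n - 1
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(np.where(np.isinf(t), 0.0, t)), dfree))
    p = np.where((se == 0) & (mean == 0), 1.0, p)
    crit = stats.t.ppf(0.975, dfree)
    lo = mean - crit * se
    hi = mean + crit * se
    return t, p, mean, lo, hi


def paired_t(d) -> tuple[float, int, float, float, float, float]:
    """Two-sided paired t-test on a vector of within-pair differences.

    Returns (t, df, p, mean difference, ci_low, ci_high) with the 95% CI
    d_bar +/- t_{0.975,df} * s_d / sqrt(n). Zero variance with a nonzero mean
    yields t = +/-inf and p -> 0 (flagged with a warning).
    """
    d = np.asarray(d, dtype=float)
    if d.size < 2:
        raise ValueError("paired t needs at least 2 differences")
    if not np.isfinite(d).all():
        raise ValueError("differences must be finite")
    t, p, mean, lo, hi = (x[0] for x in _t_rows(d[None, :]))
    if np.isinf(t):
        warnings.warn("paired_t: zero variance with nonzero mean; t is infinite")
    return float(t), d.size - 1, float(p), float(mean), float(lo), float(hi)


def permutation_paired_test(
    values,
    graph: PairGraph,
    n_perm: int = 1000,
    seed: int = 0,
    endpoint: str = "endpoint",
) -> PairedTestResult:
    """Aggregate paired t-tests over random pairings.

    ``values`` maps sample id -> endpoint value (dict or pandas Series).
    Each of ``n_perm`` iterations draws, independently and uniformly, one
    eligible relative sample per patient and computes the paired t over the
    patient - relative differences; the across-permutation arithmetic means of
    t, p, diff and the CI bounds are reported. Draw order is keyed by sorted
    patient ids (with relatives sorted within each patient), so the result is
    invariant to input ordering. Patients whose endpoint, or all of whose
    relatives' endpoints, are missing are dropped with a warning.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    getv = values.get if hasattr(values, "get") else values.__getitem__

    def _val(sid):
        v = getv(sid)
        if v is None:
            return np.nan
        return float(v)

    cand_values: list[np.ndarray] = []
    patient_values: list[float] = []
    dropped: list[str] = []
    for pid in sorted(graph.patients):
        pv = _val(pid)
        rels = sorted(r for r, _ in graph.eligible[pid])
        rv = np.array([_val(r) for r in rels], dtype=float)
        rv = rv[np.isfinite(rv)]
        if not np.isfinite(pv) or rv.size == 0:
            dropped.append(pid)
            continue
        patient_values.append(pv)
        cand_values.append(rv)
    if dropped:
        warnings.warn(f"permutation_paired_test: dropped patient(s) with missing endpoint: {dropped}")
    n_pairs = len(patient_values)
    if n_pairs < 2:
        raise ValueError("need at least 2 usable patient-relative pairs")

    rng = np.random.default_rng(seed)
    pvec = np.asarray(patient_values)
    diffs = np.empty((n_perm, n_pairs))
    for j, rv in enumerate(cand_values):
        if rv.size == 1:
            diffs[:, j] = pvec[j] - rv[0]
        else:
            diffs[:, j] = pvec[j] - rv[rng.integers(rv.size, size=n_perm)]
    t, p, mean, lo, hi = _t_rows(diffs)

    mean_diffs = mean
    # secondary interval: normal-theory CI of the permutation-mean difference
    if n_perm > 1 and np.std(mean_diffs, ddof=1) > 0:
        se_m = np.std(mean_diffs, ddof=1) / np.sqrt(n_perm)
        crit = stats.t.ppf(0.975, n_perm - 1)
        ci_m = (float(mean_diffs.mean() - crit * se_m), float(mean_diffs.mean() + crit * se_m))
    else:
        ci_m = (float(mean_diffs.mean()), float(mean_diffs.mean()))

    return PairedTestResult(
        endpoint=endpoint,
        n_pairs=n_pairs,
        df=n_pairs - 1,
        mean_t=float(t.mean()),
        mean_p=float(p.mean()),
        mean_diff=float(mean.mean()),
        mean_ci_low=float(lo.mean()),
        mean_ci_high=float(hi.mean()),
        n_permutations=n_perm,
        seed=seed,
        ci_of_mean_low=ci_m[0],
        ci_of_mean_high=ci_m[1],
        dropped_patients=dropped,
    )


def welch_t(a, b) -> tuple[float, float, float, float, float, float]:
    """Welch's two-sample t-test with Welch-Satterthwaite df.

    Returns (t, df, p, mean difference a-b, ci_low, ci_high).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0:
        warnings.warn("welch_t: zero variance in both groups")
        if diff == 0:
            return 0.0, float(na + nb - 2), 1.0, 0.0, 0.0, 0.0
        return float(np.sign(diff) * np.inf), float(na + nb - 2), 0.0, float(diff), float(diff), float(diff)
    se = np.sqrt(se2)
    t = diff / se
    dfree = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), dfree)
    crit = stats.t.ppf(0.975, dfree)
    return float(t), float(dfree), float(p), float(diff), float(diff - crit * se), float(diff + crit * se)


def fdr_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
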