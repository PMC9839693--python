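"""Metabolite-concentration preprocessing and PLS-DA separation diagnostics.

Concentration tables are log-transformed and auto-scaled (per-metabolite mean
0, sd 1), with mouse-stool tables additionally sum-normalized per sample
before the log. Class separation is assessed by partial least-squares
discriminant analysis validated with leave-one-out Q2/PRESS, permutation tests
on separation distance and accuracy, classification error rate, and AUROC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import roc_auc_score

from .tables_io import ConcentrationTable

__all__ = ["PlsdaReport", "preprocess", "plsda_validate"]

log = logging.getLogger(__name__)

MODES = ("human_serum", "human_stool", "mouse_stool")


def preprocess(c: ConcentrationTable, mode: str) -> pd.DataFrame:
    """Log-transform and autoscale; mouse stool is sum-normalized first.

    Zeros are replaced, per metabolite, by half the smallest positive value
    before the natural log (minimum-replacement rule). Zero-variance
    metabolites are dropped with a warning. Returns a samples x metabolites
    DataFrame with column means 0 and sds 1.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    x = c.values.astype(float).copy()
    if mode == "mouse_stool":
        rowsum = x.sum(axis=1, keepdims=True)
        if (rowsum == 0).any():
            raise ValueError("cannot sum-normalize an all-zero sample")
        x = x / rowsum
    # minimum replacement for zeros, per metabolite
    for j in range(x.shape[1]):
        col = x[:, j]
        if (col == 0).any():
            pos = col[col > 0]
            if pos.size == 0:
                continue  # all-zero column: dropped below as zero-variance
            x[col == 0, j] = pos.min() / 2.0
    keep = []
    for j, m in enumerate(c.metabolites):
        if (x[:, j] <= 0).any() or np.ptp(x[:, j]) == 0:
            warnings.warn(f"preprocess: dropping zero-variance/degenerate metabolite {m!r}")
        else:
            keep.append(j)
    x = np.log(x[:, keep])
    sd = x.std(axis=0, ddof=1)
    zero_sd = sd == 0
    if zero_sd.any():
        names = [c.metabolites[keep[j]] for j in np.flatnonzero(zero_sd)]
        warnings.warn(f"preprocess: dropping constant metabolite(s) after log: {names}")
        sel = ~zero_sd
        x = x[:, sel]
        keep = [k for k, s in zip(keep, sel) if s]
        sd = sd[sel]
    x = (x - x.mean(axis=0)) / sd
    return pd.DataFrame(x, index=c.samples, columns=[c.metabolites[j] for j in keep])


@dataclass
class PlsdaReport:
    n_components: int
    R2: float
    Q2: float
    accuracy: float
    CER: float
    AUROC: float
    separation_distance: float
    permutation_p_separation: float
    permutation_p_accuracy: float
    n_perm: int
    seed: int


def _fit_scores(x: np.ndarray, y: np.ndarray, ncomp: int) -> tuple[PLSRegression, np.ndarray]:
    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(x, y.astype(float))
    return pls, pls.x_scores_


def _separation(scores: np.ndarray, y: np.ndarray) -> float:
    c0 = scores[y == 0].mean(axis=0)
    c1 = scores[y == 1].mean(axis=0)
    return float(np.linalg.norm(c1 - c0))


def plsda_validate(x, y, n_components: int = 2, n_perm: int = 1000, seed: int = 0) -> PlsdaReport:
    """Validate a two-class PLS-DA model.

    * R2 = 1 - RSS/TSS of the fitted response.
    * Q2 = 1 - PRESS/TSS under leave-one-out refitting.
    * accuracy / CER / AUROC from leave-one-out predicted responses
      (threshold at the class-balance midpoint 0.5 on 0/1 coding).
    * Separation distance (between class centroids in latent-score space) and
      training accuracy are compared against label-permutation nulls with the
      (1 + #{null >= observed}) / (1 + n_perm) convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("plsda_validate needs exactly 2 classes")
    yb = (y == classes[1]).astype(float)
    if min((yb == 0).sum(), (yb == 1).sum()) < 3:
        raise ValueError("each class needs at least 3 samples")
    n = len(yb)
    ncomp = min(n_components, x.shape[1], n - 2)

    pls, scores = _fit_scores(x, yb, ncomp)
    fitted = pls.predict(x).ravel()
    tss = float(((yb - yb.mean()) ** 2).sum())
    r2 = 1.0 - float(((yb - fitted) ** 2).sum()) / tss
    sep_obs = _separation(scores, yb)
    acc_obs = float(((fitted >= 0.5) == (yb == 1)).mean())

    # leave-one-out
    preds = np.empty(n)
    for i in range(n):
        m = np.ones(n, dtype=bool)
        m[i] = False
        pls_i, _ = _fit_scores(x[m], yb[m], min(ncomp, m.sum() - 2))
        preds[i] = pls_i.predict(x[i : i + 1]).ravel()[0]
    press = float(((yb - preds) ** 2).sum())
    q2 = 1.0 - press / tss
    loo_acc = float(((preds >= 0.5) == (yb == 1)).mean())
    auroc = float(roc_auc_score(yb, preds))

    rng = np.random.default_rng(seed)
    hit_sep = hit_acc = 0
    for _ in range(n_perm):
        yp = rng.permutation(yb)
        pls_p, scores_p = _fit_scores(x, yp, ncomp)
        if _separation(scores_p, yp) >= sep_obs - 1e-12:
            hit_sep += 1
        fit_p = pls_p.predict(x).ravel()
        if ((fit_p >= 0.5) == (yp == 1)).mean() >= acc_obs - 1e-12:
            hit_acc += 1
    return PlsdaReport(
        n_components=ncomp,
        R2=r2,
        Q2=q2,
        accuracy=loo_acc,
        CER=1.0 - loo_acc,
        AUROC=auroc,
        separation_distance=sep_obs,
        permutation_p_separation=(1 + hit_sep) / (1 + n_perm),
        permutation_p_accuracy=(1 + hit_acc) / (1 + n_perm),
        n_perm=n_perm,
        seed=seed,
    )
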