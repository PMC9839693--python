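"""Mouse-arm computations: pathology scores, gut transit, divergence over time.

Disease burden is quantified by an eight-factor ordinal scoring system (total
0 = no disease to 12 = severe); gut transit is the time from carmine-red
gavage to the first red stool, observed on a 10-minute grid; community
divergence between genotypes is summarized per housing stratum and timepoint
by PERMANOVA on Bray-Curtis distances plus a Welch test on distances to the
group centroid (beta-dispersion), with FDR across timepoints within a stratum.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import permanova
from .diversity import bray_curtis, centroid_distances
from .paired_inference import fdr_bh, welch_t
from .tables_io import CohortMetadata, CountTable

__all__ = [
    "DEFAULT_BIN_RANGES",
    "PathologyObservation",
    "TransitObservation",
    "pathology_score",
    "transit_time",
    "divergence_trajectory",
]

log = logging.getLogger(__name__)

# four factors scored 0-2 and four scored 0-1, summing to the 0-12 envelope
DEFAULT_BIN_RANGES: tuple[int, ...] = (2, 2, 2, 2, 1, 1, 1, 1)

FACTORS = (
    "hind_limb_clasping",
    "grooming",
    "cataracts",
    "kyphosis",
    "motor_function",
    "tremors",
    "jumping",
    "body_condition",
)


@dataclass
class PathologyObservation:
    mouse_id: str
    dpw: int
    bins: tuple[int, ...]


@dataclass
class TransitObservation:
    mouse_id: str
    gavage_time: _dt.datetime
    first_red_stool_time: _dt.datetime | None  # None = not observed (censored)
    check_interval: int = 10


def pathology_score(obs: PathologyObservation, bin_ranges=DEFAULT_BIN_RANGES) -> int:
    """Total ordinal pathology score: the sum of the eight factor bins."""
    if len(obs.bins) != len(bin_ranges):
        raise ValueError(f"expected {len(bin_ranges)} factor bins, got {len(obs.bins)}")
    for name, b, mx in zip(FACTORS, obs.bins, bin_ranges):
        if not 0 <= b <= mx:
            raise ValueError(f"factor {name!r} bin {b} outside allowed range 0..{mx}")
    return int(sum(obs.bins))


def transit_time(obs: TransitObservation) -> tuple[int | None, bool]:
    """Minutes from gavage to first red stool, at the check-interval resolution.

    Returns (minutes, censored). Detection at the gavage check falls in the
    first interval and is reported as one check interval. A missing detection
    time is right-censored: (None, True), never imputed.
    """
    if obs.first_red_stool_time is None:
        return None, True
    delta = (obs.first_red_stool_time - obs.gavage_time).total_seconds() / 60.0
    if delta < 0:
        raise ValueError("red stool observed before gavage")
    k = obs.check_interval
    minutes = max(k, int(np.ceil(delta / k)) * k)
    return minutes, False


def divergence_trajectory(
    tables: dict[int, CountTable],
    meta: CohortMetadata,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Genotype-divergence summary per housing stratum and timepoint.

    For each (housing, DPW) cell with both genotypes present: PERMANOVA of
    mutant vs control on Bray-Curtis distances, and a Welch two-sample t-test
    on per-sample distances to the genotype centroid (dispersion contrast).
    PERMANOVA p-values get BH FDR across timepoints within each stratum.
    Cells missing a genotype are skipped with a warning.
    """
    df = meta.table
    rows = []
    for stratum in sorted(df["housing"].unique()):
        for dpw in sorted(tables):
            sub = df[(df["housing"] == stratum) & (df["dpw"] == str(dpw))]
            roles = set(sub["role"])
            if not {"fd_mouse", "control_mouse"} <= roles:
                log.warning("divergence_trajectory: stratum %r at DPW %d missing a genotype; skipped", stratum, dpw)
                continue
            sample_ids = sorted(sub["sample_id"])
            table = tables[dpw].select_samples(sample_ids)
            role_of = dict(zip(sub["sample_id"], sub["role"]))
            groups = np.array([role_of[s] for s in sample_ids])
            d = bray_curtis(table)
            res = permanova(d, groups, n_perm=n_perm, seed=seed)
            disp = centroid_distances(d, groups)
            fd_disp = disp[groups == "fd_mouse"]
            ctl_disp = disp[groups == "control_mouse"]
            t, dfree, p_w, diff, lo, hi = welch_t(fd_disp, ctl_disp)
            rows.append(
                {
                    "housing": stratum,
                    "dpw": dpw,
                    "n_fd": int((groups == "fd_mouse").sum()),
                    "n_control": int((groups == "control_mouse").sum()),
                    "pseudo_F": res.pseudo_F,
                    "R2": res.R2,
                    "permanova_p": res.p,
                    "dispersion_t": t,
                    "dispersion_df": dfree,
                    "dispersion_p": p_w,
                    "dispersion_diff": diff,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["permanova_q"] = np.nan
    for stratum in out["housing"].unique():
        m = out["housing"] == stratum
        out.loc[m, "permanova_q"] = fdr_bh(out.loc[m, "permanova_p"].to_numpy())
    return out.sort_values(["housing", "dpw"]).reset_index(drop=True)
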