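"""Mouse-arm analysis: genotype divergence per housing stratum over time
(PERMANOVA + beta-dispersion Welch tests with FDR across timepoints),
pathology-score and gut-transit contrasts between cohoused and separately
housed mutant mice.

Reads results/data/, writes results/mouse/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from paircohort import paired_inference, tables_io
from paircohort.longitudinal import divergence_trajectory

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"
OUT = ROOT / "mouse"
OUT.mkdir(parents=True, exist_ok=True)

meta = tables_io.read_metadata(DATA / "mouse_metadata.tsv")
tables = {
    int(p.stem.split("_d")[-1]): tables_io.read_count_table(p)
    for p in sorted(DATA.glob("mouse_otu_d*.tsv"))
}
traj = divergence_trajectory(tables, meta, n_perm=999, seed=SEED)
traj.to_csv(OUT / "divergence_trajectory.tsv", sep="\t", index=False, lineterminator="\n")
print("genotype divergence (PERMANOVA pseudo-F by housing and DPW):")
for _, row in traj.iterrows():
    print(f"  {row.housing:>9} d{int(row.dpw)}: F = {row.pseudo_F:6.2f}, "
          f"R2 = {row.R2:.3f}, q = {row.permanova_q:.4g}")

pathology = pd.read_csv(DATA / "mouse_pathology.tsv", sep="\t")
bins = [f"bin{i}" for i in range(1, 9)]
fd = pathology[pathology["role"] == "fd_mouse"].copy()
fd["score"] = fd[bins].sum(axis=1)
t, df, p, diff, lo, hi = paired_inference.welch_t(
    fd.loc[fd["housing"] == "cohoused", "score"],
    fd.loc[fd["housing"] == "separate", "score"],
)
print(f"pathology, mutant cohoused vs separate: t = {t:.3f}, df = {df:.1f}, "
      f"diff = {diff:.3f} (95% CI {lo:.3f} to {hi:.3f}), p = {p:.4g}")

transit = pd.read_csv(DATA / "mouse_transit.tsv", sep="\t")
transit["minutes"] = (
    (transit["first_red_stool_time"].map(np.datetime64) - transit["gavage_time"].map(np.datetime64))
    / np.timedelta64(1, "m")
)
fd_tr = transit[transit["role"] == "fd_mouse"]
t, df, p, diff, lo, hi = paired_inference.welch_t(
    fd_tr.loc[fd_tr["housing"] == "cohoused", "minutes"],
    fd_tr.loc[fd_tr["housing"] == "separate", "minutes"],
)
print(f"gut transit, mutant cohoused vs separate: t = {t:.3f}, df = {df:.1f}, "
      f"diff = {diff:.1f} min, p = {p:.4g}")
transit.to_csv(OUT / "transit_minutes.tsv", sep="\t", index=False, lineterminator="\n")
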