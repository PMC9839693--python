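"""Generate the synthetic study data: a 30-family paired human cohort and a
longitudinal mouse colony, written as TSV tables under results/data/.

The cohort plants the study's structure: patients carry a taxon-subset of
their family's community (lower richness), higher odds of the
disease-associated enterotype, and a 2-fold stool choline elevation.
"""

import sys
from pathlib import Path

import paircohort as pc
from paircohort import tables_io

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

spec = pc.CohortSpec(n_families=30, seed=SEED)
mspec = pc.MetaboliteSpec(seed=SEED)
counts, conc, meta = pc.generate_human_cohort(spec, mspec)
tables_io.write_count_table(counts, OUT / "otu_counts.tsv")
tables_io.write_concentration_table(conc, OUT / "metabolites.tsv")
tables_io.write_metadata(meta, OUT / "metadata.tsv")

roles = meta.table["role"].value_counts()
print(f"human cohort: {spec.n_families} families, {counts.n_samples} samples "
      f"({roles.get('patient', 0)} patients, {roles.get('relative', 0)} relatives), "
      f"{counts.n_features} OTUs, {len(conc.metabolites)} metabolites")

mouse_spec = pc.MouseColonySpec(seed=SEED)
tables, mmeta, pathology, transit = pc.generate_mouse_colony(mouse_spec)
for dpw, t in tables.items():
    tables_io.write_count_table(t, OUT / f"mouse_otu_d{dpw}.tsv")
tables_io.write_metadata(mmeta, OUT / "mouse_metadata.tsv")
pathology.to_csv(OUT / "mouse_pathology.tsv", sep="\t", index=False, lineterminator="\n")
transit.to_csv(OUT / "mouse_transit.tsv", sep="\t", index=False, lineterminator="\n")
print(f"mouse colony: {mouse_spec.n_fd} mutant + {mouse_spec.n_control} control mice, "
      f"timepoints {list(tables)} DPW, tables under {OUT}")
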