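"""End-to-end human-cohort pipeline: tables in, results bundle out.

Order of operations mirrors the analysis workflow: drop rare OTUs (< 100 reads
dataset-wide), rarefy to a common depth, compute alpha diversity / richness /
shared-OTU fractions, run the random-pairing permutation tests on those
endpoints, test patient-vs-relative separation by PERMANOVA on Bray-Curtis
distances, discover enterotypes by PAM with silhouette-selected k and test
their association with case status by exact Fisher, and process the metabolite
table (log + autoscale) into per-metabolite paired tests with BH FDR plus a
PLS-DA validation report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import community, diversity, metabolome, paired_inference
from .tables_io import CohortMetadata, ConcentrationTable, CountTable

__all__ = ["RunConfig", "run_report"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of the human-cohort pipeline, with the workflow defaults."""

    rarefy_depth: int = 9848
    min_otu_total: int = 100
    window_days: int = 90
    n_perm_paired: int = 1000
    n_perm_permanova: int = 9999
    n_perm_plsda: int = 1000
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    metabolome_mode: str = "human_stool"
    use_rarefied_for_presence: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        if "k_range" in d:
            cfg.k_range = tuple(int(k) for k in d["k_range"])
        return cfg

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


def _paired_result_row(r: paired_inference.PairedTestResult) -> dict:
    return {
        "endpoint": r.endpoint,
        "n_pairs": r.n_pairs,
        "df": r.df,
        "mean_t": r.mean_t,
        "mean_p": r.mean_p,
        "mean_diff": r.mean_diff,
        "mean_ci_low": r.mean_ci_low,
        "mean_ci_high": r.mean_ci_high,
        "q": r.q,
    }


def run_report(
    counts: CountTable,
    concentrations: ConcentrationTable | None,
    meta: CohortMetadata,
    config: RunConfig,
) -> dict:
    """Run the full human-cohort analysis; returns a results bundle dict.

    Bundle keys: ``alpha`` (per-sample DataFrame), ``paired_tests``
    (DataFrame), ``permanova`` (PermanovaResult), ``enterotype``
    (EnterotypeResult), ``fisher`` (FisherResult), ``metabolite_tests``
    (DataFrame or None), ``plsda`` (PlsdaReport or None), ``rarefaction``
    (dict), ``config`` (RunConfig). Deterministic given the config.
    """
    filtered = diversity.filter_rare_features(counts, config.min_otu_total)
    rarefied, dropped = diversity.rarefy(filtered, config.rarefy_depth, seed=config.seed)
    log.info("rarefied to %d reads; %d sample(s) dropped", config.rarefy_depth, len(dropped))
    meta_r = meta.subset(meta.table["sample_id"].isin(rarefied.samples).to_numpy())
    presence_table = rarefied if config.use_rarefied_for_presence else filtered.select_samples(rarefied.samples)

    frame = presence_table.to_frame()
    alpha = pd.DataFrame(
        {
            "sample_id": rarefied.samples,
            "inverse_simpson": [diversity.inverse_simpson(frame.loc[s]) for s in rarefied.samples],
            "richness": [diversity.richness(frame.loc[s]) for s in rarefied.samples],
        }
    ).set_index("sample_id")

    graph = paired_inference.build_pair_graph(meta_r, window_days=config.window_days)

    # shared-OTU % toward the paired relative requires a pairing; use the mean
    # over eligible relatives as the per-patient endpoint and vice versa
    shared_patient = {}
    shared_relative = {}
    for pid, rels in graph.eligible.items():
        pvec = frame.loc[pid]
        vals_pr, vals_rp = [], []
        for rid, _ in rels:
            rvec = frame.loc[rid]
            vals_pr.append(diversity.shared_fraction(pvec, rvec))
            vals_rp.append(diversity.shared_fraction(rvec, pvec))
            shared_relative[rid] = diversity.shared_fraction(rvec, pvec)
        shared_patient[pid] = float(np.mean(vals_pr))

    endpoints = {
        "inverse_simpson": alpha["inverse_simpson"],
        "richness": alpha["richness"].astype(float),
    }
    paired_rows = []
    for name, values in endpoints.items():
        res = paired_inference.permutation_paired_test(
            values, graph, n_perm=config.n_perm_paired, seed=config.seed, endpoint=name
        )
        paired_rows.append(_paired_result_row(res))
    # shared-OTU endpoints: patient->relative minus relative->patient handled as
    # a per-pair difference inside the permutation scheme via a merged endpoint
    shared_values = pd.Series({**shared_patient, **shared_relative})
    res_shared = paired_inference.permutation_paired_test(
        shared_values, graph, n_perm=config.n_perm_paired, seed=config.seed, endpoint="shared_otu_pct"
    )
    paired_rows.append(_paired_result_row(res_shared))
    paired_tests = pd.DataFrame(paired_rows).set_index("endpoint")

    # beta diversity and case-control separation
    d = diversity.bray_curtis(rarefied)
    roles = np.array([meta_r.role_of(s) for s in rarefied.samples])
    perma = community.permanova(d, roles, n_perm=config.n_perm_permanova, seed=config.seed)

    # enterotypes on the joint sample set
    k = community.select_k(d, k_range=[kk for kk in config.k_range if kk < len(d.ids)], seed=config.seed)
    ent = community.pam(d, k, seed=config.seed)
    # 2x2: cluster-1 membership vs case status (only meaningful at k = 2)
    in1 = ent.labels == 1
    patients = roles == "patient"
    table = np.array(
        [
            [int((in1 & patients).sum()), int((in1 & ~patients).sum())],
            [int((~in1 & patients).sum()), int((~in1 & ~patients).sum())],
        ]
    )
    # orient so cluster 1 is the patient-enriched configuration
    if table[0, 0] * table[1, 1] < table[0, 1] * table[1, 0]:
        table = table[::-1]
    fisher = community.fisher_exact_2x2(table)

    metabolite_tests = None
    plsda = None
    if concentrations is not None:
        # metabolite endpoints are independent of sequencing depth, so their
        # pair graph comes from the full metadata, not the rarefied subset
        met_graph = paired_inference.build_pair_graph(
            meta.subset(meta.table["sample_id"].isin(concentrations.samples).to_numpy()),
            window_days=config.window_days,
        )
        processed = metabolome.preprocess(concentrations, mode=config.metabolome_mode)
        raw = concentrations.to_frame()
        met_rows = []
        for m in processed.columns:
            logconc = np.log(raw[m].where(raw[m] > 0, raw[m][raw[m] > 0].min() / 2.0))
            res = paired_inference.permutation_paired_test(
                logconc, met_graph, n_perm=config.n_perm_paired, seed=config.seed, endpoint=m
            )
            met_rows.append(_paired_result_row(res))
        metabolite_tests = pd.DataFrame(met_rows).set_index("endpoint")
        metabolite_tests["q"] = paired_inference.fdr_bh(metabolite_tests["mean_p"].to_numpy())
        y = (np.array([meta.role_of(s) for s in concentrations.samples]) == "patient").astype(int)
        plsda = metabolome.plsda_validate(
            processed.to_numpy(), y[[concentrations.samples.index(s) for s in processed.index]],
            n_perm=config.n_perm_plsda, seed=config.seed,
        )

    return {
        "config": config,
        "rarefaction": {"depth": config.rarefy_depth, "dropped_samples": dropped},
        "alpha": alpha,
        "pair_graph": graph,
        "paired_tests": paired_tests,
        "permanova": perma,
        "enterotype": ent,
        "fisher": fisher,
        "fisher_table": table,
        "metabolite_tests": metabolite_tests,
        "plsda": plsda,
        "distance": d,
        "roles": roles,
    }
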