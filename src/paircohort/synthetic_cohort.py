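"""Synthetic paired-cohort and mouse-colony generators.

These generators emulate the statistical structure of a familial case-control
microbiome/metabolome study so every downstream stage is testable without the
deposited data:

* families contain one patient and 0-3 relatives, with relative collection
  dates jittered around the patient's date (so the 90-day pairing window has
  something to exclude);
* two community enterotypes; patients carry higher odds of the
  disease-associated enterotype than relatives;
* each patient hosts only a subset of the family's taxa (structural zeros
  applied to the composition before sequencing-depth sampling), which lowers
  patient richness and makes shared-OTU fractions asymmetric;
* log-normal metabolite concentrations with patient fold-change effects
  (by default a 2-fold choline elevation) and a family random effect;
* a mouse colony whose mutant-genotype communities drift away from the control
  baseline with days post-weaning, attenuated by cohousing, with matching
  pathology scores and gut-transit observations.

All randomness flows from the explicit seeds in the spec objects.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import CohortMetadata, ConcentrationTable, CountTable

__all__ = [
    "CohortSpec",
    "MetaboliteSpec",
    "MouseColonySpec",
    "default_enterotype_compositions",
    "generate_human_cohort",
    "generate_mouse_colony",
]

_ANCHOR_DATE = _dt.date(2019, 6, 1)


def default_enterotype_compositions(n_taxa: int) -> tuple[np.ndarray, np.ndarray]:
    """Two well-separated geometric rank-abundance compositions.

    Both use the same abundance profile; the second reverses the taxon order,
    so the dominant taxa of one type are the rare tail of the other — a crude
    but effective stand-in for two gut community configurations.
    """
    w = np.exp(-np.arange(n_taxa) / (n_taxa / 6.0))
    w /= w.sum()
    return w.copy(), w[::-1].copy()


@dataclass
class CohortSpec:
    """Generative parameters for the paired human cohort.

    The relatives-per-family weights default to the enrollment structure of a
    ~48-family familial cohort (no relative for ~15% of families, one for most,
    two or three for the rest). ``enterotype_assignment_odds`` is the odds that
    a patient's community is type 1 (relatives get the inverse odds), so the
    implied role-by-enterotype odds ratio is the square of this value.
    """

    n_families: int = 30
    relatives_per_family_weights: tuple[float, ...] = (7 / 48, 27 / 48, 13 / 48, 1 / 48)
    n_taxa: int = 200
    enterotype_base_compositions: tuple[np.ndarray, np.ndarray] | None = None
    enterotype_assignment_odds: float = 3.0
    patient_taxon_dropout: float = 0.3
    depth_mean: float = 20000.0
    depth_dispersion: float = 5.0
    date_jitter_days: int = 45
    dm_concentration: float = 50.0
    family_concentration: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("need at least one family")
        w = np.asarray(self.relatives_per_family_weights, dtype=float)
        if w.size != 4 or abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ValueError("relatives_per_family_weights must be a probability vector over {0,1,2,3}")
        if not 0.0 <= self.patient_taxon_dropout <= 1.0:
            raise ValueError("patient_taxon_dropout must lie in [0, 1]")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if self.enterotype_base_compositions is None:
            self.enterotype_base_compositions = default_enterotype_compositions(self.n_taxa)
        c1, c2 = (np.asarray(c, dtype=float) for c in self.enterotype_base_compositions)
        for c in (c1, c2):
            if c.size != self.n_taxa or abs(c.sum() - 1.0) > 1e-12 or (c < 0).any():
                raise ValueError("base compositions must be probability vectors of length n_taxa")
        self.enterotype_base_compositions = (c1, c2)


@dataclass
class MetaboliteSpec:
    """Generative parameters for log-normal metabolite concentrations.

    ``effect_metabolites`` maps metabolite name to the multiplicative
    fold-change applied to patients (2.0 doubles the patient's expected
    concentration). Baseline log-means/sds default to 3.0 / 0.5 for every
    metabolite.
    """

    n_metabolites: int = 20
    baseline_log_means: np.ndarray | None = None
    baseline_log_sds: np.ndarray | None = None
    effect_metabolites: dict[str, float] = field(default_factory=lambda: {"choline": 2.0})
    family_random_effect_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_log_means is None:
            self.baseline_log_means = np.full(self.n_metabolites, 3.0)
        if self.baseline_log_sds is None:
            self.baseline_log_sds = np.full(self.n_metabolites, 0.5)
        self.baseline_log_means = np.asarray(self.baseline_log_means, dtype=float)
        self.baseline_log_sds = np.asarray(self.baseline_log_sds, dtype=float)
        if self.baseline_log_means.size != self.n_metabolites or self.baseline_log_sds.size != self.n_metabolites:
            raise ValueError("baseline vectors must have length n_metabolites")
        if (self.baseline_log_sds < 0).any() or self.family_random_effect_sd < 0:
            raise ValueError("sds must be nonnegative")
        if any(f <= 0 for f in self.effect_metabolites.values()):
            raise ValueError("fold-changes must be positive")
        if len(self.effect_metabolites) > self.n_metabolites:
            raise ValueError("more effect metabolites than metabolites")

    @property
    def metabolite_names(self) -> list[str]:
        names = list(self.effect_metabolites)
        names += [f"met_{i:03d}" for i in range(self.n_metabolites - len(names))]
        return names


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial library sizes with the (mean, dispersion r) model."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(np.int64)


def generate_human_cohort(
    spec: CohortSpec, mspec: MetaboliteSpec
) -> tuple[CountTable, ConcentrationTable, CohortMetadata]:
    """Generate one paired human cohort.

    Per family: one patient plus 0-3 relatives. Each subject is assigned an
    enterotype (patients with odds ``enterotype_assignment_odds`` for type 1,
    relatives with the inverse odds); a family-level composition is drawn once
    per (family, enterotype) around the enterotype base; each relative's counts
    are Dirichlet-multinomial around the family composition; the patient's
    composition first has a Bernoulli(``patient_taxon_dropout``) taxon subset
    zeroed and renormalized (structural zeros), so expected patient richness is
    (1 - dropout) times relative richness at saturating depth. Deterministic
    given the spec seeds.
    """
    rng = np.random.default_rng([spec.seed, mspec.seed])
    base = spec.enterotype_base_compositions
    n_rel_choices = rng.choice(4, size=spec.n_families, p=np.asarray(spec.relatives_per_family_weights))

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    p1_patient = spec.enterotype_assignment_odds / (1.0 + spec.enterotype_assignment_odds)
    p1_relative = 1.0 - p1_patient

    for fam in range(spec.n_families):
        fam_id = f"F{fam:03d}"
        fam_comp: dict[int, np.ndarray] = {}

        def family_composition(e: int) -> np.ndarray:
            if e not in fam_comp:
                alpha = spec.family_concentration * base[e] + 1e-9
                fam_comp[e] = rng.dirichlet(alpha)
            return fam_comp[e]

        anchor = _ANCHOR_DATE + _dt.timedelta(days=int(rng.integers(0, 365)))
        members = [("patient", f"{fam_id}P")] + [
            ("relative", f"{fam_id}R{j}") for j in range(int(n_rel_choices[fam]))
        ]
        for role, sid in members:
            p1 = p1_patient if role == "patient" else p1_relative
            e = 0 if rng.random() < p1 else 1
            comp = family_composition(e)
            if role == "patient" and spec.patient_taxon_dropout > 0:
                for _attempt in range(20):
                    mask = rng.random(spec.n_taxa) >= spec.patient_taxon_dropout
                    kept = comp * mask
                    if kept.sum() > 0:
                        comp = kept / kept.sum()
                        break
                else:
                    raise RuntimeError("all-zero patient composition after repeated dropout draws")
            depth = max(1, int(_nb_depth(rng, spec.depth_mean, spec.depth_dispersion, 1)[0]))
            theta = rng.dirichlet(spec.dm_concentration * comp + 1e-9)
            rows.append(rng.multinomial(depth, theta))
            sample_ids.append(sid)
            if role == "patient":
                date = anchor
            else:
                date = anchor + _dt.timedelta(days=int(rng.integers(-spec.date_jitter_days, spec.date_jitter_days + 1)))
            meta_rows.append(
                {
                    "sample_id": sid,
                    "subject_id": sid,
                    "family_id": fam_id,
                    "role": role,
                    "collection_date": date.isoformat(),
                    "enterotype_truth": str(e + 1),
                    "age": str(int(rng.integers(8, 60))),
                    "sex": rng.choice(["female", "male"]),
                    "g_tube": rng.choice(["none", "partial", "exclusive"]) if role == "patient" else "none",
                    "antibiotics_3mo": rng.choice(["true", "false"]),
                }
            )

    counts = CountTable(
        samples=sample_ids,
        features=[f"OTU{i + 1:04d}" for i in range(spec.n_taxa)],
        counts=np.vstack(rows),
    )
    meta = CohortMetadata(pd.DataFrame(meta_rows))

    # metabolites: log-normal with family random effects and patient fold-changes
    names = mspec.metabolite_names
    log_fold = np.zeros(mspec.n_metabolites)
    for j, name in enumerate(names):
        if name in mspec.effect_metabolites:
            log_fold[j] = np.log(mspec.effect_metabolites[name])
    fam_ids = sorted({r["family_id"] for r in meta_rows})
    fam_effects = {
        f: rng.normal(0.0, mspec.family_random_effect_sd, size=mspec.n_metabolites) for f in fam_ids
    }
    conc = np.empty((len(sample_ids), mspec.n_metabolites))
    for i, r in enumerate(meta_rows):
        mu = mspec.baseline_log_means + fam_effects[r["family_id"]]
        if r["role"] == "patient":
            mu = mu + log_fold
        conc[i] = np.exp(mu + rng.normal(0.0, mspec.baseline_log_sds))
    concentrations = ConcentrationTable(
        samples=list(sample_ids),
        metabolites=names,
        values=conc,
        units={m: "nanomoles/gram" for m in names},
    )
    return counts, concentrations, meta


@dataclass
class MouseColonySpec:
    """Generative parameters for the longitudinal mouse colony.

    ``cages`` lists (n_mutant, n_control) per cage; a cage with both genotypes
    is cohoused, otherwise separately housed. Mutant communities drift from the
    control baseline with mixing weight
    ``min(1, divergence_rate * (1 - attenuation) * dpw)`` where the attenuation
    applies only in cohoused cages. ``pathology_progression`` maps DPW to the
    expected mutant pathology score per housing condition.
    """

    n_fd: int = 20
    n_control: int = 20
    cages: list[tuple[int, int]] = field(
        default_factory=lambda: [(5, 0), (5, 0), (0, 5), (0, 5), (5, 5), (5, 5)]
    )
    timepoints_dpw: tuple[int, ...] = (79, 179, 279)
    divergence_rate: float = 0.004
    cohousing_attenuation: float = 0.8
    pathology_progression: dict[int, dict[str, float]] = field(
        default_factory=lambda: {
            79: {"separate": 4.0, "cohoused": 2.2},
            179: {"separate": 6.0, "cohoused": 3.9},
            279: {"separate": 7.0, "cohoused": 4.8},
        }
    )
    n_taxa: int = 150
    depth_mean: float = 9000.0
    depth_dispersion: float = 8.0
    dm_concentration: float = 60.0
    transit_means_min: dict[str, float] = field(
        default_factory=lambda: {
            "fd_separate": 260.0,
            "fd_cohoused": 200.0,
            "control_separate": 180.0,
            "control_cohoused": 190.0,
        }
    )
    transit_sd_min: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cages:
            raise ValueError("empty cage list")
        tot_fd = sum(c[0] for c in self.cages)
        tot_ctl = sum(c[1] for c in self.cages)
        if (tot_fd, tot_ctl) != (self.n_fd, self.n_control):
            raise ValueError(
                f"cage totals ({tot_fd} mutant, {tot_ctl} control) must match "
                f"n_fd={self.n_fd}, n_control={self.n_control}"
            )
        tps = list(self.timepoints_dpw)
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.divergence_rate < 0 or not 0.0 <= self.cohousing_attenuation <= 1.0:
            raise ValueError("divergence_rate >= 0 and attenuation in [0,1] required")


def generate_mouse_colony(
    spec: MouseColonySpec,
) -> tuple[dict[int, CountTable], CohortMetadata, pd.DataFrame, pd.DataFrame]:
    """Generate the longitudinal colony.

    Returns (count table per DPW timepoint, metadata, pathology observations,
    transit observations). Pathology rows carry the eight ordinal factor bins
    (four scored 0-2, four scored 0-1; total 0-12); transit rows carry gavage
    and first-red-stool clock times on a 10-minute observation grid.
    """
    rng = np.random.default_rng(spec.seed)
    p0, p1 = default_enterotype_compositions(spec.n_taxa)

    mice: list[dict] = []
    for ci, (n_mut, n_ctl) in enumerate(spec.cages):
        housing = "cohoused" if (n_mut > 0 and n_ctl > 0) else "separate"
        for j in range(n_mut):
            mice.append({"mouse_id": f"C{ci:02d}FD{j}", "role": "fd_mouse", "cage": f"C{ci:02d}", "housing": housing})
        for j in range(n_ctl):
            mice.append({"mouse_id": f"C{ci:02d}CT{j}", "role": "control_mouse", "cage": f"C{ci:02d}", "housing": housing})

    tables: dict[int, CountTable] = {}
    meta_rows: list[dict] = []
    features = [f"OTU{i + 1:04d}" for i in range(spec.n_taxa)]
    for dpw in spec.timepoints_dpw:
        rows = []
        sids = []
        for m in mice:
            if m["role"] == "fd_mouse":
                att = spec.cohousing_attenuation if m["housing"] == "cohoused" else 0.0
                w = min(1.0, spec.divergence_rate * (1.0 - att) * dpw)
                comp = (1.0 - w) * p0 + w * p1
            else:
                comp = p0
            depth = max(1, int(_nb_depth(rng, spec.depth_mean, spec.depth_dispersion, 1)[0]))
            theta = rng.dirichlet(spec.dm_concentration * comp + 1e-9)
            rows.append(rng.multinomial(depth, theta))
            sid = f"{m['mouse_id']}_d{dpw}"
            sids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "subject_id": m["mouse_id"],
                    "family_id": m["cage"],
                    "role": m["role"],
                    "collection_date": (_ANCHOR_DATE + _dt.timedelta(days=dpw)).isoformat(),
                    "cage": m["cage"],
                    "housing": m["housing"],
                    "dpw": str(dpw),
                }
            )
        tables[dpw] = CountTable(samples=sids, features=list(features), counts=np.vstack(rows))
    meta = CohortMetadata(pd.DataFrame(meta_rows))

    # pathology: eight ordinal bins, four with range 0-2 and four with 0-1
    bin_max = np.array([2, 2, 2, 2, 1, 1, 1, 1])
    path_rows = []
    for dpw, by_housing in sorted(spec.pathology_progression.items()):
        for m in mice:
            if m["role"] == "fd_mouse":
                mean = by_housing[m["housing"] if m["housing"] == "cohoused" else "separate"]
            else:
                mean = 0.5
            total = int(np.clip(round(rng.normal(mean, 1.5)), 0, 12))
            bins = np.zeros(8, dtype=int)
            order = rng.permutation(8)
            left = total
            for b in order:
                take = min(left, int(bin_max[b]))
                bins[b] = take
                left -= take
                if left == 0:
                    break
            row = {"mouse_id": m["mouse_id"], "dpw": dpw, "housing": m["housing"], "role": m["role"]}
            row.update({f"bin{i + 1}": int(v) for i, v in enumerate(bins)})
            path_rows.append(row)
    pathology = pd.DataFrame(path_rows)

    transit_rows = []
    gavage = _dt.datetime(2020, 3, 1, 10, 0)
    for m in mice:
        key = ("fd" if m["role"] == "fd_mouse" else "control") + "_" + (
            "cohoused" if m["housing"] == "cohoused" else "separate"
        )
        minutes = max(10.0, rng.normal(spec.transit_means_min[key], spec.transit_sd_min))
        minutes = 10 * int(np.ceil(minutes / 10.0))
        transit_rows.append(
            {
                "mouse_id": m["mouse_id"],
                "housing": m["housing"],
                "role": m["role"],
                "gavage_time": gavage.isoformat(),
                "first_red_stool_time": (gavage + _dt.timedelta(minutes=minutes)).isoformat(),
                "check_interval": 10,
            }
        )
    transit = pd.DataFrame(transit_rows)
    return tables, meta, pathology, transit
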