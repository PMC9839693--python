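# Methods

## Study design and the pairing problem

The package analyses a paired case–control design: each family contributes
one patient and zero to three healthy relatives, sampled on nearby dates.
Pairing controls household factors (diet, environment, genetics) but leaves
ambiguity — a patient may have several eligible relative samples, or none.
A relative sample is *eligible* for a patient when it comes from the same
family and its collection date lies within a window of the patient's date
(default 90 days, the `window_days` parameter). Patients with no eligible
relative are excluded from paired analyses and recorded; the number of pairs,
and hence df = n_pairs − 1, is fixed per endpoint before any permutation.

## The random-pairing permutation statistic

`permutation_paired_test` draws, in each of `n_perm` iterations, one eligible
relative per patient uniformly at random (independently across patients, so a
relative shared by two patients of one household can serve both; such
relatives are flagged), computes the two-sided paired t-test on the
patient − relative differences, and reports the across-permutation arithmetic
means of t, p, the mean difference and the 95 % CI bounds. Design notes:

* **n_perm = 1000 by default** — stabilises the means to about two decimals
  at cohort scale; the Monte-Carlo error of every mean shrinks as 1/√n_perm
  and is verified against exhaustive enumeration over all pairing assignments
  in the tests.
* **The canonical interval is the mean of the per-permutation CI bounds**
  (the quantity a reader of "mean 95 % CI" expects); the normal-theory CI of
  the permutation-mean difference is also reported as a secondary field.
* **Draws are keyed by sorted patient and relative ids**, making the result
  invariant to input row order for a fixed seed.
* **Date gaps do not weight the draw** — selection is uniform over eligible
  samples.
* **Calibration.** When every patient has exactly one eligible relative the
  statistic reduces exactly to the paired t-test. With ambiguous pairings the
  mean-p aggregation is mildly *conservative*: averaging p over assignments
  shrinks the tails, and on null synthetic cohorts the empirical type-I rate
  at the 0.05 level measures ≈ 3–4 % rather than 5 %. This is a property of
  the aggregation itself (a pure Gaussian endpoint shows the same rate), not
  of the implementation; it errs on the safe side and is left as is.

`welch_t` implements Welch's two-sample test with Welch–Satterthwaite df for
the mouse contrasts; `fdr_bh` applies Benjamini–Hochberg step-up correction
(via statsmodels) to mean p within one table family (e.g. all metabolites of
one biofluid), mirroring per-biofluid correction practice.

## Diversity primitives

All count-based metrics are computed from their definitions on integer
tables. Rare OTUs are removed when their dataset-wide total falls below
`min_otu_total` (default 100 reads). Rarefaction is a *single* multivariate
hypergeometric draw per sample to a common depth (default 9,848 reads for the
human tables and 5,308 for mouse, the conventional least-sample depths of
this design); samples under the depth are dropped and reported, never scaled.
Presence (richness, shared-OTU sets) is count ≥ 1 on the rarefied table by
default — whether presence contrasts should use rarefied or unrarefied tables
is genuinely open, so `use_rarefied_for_presence` exposes the choice.
Bray–Curtis is computed on rarefied counts (equal depths make counts and
relative abundances equivalent). `shared_fraction(a, b)` is deliberately
asymmetric — 100 · |present(a) ∩ present(b)| / |present(a)| — because the
design's signature is that patients' communities are *subsets* of the family
community: the patient→relative percentage exceeds the relative→patient one.

In the pipeline the shared-OTU endpoint is summarised per sample (for a
patient, the mean over its eligible relatives; for a relative, its fraction
toward the patient) before entering the permutation test; with one relative
per family this is exact, with several it is a per-sample summary of a
pair-valued quantity — a deliberate simplification recorded here.

`centroid_distances` implements Anderson-style multivariate dispersion: the
distance matrix is embedded by principal coordinates *keeping*
negative-eigenvalue axes, and the squared distance of a sample to its group
centroid is the real-axis part minus the imaginary-axis part, floored at zero
before the square root. For Euclidean-embeddable matrices this equals plain
centroid distance in the embedding (tested against a coordinate oracle);
singleton groups get dispersion 0 with a warning.

## PERMANOVA

pseudo-F = (SS_between/(k−1)) / (SS_within/(n−k)) with
SS_total = (1/n)Σ_{i<j}d²_ij and SS_within accumulated per group; the p-value
uses whole-label permutations with the +1 convention (observed counted among
permutations, so p > 0), 9,999 permutations by default. An `exhaustive` mode
enumerates every distinct label arrangement for small n and returns the exact
fraction with F ≥ F_obs; this is the oracle mode used in tests. R² is
invariant to distance scaling; p is reproducible given the seed.

## Enterotypes

PAM runs on the Bray–Curtis matrix of the rarefied OTU table (the distance is
a flag; Bray–Curtis keeps the clustering consistent with the rest of the
beta-diversity analysis). BUILD seeds greedily; SWAP applies the best
strictly-improving (medoid, non-medoid) exchange until none remains, so the
cost is nonincreasing and terminates. Because single-start BUILD+SWAP is a
local search that can miss the optimal medoid set even at n = 7 (the
canonical R implementation lands in the same trap on such instances), `pam`
restarts SWAP from nine additional seeded random medoid subsets and keeps the
lowest-cost local optimum — a standard k-medoids practice that makes small
instances reliably optimal and is deterministic given the seed. `select_k`
maximises the average silhouette width over k = 2…5 (ties to the smallest k)
and warns when the winner is below 0.25, i.e. when no convincing cluster
structure exists. Cluster–case association uses the exact conditional 2×2
machinery: the two-sided Fisher p sums hypergeometric probabilities of
tables no more probable than observed, and the odds ratio is the conditional
MLE with an exact 95 % CI (the convention of standard exact-test software).
`rank_cluster_features` ranks taxa by permutation importance from an
out-of-bag-validated random forest (500 trees, √m features per split) on
relative abundances; note that compositional closure can spread a large
marker's signal across all columns, so importance is interpreted jointly with
the per-cluster median abundance direction that accompanies each feature.

## Metabolome

Concentrations are natural-log transformed and autoscaled per metabolite
(mean 0, sd 1); mouse-stool tables are sum-normalized per sample first.
Zeros are replaced by half the smallest positive value of that metabolite
before the log (minimum-replacement rule; the choice is logged). Zero-variance
metabolites are dropped with a warning. Paired testing uses the natural-log
concentrations, so mean differences read as log fold-changes.

PLS-DA uses two components by default (matching two-axis ordinations; a flag
allows Q²-maximising selection) on the NIPALS core of scikit-learn. Q² is
1 − PRESS/TSS under leave-one-out refitting; accuracy, CER and AUROC come
from the leave-one-out predicted responses thresholded at 0.5 on 0/1 class
coding; separation distance (between class centroids in score space) and
training accuracy are compared to 1,000 label-permutation nulls with the +1
convention. The report is descriptive — no pass/fail threshold is imposed.

## Mouse arm

The pathology score sums eight ordinal factor bins (hind-limb clasping,
grooming, cataracts, kyphosis, motor function, tremors, jumping, body
condition). Bin ranges are configuration, defaulting to 0–2 for the first
four factors and 0–1 for the last four so the total spans 0 (no disease) to
12 (severe) — studies differ in exact bin widths, so the ranges are supplied
rather than hard-coded. Gut transit is the time from carmine-red gavage to
first red stool on a 10-minute observation grid, rounded up to the grid
(detection at the gavage check reports as 10 min); missing detections are
right-censored and flagged, never imputed. `divergence_trajectory` computes,
per housing stratum and timepoint, the genotype PERMANOVA on Bray–Curtis
distances plus a Welch test on distances to the genotype centroid, with BH
FDR across timepoints within each stratum. Cage is recorded and reported but
not modelled as a random effect — tests are sample-level by design.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
sizes a desk run can afford:

* **Families.** 30 families by default; relatives per family drawn from
  weights (7, 27, 13, 1)/48 over {0, 1, 2, 3} — the enrollment profile of a
  ~48-family familial cohort. Patient date anchors the family; relative dates
  jitter uniformly within ±45 days (so the 90-day window logic, including
  exclusions, is exercised when the jitter is widened).
* **Communities.** Two enterotype base compositions (geometric rank-abundance
  profile; the second reverses the taxon order), 200 taxa. A family-level
  composition is drawn per (family, enterotype) from a Dirichlet around the
  base (concentration 200); samples are Dirichlet-multinomial around the
  family composition (concentration 50) with negative-binomial library sizes
  (mean 20,000, dispersion 5 — overdispersed depths deliberately stress the
  rarefaction step). Patients get an enterotype-1 odds of 3 (relatives the
  inverse), implying a role-by-enterotype odds ratio of ~9, the magnitude
  such studies report.
* **Patient subset effect.** Before sequencing-depth sampling, a
  Bernoulli(0.3) taxon subset of the patient's family composition is zeroed
  and the rest renormalised (structural zeros), so expected patient richness
  is 0.7× relative richness at saturating depth and shared-OTU fractions are
  asymmetric. An all-zero draw is retried up to 20 times, then errors.
* **Metabolites.** 20 metabolites, log-normal with baseline log-mean 3.0 and
  log-sd 0.5 (a realistic between-subject CV for quantified polar
  metabolites), a family random effect (sd 0.3) that cancels within pairs,
  and a planted patient fold-change map defaulting to choline → 2.0. Under
  these conditions the 2-fold effect is detected at q < 0.05 in ≈ 90 % of
  30-family cohorts.
* **Mouse colony.** 20 mutant + 20 control mice in cages of 5 (two mutant-
  only, two control-only, two mixed); mixed cages are "cohoused". Mutant
  compositions at t days post-weaning are mixed toward a divergent target
  with weight min(1, rate·(1−attenuation)·t), rate 0.004/day, cohousing
  attenuation 0.8. Pathology totals are drawn around housing-dependent means
  rising with DPW and distributed into the factor bins; transit times are
  normal around group means (separately housed mutants slowest), quantised to
  the 10-minute grid.

All randomness flows from the explicit seeds in the spec dataclasses (the
human generator consumes a single stream seeded from both the cohort and
metabolite seeds); identical seeds give byte-identical tables.

**What the generator does not emulate:** real taxon co-occurrence structure,
compositional covariance between metabolites and microbiome, longitudinal
autocorrelation within subjects, batch effects, or measurement error in
metabolite quantification. Passing tests therefore demonstrate that the
statistics are implemented correctly and behave as designed under the planted
effects — not that the pipeline's modelling assumptions hold on any
particular real dataset.

## Problem sizes and numerical choices

The test suite and the acceptance script run null calibration on 200
reduced-size cohorts (60 taxa, depth ~3,000, rarefied to 1,500) and power on
200 default-size cohorts — sizes chosen so the whole suite completes in well
under a minute of compute while keeping Monte-Carlo error small relative to
the asserted bands. Tolerances: exact oracles (Fisher enumeration, PAM
brute force, exhaustive PERMANOVA) to 1e-12 or exact float equality;
Monte-Carlo comparisons at 3σ; calibration bands as stated above. Degenerate
inputs follow explicit conventions: zero-variance paired differences give
t = ±∞ with p → 0 (flagged) or t = 0, p = 1 when the mean is also zero;
all-zero samples are rejected by Bray–Curtis and inverse Simpson; empty
feature sets after filtering are allowed with a warning.

## Known limitations

* The shared-OTU endpoint's per-sample summarisation (above) approximates
  the pair-valued quantity for multi-relative families.
* PLS-DA permutation nulls reuse the full-data fit per permuted labelling
  (not nested leave-one-out), the usual cost compromise.
* No phylogeny-aware beta diversity, no mixed-effects models for repeated
  measures, no survival analysis of the mouse arm.
* The mean-p aggregation's mild conservatism under pairing ambiguity is
  inherent to the method and documented rather than corrected.
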