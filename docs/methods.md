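# Methods

## Scope and data model

`eicostats` analyses paired concentration matrices from a whole-blood
stimulation design: for each subject, an unstimulated EDTA-plasma
measurement (*baseline*) and a zymosan-stimulated supernatant measurement
(*stimulated*) of the same targeted eicosanoid panel. Units are fixed
throughout: concentrations in ng/ml, white-blood-cell (WBC) counts in
10⁶ cells/ml, net release in ng per 10⁶ leukocytes. Each panel entry carries
one or more pathway labels from {COX, 5-LOX, 12-LOX, 15-LOX, CYP, AUTOX};
AUTOX (non-enzymatic auto-oxidation) is a real label so that its exclusion
from pathway scoring is an explicit downstream filter rather than a
parse-time drop. A cell can be *censored* (measured, below the limit of
detection) or *missing* (not measured); the two are distinct: censored cells
are substituted, missing cells drop the subject from that metabolite's test
only (pairwise deletion, with the effective group sizes recorded per
result).

## Preprocessing

**Detection filter.** For a two-group comparison, metabolite *j* is excluded
iff its censored fraction is ≥ `detect_threshold` (default 0.8) in **both**
groups. The boundary case excludes ("at least 80 %"). The filter is
evaluated per contrast on the matrix the analysis actually tests — the
stimulated matrix for the release analysis, the baseline matrix for the
plasma analysis — because the rule refers to the samples entering the test.
Raising the threshold can only enlarge the kept set (monotone; property-
tested).

**Censoring substitution** (applied to both matrices, before subtraction):

* `zero` (default): censored cells → 0;
* `half_lod`: censored cells → LOD/2;
* `km`: censored cells → the conditional mean below the LOD of a reversed
  Kaplan–Meier fit. We flip signs (left-censored *x* < LOD becomes
  right-censored −*x* at −LOD), apply the standard product-limit estimator
  (via `lifelines.KaplanMeierFitter`), and flip back. With a common LOD per
  metabolite the product-limit estimator assigns each detected value mass
  1/n and leaves the remaining mass *somewhere* below the LOD — its location
  is not identified. We place that atom at LOD/2 (the midpoint of the
  censored interval), which keeps every imputed value strictly below the LOD
  and makes the estimator's mean well defined. A consequence worth stating
  plainly: with a single common LOD the `km` substitution coincides with
  `half_lod`; the two differ only for heterogeneous censoring patterns. A
  metabolite whose measured cells are all censored falls back to zero, with
  a log line.

Because the downstream tests are rank-based, replacing all censored cells of
a metabolite by *any* common constant strictly below every detected value
yields identical test results; this is why the three schemes agree on data
where detected values sit above the LOD (they do by construction), and it is
verified bit-for-bit in the test suite.

**Net release.** Stimulated minus baseline, cell-wise, negative differences
retained — clipping at zero would manufacture ties and distort ranks. Then
each subject's row is divided by their WBC count. Normalisation matters
because asthmatics run systematically higher leukocyte counts than controls;
under the generative model below it is exactly the right correction.

## Inference

**Statistic.** Wilcoxon rank-sum *W* of group A over pooled midranks;
two-sided evidence is the centred absolute statistic |W − n_A(n+1)/2|
(symmetric and tie-safe; midranks keep E[W] = n_A(n+1)/2 under ties).

**Joint permutation ensemble.** One set of B (default 10 000) uniformly
random group-label assignments — sampled with replacement over the
assignment space; collisions are negligible at realistic n and sampling
stays O(B) — plus the identity as permutation 0, shared by **all**
metabolites. Sharing preserves the inter-metabolite correlation of the null
and is what makes both the minP adjustment and the pathway calibration
valid. For total n ≤ `exhaustive_max_n` (default 12) the ensemble instead
enumerates all C(n, n_A) assignments and p-values are exact. Subjects are
first put in a canonical (sorted-id) order so results are invariant to input
row order.

**p-value convention.** p = (1 + #{b ≥ 1 : |T_b − E_b| ≥ |T_obs − E|}) / (B+1).
This is a valid test (p ≥ 1/(B+1), never 0); ties between permuted and
observed statistics count as at least as extreme (conservative). All
comparisons internally use integer extremity counts, so ties are exact
rather than floating-point accidents.

**Step-down minP adjustment** (default). For each permutation b and
metabolite j, the count matrix C[b, j] = #{b′ : |T_{b′,j}| ≥ |T_{b,j}|}
gives the p-value metabolite j would have if permutation b had been
observed (row 0 reproduces the raw p-values exactly). Hypotheses are
processed from most to least significant; the adjusted p of the i-th is the
permutation frequency with which the minimum p over hypotheses i..m falls at
or below the observed one, with monotonicity enforced by a running maximum.
Perfectly correlated hypotheses therefore incur no penalty (tested with
duplicated columns), and adjusted ≥ raw always. Benjamini–Hochberg step-up
(`method="bh"`, via statsmodels) is the marginal cross-check; the adjustment
family is one contrast (recorded in the manifest).

**Pathway functional class scoring.** Within each non-AUTOX pathway with at
least one kept member, the Tippett combining function takes the minimum of
the member p-values. Calibration reuses the metabolite count matrix: for
each permutation b, each member's p-value is its statistic ranked within the
full ensemble (double ranking, which keeps per-permutation member p-values
exchangeable), and their minimum forms the pathway's null draw; the pathway
p-value applies the same (1 + #)/(B + 1) convention. Because group labels —
not memberships — are permuted, this is a *self-contained* test (null: no
member associated with the grouping). For a singleton pathway it reduces
exactly to the member's raw p. Dual-annotated metabolites (e.g.
5-LOX/15-LOX) count in every pathway they carry by default; a
primary-label-only mode exists because published pathway counts cannot
disambiguate the convention. Pathway p-values are adjusted with the same
step-down machinery over the (4–5 member) pathway family.

## Synthetic cohorts

The generator exists so that every pipeline stage is testable without any
deposited data; its defaults encode the study conditions.

* **Design**: 63 healthy controls, 108 mild-to-moderate asthmatics
  (OCS-naive by definition), 90 severe asthmatics of whom 44 use oral
  corticosteroids permanently.
* **WBC**: truncated normal (floor 0.5 ×10⁶/ml), 6.02 ± 1.46 for controls
  and 7.87 ± 2.61 for both asthma groups — truncated normal rather than
  log-normal because the source scale is reported as mean ± SD.
* **Baseline concentrations**: per-metabolite log-normal, moment-matched to
  the published control plasma means/SDs for the 41 plasma-detected
  analytes (σ² = ln(1 + (SD/mean)²), log-median = ln(mean) − σ²/2); the 26
  not-detected analytes get a synthetic low scale (mean 0.002 ng/ml) below
  their synthetic LOD (0.01 ng/ml). True assay LODs are not published; for
  detected analytes the shipped LOD is one fifth of the smaller group mean.
* **Stimulated = baseline + release**, additive on the concentration scale,
  so baseline subtraction is exactly the right deconfounding at fold-change
  1. Release is log-normal (log-SD 1.0, a typical right-skew for stimulated
  mediator release) scaled **linearly in the subject's WBC** relative to a
  reference count of 6.0 ×10⁶/ml — making WBC division exactly the right
  normalisation — with median 5× the baseline mean for plasma-detected
  analytes. Ten analytes of the leukotriene cascade and related products
  that are undetectable in circulation but produced by stimulated leukocytes
  get release median 0.05 ng/ml (well above LOD); the remaining sixteen stay
  essentially always below LOD, so the reference cohort yields 51 detectable
  analytes after stimulation and 41 at baseline.
* **Censoring**: any drawn cell below its metabolite's LOD is flagged and
  stored as 0 (the pre-substitution sentinel). Flags are consistent with the
  latent draws by construction (tested via `return_latent`).
* **Effects** are multiplicative shifts of a stratum's release median
  (fold 1 = null). The reference configuration plants the reported
  directions: LTE4 up ×3 in mild-to-moderate and ×2.5 in OCS-naive severe
  disease; 15-HETE up ×2 in mild-to-moderate only; all detected COX products
  down ×0.35 under permanent OCS, with a milder ×0.6 suppression of 12-HHT
  and 11-HETE in OCS-naive severe disease. Magnitudes are the package's own
  choice (the source reports directions and significance, not effect sizes).

What the generator deliberately does **not** emulate: measurement error on
top of the biological draw, within-subject correlation beyond the shared
baseline term, batch/chromatographic effects, heterogeneous per-sample LODs,
and missing-at-random cells. Passing tests therefore demonstrate the
statistical machinery's correctness and calibration under a clean
exchangeable null — not robustness to assay artefacts.

## Validation and problem sizes

The acceptance layer (tests and `scripts/acceptance.py`) recomputes:

* exact equality of exhaustive-mode p-values with brute-force enumeration
  over all C(n, n_A) assignments (n ≤ 12, no ties), including the fully
  separated 3-vs-3 split (p = 2/20 = 0.1) and agreement with the exact
  two-sided Mann–Whitney p;
* type-I calibration: 1000 null cohorts (n = 20/group, 10 metabolites,
  B = 2000), pooled rejection rate at α = 0.05 inside the 99 % binomial
  envelope [0.032, 0.068];
* FDR control: 20 metabolites (15 null, 5 at fold 3), n = 30/group, 200
  replicates, mean false-discovery proportion at q = 0.05 within two
  Monte-Carlo SEs of the level for both minP and BH;
* zero vs LOD/2 substitution: bit-identical results on cohorts where the
  premise (substitution constants below all detected values) holds;
* the Tippett null law: ECDF of the min of k uniforms within the DKW band
  of 1 − (1−t)^k at n = 10 000 for k ∈ {2, 5, 10};
* pathway selectivity: a fold-4 effect confined to one 5-member pathway is
  the top-ranked pathway in ≥ 95 % of 100 replicates; duplicated-column
  pathways equal their singleton exactly;
* the ≥ 80 % filter boundary and byte-identical reruns from an identical
  run configuration.

These problem sizes (hundreds of replicates, B in the hundreds-to-thousands
for simulation studies, B = 10 000 for single analyses) keep the full
validation run in the tens of seconds on one core while leaving Monte-Carlo
error well inside the asserted margins; the statistics scale linearly in B
and in the number of metabolites.

## Known limitations

* The "step-down FDR" adjustment family is one contrast; adjusting jointly
  across contrasts is not implemented.
* minP's resolution is limited by B: with m metabolites the smallest
  achievable adjusted p is roughly m/(B+1), so small B can leave floor-level
  raw p-values non-significant after adjustment. Use B = 10 000 (the
  default) for real analyses.
* The `km` scheme's below-LOD atom placement (midpoint) is a convention;
  with a single common LOD it cannot be distinguished from LOD/2
  substitution by design.
* Paired/stratified permutation schemes, covariate adjustment, Tobit-style
  censored regression and multivariate pathway statistics are out of scope.
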