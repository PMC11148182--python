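# Methods

## The functionality score

Each tumor sample sits in wells of a 96-well plate together with a reporter
cell line that overexpresses PD-1 and secretes murine IL-2 upon ligand
engagement. Four well conditions matter: unblocked (`NO_AB`), receptor
blocked with pembrolizumab (`BLOCK_PD1`), PD-L1 blocked with durvalumab
(`BLOCK_PDL1`), and PD-L2 blocked with anti-CD273 (`BLOCK_PDL2`). For one
sample and one blocking condition,

    Δ     = mean(unblocked signal) − mean(blocked signal)
    score = Δ / log2(coverage mm²) × PC ratio

The `log2` coverage term normalises for tissue quantity; the PC ratio
(`pc_reference / mean positive-control signal on the plate`) harmonises
across plates and experiments. Three scores per patient result: PD-1
(receptor block, total functionality), PD-L1 and PD-L2 (ligand-specific).

Numerical conventions, chosen where the assay description leaves room:

- **Replicates** are aggregated by arithmetic mean of signals *and* of
  coverages before the formula is applied; replicate SDs are retained for
  QC. The formula can equivalently be read per-well; averaging first is the
  stabler choice at duplicate/triplicate depth and is what the round-trip
  tests pin down.
- **Negative Δ** (blocked wells brighter than unblocked) is retained, not
  clamped, and flagged `negative_delta` — a blocking failure should be
  visible, not silently zeroed.
- **Coverage ≤ 1 mm²** is a hard error (`coverage_too_small`): `log2`
  crosses zero there and would flip or explode the score.
- **PC reference** defaults to the grand mean of positive-control wells
  across the plates in the run (so a single-plate run has PC ratio 1); an
  external reference value can be supplied to harmonise across runs.
- **Blank wells**, when present, are averaged per plate and subtracted from
  that plate's other wells (floored at 0) before anything else.
- The optional **ELISA standard curve** is a four-parameter logistic fitted
  by least squares (scipy `curve_fit`), requiring ≥ 5 distinct calibrator
  concentrations and a monotone calibrator trend (Spearman |ρ| ≥ 0.9);
  inversion is defined only strictly between the asymptotes and within the
  calibrator signal range. Signals may arrive either as optical density
  (with a curve) or as pre-interpolated concentration.

## CPS

CPS = 100 × (PD-L1-positive tumor + immune cells) / total viable tumor
cells; scale-invariant in the counts. The positivity boundary is **CPS ≥ 1**
(inclusive, configurable), and reporting bands are <1, 1–20, >20, which
partition the nonnegative axis exactly.

## Cohort analyses

- Responder = RECIST best response CR or PR; non-responder = SD or PD.
- Score stratification uses **strict inequality**: score > cutoff (default
  4) is the high stratum; exact ties go low. Patients missing the score are
  listed in an `excluded` bucket, never dropped silently.
- Response-rate percentages are rounded to the nearest integer; an empty
  stratum reports percent as undefined, not 0.
- Kaplan–Meier estimation and the unweighted log-rank test are delegated to
  lifelines (events precede censorings at tied times); the in-package
  `SurvivalCurve` records the estimate, at-risk counts and n at the event
  times. Both are verified against hand-computed product-limit and O−E/V
  oracles in the tests.
- Group comparisons: continuous variables use the Wilcoxon rank-sum test —
  exact enumeration when both groups have ≤ 10 tie-free observations,
  otherwise the normal approximation with tie correction; categorical
  variables use Pearson χ² without continuity correction, falling back to
  Fisher's exact test for 2×2 tables with any expected count below 5.
- Response duration = (response end, or last follow-up when ongoing) −
  response start; ongoing responses are censored at follow-up and included
  in stratum means. Responders missing a start date are excluded with a
  warning.

## Predictive evaluation

A gradient-boosted tree classifier (XGBoost, logistic loss) restricted to
**exactly one boosting round** — a single tree of depth ≤ 3 — on the three
functionality scores. The single round is the regulariser: `lambda` and
`min_child_weight` are set to 0 so that splits and leaf values depend only
on class proportions, which makes the fitted tree invariant to duplicating
every row and its risk score a pure rank statistic (invariant to monotone
feature transforms).

Evaluation is stratified 3-fold cross-validation with the out-of-fold risk
scores **pooled** into one test AUC (Mann–Whitney form, ties ½) — stabler
than per-fold AUCs when test folds hold ~5 patients. The whole CV is
repeated over 100 cohorts per size, sizes 15–29, drawn from the source
cohort by **stratified bootstrap** (with replacement; a size-29 draw is
thereby still a perturbed resample rather than the identity). Two protocol
validity rules follow from resampling with replacement:

1. CV folds are grouped by original patient identity
   (`StratifiedGroupKFold`), so bootstrap copies of one patient never
   straddle a train/test boundary. Without this the evaluation leaks:
   label-independent features score ~0.64 mean AUC at size 15.
2. A draw whose class collapses onto a single distinct patient is redrawn
   (it cannot be group-split three ways); drawn class counts are floored at
   3 per class for the same reason.

The headline summary of a sampling curve is the **minimum across cohort
sizes of the per-size mean test AUC**. The minimum over individual repeats
is also reported but is not a stable statistic at this scale: with 5-patient
test folds, rare degenerate resamples produce low single-repeat AUCs even
for perfectly separable data.

Everything is bit-reproducible from a single seed: the per-repeat CV seeds
are drawn from one `numpy` generator seeded by the curve seed.

## Synthetic data

`generate_cohort` draws latent PD-L1 and PD-L2 functionalities log-normally
(defaults: log-means 0.7 and −0.1, log-SD 1.0), sets the latent PD-1
functionality to their sum (receptor blockade ablates both ligand
interactions), and then draws:

- response ~ Bernoulli(logistic(−2.2 + 0.55 × PD-1 score)) — calibrated so
  a 29-patient cohort averages ~50 % responders with ~13 patients above the
  cutoff of 4, the balance of the study design it emulates;
- OS and PFS ~ exponential with response-dependent hazards (mean OS 32 vs
  17 months, mean PFS 27 vs 7 months for responders vs non-responders, the
  reported cohort means), right-censored uniformly on (0, 60] months, with
  PFS capped at OS;
- CPS positivity agreeing with PD-L1 functionality (> 2) with probability
  0.8, so CPS-negative responders occur; positive values are drawn
  log-normally above 1, negative values uniformly below 1; one patient per
  cohort has missing CPS (excluded from CPS-stratified tables);
- treatment line ~ multinomial (10/29, 17/29, 2/29);
- response durations ~ exponential, mean 28 months above the score cutoff
  vs 8 below; responses still running at last follow-up are marked ongoing.

`generate_plates` inverts the score formula: per patient one coverage value
is drawn on (2, 8) mm² (a single tissue preparation feeds all of that
patient's wells), blocked wells sit at
`U − latent × log2(coverage) / pc_ratio` with the unblocked level `U` set
20 signal units above the largest delta, and per-plate positive-control
wells realise the plate's drawn PC ratio against a reference signal of 150.
Noise is multiplicative Gaussian (`well_noise_sd` is a fraction of the
clean signal; 0 by default). With zero noise the scoring module recovers
the latent scores to machine precision, including across plates with
different PC levels; at 5 % noise the recovered-vs-latent correlation
exceeds 0.95 at n = 200.

Presets: `default` as above; `strong-effect` makes response nearly
deterministic in the PD-1 score (logistic slope 12 centred on the cutoff)
and rejection-samples latents out of the band (3, 5) so the two strata
separate with a margin — the regime in which the sampling curve holds a
per-size mean test AUC ≥ 0.98 at every size; `null` severs the
response/score link (response probability ½ regardless of scores). For
chance-level checks of the *protocol* a larger null source cohort (n = 200)
is used, because a single 29-patient null draw carries accidental
feature–label association that the bootstrap then faithfully resamples.

What the generator does **not** emulate: ELISA optics and saturation,
spatial plate effects (edge wells), correlated measurement drift within a
plate, non-exponential survival, and any real joint distribution of the
three scores (the study reports only boxplots). Passing tests therefore
demonstrate the pipeline's correctness and statistical behaviour under the
declared model, not the assay's clinical performance.

## Problem sizes

Tests and the acceptance script run the full protocol at its native scale —
sampling curves over sizes 15–29 with 100 repeats each (~10 s per curve),
score recovery at n = 200, power simulations at 200 replicates — chosen so
the whole suite completes in well under a minute of compute per component.

## Known limitations

- The per-well versus per-sample reading of the coverage normalisation is
  ambiguous in the assay description; this package averages replicates
  first (see ledgered conventions above). With one coverage per sample the
  two readings coincide.
- The rank-sum duration comparison at the study's stratum sizes (12 vs 16)
  has ~73 % power for the 28-vs-8-month exponential contrast, so a
  non-significant duration difference in a single simulated cohort is
  expected in roughly a quarter of draws.
- Fisher's exact test is only used as the sparse-table fallback for 2×2
  tables; sparse 2×k tables with k > 2 still use χ², which can be
  anticonservative at tiny counts.
- The single-round tree cannot express interactions beyond depth 3 and its
  risk scores are piecewise constant; AUC ties are common at small n.
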