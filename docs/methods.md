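# Methods

## Ratio features and the CT convention

All features are within-sample ratios of two small ncRNA species. On the
sequencing side the feature is `log2((c_a + ε)/(c_b + ε))` with
pseudocount ε = 0.5; the pseudocount is needed because the abundance
filter is max-based (≥ 50 copies in *any one* pooled sample), so a
retained species can still be zero in other pools. On the qPCR side the
feature is `ΔCT(a/b) = CT(b) − CT(a)`: since CT falls by one cycle per
doubling of template at 100% amplification efficiency, ΔCT is the log2
abundance ratio of a over b, larger when a is relatively more abundant.
The cross-group statistic is `RATIO(X vs Y) = mean ΔCT_X − mean ΔCT_Y`
and `FC = 2^RATIO`. The package keeps the efficiency as a configurable
slope in the simulator (default 1 cycle/log2) but performs no efficiency
calibration on real data; FC = 2^RATIO *assumes* that slope.

Pairs are enumerated unordered — `n(n−1)/2` for n eligible species, e.g.
333,336 for n = 817 — and each pair is then oriented so its contrast
RATIO is non-negative; the reported label is `numerator/denominator` in
that orientation. Pre-miRNAs are excluded from enumeration. Missing CT
values (`NA`) exclude a sample pairwise from that pair's statistics;
technical replicates are collapsed by the arithmetic mean of CT values
(not of linearized quantities), with no outlier rejection.

## Differential screen

Per pair, a two-sided two-sample t-test on the (already log-scale) ratio
values — equal-variance Student's by default, Welch optional. Zero-
variance degeneracies are resolved deterministically (equal means → p = 1,
unequal means → p = 0). Multiplicity correction defaults to Benjamini–
Hochberg: with hundreds of thousands of pairs, family-wise control would
be vacuous, and BH is the field standard; Bonferroni is available via
`correction="bonferroni"`. Candidates require oriented FC ≥ 2 **and**
corrected p ≤ 0.05, applied per contrast (LAC+benign vs. control, LAC
vs. control, LAC vs. benign). No correction is attempted for the strong
dependence among pairs sharing a member; the screen is a ranking device,
not an inferential endpoint, and the panel's validity rests on the
independent-cohort evaluation.

## ROC selection

ROC curves are built over tie-grouped operating points: one cutpoint
between each run of equal scores (midpoints; ±inf at the ends), a sample
counting positive when its score is strictly above the cutpoint. The
trapezoidal area of this curve equals the Mann–Whitney statistic
U/(n₁n₂) with ties counted half — a property the test suite checks
against independent pairwise counting and against scikit-learn. The
per-pair operating point is Youden's J (max TPR − FPR, ties broken
toward higher specificity); the published tables report one SEN/SPE per
pair without naming a rule, and Youden is the conventional default.
Markers must strictly exceed SEN 0.80, SPE 0.80 and AUC 0.800; all
candidates are retained in the output tables regardless, so looser or
stricter selections can be reproduced by re-filtering.

## Panel assembly

SVM-RFE with a linear-kernel SVC (C = 1.0): fit on standardized surviving
features, remove the feature with the smallest squared weight, one per
iteration; ties are broken by eliminating the lexicographically larger
pair id, making the ranking deterministic. Standardization is per-column,
so re-standardizing survivors is a no-op and the loop is equivalent to
scikit-learn's reference RFE (cross-checked in the tests). The panel is
the smallest rank prefix maximizing the pooled out-of-fold CV AUC
(stratified 10-fold, seeded shuffle; k is reduced with a warning when the
smaller class has fewer than k members), searched up to `max_panel_size`
(default 10, bracketing the published panel sizes of 7 and 5). Per fold,
standardization constants come from the training folds only, and metrics
are computed once on the pooled out-of-fold decision values. The final
classifier is refit on all training samples; the confusion threshold is
Youden's J on the pooled CV decision values and is carried unchanged to
any validation cohort (scores strictly above the threshold are positive;
a score exactly at the threshold is negative). The positive class is the
disease arm of the contrast. When the candidate set is large, the RFE
input is capped at `max_rfe_features` (default 50) by per-pair AUC —
with ~10² samples, ranking thousands of strongly collinear features adds
cost but no information.

## Synthetic studies

The generator emulates the targeted two-cohort design: training groups of
50/35/29 (LAC/benign/control) and validation groups of 44/32/51; 415
species in the observed class composition (~310 mature miRNAs, 32
pre-miRNAs, 47 tRNAs, 19 snoRNAs, 3 rRNAs, 4 scRNAs); six pooled
sequencing samples (two per training group) at 2×10⁷ reads each;
triplicate CT values per individual.

Generative model, all log2 scale: species baseline `~ N(6, 2²)` (shared
across cohorts), per-sample expression adds the group effect and
`N(0, biological_sd²)` noise with `biological_sd = 0.5`;
`CT = 36 − expression + N(0, 0.25²)` per replicate; pool proportions are
the mean linear-scale expression of members, counts multinomial. Twelve
pairs are planted by default: seven with effects 1.7–3.4 log2 in
LAC+benign (panel-1-like) and five with ~1.0 log2 in LAC only
(panel-2-like), the effect applied to the numerator species. The noise
scales are choices typical of plasma qPCR panels (triplicate SD ≈ 0.25
cycles; interindividual spread ≈ 0.5 log2), and the log-normal abundance
baseline is a modeling choice, not an observed distribution.

Planting a shift on one species makes *every* pair containing it
differential, and those sibling pairs are statistically exchangeable with
the designated planted pair. Recovery is therefore assessed in two
complementary ways: the screen must recover the planted pairs within the
full enumeration (where hundreds of exchangeable siblings legitimately
pass too), while RFE-ranking recovery is assessed on a feature set of
planted pairs plus null pairs (two unaffected species), where "the
informative features rank first" is a well-posed claim. The generator
does not emulate batch effects, hemolysis, assay dropout at high CT, or
correlated biology between species — passing tests show the pipeline's
statistics behave as designed, not that any particular panel generalizes
to real plasma.

All randomness flows from one integer seed through fixed-purpose
`numpy.random.SeedSequence` substreams, so every artifact — including
report files — is byte-reproducible for a given configuration; report
files contain no timestamps.

## Pipeline scale and screening data

Candidate screening runs on the per-individual training-cohort ΔCT
features (30–85 samples per arm), not on the pooled sequencing samples:
with two pools per group a t-test would have n = 2 per arm and no power.
The count matrix instead contributes the ≥ 50-copy abundance filter that
fixes the species universe. At the default scale (415 species → ~74k
pairs per contrast, 114 training samples) a full three-contrast run takes
a few seconds on one CPU; tests and the acceptance script use 20–200
species cohorts, which preserve every code path at a fraction of the
cost.

## Known limitations

* "Corrected p-value" in the motivating study is unnamed; BH vs.
  Bonferroni changes the candidate set, and the choice here (BH default)
  is a documented convention, not a reconstruction.
* Per-pair SEN/SPE depend on the unstated operating-point rule; published
  per-pair specificities below 0.8 alongside a stated SPE > 80% criterion
  cannot be reconciled, so the criteria are applied as configurable
  filters and all pairs are reported.
* PPV/NPV are computed from counts only; published PPV/NPV values that
  cannot be re-derived from the printed rates and arm sizes are not
  back-solved.
* Auto panel sizing (smallest prefix maximizing CV AUC) is this package's
  rule; how the published panel sizes of 7 and 5 were chosen is not
  described.
* No nested CV: the panel-size search reuses the same folds that produce
  the reported CV AUC, which is mildly optimistic; the independent
  validation cohort is the unbiased check.
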