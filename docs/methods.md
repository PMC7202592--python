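# Methods

## Cohort model

A cohort is a sample-metadata table, an alteration-call table and an
ordered gene panel. Biopsy sites map deterministically onto disease
groups: breast and chest-wall biopsies are local disease, lymph-node
biopsies their own group, distant organs (liver, bone, lung, brain, skin,
pleura, pleural fluid, soft tissue, ovary, GI) metastases, and anything
else — including unrecognized strings — is ambiguous and excluded from
inference by default. The mapping is a module constant
(`config.SITE_GROUP`) and can be overridden, since any such assignment of
rare sites is a judgment call.

Alteration calls are binarized per gene. A gene counts as *mutated* when
it carries at least one short variant; amplification, deletion and
rearrangement are separate gene×class features, mirroring how mutation
and copy-number events behave as distinct biological endpoints in
enrichment results. Under the known/likely-only filter, short variants of
unknown significance contribute neither to the flags nor to the mutation
load. Mutation load per Mb divides the short-variant count by a panel
footprint constant (default 1.1 Mb); since the footprint enters all
models as a single multiplicative rescaling of one covariate, its exact
value does not affect any test decision. Samples mutated in more than 25
distinct genes are flagged hypermutated. Tables are UTF-8 TSV with `.`
for missing.

## Enrichment scanning

Each feature is tested by logistic regression of the group indicator on
the feature plus three covariates: probability of ER positivity, HER2
amplification, and mutation load per Mb. The covariates absorb the two
dominant confounders of metastatic genomics — subtype composition and
overall mutability — so the Wald test on the feature coefficient asks
whether the alteration is enriched *beyond* what subtype and load
predict. Features with fewer than `min_count` events (default 10) in the
tested context are skipped. Depletions (e.g. an amplification commoner in
local disease) surface as odds ratios below 1 in the same two-sided scan
rather than as a separate analysis.

The stand-alone fit is IRLS to a 1e-8 tolerance (max 100 iterations) with
rank-deficiency detection that names the collinear columns. Separation —
diagnosed by divergence of any coefficient beyond ±12 on the logit scale
or by non-convergence — triggers a Firth-penalized refit, which is always
finite; the result is flagged. The scan itself runs a Newton solver
batched across features: all per-feature designs share the covariate
block, so one iteration for the whole panel reduces to a handful of
matrix products. The scan engine and the single fit agree to ~1e-6; the
permutation loop runs the same engine in single precision (z-scores agree
with double precision to ~1e-5, far below the Monte-Carlo resolution of
any permutation p).

### Family-wise error control

Corrected p-values come from min-p (maxT) permutation: the outcome labels
are permuted B times (default 1,000) against whole sample rows — each
sample keeps its own covariates and features, so the feature–covariate
dependence structure is preserved under the null — the full scan is
re-run per permutation, and the minimum raw p across the feature family
is recorded. Then

    p_corr(j) = (1 + #{b : min-p_b ≤ p_raw(j)}) / (B + 1).

The +1 estimator cannot return zero and is unbiased under
exchangeability; `p_corr ≥ p_raw` holds by a final clamp (the estimator
itself guarantees it up to the discreteness of B). All alteration classes
of all genes form one joint family by default. Site-specific scans
compare each metastatic site against all local samples with the same
model, optionally with their own per-site permutation correction.

Supporting tests are delegated to standard implementations where they
exist: Fisher 2×2 (scipy), Mann–Whitney with tie-corrected normal
approximation (scipy), two-sample Kolmogorov–Smirnov (scipy). The r×c
Fisher test enumerates all tables with the observed margins when the
enumeration bound permits (≲2·10⁵ tables) and otherwise samples
fixed-margin tables by Patefield's algorithm, with the same +1 Monte
Carlo estimator.

## Ensemble classifiers

All classifiers are ensembles of CART trees, each fit on a
class-stratified bootstrap: the same number of samples (the minority
class size) is drawn with replacement from each class, so every tree
sees a rebalanced 50/50 problem regardless of label skew. The fraction
of tree votes for a class is that class's probability; a tree whose leaf
is exactly tied contributes half a vote, which makes probabilities
exactly complementary when the two class labels are swapped. Vote ties
at exactly 0.5 classify to the alphabetically first class.

Out-of-bag (OOB) probabilities — votes only from trees whose bootstrap
excluded the sample — provide honest training-set predictions. They are
what labelled samples receive from the ER imputation (never
resubstitution votes), what model selection scores, and the baseline for
permutation variable importance: the mean decrease in OOB accuracy over
≥5 independent shuffles of each feature column.

`mtry` (features per split) is selected by stratified 10-fold
cross-validation over {√p, p/4, p/2, p} and the final ensemble is refit
at the winner. Trees grow to purity with minimum leaf size 1. The
production default is 5,000 trees; the test suite and the bundled
analyses use 100–500 trees and, for the tissue-of-origin runs, a fixed
mtry of √p without the CV sweep — forest accuracy is flat in both
choices well before these sizes, and the smaller settings keep the full
validation suite runnable on one CPU.

The ER covariate fed to enrichment models is the imputed probability for
*all* samples (OOB probability for labelled ones), not the hard label
where known; a hard-label option exists.

## ESR1 analyses

Protein changes parse from short-form notation (`D538G`, `V422del`).
Named hotspots keep their labels at any recurrence; all other changes
pool by in-cohort recurrence — seen 2–3 times, or once — with recurrence
counted over the full analyzed cohort before any grouping, so pooling is
invariant to sample order. Changes recurring ≥4 times that are not in
the named list report as `other`, as do unparseable strings (with a
warning, never dropped). The ligand-binding domain is residues 311–547
by default (configurable; the boundary must be fixed somewhere for the
LBD/non-LBD contrast to be testable).

The hotspot-by-site (or -histology) table reports each cell as the share
of that stratum's ESR1 mutations, plus a per-stratum carrier fraction,
with an r×c Fisher p. The visceral contrast is a 2×2 Fisher of D538G vs
other named hotspots between visceral sites (liver, pleura, pleural
fluid, brain, lung) and bone. Long-tail sets (seen-once, seen-twice,
seen-once-LBD, seen-once-non-LBD) become per-sample carrier indicators
run through the covariate-adjusted enrichment model; the LBD vs non-LBD
seen-once contrast is a Wald test on the difference of the two carrier
coefficients in a joint model — algebraically the set×carrier
interaction — and the output notes this construction explicitly.

## Tissue-of-origin misdiagnosis

To ask whether metastases carrying a site-enriched alteration are
misdiagnosed primaries, a breast-vs-other ensemble is trained with every
feature column of the enriched genes removed and mutation load excluded,
so the classifier cannot key on the stratifying alteration itself; it
must rely on the correlated remainder of the genotype. Masking is
physical (columns dropped before training), so masked-in-place and
masked-by-deletion training are identical by construction. Scores for
the carrier stratum are compared with the background stratum by
two-sample KS plus the fraction above the 0.5 majority-vote threshold.
For covariate-controlled comparison, vote fractions are shrunk to the
open interval by `(p·(n−1)+0.5)/n` and modelled by beta regression
(logit mean link) on the stratum indicator plus covariates, with a Wald
test on the stratum coefficient.

## Pathology-report parsing

Anchors are the standalone token `ER` or any word starting `estrogen`
(case-insensitive). Within ±3 lines and ≤130 characters of an anchor,
the nearest status keyword decides: positive = {positive, detect,
expression}, negative = {negative, rare}, both matched as word prefixes.
Negation tokens ({not, no, non-, negative for, without}) between the
anchor and the keyword, or within 25 characters before the earlier of
the two, flip the status; the keyword's own text is never part of the
negation search, so "negative for ER" is not self-negating. Boilerplate
regions (interpretation guides, bibliography lines) are blanked before
matching so offsets stay comparable. When several anchor–keyword pairs
qualify, the smallest distance wins; exact distance ties resolve to the
negative reading (a conservative clinical default — and the one place
where the keyword-swap symmetry of the parser can break, so symmetry is
asserted on tie-free text). Double negation is not handled; the distance
and window defaults are explicit config, since the appropriate values
depend on report formatting conventions.

## CHIP diagnostics

Age bins are 20–39 (reference), 40–49, 50–59, 60–69, 70+. Per-bin
mutation prevalence is normalized to the reference bin (whose normalized
value is exactly 1) with binomial SEs. The VAF trend is an ordinary
least-squares slope of VAF on age with its normal-approximation p —
chosen over quantile regression because the expected signature (a
blood-clone fraction diluting against an unrelated tumor) shifts the
mean, and a simple slope keeps the control-gene comparison symmetric.
The CHIP signature is the conjunction: negative VAF slope *and*
age-increasing rate for DNMT3A, with PIK3CA/TP53 as age-flat controls.

## Synthetic cohort generator

The generator defines the study conditions every test runs under.
Sampling is hierarchical per sample: group → biopsy site → ER/HER2,
histology, age → per-feature Bernoulli alteration vector → ESR1 hotspot
assignment → contaminant substitution → CHIP injection. Identical
(config, seed) gives byte-identical tables; each sample has one ground
truth row.

Planted defaults equal the published prevalences: group sizes
4,512/1,357/5,034 (+713 ambiguous); ESR1 18.3% (met) / 2.2% (local),
with ER+ met rates fixed at 44% (liver), 25% (pleura/pleural fluid),
24% (lung), 20% (bone, brain); CTCF 2.0%/0.9%; CDKN1B amplification
1.3%/3.6% (plus deletion 0.2%/0.1% and mutation 1.9%/1.1%); FGF3/4/19
amplification 27%/17% (ER+) and 13%/4% (ER−); NOTCH1 8.8% in skin vs
4.5%; ASXL1 amplification and PTEN deletion enriched in brain; DNMT3A
elevated in bone; HER2 amplification 9.4%/8.7%; mean short-variant
counts 6.7/5.6; hypermutated fraction 1%; hotspot mixture D538G 33.2%,
Y537S 21.4%, E380Q 8.5%, Y537N 8.0%, Y537C 4.3%, L536H 1.9%, V422del
1.4%; 8.9% of ESR1 carriers have a second mutation.

Where the aggregate is published but the cell values are not, the
config is calibrated once, deterministically, at build time: per-site
ER+ probabilities follow a fixed clinical pattern (liver/bone high,
brain/lung low) logit-shifted so the site-weighted ER+/HER2− fraction
among metastases is exactly 64%; the ESR1 rate of the unprinted ER+ met
sites is solved linearly so the overall metastatic prevalence is
exactly 18.3% including contaminant dilution; filler-gene rates are set
so expected distinct-gene mutation counts match the group means.
Remaining unprinted values are single fixed choices: metastatic site
frequencies (liver 28%, bone 18%, lung 12%, soft tissue 8%, brain 8%,
skin 7%, GI 6%, pleura 5%, pleural fluid 4%, ovary 4%), lymph-node
rates intermediate between local and metastatic, ages N(55, 12²)
clipped to 22–92 (median 55, ~11% under 40), histology 78% IDC / 12%
ILC / 10% other, ER known from reports for 12% of samples, and the
pooled 21.3% of the hotspot mixture split 7.3% seen-2–3, 10.0%
seen-once-LBD, 4.0% seen-once-non-LBD, with the local-disease mixture
shifted toward non-LBD passengers so the long-tail LBD enrichment is a
metastasis-specific signal.

Enrichment odds multipliers apply on the logit scale, so planted
probabilities can never leave (0, 1). Features are independent
Bernoulli given covariates except two deliberate dependencies: the
lung-contaminant block and a per-sample gamma load factor (shape 8) on
filler genes, which gives mutation counts negative-binomial-like
overdispersion. Hypermutated samples draw filler genes at a flat 13%
rate (≈32 expected mutated genes). Site and histology tilts to the
hotspot mixture move probability mass between categories in balanced
pairs (visceral +0.08 D538G / −0.08 Y537S; bone −0.112 D538G / +0.076
Y537S; ILC +0.10 E380Q / −0.10 D538G), then renormalize.

Contaminants replace a fraction (default 8%) of lung-site metastases
with draws from a lung-primary profile: elevated KRAS/KEAP1/STK11/EGFR,
LRP1B, CDKN2A/B deletions, higher background load, ESR1 suppressed to
0.5%, and the KRAS/KEAP1/STK11 triplet tied to a latent 50/50
co-occurrence factor (marginals 30/20/17%, pairwise correlation ≈0.17).
Separate per-gene rate profiles exist for skin, brain and bone
primaries to train the other tissue-of-origin classifiers. CHIP
injection adds a DNMT3A short variant with probability
`0.12·σ((age−70)/8)` (≈1% at 50, ≈9% at 80) whose VAF is Beta with mean
`0.22 − 0.0022·(age−40)` (concentration 25); tumor variants draw from
an age-flat Beta with mean 0.30. Pathology-report snippets place a
positive or negated/plain negative ER sentence between boilerplate
distractor lines.

### What the generator does not emulate

Co-mutation structure beyond the contaminant block (real cohorts have
pervasive co-occurrence and mutual exclusivity), subclonal structure and
purity effects on VAF, panel version heterogeneity, germline leakage,
site-dependent histology, and any coupling between treatment history and
genotype. Passing recovery tests therefore shows the *statistical
machinery* is correct under the planted model — effect sizes at the
published magnitudes are detected, nulls stay null, FWER is controlled —
not that real-data accuracies (e.g. the published classifier or parser
accuracies) would be reproduced; those depend on structure this
generator deliberately omits, and the package makes no such claim.

## Validation scale choices

The test suite runs the family-wise-error study at 200 null cohorts ×
(n = 2,000, 100 features, 200 permutations), the misdiagnosis study at
20 seeds × (500+500 training, 4,000 scored metastases, 120 trees), the
CHIP study at 20 seeds × 4,000 samples, and generator recovery at the
full published group sizes × 5 seeds; `scripts/acceptance.py` uses 10
seeds. These sizes put every Monte-Carlo check several SEs away from
its decision boundary while keeping the whole suite inside a
single-CPU desk run.

## Known limitations

* Only binary classification targets (ER status, breast-vs-tissue);
  multi-class subtype imputation would need a one-vs-rest wrapper.
* The r×c Monte-Carlo Fisher p has resolution 1/(n_mc+1).
* Beta-regression convergence is reported, not guaranteed, for extreme
  score distributions.
* The permutation family spans all alteration classes jointly; a
  per-class family is available by subsetting columns before the scan.
* Firth fallback SEs are Wald-type; profile-likelihood intervals are not
  implemented.
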