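# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a model-documentation page: what each stage
assumes, which knobs matter, what the synthetic data does and does not
emulate, and where the design was genuinely open.

## Inheritance inference

Inheritance is called per candidate from the proband's and parents'
genotypes.  In trios: a heterozygote with both parents homozygous
reference is *de novo*; dosage 2 is *homozygous*; a het transmitted by
exactly one carrier parent *segregates dominantly* if that parent is
affected and is otherwise an *inherited het of unknown phase*.  Male
calls on non-PAR chrX are *hemizygous* (PAR intervals are configurable
and empty for the synthetic build, which carries no PAR).  Duos and
singletons support only homozygous/hemizygous calls from the genotype
alone; other configurations are *unknown*.  Segregation with affected
relatives requires every genotyped affected member to carry the variant
(configurable).

Compound heterozygotes are paired within a gene among rare hets.  In
trios a pair must be in trans (one allele from each parent, neither
parent carrying both).  Without parental data any two rare hets form a
*provisional* pair with origin `unknown`; the uncertainty is carried
forward — in review a provisional pair remains compatible with both the
recessive and the unconfirmed-de-novo dominant reading, whereas a
trio-confirmed pair requires a recessive gene.

## The filter cascade (CFA)

Ordered clauses, each attaching a reason code; a candidate passes iff no
clause fires.  Defaults: impact ∈ {HIGH, MODERATE} or ClinVar P/LP;
exon flank 20 bp; max AF 1.5 % (maximum of reference and internal cohort
frequency); het carriers ≤ 30; hom/hemi carriers ≤ 2; no benign
assertion; trio candidates need a resolvable inheritance pattern;
quality floors DP ≥ 10, GQ ≥ 20 (the source protocol says only
"low-quality"; these are conventional clinical floors).  Non-trio
candidates additionally need AF ≤ 0.1 %, strong evidence (CADD ≥ 25,
pLI ≥ 0.9, S_het ≥ 0.05 or SpliceAI ≥ 0.5 — exposed in
`CfaThresholds`), and either patient–gene phenotype overlap (≥ 1 exact
or one-level HPO match — the cheapest faithful reading, configurable)
or a pathogenic assertion.

Carrier counts are internal-cohort recurrence counts over probands.  We
deliberately do **not** fold the full reference allele count into the
het cap: at reference-population scale (AN ≈ 10^5–10^6) a het cap of 30
would amount to an AF ceiling of ~10^-4 and shadow the 1.5 % frequency
clause; the reference hom/hemi columns are instead enforced by the
review-stage recessive/dominant rules, where they belong.  A config
switch restores reference hom/hemi inside the cascade's hom cap.

## Phenotype matching and information content

IC(t) = −ln(n_t / N) over gene disease-term annotations propagated to
ancestors; unannotated terms get +∞ (never a MICA).  Natural log is
used; the cutoffs 2 and 4 are configurable since the log base of the
original cutoffs is not fixed by convention.  One-level matches pair a
patient term with a direct parent or child of a gene term — siblings are
excluded — and each patient term contributes at most one.  IC-cutoff
counts apply to exact matches only (a config flag widens them to
one-level matches).  Similarity is symmetric best-match-average Resnik:
per term, the maximum IC of a most-informative common ancestor with the
other set, averaged over both directions; an empty gene set scores 0.
Note that BMA similarity does not satisfy global self-dominance
(`sim(S,S) ≥ sim(S,T)`) when S mixes shallow and deep terms; the
per-term MICA bound is the property that holds and is what the tests
assert.

External phenotype scorers (HPO3, AMELIE, SHEPHERD) are accepted as
pass-through input columns; when absent, the built-in similarity fills
their feature slots so the feature geometry is unchanged.

Profiles combine manual and NLP term sets by union after obsolete-term
removal; ancestor-redundant terms are kept because the downstream
features are counts and no redundancy rule is imposed.

## The 43-slot feature schema

Five categorical families are one-hot encoded — inheritance pattern (6
levels; `unknown` is the all-zero baseline), gene inheritance modes (4
multi-label bits), impact tier (4), ClinVar class (7), automated ACMG
class (5; absent = all-zero) — plus 17 numeric slots: allele fraction,
depth, reference AF, cohort AF, three external-phenotype slots, the
exact+one-level match count, the IC ≥ 2 exact-match count, CADD PHRED,
REVEL, AlphaMissense, SpliceAI, MisFit D, S_coef, S_het, pLI.  The
IC ≥ 4 count is computed and available but not in the default schema;
26 + 17 = 43 and the split is a package choice — the schema object is
data-driven and replaceable.  Missing numerics stay NaN at encoding
(with a mask) and are imputed with per-column training medians inside
the standardizer; mask bits are not features, which would change the
slot count.

## The scorer (VS-NN)

A scikit-learn MLP (two hidden layers 64/16, rectifier, Adam, logistic
output, early stopping on an internal validation split) behind the
module's model/results surface.  The architecture is a package default —
the original network is unspecified — and every element is configurable.
The target is binary (reported P/LP/VUS vs unreported survivors);
per-class metrics restrict the positive set at evaluation time.  The
~14:1 negative imbalance is countered by deterministic replication of
positive rows to an effective weight (capped at 20), since the sklearn
MLP exposes no class weights.  Training protocol: 30 % validation
holdout, grouped by proband (no proband straddles the split, achieved
fraction within ±2 %) and stratified by whether a proband contributes
positives; metrics at the inclusive 0.5 threshold (TP = reported and
score ≥ 0.5, FN = reported below, FP = unreported at or above); AUC by
rank statistic; then a full-data retrain produces the production model.
A fixed seed makes the split, the training trajectory and the scores
bit-reproducible on a given platform.

## Review rules

First pass, ordered, first failure wins: (1) in-silico benign consensus
— a strict majority of available scores below benign cutoffs
(CADD < 10, REVEL < 0.2, AlphaMissense < 0.34, SpliceAI < 0.1; the
consensus rule is a package default and configurable); (2) frequency —
locus-level evidence aggregates AC/AF over co-located alleles of the
same impact tier ("similar impact" = identical tier, configurable to
consequence level); recessive: summed AF ≤ 0.001 and hom+hemi ≤ 2, any
hom/hemi presence tolerated only with a strong phenotype match;
dominant: no hom/hemi at all, AC ≤ 2 unless incomplete penetrance or a
compelling match; dominant NDD genes instead use control-population
AC ≤ 2 and non-neuro AC ≤ 1; (3) inheritance-mode consistency against
the gene's modes (an inherited het from an unaffected parent needs the
gene's incomplete-penetrance flag to support a dominant disease);
(4) susceptibility-only genes are excluded; (5) similarity floor 1.0;
(6) an allele-balance/depth proxy (het 0.25–0.75, hom ≥ 0.85, DP ≥ 10)
standing in for manual read inspection.  "Strong/compelling match" is
quantified as similarity ≥ 3.0 (≈ the level of an exact match on a
gene-specific term in the synthetic corpus).

Second pass assigns a codified ACMG subset — PVS1 (HIGH impact,
pLI ≥ 0.9), PS2 (confirmed de novo), PM2 (summed AF ≤ 10⁻⁵), PM3
(in-trans with a P/LP partner in a recessive gene), PP3/BP4 (in-silico
consensus), BA1 (AF ≥ 5 %), BS1 (AF > 1 %), BS2 (hom/hemi beyond
disease expectation) — and combines them with the Bayesian points
framework (prior 0.10, odds of pathogenicity 350, exponents 1/8, 1/4,
1/2, 1; all configurable).  Bins: P > 0.99, LP (0.90, 0.99],
VUS [0.10, 0.90], LB [0.001, 0.10), B < 0.001 — the boundary points are
assigned so that an empty criteria set (posterior = prior = 0.10) is a
VUS.  BA1 is stand-alone benign.  Returnable = P/LP, or VUS with
posterior > 0.5 ("leaning P/LP").  The second pass also deduplicates
against an already-documented variant list and applies a stricter
similarity floor (1.5).

## Branch pruning experiment

Levels count the root as 1 and use minimum depth; a term joins the
branch of every level-3 ancestor it reaches (diamonds may join several),
so removing a branch guarantees the cluster is fully absent — pruning
removes the members from the manual, NLP and combined sets.  Terms above
level 3 form a residual branch that is never pruned.  For each reported
validation variant (TP/FN at 0.5), each branch of its proband's manual
terms is removed in turn, phenotype features are rebuilt, the candidate
re-encoded and re-scored by the final model; deltas are recorded with a
flag for whether the branch overlaps the variant gene's disease terms.
Pooled comparisons (TP vs FN deltas; TP causal-branch vs disjoint-branch
deltas; manual-only vs combined profiles in TP vs FN) use the two-sided
Wilcoxon rank-sum test — exact enumeration when n_a+n_b ≤ 12, otherwise
the tie-corrected, continuity-corrected normal approximation (measured
max |exact − approx| at the switchover ≈ 0.015) — with Benjamini–
Hochberg adjustment across the comparison family of one experiment run.

## Synthetic cohort: what it emulates and what it does not

Defaults are the study conditions: 300 families (65 % trio, 12 % duo,
23 % singleton), 60 genes (50 % AD, 35 % AR, 15 % X-linked recessive) on
two autosomes plus an X-like chromosome with a simple coordinate map, a
1,400-site background panel with Mendelian transmission and a frequency
spectrum spanning the filter thresholds, causal fraction 0.30 with 30 %
of causal variants drawn VUS-like (mid-range in-silico scores), NLP
profiles with 20 % dropout and 2 spurious terms, and ~14 negatives per
positive in the assembled training set — the heavy-imbalance regime of
clinical reanalysis at desk scale.  Planted variants are constructed to
satisfy every cascade and review clause: de novo hets in dominant genes,
homozygous or correctly phased compound hets in recessive genes,
maternally inherited hemizygous variants in male probands for X-linked
genes; non-trio probands receive causal variants meeting the stricter
non-trio evidence clause.  Private variants carry internal cohort
frequency 0, modeling a frequency database snapshot that excludes the
index family.  Engineered sites exercise each rejection rule: high
cohort-carrier sites whose recorded AF lags the live cohort (annotation
lag), reference-homozygote sites, and per-rule review decoys
(frequency, MOI, susceptibility, quality, benign-consensus).  A small
fraction of planted variants is listed as already documented.

The generator does **not** emulate linkage disequilibrium, population
structure, sequencing reads, realistic gene lengths, mosaicism or
structural variation, and its phenotype noise is independent per term.
Passing tests therefore demonstrate that the machinery implements its
rules correctly and recovers planted signal under the stated noise — not
that the scorer's headline metrics transfer to institutional data, where
class overlap is far greater.  Scale choices (300 families, 1,400 sites,
60 genes) keep a full run in minutes on one CPU while leaving every
stage non-trivially populated.

## Numerical conventions

Population-moment standardization (sd with n, not n−1); constant columns
record sd 1.  Ties at the 0.5 threshold are flagged (inclusive ≥).
Deterministic ordering everywhere (sorted variants, sorted probands)
makes reports byte-identical across reruns with the same seed; the run
seed is recorded in the report header.  IC of unannotated terms is +∞ as
a sentinel and never participates in MICA scores.  Empty candidate lists
yield valid, empty reports and an all-zero funnel.

## Known limitations

Only SNVs/small indels; no CRAM/BAM access, liftover, or external
database connectivity.  The ACMG engine codifies 9 of the 28 criteria —
those derivable from the loaded tables — and is not a clinical
classifier.  The review similarity floors and the benign-consensus rule
are package choices where expert judgment is irreducibly manual; both
are configurable and documented above.
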