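# Methods

This note documents the models, procedures and design choices behind
`tracewell`, at the level a maintainer or reviewer needs to judge what
the package computes and what its passing tests do and do not show.

## Scales and their normalization

SWLS totals range over 5–35 and WHO-5 totals over 5–30 (five items
each).  Both are normalized onto [0,1] by subtracting 5 and dividing by
the scale span (30 and 25 respectively); the `ScaleSpec` invariant checks
that the endpoints map exactly to 0 and 1.  The WHO-5 raw range used here
(5–30) differs from the canonical 0–25 coding of the instrument; it is
retained for internal consistency with the normalization above, which
forces that range.  Reported statistics are rounded half-even to four
decimals.

Internal consistency uses the standard Cronbach's α,
`k/(k−1)·(1 − Σ var(item)/var(total))`, with unbiased variances.  Class
assignment discretizes the normalized score at a binary cutoff (default
0.51) or a trinary pair (defaults 0.35 / 0.59); the boundary convention
— a score equal to a cutoff belongs to the *upper* class — is a package
decision, documented because the underlying analysis never states one.

## Screening-cutoff validation

A low normalized WHO-5 score is the positive screen.  Ground truth per
condition comes from binarized questionnaires: PHQ-9 ≥ 10 (depression),
GAD ≥ 10 (anxiety), PSS ≥ 21 (stress); users missing a questionnaire are
excluded per condition.  Candidate cutoffs (by default the midpoints of
the sorted unique scores) are evaluated by exact confusion counts.
Because the original selection rule behind the published cutoffs is not
specified, the package implements an explicit, documented policy:

* binary — maximize the across-condition mean of Youden's
  J = sensitivity + specificity − 1 (ties to the smaller cutoff);
* trinary — lower cutoff = largest with mean specificity ≥ 0.8, upper =
  smallest with mean sensitivity ≥ 0.9 (floors configurable).

When a floor is unreachable, or the pair is not strictly ascending (as
happens with perfectly separable labels, where both floors bind in the
same region), the selection reports an explicit failure flag rather than
raising.

## Text features

Message tokens are assumed to be lemmas; tokenization/lemmatization is a
pluggable upstream contract and the synthetic default is the identity.

* **Sentiment** — six features: the proportion of positive and negative
  lexicon words among all tokens in the trailing 30-day window, the
  trailing 365-day window, and the entire history (windows measured
  backward from the user's reference time).  Empty windows yield 0.
* **TfIDF** — `count(w, d) · ln(N/df(w))`, no length normalization; the
  simplest textbook variant, isolated in one class (`TfidfModel`) so it
  can be swapped.  The vocabulary keeps lemmas with corpus frequency
  ≥ `min_count` (default 200); the closed-vocabulary category features
  deliberately use an unrestricted vocabulary (`min_count=1`) because
  they count every word regardless of frequency.
* **Word selection** — "ANOVA" against a continuous target is read as
  the F-test of the univariate linear regression of the target on the
  word's TfIDF score (equivalent to the Pearson-correlation test); a
  grouped one-way ANOVA would require target bins that are nowhere
  defined.  Words with p ≤ 0.01 for either scale are kept; the union is
  the modeling vocabulary.  Selection must run on a cohort disjoint from
  the modeling cohort; the package enforces this only by convention (the
  caller supplies the heldout matrix).  Word features for the final
  cohort are re-encoded with document frequencies refit on that cohort.

## Supervision-regularized consensus clustering

Frequent lemmas with embedding coverage are clustered by spherical
k-means (cosine distance on unit-normalized vectors, default k = 300,
embedding dimension 300).  The supervision penalty of a partition is the
sum over clusters of the two-sided p-value of the Pearson correlation
between the cluster's per-user TfIDF-sum feature and the target scale;
zero-variance features contribute p = 1.  How the penalty enters the
optimization is under-determined by its description, so the package
makes a defined choice: Lloyd iterations proceed unmodified, the
objective `J = cosine inertia + weight · penalty` is evaluated after
every iteration, and the argmin-J iterate is returned.  The penalty
therefore steers the choice among iterates, not the assignment rule,
which keeps convergence behavior well defined.  With weight 0 this is
exactly spherical k-means.

Ten restarts per weight (weights {0, 50, 100, 500}) are fused by the
standard consensus recipe: co-association fractions per lemma pair, a
link when the fraction reaches the threshold, consensus clusters as
connected components (singletons allowed).  Five thresholds
({0.25, 0.45, 0.65, 0.75, 0.85}) give 20 consensus solutions; each is
paired with a twin in which infrequent lemmas join the cluster whose
centroid (mean member vector) is most cosine-similar, for 40 candidates.

Candidates are ranked on a disjoint heldout cohort: clusters correlating
with the target at p < 0.05 become features (the reported cluster count
is this post-filter count), and each candidate is scored by the mean
test MAE of a 10-fold random-forest regression.  The description of that
evaluation mentions recursive feature elimination but no development
set, so the inner RFE eliminates by impurity importance within each
training fold (10% per step, down to half the features).  A candidate
with no surviving clusters receives the worst possible MAE.

## Behavior and app-category features

The 40 metadata/activity features use 30-day months counted backward
from the reference time (not calendar months), and the canonical column
names (`growth-2to-1weighted`, `AppUsage9-12Ratio`, `Alters-1` …).
Decisions the source leaves open:

* "weighted difference" is the symmetric relative difference
  `(v1 − v2)/(v1 + v2)`, bounded in [−1, 1], 0 when both are 0; used for
  both message volume and alter counts;
* message size in characters is the total lemma length (lemma streams
  carry no raw text);
* gender is encoded male → 0, female → 1 (documented, swappable);
* sessions crossing 3-hour-slot or midnight boundaries are split
  proportionally, so slot totals conserve total usage exactly;
* timestamps are interpreted in a single configured clock; real-data
  adapters must localize first.

App packages map to nine categories (unmapped → Other); the automatic
derivation of categories from app-store descriptions is out of scope and
the map ships as an editable TSV.  The 225 features are 9 raw category
totals (seconds over the whole window), 72 category × slot per-day
averages (denominator = the full window length in days, default 7, not
active days — a stable scale across users), and the 72 + 72
normalizations by category total and by slot total, with 0/0 → 0.
Category names are canonicalized without spaces
(`EDUCATION+PRODUCTIVITY_15-18/15-18`), since the source prints both
spaced and unspaced variants of the same grammar.

## Evaluation harness

Folds: shuffle (seeded), stable-sort by target, assign sorted index j to
bin j mod 10 until each bin holds ⌊n/10⌋ users; the n mod 10 leftovers
are in the train set of every fold.  The published assignment formula
cannot yield ten equal bins as printed, so this interleaving — which
satisfies both the bin sizes and the requirement that every bin span the
target range — is a reconstruction.  Fold i tests on bin i and develops
on bin (i+1) mod 10 (wraparound at i = 9).  Disjointness is asserted on
every run.

Features are standardized per fold with train-bin statistics only, so
coefficient magnitudes are comparable across families of very different
scales (ratios vs seconds).  Hyperparameters come from small documented
grids chosen by dev MAE (regression) or dev F1-macro (classification);
the original grids are unavailable, so the defaults are deliberately
modest and overridable.  RFE drops the least-important 10% of remaining
features per step (coefficient magnitude or impurity importance) and
returns the subset with the best dev score; by construction its dev
score is never worse than the full set's.  Metrics — MAE, Pearson r
(reported as 0 when undefined, e.g. a constant prediction) and R² for
regression; F1-macro/weighted, per-class F1 and low-class TPR/FPR for
classification — are arithmetic means over folds, with mean/median and
majority-class baselines.  Stable-feature reports keep features selected
in at least 5 of 10 folds with their mean coefficient over the folds
where selected.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
tested.  One latent well-being scalar per user is drawn from a Beta
distribution with mean 0.45 and sd 0.155 (skewed low, matching a
high-risk sample); SWLS and WHO-5 are independent Gaussian perturbations
of it with noise chosen so the two observed scales correlate at the
target 0.568 (noise sd = spread·√((1−r)/r)), then discretized to raw
totals.  Item-level scores are the raw total split by a symmetric
Dirichlet, so α is computable without real item data.

Messages: Poisson counts over a 365-day window with a sinusoidally
modulated daily rate; alters via a Dirichlet-multinomial; tokens mix a
Zipf-weighted neutral vocabulary, positive/negative sentiment words
whose per-token probability shifts linearly with standardized latent
well-being, and planted-effect words with signed effect sizes.  Usage:
Poisson session counts over a 7-day observation window with wall-clock
start times from a two-component circadian mixture whose night ([0,6) h)
share grows as WHO-5 falls.  Screening scores are linear in WHO-5 plus
Gaussian noise, rounded and clipped, anchored so each questionnaire's
conditional mean equals its screen-positive threshold at normalized
WHO-5 = 0.51; with the default noise (sd 5) the 0.51 cutoff yields
depression sensitivity near 0.78 and the Youden-J selector recovers the
planted boundary within ±0.08 on nearly all seeds.

Default volumes (≈400 messages and ≈150 app sessions per user) are the
package's own desk-scale choice, two orders of magnitude below the
original cohort's messaging volume, so full cohorts generate in seconds;
all rates are configurable.  Everything is a deterministic function of
the seed, and the plain-text writers (users CSV, messages JSONL, usage
CSV) are byte-stable.

What the generator does **not** emulate: real language (tokens are
synthetic lemma symbols), conversation structure, non-stationary user
behavior, missing-not-at-random patterns, or any correlation between
demographics and well-being.  Passing tests therefore demonstrate that
the pipeline recovers effects of the planted form at the planted
strength — not that comparable effects exist or are recoverable in real
populations, where observed effect sizes are far smaller.

## Numerical choices and degenerate inputs

* Undefined sensitivity/specificity (single-class labels) are reported
  as NaN with a flag, never silently dropped.
* Zero-variance word columns are excluded from selection with a logged
  note; zero-variance cluster features contribute p = 1.
* Empty co-association links above threshold 1 give all-singleton
  consensus; k ≥ vocabulary size gives singleton clusters with zero
  inertia (not an error).
* 0/0 ratios are 0 throughout (sentiment windows, slot ratios, category
  normalizations).
* Cluster ids are densified to 0..C−1 on construction.
* Child seeds derived from the acceptance-script seed stay below 2³¹.

## Known limitations

* The cutoff-selection policy is a documented stand-in for an unstated
  original rule; the published cutoff values are recovered approximately
  on synthetic cohorts, not derived.
* The regularized k-means explores penalty-steered *iterate selection*
  only; a penalty that alters assignments during optimization is a
  different (undefined) algorithm and is not implemented.
* `select_best_solution` scores candidates with a single random-forest
  configuration; model-family search at that stage is out of scope.
* Hyperparameter grids are intentionally small; the harness exposes them
  for expansion but larger searches multiply runtime.
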