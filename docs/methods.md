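# Methods

## Model

`pathcloud` scores old-versus-young transcriptomes over a *pathway cloud*
— a collection of pathway gene sets in which every member carries a
discrete activator/repressor role (ARR) weight in {−1, −0.5, 0, 0.5, 1}.
The per-pathway multiplicative estimator of disturbance is the product of
activator expression levels over the product of repressor levels (SPCD);
all members are weighted equally, on the assumption that signal
transduction proteins operate far from saturation so pathway output
responds roughly linearly to each component. Its logarithm gives the
additive pathway activation strength used throughout:

```
PAS_p = Σ_n  ARR_n · BTIF_n · log_b(OYR_n)
```

The three ingredients (log-additivity, the old-to-young ratio, the
tolerance flag) determine this assembly up to the combination itself,
which is fixed here as the plain sum: it is the only combination in which
the log of the SPCD product re-emerges when all roles are ±1 and all
flags are raised (an identity asserted in the tests), the PAS of an
undisturbed pathway is exactly zero, and activators and repressors enter
antisymmetrically.

**OYR.** The old sample's expression level divided by the mean level of
the normalized young cohort, both floored at `epsilon` before dividing.
Expression values are linear-scale non-negative intensities by contract;
log-scale inputs must be de-logged upstream.

**BTIF.** A gene contributes only when two criteria hold simultaneously,
both read with strict inequalities: OYR above 3/2 or below 2/3, and an
absolute deviation from the young mean exceeding two young-cohort sample
standard deviations. OYR exactly 3/2 or 2/3 is therefore *within*
tolerance. The 2-SD criterion is evaluated on the linear scale, the same
scale on which the SD is computed.

**Young reference.** Arithmetic mean and sample SD (n−1 denominator) over
young samples only, computed per gene; at least two young samples are
required so the SD exists. "Average" and "standard deviation" are taken
in their simplest reading, with no trimming or robust variants.

**Disturbance.** `D` is the L1 norm of a profile's PAS vector by default
(L2 optional); it is zero iff the profile is identically zero. Old
samples are scored individually and then averaged *at the PAS level*
("mean-of-old" profile) rather than averaging expression first: this
preserves per-patient profiles, which is what a personalized screen would
consume, and makes the cohort summary the mean of interpretable
quantities.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `epsilon` | 1e−6 | expression units | floor before ratios/logs; keeps OYR finite and positive on zero intensities |
| `log_base` | 10 | — | rescales every PAS by a constant; rankings unaffected (base-change covariance is tested) |
| `norm` | L1 | — | L2 optional; both zero iff the profile is zero |
| `zero_sd_policy` | `infinite` | — | with a constant young cohort (SD = 0), any nonzero deviation counts as infinitely many SDs so the 2-SD criterion passes; `always_fail` inverts this |
| tolerance bounds | 3/2 and 2/3 | ratio | fixed, strict |
| SD multiple | 2 | young SDs | fixed, strict |

Normalization is configurable (`none`, `median_scale`, `quantile`) and
defaults to `none`: the package assumes pre-normalized input, because no
single normalization is right for every platform and silently rescaling
would make scores irreproducible across runs with different method
defaults. `median_scale` equalizes sample medians at the (lower) median
of medians; `quantile` is the classic mean-sorted-profile substitution.

## Over-representation analysis

Pathways are tested against a candidate gene list with the hypergeometric
upper tail P(X ≥ k), observed overlap included. Pathways with overlap
below `min_overlap` (default 2) are excluded *before* testing;
Benjamini–Hochberg FDR is computed over all tested pathways; rows are
then kept at p ≤ `p_cutoff` (default 0.01 — the `≤` makes a cutoff of 1
disable the filter entirely) and sorted by descending overlap percentage,
ascending p, then pathway id, so output is deterministic. Filters only
remove rows; they never change a statistic.

Design choices made here:

* **The universe size N is a required explicit parameter.** Hypergeometric
  p-values depend on the source database's gene universe; a hidden default
  would make results irreproducible and unverifiable.
* **FDR is Benjamini–Hochberg step-up**, the standard choice when only
  "FDR-corrected" is specified.
* **Overlap percentage is `100·k/K` rounded half-away-from-zero to one
  decimal**, computed in exact integer arithmetic. Several `%` cells of
  the bundled 44-pathway reference table are inconsistent with their own
  printed counts (e.g. Ribosome: 21/136 = 15.4, printed 15.7; likewise
  Parkinson's, Adipocytokine, Serotonergic synapse, Peroxisome),
  suggesting an undisclosed effective background upstream of that table.
  `pathcloud` always recomputes the percentage from the counts; the
  reference table's printed p-value and FDR columns are retained for
  context but are not reproducible without the unpublished universe and
  tested-pathway count, and no attempt is made to match them.
* The bundled table ships only counts; `build_reference_cloud` synthesizes
  a cloud realizing those counts from generated symbols (explicitly
  synthetic — the member genes carry no biological identity).

## Drug screening

A drug is a set of multiplicative fold-changes on target-gene expression
(< 1 inhibition, > 1 activation; 0.5/2.0 when a library gives only a
direction) — the minimal transcriptome-level model for compounds known
only through their targets. Effects are applied to *old* samples only,
upstream of all scoring; applying them to PAS or to the flags directly
were considered and rejected as less mechanistic. Pairs combine by
gene-wise product of fold-changes (independent action on expression);
only pairs are enumerated, exhaustively, with a library-size cap —
higher-order combinations grow combinatorially and add nothing to the
method itself. Candidates are ranked by ascending treated `D` (ties by
drug id): minimizing treated `D` and maximizing the reduction
`baseline − treated` order identically for a fixed study, but treated `D`
remains well-defined when baselines differ. Targets absent from the
matrix are skipped, never imputed.

Note that a drug can change `D` through *any* measured pathway member it
touches: a sufficiently large fold-change on an unperturbed gene raises
new beyond-tolerance flags and adds disturbance. Only drugs whose targets
lie outside every pathway (or change nothing) are guaranteed to keep the
baseline — a property the tests assert.

## Synthetic data

The generator emulates the statistical structure the method assumes:
per-gene baselines are log-normal (ln-mean 3.0, ln-SD 1.0 — a realistic
spread of positive microarray-like intensities), measurement noise is
multiplicative log-normal, and planted perturbations shift all members of
a pathway coherently with their ARR signs (activators up, repressors down
for an "activated" pathway), so a planted activation has a well-defined
positive expected PAS. Pathways are non-overlapping gene blocks by
default, making planted signal attributable to a single pathway. Member
roles are drawn from {1, −1, 0.5, −0.5} (probabilities 0.4/0.3/0.15/0.15);
zero roles are excluded because a shift direction is undefined for a gene
that is both activator and repressor. The drug library contains the exact
antidote (reciprocal fold-changes to every planted shift), optional
partial antidotes, random-target distractors with folds in {0.5, 2}, and
a null drug; labels live in the truth record. Everything is deterministic
in the config seed.

Default study conditions — 50 genes, five 8-gene pathways, 5 young and 5
old samples, one pathway activated 4-fold, zero measurement noise, 10
distractors plus antidote and null — are the reference screening
experiment used by the validation suite: 100 seeded runs for antidote
recovery, 20 noisy runs (noise SD 0.1) for ORA recovery, and a full
hypergeometric sweep over universes up to 25 genes. With zero noise the
young cohort is constant, so the young SD is 0 and the `infinite`
zero-SD policy is what lets any planted shift raise its flag; the exact
antidote then restores the young means exactly and attains `D = 0`.

What the generator does **not** emulate: probe effects, library-size and
batch biases, count-data mean–variance relationships, correlated
co-expression within pathways, partially shifted pathways, or dosage
nonlinearity of drug action. Passing tests therefore demonstrate the
correctness and recovery behaviour of the scoring and screening
machinery, not performance on real microarray or RNA-seq cohorts.

## Numerical choices and degenerate inputs

* SPCD is evaluated as `exp(Σ log)` so large pathways cannot overflow.
* The `epsilon` floor (1e−6) guards every ratio and logarithm.
* Pathway members missing from the matrix are skipped and counted;
  pathways with no measured member score 0 and are flagged unmeasured.
* Empty clouds, empty gene lists, empty drug libraries and empty rankings
  are rejected with explicit errors rather than silently producing zeros.
* Ties in screening are broken lexicographically by drug id; ORA output
  ordering is fully deterministic; reports are byte-identical across runs
  on identical inputs.

## Known limitations

* ARR assignment is an input; the package offers no procedure for deriving
  roles from databases or literature.
* The linear, saturation-free pathway model ignores kinetics, feedback and
  cross-talk; the fold-change drug model ignores binding affinity,
  pharmacokinetics and off-transcriptome effects.
* BTIF's hard thresholds make PAS discontinuous in expression near the
  tolerance boundary; small input perturbations can flip a flag.
* The reference enrichment table's p-value/FDR columns cannot be
  regenerated (unknown universe and tested-pathway count), and no
  cross-species ortholog mapping is provided.
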