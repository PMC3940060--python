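# pathcloud

In-silico screening and ranking of candidate geroprotective drugs by
signalling-pathway-cloud regulation.

Transcriptomes of old tissues differ from young ones not gene by gene but
pathway by pathway: whole signalling and metabolic pathways are activated
or suppressed during aging. `pathcloud` scores those differences and asks
which drugs — modelled through their known molecular targets — would push
the *old* pathway-activation profile back toward the *young* state. It is
aimed at computational biologists prototyping aging-intervention screens
and at anyone who needs a transparent, fully reproducible implementation
of pathway activation strength scoring.

## The model

For each pathway *p* the multiplicative disturbance estimator is

```
SPCD_p = Π_i [AGEL]_i / Π_j [RGEL]_j
```

the product of activator gene expression levels over the product of
repressor levels (all members weighted equally: signal-transduction
proteins operate far from saturation, so a linear approximation
suffices). Taking logarithms gives the additive **pathway activation
strength**

```
PAS_p = Σ_n  ARR_n · BTIF_n · log(OYR_n)
```

where, per member gene *n*:

* **OYR** — old-to-young ratio: the gene's expression in an old sample
  divided by its mean expression in the normalized young cohort;
* **BTIF** — beyond-tolerance-interval flag: 1 only when OYR lies outside
  (2/3, 3/2) *and* the old level deviates from the young mean by more than
  two young-cohort standard deviations (both inequalities strict);
* **ARR** — the activator/repressor role weight ∈ {−1, −0.5, 0, 0.5, 1}.

The cloud-level disturbance `D` is an L1 (default) or L2 norm of the PAS
vector. A drug is a set of multiplicative fold-changes on its target
genes (<1 inhibition, >1 activation), applied to the old samples only;
drugs and drug pairs are ranked by the treated `D` — the best candidate
brings all PAS values as close to zero as possible.

The pathway cloud itself is assembled by over-representation analysis:
longevity-candidate gene lists are tested against pathway gene sets with
the hypergeometric upper tail and Benjamini–Hochberg FDR (defaults:
minimum overlap 2, p-value cutoff 0.01). A bundled reference table of 44
KEGG pathways enriched in a 226-gene longevity candidate list ships as
package data, and a synthetic-data module generates complete studies
(cohorts, clouds, drug libraries) with known ground truth.

## Worked example

Generate a synthetic study (50 genes, five 8-gene pathways, 5 young + 5
old samples, one pathway planted "activated" with a 4-fold shift, and a
12-drug library including the exact antidote), score it, and screen the
drugs:

```
$ pathcloud simulate --seed 17 --out-dir demo
wrote synthetic study (seed=17) to demo

$ pathcloud pas --expr demo/expr.tsv --meta demo/meta.tsv \
      --pathways demo/cloud.tsv -o demo/pas.tsv
scored 5 pathways x 5 old samples; mean-of-old D (L1) = 4.21442

$ pathcloud screen --expr demo/expr.tsv --meta demo/meta.tsv \
      --pathways demo/cloud.tsv --drugs demo/drugs.tsv -o demo/ranking.tsv
screened 12 candidates; best: antidote (D 4.21442 -> 0)
```

`demo/pas.tsv` shows the planted pathway (`PW01`, per `demo/truth.json`)
as the only nonzero PAS — 4.214 in every old sample, which is
`Σ|ARR| · log10(4)` over its members — while the other four pathways sit
exactly at zero. The top of `demo/ranking.tsv`:

```
rank	drug_id	baseline_D	treated_D	delta
1	antidote	4.214419939	0	4.214419939
2	distractor_04	4.214419939	3.762874946	0.4515449935
3	distractor_09	4.214419939	4.214419939	0
```

The antidote (reciprocal fold-changes to every planted shift) restores the
young expression profile exactly, so its treated disturbance is 0 and it
ranks first; a distractor that happens to hit one perturbed gene recovers
part of the signal; off-target distractors and the null drug leave `D`
unchanged.

`pathcloud ora` runs the enrichment step on a gene list
(`--genes list.txt --universe 20000`), writing a table with background
size, overlap, percentage, p-value and FDR per pathway.

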