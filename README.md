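# drugrepo

Omics-driven drug repositioning for metabolic disease, built as a tested,
reusable pipeline.  The worked case is diabetes: risk proteins are
unified from three layers of curated clinical evidence (GWAS genes,
proteomics proteins, metabolomics metabolites mapped to their enzymes
and transporters), joined to a catalog of target–drug development
projects, filtered by development stage and by mechanistic gain/loss-of-
function compatibility, and finally scored for expression-level support
with Connectivity-Map style rank enrichment against reference compounds
of known polarity (anti-diabetic, glucose-improving, or diabetogenic).

The package is aimed at computational biologists who want to run, audit
or extend this class of repositioning analysis: every filtering rule is
an explicit, pure function; every stage reads and writes plain TSV; and
a synthetic-data module generates all inputs with planted ground truth
so the whole funnel is testable offline.

## The scoring statistic

A treatment *instance* is a full rank permutation of the gene universe
(rank 1 = most up-regulated).  For a tag set with sorted ranks
V(1) < … < V(t) in a list of n genes, the signed Kolmogorov–Smirnov
enrichment is

    a = max_j [ j/t − V(j)/n ],   b = max_j [ V(j)/n − (j−1)/t ]
    KS = a  if a > b  else  −b

An instance's connectivity score against an up/down signature is
`KS_up − KS_down`, set to 0 when the two statistics share a sign.
Instance scores are max-normalised to [−1, 1], instances are ordered by
descending score, and one perturbagen's association with the signature
is the same KS statistic applied to the positions of its instances in
that ordering, with a two-sided permutation p-value (add-one corrected,
random t-subsets of positions).  A candidate drug is *supported* when at
least one association is significant and direction-consistent: positive
against an anti-diabetic/glucose-improving reference, or negative
against a diabetogenic one.

## The mechanistic filter

Inhibitors/antagonists induce a loss of target function (LOF),
agonists/activators a gain (GOF).  Curated pathogenesis annotations
state whether GOF or LOF of a target is harmful or beneficial for the
disease.  A LOF-inducing drug is *therapeutic* on any (GOF, harmful) or
(LOF, beneficial) annotation; mirrored combinations are *aggravating*
(the GOF-like case is symmetric).  Aggravating evidence vetoes
therapeutic evidence; targets with no direct disease link, or only a
complication link, are excluded outright.

## Worked example

```python
from drugrepo import run_pipeline

result = run_pipeline({"mode": "fixtures"})
print(result["funnel"].to_frame().to_string(index=False))
print(sorted(result["supported_list"]))
```

prints

```
                     stage  count
             risk_proteins    992
     targets_with_projects    108
         druggable_targets     35
known_antidiabetic_targets      5
             novel_targets     30
         therapeutic_drugs     58
       therapeutic_targets     12
           supported_drugs      9
['D-cycloserine', 'Diflorasone', 'Diflunisal', 'Idazoxan', 'Nabumetone',
 'Niflumic Acid', 'Perhexiline', 'Phenoxybenzamine', 'Valdecoxib']
```

The funnel counts the candidate sets at each stage: 992 disease-risk
proteins, 108 of them with at least one drug project, 35 surviving the
development-stage filter (5 already known anti-diabetic targets, 30
novel), 58 drugs over 12 targets passing the mechanistic filter, and 9
drugs with direction-consistent expression support.  Four of the nine
(diflunisal, nabumetone, niflumic acid, valdecoxib) inhibit COX2
(prostaglandin G/H synthase 2) and two (phenoxybenzamine, idazoxan)
antagonise the alpha-2A adrenergic receptor.

A fully synthetic run with planted ground truth:

```python
result = run_pipeline({"mode": "synthetic", "seed": 7, "n_perm": 500})
```

`result["truth"]` carries the planted answers (evidence union, catalog
survivors, expected verdicts, linked perturbagens) so every stage can be
checked for exact recovery.

The `drugrepo` console script exposes each stage
(`simulate`, `ingest`, `network`, `map-drugs`, `filter-pathogenesis`,
`connectivity`, `run`); see `drugrepo --help`.

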