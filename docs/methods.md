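# Methods

## Pipeline model

The package treats drug repositioning as a funnel of nested candidate
sets over plain tables:

1. **Evidence unification.** Three curated evidence layers — GWAS genes,
   proteomics proteins, and metabolomics metabolites — are reduced to one
   deduplicated set of risk-protein accessions.  Metabolites contribute
   indirectly: an HMDB-style mapping table links each metabolite to the
   enzymes and transporters that turn it over, and those proteins join
   the union.  Identifier matching is case-insensitive after whitespace
   trimming because curated literature tables are typographically
   inconsistent; gene symbols without a stable accession are resolved
   through an explicit symbol→accession lookup supplied as input, and
   unresolvable symbols are reported, never silently dropped.
2. **Metabolite–protein network.** The mapping rows whose metabolite
   occurs in the evidence form a strictly bipartite graph.  Duplicate
   (metabolite, protein) pairs with different roles keep a single edge
   carrying the union of roles as an attribute, since the association is
   one biological relationship observed in two capacities.  Export is
   GraphML (attribute-preserving, round-trippable) or SIF.
3. **Catalog join and stage filter.** Risk proteins are joined to a
   TTD-style project catalog by accession (exact normalised target name
   as an explicit fallback for catalogs without accessions).  Free-text
   stages are normalised by an ordered regex table shipped as a data
   file; withdrawal/suspension wording is matched before plain phase
   wording, so any phase-bearing text classifies as clinical or
   withdrawn/suspended-clinical, never preclinical.  Research and
   preclinical projects are removed: they carry no human toxicity data,
   which is the premise of repositioning.  Withdrawn or suspended
   *clinical* projects are retained — such drugs reached humans and
   remain informative repositioning candidates.
4. **Mechanistic (GOF/LOF) filter.** See below.
5. **Connectivity support.** See below.

Funnel counts are always computed from actual stage outputs, and the
monotone containments (targets with projects ≥ druggable targets ≥
therapeutic targets; therapeutic drugs ≥ supported drugs) are asserted at
report construction, so a violating run fails loudly.

## The compatibility rule engine

The decision is a pure function of the drug's induced effect direction
(inhibitor/antagonist → LOF-like, agonist/activator → GOF-like, unknown
modulators → unknown) and the target's structured annotations
(direction ∈ {gof, lof}, valence ∈ {beneficial, harmful}, scope ∈
{direct, complication-only, none}).  Decision order: no informative
annotations → excluded (no link); only complication-scope annotations →
excluded (complication); unknown effect → indeterminate; otherwise a
LOF-like drug is therapeutic on any (gof, harmful) or (lof, beneficial)
annotation and aggravating on the mirrored pairs, the GOF-like case
symmetric; aggravating evidence vetoes therapeutic evidence when both
exist.  The veto is deliberately conservative: a drug with any evidence
of worsening the disease through its own direction of action should not
be repurposed on balance-of-evidence grounds.  At the drug level the
veto extends across targets — a drug therapeutic under one target but
aggravating under another is dropped.

Annotations are consumed as structured triples with the verbatim curated
phrase carried alongside for audit; free text is never parsed, because a
deterministic, inspectable rule base matters more here than recall.

## Connectivity scoring

The signed KS tag-set statistic, the same-sign zero rule for combining
up- and down-tag statistics, the positive/negative max-normalisation,
and the set-level enrichment of a perturbagen's instance positions are
implemented exactly as stated in the README.  Numerical choices:

- **Strict permutations only.**  Ranks must be a bijection onto 1..n;
  when raw expression values are supplied, ties are broken by stable
  input order (never average ranks, which would leave the statistic
  undefined).
- **Ordering ties at set level.**  Many null instances score exactly 0
  under the same-sign rule.  Ties in the connectivity ordering are
  therefore broken by a seeded random key: a stable tie order would bias
  instance positions toward collection order and visibly miscalibrate
  the permutation p-values under the null.
- **Permutation p-values.**  Two-sided on the enrichment magnitude, with
  add-one correction: p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm), null
  draws being uniform random t-subsets of the N positions.  Default
  n_perm = 10000; a seed is mandatory.  The magnitude comparison uses a
  1e-12 guard so discrete ties count as exceedances (conservative).
- **Support rule.**  alpha defaults to 0.05; a drug is supported by a
  significant positive association with an anti-diabetic or
  glucose-improving reference, or a significant negative association
  with a diabetogenic one.  Significant associations in the wrong
  direction never support.

## Synthetic data: what it emulates and what it does not

The generators produce every input class with planted ground truth:
evidence tables with a configurable identifier overlap, a mapping table
with per-metabolite out-degree floor(m) + Bernoulli(frac(m)) (an integer
mean forces an exact degree, handy for exact assertions), a project
catalog with configurable stage/action-mode categoricals rendered in
random raw stage dialects, one pathogenesis scenario per target with the
expected verdict recorded from an independently written truth table, and
rank-permutation profiles in which a fraction `signal_strength` of the
query's up tags is placed uniformly in the top `tag_size` ranks (down
tags at the bottom), remaining genes uniformly permuted.  A single root
seed feeds fixed named substreams, so adding a generator never perturbs
another's output.

Default sizes mirror the curated study scale (115/56/227 hits, ~7.3
links per metabolite); the 1000-gene default universe is a desk-scale
stand-in for a genome-wide array.  The generators use uniform sampling
throughout and model no microarray noise, batch structure, chemical
similarity or pharmacology text.  Passing tests therefore demonstrate
correctness of the pipeline's logic and calibration of its statistics
under exchangeable nulls — not robustness to the batch effects and
annotation noise of real compendia.

## Orchestration sizes

The synthetic end-to-end mode profiles roughly ten instances per
candidate perturbagen (set-level enrichment over one or two member
instances has no useful permutation resolution) and skips connectivity
when fewer than two candidates survive the mechanistic filter, since a
single perturbagen would own every position.  Test and acceptance runs
use reduced problem sizes (hundreds of genes and projects, n_perm in the
hundreds) chosen as the smallest scales at which the planted effects and
calibration properties are comfortably resolvable.

## Known limitations

- The fixture replay carries the source tables' own internal
  inconsistencies (two variants of the study counts; a printed
  unique-drug total of 58 against 56 enumerable distinct names); the
  report surfaces these side by side rather than adjudicating.
- Database-snapshot-dependent quantities (how many risk proteins a live
  HMDB or TTD search would yield) are treated as fixture metadata only;
  they are not recomputable from first principles.
- The stage-normalisation regex table covers the dialects observed in
  the packaged catalog plus common variants; genuinely novel stage
  wording raises a classification error listing the literal, by design.
- Query orientation (candidate profiles scored against a reference
  signature, or the reverse) is the caller's choice; the package makes
  no claim that one orientation reproduces any externally published
  score against a live compendium.
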