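# Methods

## Gene models and coordinates

All interval arithmetic uses 0-based half-open coordinates; GTF input and
output (1-based inclusive) convert at the boundary.  A gene model is the
union of the exons of **all** annotated transcripts, and introns are the
maximal gaps in that union.  This is the conservative definition of "an
intron of" a gene: a region is intronic only if no transcript has exonic
sequence there.  Genes on unplaced scaffolds are kept; chromosome names are
opaque strings.  Duplicate gene records merge into one model; records with a
strand other than `+`/`-` are dropped with a warning; structurally broken
GTF lines abort the parse with the offending line number.

## Nested-pair detection

A pair (external, internal) is emitted when the internal gene's span is
contained in a single intron interval of the external gene.  Containment is
interval containment (`intron.start <= span.start` and
`span.end <= intron.end`); a gene abutting the intron's endpoints still
counts, since those endpoints abut exons by construction.  Design choices
where the biology leaves room:

* **Chains** (A hosts B, B hosts C): each internal gene is assigned to its
  *innermost* host (smallest span, gene id breaking exact ties), so only
  direct host relationships appear; (A, C) is not emitted.
* **Simple pairs**: an external gene hosting exactly one internal gene.
  Strand-bias summaries default to simple pairs, which keep the
  external/internal comparison 1:1.
* **The unnested universe** contains genes whose span overlaps no other
  gene's span.  Partially overlapping genes are excluded from both sides of
  every nested-vs-unnested comparison.

Intra-/inter-chromosomal pair universes are exact integer counts:
intra = Σ_c C(n_c, 2), inter = C(Σ n_c, 2) − intra.

## Event inference

Fixed topology: ingroup {human, mouse}; outgroups cow, opossum, platypus,
chicken, zebrafish.  Orthogroups are assembled by pivoting pairwise 1:1
ortholog maps through the single species common to all maps (normally
human); inferring the pivot rather than hard-coding it makes the operation
symmetric under species relabeling.  Per-species status of a candidate pair
is `nested`, `unnested` (both orthologs present, pair not nested), or
`absent` (an ortholog link missing).  Rules, applied in order:

1. nested in both ingroup species → `pre_divergence`;
2. nested in exactly one ingroup species, `unnested` in the other, no
   outgroup with both orthologs nested, and ≥ 1 outgroup with both
   orthologs present → lineage-specific nesting.  The outgroup requirement
   prevents calling an event when the genes are simply absent ancestrally;
3. `unnested` in one ingroup species, nested in the other ingroup species
   and in ≥ 1 outgroup → lineage-specific unnesting (the nesting is
   ancestral by parsimony and was lost);
4. otherwise `unresolved`.

A pair nested in one ingroup species and one outgroup but unnested in the
other ingroup species therefore reads as an unnesting, not a new nesting:
the outgroup observation places the nested state ancestrally.  Conflicting
signals that match no rule — e.g. nesting in one ingroup species with a
nested outgroup *and* an absent other ingroup — stay unresolved.  Repeated
nesting/unnesting cycles are not modeled.

## Expression

Only genes with TPM ≥ 1 in at least one of the seven tissues enter the
analysis, and pair-level analyses require both members to pass, so that
interference between them is possible and single- and pair-gene analyses
cover the same universe.  The relative profile is the TPM vector divided by
its 7-tissue sum (positive after filtering); τ and the Euclidean distance
are computed as in the README.  Primary-tissue ties are broken by the
canonical tissue order (brain, lung, liver, spleen, kidney, colon, testis)
and logged.  Replicate averaging and normalization are assumed done
upstream (the supported input matrices are already averaged and quantile
normalized).

The intra- and inter-chromosomal divergence universes are drawn as seeded
uniform subsamples without replacement (default 10,000 pairs) from the
unnested expressed genes; full enumeration (10⁸ pairs at genome scale) adds
nothing to a distribution comparison.  When a requested subsample reaches
the universe size the universe is enumerated with a warning.

For lineage-specific nestings, derived-vs-ancestral divergence compares
each member gene's profile in the nested lineage with its ortholog's
profile in the other (unnested) ingroup lineage — the available proxy for
the ancestral expression state.

## Statistics

* **Binomial**: exact, two-tailed by the minimum-likelihood convention
  (sum of P(X = k) over all k with P(X = k) ≤ P(X = x)).  This is the
  convention of R's `binom.test` and is required to reproduce the published
  strand-bias p-values; implemented via `scipy.stats.binomtest`, which uses
  the same rule.
* **Fisher**: exact, two-tailed by summing hypergeometric probabilities at
  fixed margins no larger than the observed table's
  (`scipy.stats.fisher_exact`).  A table with a zero margin is reported as
  p = 1 and logged.
* **Permutation**: difference in means, two-sided.  With
  C(n_a + n_b, n_a) ≤ 20,000 the null distribution is enumerated exactly
  (p has no Monte-Carlo error and can be 0 < p ≤ 1 in multiples of
  1/arrangements); beyond that, B seeded permutations give
  p = (b + 1)/(B + 1), the add-one estimator that never reports zero.
  Ties in |T| are counted as "at least as extreme" with a 10⁻¹² guard.
* **Bonferroni**: min(1, p·m); tissue-level tests correct over the seven
  tissues.
* **Hanging chi-gram**: bar heights are signed standardized residuals
  (O − E)/√E against expected proportions (e.g. the tissue distribution of
  tissue-specific unnested genes); a zero expected proportion with a
  nonzero count yields a flagged infinite bar.

## Synthetic data

The generators emit the same GTF/TSV formats the analysis consumes, with a
ground-truth table, and are deterministic under the config seed.

* **Annotation**: external genes have 3–7 exons with log-normal intron
  lengths (default median ≈ 6 kb, heavy right tail — the "large introns"
  regime that makes nesting possible); internal genes are short single-exon
  genes planted wholly inside randomly chosen host introns, at most one per
  intron, with opposite-strand probability 0.75 by default (the observed
  mammalian bias is 74–78%).  Unnested genes fill intergenic space.
  Sequential placement with generous random gaps guarantees no unplanned
  overlaps, so planted pairs are the complete truth; requesting more nested
  internals than available host introns raises an error.
* **Orthologs/events**: each planted event is one orthogroup with
  species-prefixed copies of a root id.  Every gene exists in every
  species' catalog; `ortholog_dropout` removes individual human-anchored
  ortholog links, mimicking how real 1:1 tables lose genes.  Under dropout,
  definite calls can only disappear or become unresolved — a planted class
  never converts into another, which the tests assert.
* **Expression**: a `specificity_fraction` of genes (default 0.3) gets a
  dominant tissue holding ≥ 95% of relative expression (guaranteeing
  τ > 0.9); the rest draw symmetric-Dirichlet relative profiles
  (concentration 3 by default; infinity yields the exactly uniform
  profile).  Per-gene totals are log-normal (median ≈ 20 TPM), so a
  realistic minority of genes fails the TPM ≥ 1 filter.  By default all
  profiles are independent — the no-interference null under which nested
  and inter-chromosomal divergence agree; `disjoint_pairs` forces pair
  members into different primary tissues, the interference scenario.

What passing tests on these data do **not** show: the generators have no
shared chromatin domains, no correlated neighboring-gene expression, no
annotation error, and no lineage-specific expression drift, so recovery
rates on real genomes can be lower than the exact recovery achieved here.

## Problem sizes and numerics

The test suite and the acceptance script run planted detection at ~320
pairs, strand-recovery at 400 pairs, event recovery at 19 planted events,
and permutation calibration at 400–500 null replicates of B = 1000
permutations — sizes at which every stochastic check sits comfortably
inside its binomial 99% band while the whole suite stays interactive.
Acceptance bands for stochastic recoveries are computed from the binomial
law at the planted parameter, never tuned to observed values.

## Known limitations

* Nesting is assessed against the union-of-transcripts gene model;
  transcript-level nesting (a gene intronic in some but not all isoforms)
  is deliberately out of scope.
* The event caller is a strict-parsimony classifier on presence/absence
  patterns; it uses no branch lengths and cannot detect repeated
  nesting/unnesting on one lineage.
* Expression inputs must share the exact seven-tissue panel; no replicate
  handling or re-normalization is performed.
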