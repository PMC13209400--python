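# Methods

This note documents the models, conventions and numerical choices
behind each analysis stage, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Alignment engine

All sequence comparison uses one local-alignment engine: exact
affine-gap Smith–Waterman (delegated to Bio.Align.PairwiseAligner's C
implementation), with the package owning the scoring conventions.

- **Scoring defaults.** Nucleotide: match +1 / mismatch −2, gap open −5
  / extend −2, Karlin–Altschul λ = 1.28, K = 0.46. Protein: BLOSUM62,
  gap open −11 / extend −1, λ = 0.267, K = 0.041 (the standard gapped
  values). All exposed via `ScoringScheme`.
- **Gap convention.** A gap of length L costs open + (L−1)·extend (the
  opening position carries the open penalty). The brute-force
  enumeration oracle in the tests uses the same convention.
- **Identity.** n_matches / n_columns over *all* alignment columns,
  internal gap columns included — the stricter BLAST-style
  "identities / alignment length". One convention had to be fixed;
  because every index (clustering, ANI, AAI, POCP) shares the engine,
  they share the convention.
- **Coverage.** Aligned residues of a sequence divided by its full
  length.
- **E-values.** E = K·m·n·exp(−λS), an explicit approximation of
  BLAST's statistics. Every E-value threshold downstream is
  configurable, so the filters, not the exact E, carry the semantics.
- **Ties.** Equal-scoring optima resolve to the engine's first
  traceback, which is deterministic — the property downstream stages
  actually require.
- **Degenerate case.** When no positive-scoring local alignment exists
  (e.g. disjoint alphabets), the engine reports score 0, identity 0 and
  empty spans rather than failing.
- **Prescreen.** A k-mer set index shortlists candidate targets by
  shared k-mer count (protein k = 4, genome fragment index k = 14).
  The prescreen orders and limits full alignments; it promises no
  superset guarantee relative to the final filters, and with
  min_shared = 0 it degrades to "all targets".

## Ortholog clustering

Classic greedy incremental clustering (UCLUST/CD-HIT style): proteins
sorted by decreasing length (ties by id) are swept once; each joins the
*first-founded* centroid reaching identity ≥ 0.5 and
coverage-of-the-shorter ≥ 0.8, else founds a new cluster. First-fit
(not best-fit) matches the classic scheme and keeps the pass O(candidates)
per protein; the canonical ordering makes the result independent of
input order. The 50% identity default mirrors the common default of
pan-genome pipelines; the coverage floor prevents unrelated
domain-sharing proteins from chaining. Centroids sharing fewer than 3
k-mers with the query (1 for sequences under 30 residues) are not
aligned at all — at the 50% identity floor a qualifying centroid cannot
realistically share fewer. Paralogs may co-cluster; presence in the
matrix is boolean, so multiplicity collapses for all downstream
statistics.

## Pan-genome structure

Core = present in every genome; accessory = in ≥ 2 but not all; unique
= in exactly one. Rarefaction draws random genome orderings
(default 20 permutations) and records cumulative union (pan) and
intersection (core) sizes; the per-step *median* is reported, with the
even-count median defined as the mean of the two central values. The
pan curve is fitted with y = A·x^b: ordinary least squares in log–log
space initialises a Levenberg–Marquardt refinement minimising squared
error on the original scale (a pure log fit biases b under additive
noise); b < 1 flags an open pan-genome. Noise-free power-law data is
recovered to 1e−9; a planted b = 0.38 under 1% multiplicative noise is
recovered within ±0.03.

## Relatedness indices

- **ANI** (fragment-based, ANIb-style): the query genome is cut into
  consecutive 1020-bp fragments (trailing remainder dropped — the
  fixed-width convention). Each fragment is located on the subject by
  diagonal k-mer voting (k = 14, both strands; the modal
  target-minus-query offset wins, and the better strand is chosen by
  vote count), then aligned against a ±150-bp window around the voted
  location. Fragments with identity ≥ 0.3 and coverage ≥ 0.7 are
  retained; ANI = mean retained identity × 100, symmetrised as the mean
  of both directions. No retained fragment in either direction yields
  an undefined value with n_support = 0, not an error.
- **AAI**: best hits in both directions under identity ≥ 0.3, coverage
  of the *shorter* sequence ≥ 0.7 and E ≤ 1e−3; reciprocal best-hit
  pairs retained; AAI = mean RBH identity × 100. Zero RBHs → undefined.
- **POCP**: C1 = query proteins with ≥ 1 hit passing E ≤ 1e−5,
  identity ≥ 0.4 and *query* coverage ≥ 0.5 (the original POCP
  filters); POCP = 100·(C1+C2)/(T1+T2); zero is a valid value.
- Interpretation flags: ANI ≥ 95 same species; AAI ≥ 65 and POCP ≥ 50
  same genus.

Because the search engine here is not BLAST, published values computed
with BLAST-based tools are reproduction targets with tolerance, not
exact expectations; the threshold semantics are what is preserved.

## Environment association

Each non-core cluster yields a 2×2 table (present/absent ×
HTV/non-HTV). The two-sided Fisher exact p sums hypergeometric point
probabilities ≤ the observed one (computed with log-gamma factorials; a
1e−7 relative tolerance captures numerically tied tables — the
convention of mainstream statistical software). Benjamini–Hochberg
step-up values q_(i) = min_{j≥i} min(1, m·p_(j)/j) are reported for all
tested clusters.

Significance is called on the **raw p < α** (default α = 0.05), with q
alongside: with 2 vs 14 genomes the smallest attainable two-sided p is
1/120 ≈ 0.0083, which cannot survive FDR correction across thousands of
clusters, so any reference-style call count is only reachable on raw p.
Both thresholds are configurable. Exact-test p-values are rationals;
when the computed p lands within 1e−9 (relative) of α it is treated as
equal to α and the strict inequality fails — the pattern "absent from
both HTV genomes, present in 12 of 14 others" has p = 1/20 exactly and
is *not* called at α = 0.05. Direction is the group with the higher
presence fraction; a tied fraction cannot be directed and the cluster
is demoted to non-significant (logged). By enumeration, the 2-vs-14
design admits HTV-specific calls only for presence in both HTV genomes
and ≤ 1 other, and non-HTV calls only for absence from both and
presence in ≥ 13 others.

## COG enrichment index

EI = (x − n·p)/√(n·p(1−p)) with x = focal genes carrying the category,
n = COG-annotated focal genes, p = background category proportion
computed the same way. Genes with several category letters count once
per letter; unannotated genes are excluded from n. The default
background is all annotated clusters of the pan-genome (the complement
of the focal set is the alternative; the choice is exposed because
references rarely state theirs). Significance is strictly EI > 2 —
the boundary value 2.0 (e.g. x = 60, n = 100, p = 0.5) is not called.
Monte-Carlo draws of focal sets from the background keep
P(EI > 2) ≤ 5%, the nominal one-sided normal tail.

## KEGG-module completeness

A module is an ordered list of KO alternative-groups; a step is
satisfied when any of its KOs is annotated. Categories, judged on the
number of unsatisfied steps: complete (0 missing), almost complete
(1–2), partially complete (≥ 3 but ≥ 1 module KO present), absent (no
module KO annotated at all) — evaluated in that precedence so that a
one-step module with nothing annotated is absent, not almost complete.
The ordinal score map defaults to 0/1/2/3; any strictly monotone map
preserves every ordinal conclusion, so the mapping is configurable but
validated for monotonicity. The flattened alternative-group
representation supports the missing-KO criterion exactly; the full
KEGG boolean grammar (complexes, optional KOs) is deliberately out of
scope. Genome profiles are compared by Euclidean distance on score
columns and clustered by UPGMA (merge height = half the average
between-cluster distance, ties broken by lexicographically smallest
cluster label), emitting an ultrametric dendrogram as Newick. Distance
and linkage are configurable choices; published analyses made with
interactive tools rarely state theirs.

## Synthetic data

The generator emulates the *statistical design* of a 16-genome panel —
2 HTV vs 14 non-HTV — not its biology:

- ~800 core families present everywhere; accessory families draw an
  occurrence probability from Beta(0.3, 0.3) — a U-shaped occupancy
  spectrum mimicking the empirically bimodal gene-frequency
  distribution, which yields an open pan-genome (b ≈ 0.4 at the default
  design) — then per-genome Bernoulli presence; per-genome unique
  families with Poisson(250) counts.
- 57 HTV-specific and 82 non-HTV-specific planted patterns (present in
  every genome of their group, absent from the other by default; a
  configurable leak allows softer patterns). Background accessory
  draws whose pattern would itself pass the association screen are
  redrawn, so the planted sets are exactly the recoverable truth —
  the generator's guard uses the same exact test as the analysis.
- COG letters drawn from a rough bacterial frequency profile, with
  categories E and H at 3× weight in planted HTV clusters (a
  vent-adaptation signature analogue).
- Module plans: shared housekeeping modules complete everywhere except
  one distinct single-step perturbation per non-vent genome, plus
  vent-only modules complete in the HTV pair and absent elsewhere (the
  desk-scale analogue of vent-restricted cofactor pathways), which
  makes the vent pair the unique closest pair in profile space.
- Sequence evolution: per-site substitution to a uniformly chosen
  different symbol at rate d, optional single-symbol indels. With
  indels off, expected identity of an ancestor/descendant pair is
  exactly 1 − d, the analytic oracle behind the ANI (d = 0.05 → 95%)
  and AAI (d = 0.10 → 90%) checks. Proteome simulation draws one
  ancestor per family (length 80–400) and one descendant per genome.

Every generator is a pure function of spec + seed.

What passing on this data does **not** show: robustness to annotation
error, paralog-rich families, mosaic genomes, phylogenetic correlation
between genomes (gene gain/loss on a tree), codon-level evolution, or
BLAST-exact hit lists. In particular the association test treats
genomes as exchangeable; phylogenetically corrected association is out
of scope.

## Problem sizes and determinism

The test suite and acceptance script run the full 16-genome
presence/absence design (~7 000–8 000 clusters) for matrix-level
stages, and desk-scale sequence sets for alignment-heavy stages:
100-kb genome pairs for ANI, 50 families × 16 genomes for clustering
recovery, tens of proteins for AAI/POCP oracles. These sizes make every
oracle statistically decisive while keeping a full run in tens of
seconds. The pipeline derives all stage seeds from one root seed via
`numpy.random.SeedSequence.spawn`, and a rerun with identical config and
seed is byte-identical across all outputs; the run report carries the
config hash (output location excluded), seed and package version.

## Known limitations

- The greedy first-fit clustering is order-canonical but not globally
  optimal; families straddling the identity threshold can shatter
  (observed deliberately at 70% divergence in the tests).
- Fragment location by modal diagonal voting assumes mostly collinear
  genomes; heavy rearrangement within a fragment length degrades ANI
  support counts before it degrades identity.
- E-values use fixed Karlin–Altschul constants rather than
  composition-adjusted estimates.
- The accession-backed descriptive check (chromosome length and GC of
  CP176011) requires one small download; offline runs report it as a
  failure with instructions rather than skipping it silently.
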