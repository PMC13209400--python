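# pankit

Comparative bacterial pan-genomics for small genome panels, built around
the question of how isolation environment shapes gene content — for
example, what distinguishes hydrothermal-vent (HTV) isolates of a genus
from their terrestrial relatives. The package re-implements, as a
tested and reusable pipeline, the standard comparative workflow:

- **Ortholog clustering** — greedy centroid clustering of all proteins
  from all genomes (50% identity, 80% coverage-of-shorter by default)
  into gene clusters (GCs), collapsed to a presence/absence matrix.
- **Pan-genome structure** — partition into core (in all genomes),
  accessory (≥ 2 but not all) and unique (exactly one) clusters;
  permutation rarefaction curves; Heaps-style power-law fit of the pan
  curve *y = A·x^b*, with *b* < 1 diagnosing an open pan-genome.
- **Genome relatedness** — fragment-based ANI (ANIb-style, 1020-bp
  fragments, both strands), reciprocal-best-hit AAI, and POCP
  = 100·(C1+C2)/(T1+T2), with the conventional interpretation
  thresholds (ANI ≥ 95% same species; AAI ≥ ~65% and POCP ≥ 50% same
  genus).
- **Environment association** — a two-sided Fisher exact test on each
  accessory/unique cluster's presence pattern across the two
  environment groups, Benjamini–Hochberg adjusted values reported
  alongside raw-p calls, and a direction (HTV / non-HTV) per
  significant cluster.
- **COG enrichment** — the binomial enrichment index
  EI = (x − n·p) / √(n·p·(1−p)) per functional category of an
  associated gene set against the pan-genome background; EI > 2 is
  called significant.
- **KEGG-module completeness** — per-genome scoring of modules (ordered
  KO alternative-groups) into absent / partially complete (≥ 3 steps
  missing) / almost complete (1–2 missing) / complete, an ordinal score
  matrix, and UPGMA clustering of genome profiles.
- **Synthetic data** — a generator that emulates a 16-genome panel
  (2 HTV vs 14 non-HTV) with planted core/accessory/unique structure,
  57 + 82 planted environment-specific patterns, COG/KO annotation and
  sequences evolved at controlled divergence, returning the exact
  ground truth used as the test oracle.

All pairwise sequence comparison runs through one local-alignment
engine (affine-gap Smith–Waterman with a k-mer candidate prescreen and
Karlin–Altschul E-values), so identity conventions are consistent
across clustering, ANI, AAI and POCP.

## Worked example

Run the whole pipeline on the default synthetic panel:

```bash
pankit run --outdir demo --seed 42
```

This simulates the 16-genome design, partitions the pan-genome, fits
the openness curve, tests environment association, scores enrichment
and module profiles, and prints a JSON report whose stages include:

```json
"pangenome": {
  "n_clusters": 7842, "n_core": 800, "n_accessory": 2939,
  "n_unique": 4103, "power_law_b": 0.4026, "open": true
},
"association": {
  "n_tested": 7042, "n_significant": 139,
  "n_htv_direction": 57, "n_nonhtv_direction": 82
},
"enrichment":  {"htv": {"significant": ["H"]}},
"modules":     {"first_merge": ["SG01", "SG02"]}
```

Reading the numbers: of 7842 gene clusters, 800 are core — a genuine
minority, and the fitted exponent *b* ≈ 0.40 < 1 confirms an open
pan-genome that keeps growing as genomes are added. The association
stage tests the 7042 non-core clusters and calls exactly the 139
planted environment-specific patterns (57 vent-specific, 82
non-vent-specific) — with 2-vs-14 groups the only patterns callable at
p < 0.05 are presence in both vent genomes and ≤ 1 other, or absence
from both and presence in ≥ 13 others. The vent-specific set is
enriched in coenzyme metabolism (COG category H, planted at three times
the background rate), and the module-profile dendrogram merges the two
vent genomes (SG01, SG02) first — they share complete "vent modules"
absent elsewhere.

Each stage is also available separately (`pankit simulate | stats |
cluster | pangenome | relatedness | associate | enrich | modules`);
`pankit run --config run.yaml` drives everything from a single YAML
file, and identical config + seed reproduces every output byte for
byte.

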