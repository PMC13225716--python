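# Methods

## The screen

`golgiscreen` implements a candidate-gene prioritization pipeline for
regulators of Golgi organization. The premise: within a cancer type, two
cell lines with opposite Golgi phenotypes — one with a compact, organized
ribbon, one with a dispersed, disorganized Golgi — differ in the expression
of the genes that drive the phenotype. The pipeline therefore

1. assembles a **gene universe** of Golgi-associated genes (annotation-term
   query unioned with a curated regulator list, with per-gene provenance);
2. **screens** the universe for differentially expressed genes (DEGs)
   between the organized and disorganized line of each cancer-type pair;
3. **scores** each DEG on two components — literature knockdown evidence
   and Golgi-associated interaction-network neighbors;
4. **selects and ranks** genes with combined score ≥ 3 per cancer type and
   intersects the lists across cancer types.

Default study layout: a breast pair (MDAMB231 organized vs MCF7
disorganized, fold-change threshold 10) and a lung pair (A549 organized vs
CALU1 disorganized, threshold 5).

### Fold-change screen

The per-gene statistic is the **symmetric fold change** `max(a, b) / min(a, b)`
of the two RPKM values, with the direction (which line is higher) kept as
metadata. Symmetric because a true regulator can be over-expressed in
either line of a pair — the same gene can be higher in the organized line
in one cancer type and higher in the disorganized line in the other — so a
one-directional screen would drop valid candidates. Thresholds are
inclusive (fc ≥ 10, fc ≥ 5).

When the smaller value is zero the ratio is stabilized as
`(max + pseudocount) / pseudocount` with pseudocount 0.01 RPKM. The
pseudocount is applied *only* in that case, so all nonzero ratios are
exact. Two values within relative tolerance 1e-9 are called equal
(fc = 1, no direction). Both values zero with a zero pseudocount is an
error; with the default pseudocount it is simply fc = 1.

**Adaptive cap.** If more genes meet the base threshold than the cap
(default 50) allows, the effective threshold is raised so that exactly the
cap highest-fold-change genes remain. Ties at the cap boundary are broken
by ascending gene symbol, making the screen fully deterministic. Output is
ordered by fold change descending, then symbol.

### Score component 1 — literature knockdown concordance

Each pair couples an expression contrast to a phenotype contrast. If a gene
is lower-expressed in (say) the disorganized line, then its knockdown
should — if the gene drives the phenotype — reproduce disorganization.
The rubric:

| knockdown phenotype reported | relation to predicted phenotype | score |
|---|---|---|
| matches phenotype of the low-expression line | concordant | 2 |
| data exists but differs | discordant | 1 |
| none reported | no data | 0 |

One genuinely open cell: discordant knockdown data for a gene whose
`golgi_involvement` flag is false. We score it 1 — data exists, so not 0;
it is not concordant, so not 2 — and use the involvement flag only to
distinguish the rationale tag (`involved_discordant` vs `discordant`).

Evidence is a curated CSV input, not automated literature mining.

### Score component 2 — Golgi-associated interactors

From a STRING-style edge list, only the **experimental-evidence channel**
is used, thresholded inclusively at confidence ≥ 0.4 (channel name and
cutoff configurable). Scores on the STRING 0–1000 integer convention are
auto-detected (any channel column with a value > 1) and divided by 1000.
The graph is undirected; duplicate unordered pairs are merged taking the
per-channel maximum; self-loops are dropped. Score 2 is the raw count of a
gene's distinct first-shell neighbors that belong to the universe —
uncapped, with no restriction on interactor number. Binning the count is
left as a hook; the raw count is the default because nothing in the
workflow requires a bounded component.

### Selection, ranking, intersection

Combined score = score1 + score2; selection requires combined ≥ 3
(configurable). Ranking is by combined descending, then fold change
descending, then symbol ascending — the tie-break order is our choice, made
for determinism. Genes missing from the evidence table or the network score
0 on that component (with a logged warning) so partially curated inputs
still run. The cross-cancer candidate set is the plain set intersection of
the per-type selected gene symbols.

All analysis stages are seed-free and deterministic; identical inputs and
configuration give byte-identical candidate TSV and JSON reports.

## Synthetic data generator

The generator emulates the five inputs the pipeline consumes, with planted
ground truth so every stage is testable end to end:

* **Universe inputs** — the universe genes are split ~2/3 into the
  annotation table (term `golgi organization`) and ~2/3 into the curated
  list with an overlapping middle third, exercising union and provenance;
  a few non-universe genes carry unrelated terms as distractors.
* **Expression** — 4 cell lines named as the default study layout.
  Background values are iid log-normal with log-mean 1.0 and log-sd 0.8, a
  plausible heavy-tailed RPKM spread. Each planted gene's pair of values is
  a drawn baseline and that baseline times the planted ratio; the baseline
  is snapped to a power of two so the planted ratio is recovered
  **bit-exactly** by the screen (multiplying/dividing by a power of two is
  exact in binary floating point).
* **Network** — a random background graph at configurable density with
  experimental confidences drawn Beta(2, 5) (mostly below 0.4); each
  planted gene is wired to exactly `n_golgi_neighbors` non-planted universe
  members with confidence uniform on [0.4, 1].
* **Evidence** — planted records invert the scoring rubric (concordant
  phenotype for a requested score 2, the opposite for 1, no data for 0);
  background universe genes get no-data records.

Two constructive guarantees make the ground truth derivable from the
configuration alone, before any pipeline run:

1. **Bounded background ratios.** A background gene's per-pair values are
   redrawn until their ratio falls strictly below `max_background_ratio`
   (default 4.0, below the smaller screen threshold), so no background gene
   can ever pass the screen. Configurations without a valid bound are
   rejected when ground truth is requested. Unbounded iid background
   (`max_background_ratio=None`) remains available for stress tests.
2. **Isolated planted genes.** Background edges never touch planted genes,
   so a planted gene's Golgi-interactor count equals exactly its
   configured neighbor number.

The default bundle (500 genes, universe of 120, seeds swept in tests)
plants three shared candidates (combined scores 5, 3, 3), one breast-only
candidate, and three decoys that each violate exactly one criterion:
sub-cutoff combined score, no evidence data, and sub-threshold fold change.

### What the generator does not emulate

Real expression data has correlated genes, batch effects, and
count-derived noise; real interaction networks have hubs, degree
heterogeneity and community structure; real literature evidence is
ambiguous and citation-dependent. None of these are modeled. Passing tests
therefore demonstrate that the *pipeline logic* is correct — screening,
scoring, selection and intersection do exactly what they claim on inputs
with known truth — not that the screen's published gene lists would be
recovered from live databases. The original counts (universe of 390, 42/35
DEGs, 20/14 candidates, 8 common) depend on unpublished curated lists and
specific database versions and are not reproduction targets.

## Numerical and design choices

* Gene symbols are compared after uppercase/trim normalization; term
  matching is exact (case-insensitive), with no ontology traversal.
* Fold-change threshold comparisons are inclusive (≥).
* Equality tolerance for direction calls: relative 1e-9.
* All randomness lives in the generator and is driven by a single integer
  seed through independent `numpy` `SeedSequence` streams per generator;
  analysis stages contain no randomness.
* Problem sizes in the test suite: oracle-equivalence checks run 200
  random configurations at ≤ 50 genes and ≤ 100 network nodes against
  hand-written brute-force enumerations; the recovery sweep runs the
  500-gene default bundle over seeds 1–20. These sizes exercise every
  code path (cap trimming, zero RPKM, score ties) while keeping the suite
  fast.

## Known limitations

* The evidence rubric assumes one knockdown record per gene; conflicting
  reports must be resolved upstream during curation.
* A planted gene's direction is shared across cancer-type pairs in the
  generator; opposite-direction planting (as real genes can show) would
  need per-pair planted entries.
* The screen operates within the supplied universe only; genome-wide
  screening followed by universe intersection would need the universe
  filter moved after the fold-change step.
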