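# Methods

## Model

orthonet treats network construction for an unannotated target species as
a pure transfer problem: it never infers new edges from target-species
data. Every edge in the output is an *interolog* — a source-species edge
whose two endpoints both have one-to-one orthologs in the target — and it
keeps the source's log-likelihood score (LLS) unchanged. The underlying
assumptions are (i) functional modules are conserved at the protein
sequence level, so BBH pairs are a usable proxy for functional
equivalence, and (ii) the quality of the curated annotations that scored
the source networks is comparable across species, so source LLS values
remain interpretable for the target.

LLS is the natural-log odds that two linked genes share a curated
biological process, relative to the background odds among all annotated
genes: with P/N positive/negative pair counts among the evaluated edges
(both genes annotated) and P′/N′ the same counts over all annotated-gene
pairs, LLS = ln[(P/N)/(P′/N′)]. `benchmark.lls_score` applies one shared
pseudocount (default 1.0) to all four counts; an unbiased sample of
universe pairs therefore scores ≈ 0 and the score is exactly 0 whenever
the evaluated odds equal the background odds, for any pseudocount.

## Orthology

* Bidirectional best hit only. Co-ortholog (in-paralog) expansion is
  deliberately out of scope: it buys little when many source networks are
  available, costs a bootstrap-scale computation, and breaks the
  one-to-one invariant that makes edge transfer unambiguous.
* Best-hit ties break by higher bitscore, then lower E-value, then
  lexicographically smallest subject id — fully deterministic.
* Built-in engine: Smith–Waterman with affine gaps via Biopython's
  `PairwiseAligner` (BLOSUM62, gap open 11, gap extend 1 — common
  protein-search defaults). It reports the raw alignment score and no
  E-value: BBH needs a consistent ranking, not calibrated significance,
  so no Karlin–Altschul calibration is attempted. Residues absent from
  the matrix (U, O, J) score as X; anything else is rejected by name.
* Because the substitution matrix is symmetric, the score matrix of a
  proteome pair is computed once and transposed for the reverse search
  direction, halving alignment work without changing results.
* External hits (DIAMOND/BLAST 12-column tabular) are ingested unchanged
  and filtered at E ≤ 1e-5 by default — a conventional homology cutoff,
  exposed as a parameter since no principled value exists for all
  proteome sizes.

## Transfer and integration

* Within one source network, multiple interologs landing on the same
  target pair collapse to that network's maximum LLS *before* cross-source
  integration. This keeps max-integration idempotent and prevents one
  network from double-counting under sum-integration.
* Across source networks the default is `max` (sources treated as fully
  correlated), with `sum` (naive-Bayes independence) retained for
  comparison; for every edge score(max) ≤ score(sum), with equality iff
  a single network supports it. Both are order-independent.
* All networks are undirected; the lexicographically sorted gene pair is
  the single canonical representation everywhere. Duplicate pairs in an
  input file collapse to the maximum score (consistent with
  max-integration); self-edges are dropped — a co-functional link relates
  two distinct genes.
* Genome coverage in the build report is network nodes / input genes
  (after isoform selection).

## Evaluation

* Gold standards take terms of 5–300 genes by default: smaller terms are
  statistically unstable, larger ones (top-level processes) uninformative.
  Both bounds are exposed.
* Partial AUROC integrates the ROC over FPR ∈ [0, c] and divides by c,
  so a perfect ranking scores 1 and a random one c/2 (0.005 at the
  default c = 0.01). Ties are traversed as single diagonal segments —
  equivalent to averaging over random tie orders, with no RNG in
  evaluation.
* Guilt-by-association rankings are leave-one-out for term members: a
  member's own annotation never contributes to its score, preventing
  self-annotation leakage.
* The Wilcoxon signed-rank comparison is two-sided, drops zero
  differences, and uses average ranks for tied |differences|. For n ≤ 25
  the null is computed exactly *conditional on the observed ranks* (a
  generating-function convolution over doubled ranks, so half-integer
  average ranks stay exact); beyond that, a normal approximation with
  continuity correction. The exact-with-ties distribution is computed
  in-package because standard library routines substitute the tie-free
  tables for the tied case.
* The random baseline randomizes both topology (degree-preserving
  double-edge swaps, 10 attempted swaps per edge) and the score
  assignment (permutation) — a stronger null than score shuffling alone.
* Precision–coverage curves support two coverage scopes: annotated genes
  seen / annotated universe, or all genes seen / total coding genes;
  neither is privileged.

## Synthetic study system

The generator emulates the builder's real inputs with known truth: an
ancestral proteome (i.i.d. residues from BLOSUM62 background
frequencies, geometric lengths around 150, floor 30) radiates into one
target and several source species; each gene survives with the
conservation rate and mutates by per-residue substitution. Defaults: 3
source species, 300 ancestral genes, 90% conservation, 5% substitution,
6 disjoint planted modules of 5–10 genes, within-module edge probability
0.8 with LLS ~ N(4.0, 0.5), background edge probability 0.001 per network
with LLS ~ N(0.8, 0.3) (floored at 0.01), two networks per source
species, up to 3 isoforms per target gene (non-longest isoforms are
C-terminal truncations).

Choices worth flagging:

* **300 genes** is large enough that a planted module is a small
  (≈ 2–3%) fraction of the genome — without that, strong enrichment of
  prioritized candidates is arithmetically impossible — while keeping
  full all-vs-all built-in alignment at around a minute per bundle.
* **Background density 0.001 per network** gives the integrated network
  the sub-percent edge density real co-functional networks exhibit
  (~1.5 M links over ~20 k genes is ≈ 0.7% of all pairs); a dense random
  background would be both unrealistic and would bury the planted signal
  among spurious neighbors.
* **Substitutions only (no indels)**: keeps the aligner's recovery
  behavior analyzable (a conserved pair's self-like alignment dominates);
  indel support is future work.
* All randomness flows from one master seed through named substreams;
  the same seed reproduces byte-identical bundles.

What passing tests on this system do **not** show about real data:
sequences are i.i.d. (no domain structure, no repeats, no compositional
bias), orthology is strictly one-to-one by construction (no paralog
confusion), modules are disjoint and terms map one-to-one onto modules,
and source networks are independent given the modules (real evidence
types are correlated). Recovery rates here are therefore upper bounds on
what equally parameterized real inputs would give.

## Degenerate inputs and errors

Empty gold standards, rankings without both classes, all-zero paired
differences, guide sets absent from the network, and catalogs with no
qualifying term all raise typed exceptions (`EmptyResultError`,
`DegenerateInputError`) rather than returning sentinel values; the CLI
maps them to distinct exit codes (0 success, 2 usage, 3 data format,
4 empty result).

## Known limitations

* No co-ortholog transfer; genes without a one-to-one ortholog in any
  source contribute nothing, which bounds genome coverage.
* LLS values pass through unrescored; if a source network's scoring was
  miscalibrated, the target inherits that miscalibration.
* The built-in aligner is quadratic per pair and intended for desk-scale
  proteomes; real proteomes should come through the external-hit adapter.
* The evidence-code vocabulary is free-form; two files with the same
  (species, evidence) pair are treated as one source network.
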