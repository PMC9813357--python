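# Methods

This note documents the models and procedures implemented in `woodbarcode`,
the parameters that matter, the design choices made where several defensible
options existed, and what the synthetic benchmarks do and do not demonstrate.

## Distance model

Pairwise distances use the Kimura 2-parameter (K2P) estimator. For two
aligned sequences, comparable sites are those where **both** residues are in
{A, C, G, T}; gaps, `N` and all IUPAC ambiguity codes are excluded pair by
pair (pairwise deletion). With transition proportion *P* (A↔G, C↔T) and
transversion proportion *Q* over the *n* comparable sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q),

with large-sample variance (delta method on the multinomial counts)

    V(d) = [c1^2 P + c3^2 Q - (c1 P + c3 Q)^2] / n,
    c1 = 1/(1-2P-Q),  c2 = 1/(1-2Q),  c3 = (c1+c2)/2.

Choices and rationale:

* **Ambiguity codes are missing, not partially matched.** Partial-match
  scoring schemes introduce tool-specific conventions and non-determinism in
  what counts as a difference; excluding the site is the conservative
  convention compatible with pairwise deletion. Surfaced as data, not
  configuration: the parser accepts the codes, the estimator ignores them.
* **`min_overlap` (default 20 comparable sites).** Mini-barcodes are short;
  after dropout two queries may overlap at only a handful of columns, where
  a K2P estimate is noise. Below the floor the pair is *undefined*.
* **Undefined is a typed state, never NaN arithmetic.** A matrix records its
  undefined pairs; tree building refuses such a matrix with an actionable
  message (drop a sample or adjust `min_overlap`), and the combination sweep
  marks the affected combination "not evaluable" instead of aborting.
* **No gamma rate heterogeneity** — plain K2P is the model used throughout.

## Neighbour joining

Standard Saitou–Nei agglomeration: join the pair minimising
Q(i,j) = (n-2) d(i,j) - Σ_k d(i,k) - Σ_k d(j,k); branch lengths from the
two-point formulas; distance reduction d(u,k) = (d(i,k)+d(j,k)-d(i,j))/2;
three-point termination. Numerical/determinism choices:

* **Tie-breaking**: among pairs tying on Q (exact float equality), the pair
  whose clusters have the lexicographically smallest representative ids is
  joined (a cluster's representative is its smallest leaf id). This makes
  trees bit-reproducible across runs and platforms, which the bootstrap
  determinism contract relies on.
* **Negative branch lengths are clamped to 0**, length only, with no
  transfer to the sibling edge; clamp counts are logged.
* **Two-taxon trees** are represented as a degree-2 junction splitting the
  total path evenly; all larger trees are fully resolved unrooted trees with
  2n-3 edges.

On additive (tree-metric) inputs NJ provably recovers the generating tree;
the test suite exercises this on random trees up to 12 taxa against
independently computed path-length matrices and dendropy's bipartition
encoding.

## Bootstrap support

Columns of the analysed matrix are resampled with replacement (whole-matrix
by default; per-locus stratified resampling is available for supermatrices,
since the literature is usually silent on which was used). Each replicate
rebuilds distances and the NJ tree; support of an edge of the full-data tree
is the fraction of completed replicates containing its bipartition. No
consensus tree is built: supports annotate the full-data NJ tree, matching
how barcoding studies report "bootstrap values of the clades".

* Replicate *r* draws from `numpy` stream seeded `(seed, r)`, so replicate
  sets are order-independent and reproducible.
* Replicates whose resampled matrix has an undefined pair are discarded and
  counted; denominators use completed replicates. More than 50% discards is
  an error recommending a longer alignment or different overlap floor.
* Supports serialise to Newick as integer-percent internal node labels;
  branch lengths use fixed 6-decimal format. Round-trips preserve topology,
  lengths at that precision, and supports exactly.

## Identification and scoring

All placement logic is bipartition arithmetic on unrooted trees; a leaf set
is monophyletic iff it is one side of some edge's split (singletons and the
full leaf set trivially qualify).

* **Species-level call**: some edge separates the query together with the
  *complete* reference set of exactly one species, plus possibly other query
  leaves. Queries are unknowns under test, so by default a query nested in an
  otherwise-exclusive species clade neither blocks that species' monophyly
  count nor other queries' calls (`strict`/`sister_ok` flags give the
  stricter behaviours). "Inside or sister" is the default because an
  unrooted tree cannot distinguish the two without assuming a root; the
  `sister_ok=False` mode demands that the query's attachment break the bare
  species clade.
* **Genus-level call**: the smallest separable set around the query whose
  references are all of one genus (mixed or incomplete species).
* **No support threshold gates assignment by default**; `min_support`
  optionally requires the separating edge's bootstrap support.
* **Singleton reference species count as monophyletic** — species
  represented once cannot be split, and library evaluation tables
  conventionally include them.
* **Discrimination success rate** = species-level calls / queries evaluated,
  per combination. Queries lacking every locus of a combination are excluded
  from that combination's denominator and logged with reasons. Each query id
  is one wood sample; if multiple sections of a physical sample are
  sequenced they should be merged to one record upstream.
* **Per-product identification** uses all loci available for that product
  (mirroring per-product amplification success); single-locus
  identifications are flagged lower-confidence in the log.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
not any real phylogeography:

* **Species tree**: forward Yule (pure birth) simulation, ultrametric,
  rescaled so every root-to-tip path equals `interspecific_depth / 2`
  (between-species paths are then at most `interspecific_depth`).
* **Guaranteed barcoding gap**: a raw Yule draw can place a split below the
  intraspecific depth, creating species that are unidentifiable by
  construction rather than by data quality. Split ages are therefore clamped
  so every species pair is separated by at least `min_species_divergence`
  (default `min(10 x intraspecific_depth, interspecific_depth / 2)`,
  defaults: 0.05). The 10x ratio is the conventional "barcoding gap" regime
  in which tree-based assignment is expected to work; the clamp keeps the
  tree ultrametric and the scaling exact, at the cost of zero-length
  internal edges where several recent splits collapse to the floor age.
* **Sequence evolution**: root drawn i.i.d. uniform over {A,C,G,T};
  continuous-time K2P along each branch with transition rate κβ and each
  transversion rate β, β = 1/(κ+2), so branch length equals expected
  substitutions per site (the estimator is correctly specified; unbiasedness
  is verified across depths 0.01–0.3). Default κ = 2.
* **Within-species structure**: references and queries hang star-like off
  their species tip at `intraspecific_depth` (default 0.005). No coalescent
  — sufficient to exercise monophyly logic, but it cannot produce
  incomplete lineage sorting or shared haplotypes between species.
* **No indels**: alignments are gap-free; missing data enters through
  per-query, per-locus dropout (`dropout_prob`, with `force_locus` never
  dropped), emulating failed PCR on degraded wood. Variable-length loci are
  modelled at a fixed representative length (e.g. 170 bp for a 167–173 bp
  amplicon).
* **Determinism**: all randomness flows through named streams derived from
  the seed (`(seed,0)` tree, `(seed,1,locus)` evolution, `(seed,2)`
  dropout); identical configurations give byte-identical output files.

Default study-scale conditions: 5 species × 3 references, 10 queries, loci
of 181/209/280 bp, interspecific 0.10 / intraspecific 0.005. The
`study_configs()` preset mirrors a three-genus timber panel (5/7/3 species;
genus-specific locus menus at mini-barcode lengths; 5/4/3 queries; 30%
dropout sparing ITS2).

**What passing benchmarks show — and don't.** Under these favourable,
correctly-specified conditions the pipeline must and does recover 100%
discrimination and full clade counts; failures would indicate implementation
defects. Real wood data add alignment error, indels, ambiguous base calls,
incomplete reference libraries, shared haplotypes between recently diverged
species, and contamination — none of which the simulator produces — so
benchmark success bounds implementation correctness, not field performance.

## Problem sizes in tests and the acceptance script

Unit and acceptance tests run NJ consistency and monophyly oracles at 1000
random instances (≤ 12 taxa), estimator calibration at 50 kb × 50 replicates
× 4 depths, and the end-to-end benchmark at 100 bootstrap replicates; the
acceptance script evaluates all three genus panels (7/15/15 combinations) at
100 bootstrap replicates per combination. These sizes make the whole suite
run in well under a minute while keeping Monte-Carlo error far below the
asserted margins.

## Known limitations

* Plain NJ only (no BIONJ variance weighting, no branch swapping); no
  likelihood or Bayesian alternatives.
* No distance-threshold ("best close match") or diagnostic-character
  identification modes; assignment is purely tree/monophyly based.
* Alignments are taken as given; the package does not align sequences.
* Ambiguity codes carry no information in distances (treated as missing).
* The 2-taxon tree is a degenerate representation (no internal edge), and
  constant alignments yield all-zero distances whose arbitrary (but
  deterministic) resolution carries no signal — supports on such trees are
  reported as computed and should be ignored.
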