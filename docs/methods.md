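# Methods

## Model

`phenotether` implements one-hop, weight-proportional label transfer on an
undirected PPI network. A query protein `q` receives, for each of the K
phenotype categories, a tethering potential

    F_j(q) = Σ_{s ∈ seeds} w(q, s) · X_j(s),    w(q, q) = 0,

where `w` is the integer interaction confidence (STRING combined score,
0–999, kept on its raw scale) and `X_j(s)` the 0/1 annotation indicator of
seed `s`. The categories are then ranked by descending `F_j`. The model
assumes *phenotype assortativity*: interacting proteins — typically
members of one complex or pathway — tend to share phenotypes, so summed
confidences to same-phenotype neighbors are evidence for that phenotype.
The score deliberately stops at direct neighbors; there is no diffusion,
random-walk smoothing or multi-hop propagation, and no learned weights.

A seed contributes its full edge confidence to *every* category it
carries, so pleiotropic neighbors vote multiple times; consequently
`Σ_j F_j(q)` equals the confidence-weighted sum of neighbor label counts
(a tested invariant).

## Ranking and ties

Scores are exact integer sums (integer weights), so equality of scores is
meaningful and no floating-point ordering ambiguity arises; the public
contract types scores as reals to allow generalized weights. Ranking
draws a uniformly random permutation of the K categories and applies a
stable descending sort on top of it, which makes each maximal run of tied
scores uniformly randomly ordered while leaving untied scores
RNG-independent. The tie RNG is an explicit, seedable parameter of every
ranking entry point (library and CLI); queries whose score vector is
entirely zero get a fully random permutation, are flagged `all_zero`, and
*remain in all evaluation denominators* — the jackknife statistics divide
by the full seed-set size N.

## Evaluation

Leave-one-out validation treats each seed protein in turn as unannotated
and scores it against the remaining seeds. Because `w(q, q) = 0` the
query can never vote for itself anyway, but the voter pool excludes the
query explicitly. Statistics:

* `A_i` (% of N): the rank-`i` category is among the protein's true
  labels. "Correct at order i" is membership of the i-th ranked category
  in the true set, which makes the profile a descending curve with
  `Σ_i A_i = 100·M̄` exactly (each true label occupies exactly one rank —
  ties reorder ranks but never drop labels).
* `M̄`: arithmetic mean of true-label-set sizes.
* `L(r)` (% of N): the entire true label set lies in the top `r` ranks.
  Non-decreasing in `r` with `L(K) = 100%`.
* Random baseline `100·M̄/K`, the success chance of a single random guess.
  At the yeast study conditions this is `100 × 1.7 / 11 = 15.45…%`,
  reported as 15.5% at 3 significant figures (the source material rounds
  it once to 15.4% in prose and prints 15.5 in its results table; the
  computed value wins here).

Tie randomization makes the percentages weakly stochastic; `evaluate`
exposes the seed and an optional repeat-and-average mode (default: one
pass, fixed seed). Percentages are displayed at 3 significant figures.

## Input conventions

* Edge lists are whitespace/TSV triples; the confidence cutoff is
  **inclusive** (`score ≥ 900` for the "highest confidence" band), header
  rows are auto-detected by a non-numeric score field, self-loop rows are
  dropped, and duplicate or reciprocal rows keep the maximum weight (a
  no-op for STRING exports, which list each pair twice with equal
  scores). Malformed rows abort with the 1-based line number.
* Annotation rows map a protein to comma-separated category indices
  (1..K); duplicate rows merge by union with a warning.
* Membership rows map a protein to comma-separated complex/pathway IDs;
  the literal token `no annotation` marks a protein explicitly known to
  lack membership, which is distinct from absence from the table.
* Protein identifiers are opaque case-sensitive strings; no ID mapping
  between naming systems is attempted.

## Phenotype separability

Each category is represented by the component-wise **sum** of the binary
membership indicator vectors of its single-phenotype proteins (counts of
member proteins per complex/pathway). Cosine similarity between two such
vectors is invariant to positive rescaling, so summing vs. averaging the
indicators is immaterial — this is documented and property-tested rather
than left implicit. Categories with an all-zero vector (no membership
annotation at all, e.g. the immunosuppressant-sensitivity category under
pathway data) are dropped from the similarity matrix rather than emitted
as NaN rows, giving K′ retained categories and K′(K′−1)/2 pairs. Pairs
with similarity above a configurable threshold (default 0.5) are counted
as hard to discriminate. By default all single-phenotype proteins of the
annotation set contribute; a `restrict_to` option limits the analysis to
(e.g.) the network-mapped seed set, since either choice is defensible.

## Knockout analysis

"Inactivating" an interacting protein is implemented as full node
deletion (node plus incident edges) before re-scoring the query — the
literal reading of removing the protein from the network. For a one-hop
score this coincides with merely silencing the node's annotation; node
deletion was chosen as the more faithful operation. The query's own
annotation is withheld in both the intact and broken conditions, so the
baseline column equals the jackknife prediction and the two rankings are
directly comparable.

## Synthetic data

The generator plants multi-label communities: K blocks of
`n_per_category` nodes, one base label each; with probability
`multi_label_rate` a node gains a second uniform label (so
`M̄ = 1 + multi_label_rate` in expectation — the minimal pleiotropy
mechanism, which also connects the node to both label communities). Each
unordered pair receives an edge with probability `p_in` when the nodes
share ≥ 1 label, else `p_out`; weights are uniform integers in
`weight_range`. A fraction `unlabeled_fraction` of nodes is stripped of
labels to serve as prediction targets. Membership tables give each
category `complexes_per_category` synthetic complexes; proteins join 1–2
complexes per own label and, with probability `membership_overlap`, one
complex of another category — raising the overlap raises the pairwise
phenotype similarity.

Defaults mirror the yeast study conditions: `K = 11`,
`multi_label_rate = 0.7` (M̄ ≈ 1.7), `weight_range = (900, 999)`,
`p_in = 0.3`, `p_out = 0.01`, `unlabeled_fraction = 0.1`, and
`n_per_category = 30` (330 nodes), sized so that a full generate → TSV →
jackknife cycle completes in about a second. Generation is
bit-reproducible for a fixed seed, and the emitted TSVs use exactly the
dialects the readers consume, exercising the full I/O path.

What the generator does **not** emulate: the degree distribution,
clustering and component structure of a real interactome, correlated
multi-phenotype patterns beyond a single extra label, and biased
annotation coverage. Passing synthetic tests therefore demonstrates
correctness of the scoring, ranking and evaluation machinery and the
qualitative assortativity→accuracy relationship — not the quantitative
accuracy attainable on real yeast data, which the full-data tests cover
when the converted supplementary tables are supplied.

## Problem sizes and numerical choices in the test suite

Property tests use random graphs of ≤ 30 nodes against a brute-force
all-pairs oracle (1,000 cases in the acceptance suite), 20-seed averages
for stochastic generator calibrations (null-model accuracy within 5
percentage points of `100·M̄/K`; `M̄` within 0.1 of its target), and
10,000 draws for the two-way-tie frequency check (±2 percentage points).
Exact assertions (integer potentials, `Σ A_i = 100·M̄`, `L(K) = 100`) use
no tolerance beyond 1e-9 for float accumulation. The acceptance script
runs the default 330-node synthetic condition; the whole suite completes
in a few seconds on one CPU.

## Known limitations

* Strictly one-hop: a protein whose only annotated partners are two hops
  away is unpredictable (`all_zero`), and such queries depress the
  reported accuracies by design rather than being excluded.
* No negative evidence: activators and repressors in one complex vote
  identically, a direction the confidence weights cannot express.
* Exact reproduction of the published seed-set size depends on how the
  source databases' protein names were matched, which the available
  material does not fully specify; counts are therefore checked only in
  the optional full-data tests.
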