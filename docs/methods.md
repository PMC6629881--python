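# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `fossilfit`. It describes what the code computes; every
empirical number quoted here is produced by the test suite or
`scripts/acceptance.py`.

## Character matrices and missing data

Matrices are taxa × unordered multistate characters. Three cell kinds are
distinguished: observed (one state), polymorphic (an explicit state set,
written `{01}` or `(01)` in NEXUS), and missing (`?`). The gap symbol `-`
is treated as missing throughout: these are morphological matrices with no
alignment, so no gap state exists. In all parsimony computations a missing
cell behaves as the full state set of its character and a polymorphic cell
as its coded set — this is what lets a fossil coded for 6 of 28 characters
be scored at all: its 22 unknown cells never force a change, so an
all-missing taxon attaches anywhere at zero cost (a tested invariant).

Character indices are 1-based at every user-facing boundary, matching the
taxonomic convention of writing codings as "characters 5(0), 10(0), …".
NEXUS reading is delegated to dendropy (both interleaved and flat layouts);
writing emits one canonical dialect (non-interleaved, `{}` polymorphism).

## Parsimony scoring

Tree length is Fitch small parsimony: the minimum number of state changes
over the tree, summed over characters. Binary trees are scored with the
classic bitmask Fitch pass (state sets as integer masks, vectorised over
characters). Multifurcating trees — needed for the branch-collapse rule —
are scored exactly with unit-cost Sankoff dynamic programming, which on
binary trees coincides with Fitch. Correctness is accepted against two
independent oracles: an exhaustive enumeration of all internal-state
assignments on small trees (200 random cases per run), and dendropy's
Fitch down-pass.

Consensus trees are never length-scored in reports: published tree lengths
refer to the binary most parsimonious trees (MPTs), not to their consensus.

## Tree search

*Exact.* Branch-and-bound stepwise addition returns **all** MPTs for small
matrices (default refusal above 12 taxa; partial-tree length is monotone
under taxon addition, so subtrees exceeding the incumbent length are
pruned). Taxa are added in decreasing-variability order, ties broken by
matrix row order; the initial bound comes from greedy addition. Equality
with exhaustive scoring of all 945 seven-taxon topologies is part of the
acceptance suite.

*Heuristic.* Random-addition starting trees are improved by
subtree-pruning-regrafting (SPR) hill climbing with parsimony-ratchet
cycles: a random fraction of characters (default 25%) is temporarily
doubled in weight, the tree is re-optimised under the perturbed weights,
then re-optimised under the originals. The original analysis used TNT's
"New Technology" search (ratchet + tree-drifting + tree-fusing); drifting
and fusing are deliberately not replicated — the surface being reproduced
is the best length and the MPT set, not TNT's trajectory. All distinct
trees at the best length are collected, exploring equal-length SPR
neighbours up to a cap (`max_equal_trees`, default 64). One integer seed
drives addition orders, ratchet reweighting and bootstrap resampling
through a single numpy generator stream; results are deterministic given
the seed.

*MPT counting.* Published MPT counts depend on the branch-collapse rule of
the software used. Here a binary MPT's internal edge is collapsed when
contracting it (tested by exact Sankoff scoring of the resulting polytomy)
leaves tree length unchanged — i.e. when the branch can carry zero changes
in some optimal reconstruction. `TreeSet.n_mpts_collapsed` reports the
count of distinct collapsed topologies; exact equivalence with TNT's
enumeration is not claimed.

## Ensemble indices

Per character, the minimum possible steps is (number of distinct states
among singleton-observed cells) − 1, floored at zero; the maximum is the
number of coded taxa minus the largest number of coded taxa that can share
one state, counting a polymorphic cell toward any state in its set (the
generous reading; the published construction does not specify one, so this
choice is unit-tested against hand enumerations). With `m = Σ min`,
`g = Σ max`: `CI = m/TL`, `RI = (g−TL)/(g−m)`, with `RI = 1` when `g = m`
and `CI = 1` when `TL = 0`. The identities `CI·TL = m` and
`RI·(g−m) = g−TL` are asserted in exact arithmetic. Indices are reported
both at full precision and rounded to two decimals, the printing convention
of tree-figure captions.

## Bootstrap

Nonparametric bootstrap over characters: each replicate draws a multinomial
weight vector (equivalent to resampling characters with replacement to the
original count), reruns the heuristic search at reduced effort under those
weights, and records the splits of the replicate's strict consensus of best
trees. Support is the percentage of replicates containing a split; supports
of mutually incompatible splits may both be reported. Support values are
attached for display to the strict consensus of the full-data MPTs.

## Best-fit assignment

A group's range for a trait is pooled over all of its modern species, so a
state occurring in a minority of species still belongs to the set —
presence suffices for fit (this is how "four lacrimal tubules, less
frequently five" is meant to be encoded). A fossil fits a group iff every
one of its *observed* traits intersects the group's range; traits the
reference does not record for a group are excluded from numerator and
denominator, and a group compared on zero traits is "indeterminate", never
a candidate. Genus-level comparison runs only inside candidate tribes;
a candidate tribe without a genus table is reported as unresolved, not an
error. Fin formulas decompose into separate spine and ray interval traits
so that overlap is well defined. Ranges may carry a `partial` flag, printed
"(+)": compatible for candidacy but displayed distinctly — this encodes
published "partial/qualified" verdicts such as a lacrimal depth judged very
similar but not inside the strict literature interval.

Two interpretive choices are flagged: overlap means interval
*intersection*, not containment (the published bolding convention does not
distinguish them); and soft qualitative traits (e.g. caudal-fin shape) are
handled as categorical sets by the table author, not interpreted by the
engine.

Monotonicity is a structural property of the rule — removing an observed
trait can only grow the candidate set — and is property-tested.

## Morphometrics

Standardisation is `100 × measurement / reference` with the basis (SL, BL
or HL) carried along; BL (posterior opercle margin to posterior hypural
margin) exists because fossils often lack the snout. Scale statistics
aggregate by the mean over a specimen's "normal" scales per site, then by
specimen — an aggregation rule is required and unstated in the source
conventions, so per-specimen means are used and flagged. Display rounding
follows printed granularity (ratios and size factors to one decimal,
half-up so 1.25 → 1.3; lacrimal depth to whole percent); internal math is
full precision.

Tooth classification fits one least-squares line of crown width on body
size per tooth row (inner/outer) and assigns a query tooth to the row with
the smaller absolute residual, reporting both residuals; near-equal
residuals (relative tolerance 1e−9) are "ambiguous", and a class whose
reference points share a single body size falls back to its mean crown
width. This transparent two-line rule is an interpretation: the original
comparison was a scatter plot with trend lines, not a formal classifier.

## Ordination

Gower distance: per variable, absolute difference divided by the variable's
observed range, averaged over the variables both specimens share; a pair
sharing no variable is an error, a constant variable contributes zero.
Gower is chosen precisely because missing-value tolerance is the stated
reason for preferring PCoA over PCA in this setting; a Euclidean option
exists behind a flag. PCoA is classical metric scaling: double-centre
`−½·J·D²·J`, symmetric eigendecomposition, coordinates scaled by
`√eigenvalue` for positive eigenvalues. Negative eigenvalues (expected for
non-Euclidean Gower distances) are reported and their axes dropped; no
Cailliez/Lingoes correction is applied by default because corrections alter
coordinates and there is no indication one was used originally. Raw counts
enter untransformed (the original software's default transformation, if
any, is unknown; flagged). The Euclidean-input round trip is accepted at a
Procrustes disparity below 1e−6. Group comparison on the first two axes
uses convex-hull intersection (shapely) with centroid distances; groups
under three points get centroid-only comparison.

## Synthetic data

The generators are pure functions of (config, seed), using numpy's PCG64
streams with no global state.

*Reference systems.* Tribes receive integer trait intervals inside
biologically plausible bounds (total vertebrae 20–45, cichlid-typical fin
count windows). For a requested inter-clade separation, traits whose
bounds can host `n_clades` disjoint stepped intervals (typically the wide
vertebral count) become separating traits; narrower traits receive random
subintervals that may overlap, as real tribes' fin formulas do. Separation
0 means identical ranges. Genus ranges are random subintervals of their
tribe's range; species values are drawn uniformly within their genus
range. A masked fossil observes each trait independently with probability
1 − mask_fraction (default 0.3, mirroring a fossil preserving roughly
two-thirds of surveyed characters) and carries its true labels.

*Character matrices.* Characters evolve down a random binary tree by a
symmetric k-state process with a single per-edge change probability — not
branch lengths and rates, because the parsimony engine is
branch-length-agnostic and the simpler process is easier to reason about.
Cells are masked to missing independently. At 8 taxa, 50 binary characters
and change probability 0.05 per edge, the strict consensus of the exact
MPT set is compatible with the generating topology in roughly three
quarters of seeds; chance homoplasy accounts for the rest, so tests assert
the majority-recovery property rather than near-certain recovery.

What passing synthetic tests does *not* show: real morphological characters
are correlated, states are not exchangeable, and real trait ranges overlap
far more than a disjoint-range system — so the measured recovery rates are
upper bounds on what comparable real data could give, and the published
assignment itself rests on the transcribed range compilations, not on
these simulations.

## Problem sizes and defaults

Default test and acceptance problem sizes — 4–8 taxa for oracle-checked
scoring, 7 taxa for search benchmarks (945 topologies, exhaustively
enumerable), 200 masked fossils, an 18-taxon + fossil miniature study with
28 binary characters (the shape of the published subfamily matrix) — were
chosen so that every check has an exact or enumerable oracle while a full
run stays in the minutes range on one core. The published matrices
themselves (19 × 28 and 69 × 41) are supplementary downloads; when present
under `data/external/`, dedicated acceptance tests run the engine against
their printed statistics (TL 35 / CI 0.89 / RI 0.94 / 2 MPTs; TL 197 /
CI 0.42 / RI 0.79).

## Known limitations

- No implied weighting, character ordering, step matrices, or
  likelihood/Bayesian inference; strictly equal-weight unordered parsimony.
- SPR (not TBR) neighbourhoods; very large matrices would want TBR and
  faster incremental scoring.
- The MPT plateau enumeration is capped, so "number of MPTs" is a lower
  bound on plateaus larger than the cap.
- Bootstrap replicates rerun the heuristic at reduced effort; support for
  weakly supported splits is therefore noisier than the full-effort search
  would give.
- The best-fit rule is purely set-theoretic: no probabilistic placement, no
  phylogenetic correction, no weighting of traits by reliability.
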