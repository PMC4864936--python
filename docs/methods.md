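# Methods

This note records the model behind `jumpscaf`, the parameters that
matter, what the synthetic data emulate, and the numerical and design
choices a maintainer would want to know about.

## Scaffold graph model

Contigs are nodes; a scaffold edge bundles the read pairs linking one
contig pair in one relative-orientation class. Edges are canonical
(lexicographically smaller contig first; the four orientation classes
(+,+), (+,−), (−,+), (−,−) are each closed under whole-scaffold
reversal after this normalization, so all four are kept). A scaffold is
a signed permutation of contig *instances* — repeats may recur — plus
gap sizes. An edge ⟨c1 o1, c2 o2; g, σ, n⟩ is satisfied by an instance
pair when the orientations match one of the edge's two mirror readings
and the implied gap lies in g ± mσ (m = 6 by default). Edges between
two repeat contigs are ignored everywhere: their concordance cannot be
assessed without knowing every instance, and no component of the method
uses them.

### Coverage classification

Contig coverage is mapped bases over length from primary alignments.
A contig is a repeat iff coverage ≥ 1.5× the length-weighted genome
mean (the boundary counts as repeat). The factor is configurable
(`repeat_factor`).

### Library estimation

A preliminary insert size is the mean outer span of the first 1000
same-contig pairs in input order; contigs longer than twice that
estimate then provide the estimation set (applied to orientation voting
and to μ/σ alike). Orientation is the majority class over same-contig
pairs, with the deterministic tie order inward > outward > same-strand.
Distances outside [Q1 − 3·IQR, Q3 + 3·IQR] (type-7 quartiles) are
discarded once (the filter is not iterated); μ and σ are the mean and
population standard deviation of the survivors, with a 1-bp floor on σ
so span bounds and concordance windows stay positive. The library span
bound is L = μ + 6σ. Pair distance is always the outermost-coordinate
span, i.e. it includes both read lengths.

### Edge length estimation (truncation correction)

Pairs observed across a gap g between flanks of total length l are a
truncated sample: the insert must lie in [g, C], C = g + l. With Ŝ the
contig-covered part of the insert (I = Ŝ + g), the model tabulates
E(Ŝ)(g) = E(I | g ≤ I ≤ C) − g over g ∈ [0, L] from the empirical
insert histogram, in linear time via cumulative sums, one table per
500-bp bucket of l (ties round down; tables are built lazily for any
requested bucket, with the window clamped at the largest observed
insert). The estimate is the g whose E(Ŝ) is nearest the observed mean
of Ŝ; observed means outside the table's range clamp to the boundary
and flag the edge. E(Ŝ) is non-increasing in g wherever defined —
strictly decreasing where the window clips the distribution — so the
inversion is unique up to table resolution; with an *empirical*
histogram, monotonicity holds at the 500-bp stride but individual 1-bp
steps can jitter in sparse tails. σ_e = σ_lib/√n_e (the standard error
of the bundled estimate; the per-edge empirical SD is deliberately not
used because n_e is often small).

### Multi-library merging and filters

Per (pair, orientation class): seed a cluster with the largest-σ
unmerged edge, absorb edges within 6 seed-σ of its mean, merge by
inverse-variance weighting (g = Σw_i g_i/Σw_i, σ = (Σσ_i⁻²)^−1/2,
support summed); iterate on the remainder. If several merged edges
survive for a unique–unique pair the best-supported one wins; pairs
involving a repeat keep all survivors. Contigs shorter than
max(500, 2 × smallest-library insert) and edges with support < 5
(1 in long-read mode) are filtered; filtered contigs are emitted as
singletons. Libraries can be staged by insert size ((0,1k], (1k,10k],
(10k,∞); off by default) with later stages scaffolding the earlier
stages' scaffolds as units — reads on contigs placed exactly once are
projected into scaffold coordinates, reads on multiply-placed repeats
are dropped for those stages.

## The exact search

State: placed instances with coordinates; per-edge status
(satisfied / pending / discordant); k = discordant count. Placement is
**anchored**: an appended instance sits at `anchor.end + g_e` for the
best in-reach orientation-matching edge from a placed instance (most
support, then smallest σ, then rightmost anchor, then edge id), clamped
to at least δ_min = −500 bp past the tail; with no anchor it starts a
new piece one reach beyond the tail (a "break", later split into a
separate scaffold). Gaps therefore sit at their edge estimates until
final gap sizing. Pending edges die (become discordant) exactly when no
future right-extension can satisfy them — their last reachable window
drops behind the tail.

Candidates are the far endpoints of pending edges whose placed endpoint
is a *unique* contig (repeats never propose extensions), tried in both
orientations, ordered by BFS-estimated distance from the tail (each
edge visited once; multi-path candidates get the mean of path estimates
weighted by 1/edges-in-path); break candidates (any unplaced unique,
optionally led by one repeat connected to it) follow. All unique
contigs, in both orientations, serve as starting points; repeat-led
starts cover scaffolds that begin with a repeat.

Repeat instances farther from the tail than the maximal pairing reach
(max(g_e + mσ_e) − δ_min) are *confirmed* if removing them (geometry
preserved; the vacated span becomes gap) would turn a satisfied edge
discordant, and removed otherwise; a final sweep applies the same rule
to trailing instances. This yields the minimal-repeat property: no
instance of the returned scaffold can be deleted without increasing
discordance. A repeat extension is explored only if it immediately
satisfies a pending edge or offers a reachable window for one — a
useless instance would be removed at confirmation anyway.

**Memoization.** States equal in (active-region geometry, pending-edge
set, placed unique set) have identical futures; a prefix tree over this
canonical encoding stores the best k per key, pruning a state iff an
equal key was seen with k′ ≤ k. The active-region encoding keeps only
the *relevant* suffix instances — unconfirmed repeats and instances
holding a reachable window for a pending edge — with their
distance-to-tail, which collapses states that differ only in frozen
history. One unified key serves graphs with and without repeats (it is
sound for both and strictly stronger than keying on the discordant set
in the unique-only case). The search stack itself stores only per-step
deltas (an undo journal), not copies of the state.

**Iterative deepening and ties.** p = 0, 1, 2, … until a complete
scaffold (covering all unique contigs) with ≤ p total unsatisfied edges
exists; the first completion found is returned. First-found semantics
under the fixed exploration order make the result reproducible and —
because a pruned prefix's completions are always produced earlier from
the equal state that pruned it — identical with memoization on or off.

**Hybrid-exact fallback.** The explored-state counter is capped
(10⁶ by default); exceeding it raises the edge-support threshold by the
configured step, rebuilds the subgraph and restarts, flagging the
result in the AGP and the log.

**Copy bound.** Live instances per repeat contig are capped at 8 purely
as a termination guard with memoization disabled; the parsimony
criterion itself keeps optimal solutions far below it.

## Contraction

Borders are unique contigs at least as long as the largest library
bound L; defensively, a contig spanned by some single edge's window
(g + mσ ≥ length) is not a border. Fenced subgraphs are the connected
components of the unique subgraph minus borders, closed by their
adjacent borders (a border's edges partition by intrinsic end, so it
joins at most two subgraphs; components competing for the same border
end are merged), then augmented with adjacent repeats — each
non-repeat–repeat edge lands in exactly one subgraph. Subgraphs whose
border-sharing structure contains a cycle cannot be linearized by
concatenation (the shared borders would recur), so each cyclic cluster
is merged and searched jointly. Stitching concatenates pieces at shared
borders (terminal by construction), flipping the later piece to
reconcile orientation.

## Gap sizing

With order and orientation fixed, gaps minimize
Σ_e w_e (D_e(x) − g_e)², w_e = n_e/σ_e² (the support factor can be
switched off), D_e = spanned gaps + interior contig lengths, subject to
x_t ∈ [δ_min, δ_max] (defaults −500 bp and the largest library L).
A projected coordinate descent with deterministic sweep order solves
the convex QP; iteration stops when the largest coordinate move falls
below 1e−8 (relative), and the reported KKT residual is the largest
projected-gradient violation. The solver initializes at δ_min, so flat
directions resolve toward the lower bound. Gaps spanned by no
concordant edge keep the anchored-placement (source-edge) value.
Negative or zero gaps render as a single N in FASTA and gap length 1 in
AGP, with the estimate preserved in a trailing `est=` column so the
structure round-trips.

## Long-read links

Each contig link becomes an edge with g = estimated distance and
σ = max(0.1·distance, 30 bp) — the 10% rule reflects indel noise in
long reads; the 30-bp floor (10% of the smallest bin's upper edge)
keeps zero-distance links usable. Duplicate links for one constraint
merge by support summing and inverse-variance distance averaging.
Links are grouped into synthetic libraries by distance — [0,300),
[300,1000), [1000,2000), [2000,5000), [5000,15000), [15000,40000]
(half-open, lower-inclusive; the final upper edge included) — and
links beyond 40 kbp are discarded with a logged count. The support
threshold defaults to 1 in this mode.

## Synthetic data: what it does and does not emulate

`simulate_genome` draws an i.i.d. uniform genome and plants repeat
families as identical copies at non-overlapping positions (≥ 20 kbp of
unique sequence between copies). `derive_contigs` tiles the genome into
contigs broken at repeat boundaries and at random unique-region
breakpoints (segments ≥ 15 kbp, mean ≈ 30 kbp), collapsing each family
into a single contig — the coverage of which then reflects its copy
number, exercising the classifier. `simulate_mate_pairs` draws uniform
fragment positions and Normal(μ, σ) outer spans, mapping each read onto
its containing contig directly (reads straddling a contig boundary drop
the pair; mate labels of inward/outward pairs are swapped at random).
The default study is a 1-Mbp genome, ~10% repeat content (four families
× three 8-kbp copies), and two inward libraries — 3 kbp ± 300 and
10 kbp ± 1000 — at 2× pair coverage each (n = coverage·G/(2·read
length) pairs).

Not emulated: base-calling errors and mis-mappings (mappings are exact
by construction), chimeric pairs, diverged repeat copies, GC and
mappability bias, and multi-chromosome genomes (the evaluator supports
them; the default generator plants one chromosome). Passing tests
therefore demonstrate the correctness of the combinatorics and the
estimators under the stated noise model, not robustness to alignment
artifacts.

The random scaffold-graph generator used by the validation batteries
plants a true signed layout, derives edges for adjacent pairs, adds an
edge spanning each short repeat run — keeping the unique subgraph
connected, as a spanning mate-pair library does in practice — plus a
few longer-range and contradictory noise edges between unique contigs.

## Evaluation conventions

Consecutive unique contigs in a scaffold are classified against truth
coordinates: translocation (different chromosomes), inversion (wrong
relative orientation), relocation (wrong order, or separation off by
more than max(1 kbp, 6σ of the supporting edge) when that exceeds
1 kbp), scaffold-indel (separation off by more than 1 kbp — room for a
missing contig). Repeat instances between unique flanks are correct if
the true gap holds a copy of that contig in matching order and
orientation; "placeable" copies are true copies inside the gaps of
scaffolded unique pairs. N50 is the fragment length at which the
descending cumulative sum first strictly exceeds half the genome;
corrected N50 recomputes it after splitting scaffolds before every
erroneous join.

## Problem sizes used by the test suite and acceptance script

The batteries use 200 random graphs (4–7 unique + 0–2 repeat contigs,
≤ 12 edges) for exactness, 50 twelve-contig graphs with planted borders
for contraction, 105 simulated edges (21 gap values × 5 replicates,
100 pairs each) for the length estimator, ten 10,000-pair simulations
for library recovery, and one full 1-Mbp end-to-end study; the entire
suite runs in seconds on one CPU, so these sizes are comfortable
package defaults rather than compromises.

## Known limitations

- Concordance uses each edge's own ±6σ window around its gap estimate
  with gaps held at anchored values during the search; a feasibility
  check over joint gap assignments (as the final QP performs) could in
  principle judge borderline edges differently.
- Scaffolds are linear; circular chromosomes surface as one cyclic
  cluster searched jointly, with one edge left discordant.
- Polyploid-aware edge handling and graph-structural repeat detection
  are out of scope.
- With staging enabled, reads on repeat contigs are dropped from later
  stages (their placement is ambiguous), slightly thinning long-range
  support across repeats.
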