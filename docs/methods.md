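# Methods

## Model and data

A ploidy profile **m** = (m₁ ≥ … ≥ mₙ ≥ 1) assigns each taxon its ploidy
level (dimensionless copy-number of the full chromosome set).  A rooted
directed acyclic multigraph realizes **m** when the number of directed
root-to-leaf paths to the taxon indexing mᵢ is exactly mᵢ, with every
internal vertex either a tree vertex (in 1 / out 2) or a reticulation
(in 2 / out 1), the root of outdegree 2, and parallel-arc pairs
("beads", multiplicity capped at 2) permitted.  Beads model
autopolyploidization; reticulations outside beads model
allopolyploidization.  The degenerate profile (1) is realized by a
single labelled vertex, which also serves as the endpoint of cherry
reductions.

Profiles are inputs; the package infers nothing from sequence data.

## Simplification and traceback

Each simplification step compares the two largest components
(α = m₁ − m₂) and applies one of three reductions; the component sum
strictly decreases, so the sequence terminates in a simple profile.
When α is inserted back into the vector it goes directly after the last
occurrence of the same value, or — when the value is absent, where that
rule is vacuous — at the unique position preserving descending order.
Inserted components receive labels from a reserved `_s<counter>`
namespace that cannot collide with user taxa, and every step records
the predecessor's first two taxa and the inserted label so the
traceback is self-contained.

In the traceback of the insert case, the text of the source
construction deletes the inserted leaf "and its incoming arc (u, x_j)";
after the prescribed subdivision the leaf's parent is the new vertex v,
so the implementation deletes (v, x_j) and suppresses v — the only
reading that leaves a valid network (a suspected typo, resolved in
favour of well-formedness; the realization property is re-checked after
every traceback).

## The beaded core network

For a simple profile with largest entry m₁ = 2^{i₁} + ⋯ + 2^{i_k}, the
core is a chain of i₁ beads (realizing 2^{i₁}) with one cross arc per
further exponent i_j, whose target s_j′ subdivides the outgoing arc of
the bead reticulation with exactly i_j bead reticulations of the chain
strictly below it.  Two consequences of the construction worth stating
because they are easy to miscount:

* the subdivision vertex s_k (and w, when m₁ is a power of two and unit
  taxa exist) sits on one strand of the *root* bead, which therefore
  stops being a bead: B((77)) has 9 reticulations of which 5, not 6,
  remain in beads.  The constructed labelling depends on this: the root
  chain vertex gets the first reticulation's stamp, satisfying its
  horizontal-parent requirement.
* a core for (5,1,1) needs at least ⌈log₂ 5⌉ = 3 reticulations, and the
  construction uses exactly i₁ + (k − 1); with two insert steps the
  realization of (7,6,6,5) therefore has 5 reticulations.

The subdivided root arc is always the strand towards the first bead's
reticulation, chosen deterministically so serializations are stable.
The alternative `naive_core` (a directed path with chords) realizes the
same profiles without horizontal structure; its primed vertices appear
in reverse order along the path, the arrangement under which each chord
adds exactly the upstream count (verified against the brute-force path
oracle).

## Time labellings

Stamps are exact `Fraction`s so the equality in the horizontal-parent
rule (P3) is exact; the "sufficiently small ε" of the constructions
becomes a midpoint of the relevant open interval.  Bead reticulations
are exempt from P3 by filtering before the scan.  The weak rule (P3′)
additionally requires the single exempt reticulation to have distinct,
comparable parents, checked by reachability.

`verify_labelling` is the sole authority: both constructors
(`label_core` from the core's construction metadata,
`label_from_cherry_sequence` by reverse replay of a certificate) are
tested only through it.  Reverse replay assigns increasing integer
stamps as operations are undone root-downwards; an undone cut gives its
two subdivision vertices a shared stamp (the new horizontal arc), and
an undone trim places the re-added vertex at the midpoint of its arc —
or at its child's stamp when that child is a reticulation, which has
just lost its previous partner and needs the new arc horizontal.

## Cherry operations

`simp` (delete a bead strand above a leaf) and `trim` (delete the upper
parent's arc into a reticulation above a leaf) are applied to any leaf
in the recognized configurations, not only when one taxon remains: the
worked examples apply `simp(x₁)` on a three-leaf core, and the core of
(7,6,6,5) is irreducible under the narrower reading, which would
contradict the certificate theorem the package implements.  For the
degenerate-cherry case in which one parent of the reticulation is a
bead reticulation, trimming deletes the other parent's arc — the
mechanics of the triangle case, and exactly the worked trim example on
B((77)).

The orchard decision is a backtracking search (cut before reduce before
simp before trim, lexicographic within kind) memoized on an unfolding
signature with exact-isomorphism collision resolution, so memo hits are
sound.  Certificates for N(m) are instead read directly off σ(m) — one
reduce or cut per step, concatenated with a searched sequence for the
small core — and replayed to verify completeness.

## Profile space

`split` duplicates the subtree below a reticulation's child; public
`split` requires distinct parents (the definition's p₁ ≠ p₂), while
unzipping applies the same duplication to beads (both copies under the
single parent), since the root-bead inverse is not count-conserving and
cannot remove interior beads.  Unzipping always splits a *lowest*
reticulation: its child's subtree is then reticulation-free, the child
arc is necessarily a cut-arc, and each split removes exactly one
reticulation, so #splits = #reticulations.

Tree-basedness is decided exactly by bipartite matching between
vertices whose children are all reticulations and the reticulations
that can keep an arc from them; a saturating matching yields the kept
arcs, and suppressing the spanning tree gives the base tree.  The
MUL-tree edit distance in `distance_upper_bound` is a deliberate
plug-in (the default refuses non-isomorphic trees): exact SPR-type
distances are NP-hard and out of scope, so published distance bounds
that depend on a specific solver are not reproduced.

Exhaustive enumeration of realizations generates degree-feasible arc
assignments for at most two taxa and three reticulations (hard guards),
filtered by validity and path counts and deduplicated by isomorphism;
that suffices for the (2)-uniqueness and (3)-search facts and is not a
general enumerator.

## Scaled composition

`compose_scaled(N, i)` realizes (2ⁱm₁, …, 2ⁱmₙ, 2^{i−1}, …, 1) by
joining a realization of the fresh powers-of-two profile to N through
two subdivision vertices feeding a common child above N's root.  For
i = 1 the powers-of-two part is the single-vertex network with no arc
to subdivide, so the doubling vertex is supplied by a root bead gadget
instead: a new root with the fresh unit taxon on one side and a bead
over N's root on the other.

## Synthetic data and test scale

Random profiles draw n ≤ 8 components uniformly from 1..200 (the Viola
range is 2–18, so this covers realistic ploidy levels with ample
headroom); random simple profiles draw m₁ ≤ 256, giving binary
representations up to nine exponents.  All generators are seeded and
deterministic.  What they emulate is the combinatorial input space of
profiles, not empirical ploidy distributions; passing tests therefore
establish the constructive guarantees (realization correctness,
labelling strength, certificate completeness, conservation laws) on
that space, and say nothing about the biological plausibility of any
particular profile.  Property corpora of 200 profiles per law keep the
full suite under half a minute while exercising every case split
(including subtract steps, which need component ratios above 2).

## Known limitations

* Labellings are verified or constructed from the two constructors;
  deciding labellability of an arbitrary input network is not
  attempted.
* Orchard search is exponential in the worst case (fine at the sizes
  the constructions produce; memoization keeps the worked examples
  instant).
* The published minimum-reticulation property of N(m) is reported (the
  Viola realization attains it with five non-bead reticulations) but
  not re-proved: no search over all cores is performed.
* eNewick serialization is this package's own canonical dialect
  (children ordered by subtree string, beads as a repeated hybrid tag
  under one parent); other tools' eNewick dialects are parsed on a
  best-effort basis.
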