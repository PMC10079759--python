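# ploidynet

Realizing ploidy profiles as phylogenetic networks with beads and
horizontal arcs.

## The problem

Polyploid species carry multiple copies of their complete chromosome
set, acquired by whole-genome duplication (autopolyploidy) or by
hybridization with a related species (allopolyploidy).  The standard
route to a phylogenetic network for such a dataset goes through a
multiple-labelled gene tree, which is often not available.  `ploidynet`
asks how much can be reconstructed from the ploidy levels alone: given a
*ploidy profile* **m** = (m₁, …, mₙ) on taxa X = {x₁, …, xₙ}, it builds
a rooted phylogenetic network N — allowed to contain *beads* (pairs of
parallel arcs, modelling whole-genome duplication) — in which the number
of directed root-to-leaf paths to xᵢ equals mᵢ.  Such an N *realizes*
**m**.

The pipeline:

1. **Simplification sequence σ(m).**  With α = m₁ − m₂, the profile is
   iteratively reduced (drop m₁ if α = 0; replace m₁ by α if α > m₂;
   otherwise drop m₁ and insert α at its descending-order slot) until a
   *simple* profile (m, 1, …, 1) remains — the terminal element.
2. **Core network B(m).**  The binary representation
   m = 2^{i₁} + ⋯ + 2^{i_k} drives a chain of i₁ beads plus one cross
   arc per further exponent; unit taxa attach as a caterpillar tree.
3. **Traceback.**  Undoing σ(m) step by step adds a cherry (α = 0) or a
   reticulate cherry (α ≠ 0) per step, yielding N(m) with
   rets(N(m)) = rets(B) + #{steps with α ≠ 0}.

Beyond construction, the package decides what the result *means*:

* **Time labellings.**  A map t : V(N) → ℚ≥0 is *HGT-consistent* when
  time moves forward (P1), every ancestor has a strictly later child
  (P2), and every non-bead reticulation has exactly one parent with the
  same stamp (P3) — that arc is *horizontal*: its endpoints co-existed.
  Core networks of *practical* profiles admit such a labelling; of
  *arc-rich* ones only a weak labelling (one exempt reticulation).
* **Cherry-modification sequences.**  reduce/cut/simp/trim operations
  reduce N(m) to a single vertex; the certificate is read directly off
  σ(m) and certifies (weak-)orchard status, tree-basedness, and
  produces the labelling constructively.
* **Ploidy-profile space.**  Split operations unzip any realization to
  a multiple-labelled tree while conserving path counts; together with
  a pluggable MUL-tree edit distance this bounds the distance between
  alternative realizations of one profile.

## Worked example

```sh
python examples/01_simplify_and_realize.py
```

prints

```
simplification sequence:
  (7,6,6,5)  --REMOVE_INSERT(alpha=1)-->
  (6,6,5,1)  --REMOVE_EQUAL(alpha=0)-->
  (6,5,1)  --REMOVE_INSERT(alpha=1)-->
  (5,1,1)  (terminal)

N(m) as eNewick: (((((((((((x1)#H5,x2),x3))#H4,x4))#H3)#H2,#H2))#H1,(#H3,(#H4,#H5))),#H1);
root-to-leaf path counts: {'x4': 5, 'x3': 6, 'x2': 6, 'x1': 7}
summary: {'counts': {'x4': 5, 'x3': 6, 'x2': 6, 'x1': 7}, 'reticulations': 5, 'bead_reticulations': 1, 'non_bead_reticulations': 4, 'beads': 1}
```

The terminal element (5,1,1) seeds the beaded core; tracing back the
three steps restores the four taxa, and the path counts reproduce the
input ploidy levels exactly.  The other examples cover the core
construction and its labelling (`02`), orchard certificates (`03`), the
Viola dataset (`04`) and profile-space exploration (`05`).

A thin CLI mirrors the API:

```sh
ploidynet realize --profile 7,6,6,5 --format dot
ploidynet orchard --network net.enwk --weak
```

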