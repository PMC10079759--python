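"""Building N(m): traceback through the simplification sequence.

Starting from a core network realizing the terminal element, the
simplification steps are undone in reverse.  Each undone step adds either
a cherry (the alpha = 0 case) or a reticulate cherry (the two alpha > 0
cases), which is why the resulting network N(m) is reducible by cherry
operations (see :mod:`ploidynet.cherries`).

The reticulation count grows by exactly one per step with alpha != 0, so
``rets(N(m)) = rets(core) + #{steps with alpha != 0}``.
"""

from __future__ import annotations

from .corenet import build_B
from .netgraph import Network, NetworkError, count_paths
from .profiles import (
    Case,
    PloidyProfile,
    ProfileError,
    SimplificationStep,
    halve,
    normalize,
    simplification_sequence,
)

__all__ = [
    "traceback_step",
    "realize_profile",
    "prepend_bead",
    "compose_scaled",
    "realization_summary",
]


def _leaf(net: Network, label: str) -> str:
    return net.vertex_with_label(label)


def _replace_leaf_by_cherry(net: Network, leaf: str, lab1: str, lab2: str) -> tuple[str, str]:
    """Turn *leaf* into an internal vertex with two new leaves below it."""
    del net.g.nodes[leaf]["label"]
    l1 = net.new_vertex("L")
    l2 = net.new_vertex("L")
    net.g.nodes[l1]["label"] = lab1
    net.g.nodes[l2]["label"] = lab2
    net.add_arc(leaf, l1)
    net.add_arc(leaf, l2)
    return l1, l2


def traceback_step(n_succ: Network, step: SimplificationStep) -> Network:
    """Undo one simplification step on a realization of the successor.

    * REMOVE_EQUAL: the leaf carrying the successor's first taxon becomes
      the cherry on the predecessor's first two taxa.
    * SUBTRACT: a new reticulation u above the first taxon receives an arc
      from a vertex v above the second, adding the second's path count.
    * REMOVE_INSERT: as REMOVE_EQUAL plus a reticulation u above the new
      first taxon fed from the position of the inserted component's leaf,
      which is then deleted (its feeding vertex suppressed).
    """
    net = n_succ.copy()
    if step.case is Case.REMOVE_EQUAL:
        leaf = _leaf(net, step.pred_second)
        _replace_leaf_by_cherry(net, leaf, step.pred_first, step.pred_second)
    elif step.case is Case.SUBTRACT:
        x1 = _leaf(net, step.pred_first)
        x2 = _leaf(net, step.pred_second)
        pu = next(iter(net.g.predecessors(x1)))
        u = net.subdivide(pu, x1, "u", role="traceback_u")
        pv = next(iter(net.g.predecessors(x2)))
        v = net.subdivide(pv, x2, "v", role="traceback_v")
        net.add_arc(v, u)
    elif step.case is Case.REMOVE_INSERT:
        assert step.inserted_label is not None
        xj = _leaf(net, step.inserted_label)
        pj = next(iter(net.g.predecessors(xj)))
        v = net.subdivide(pj, xj, "v", role="traceback_v")
        leaf = _leaf(net, step.pred_second)
        l1, _ = _replace_leaf_by_cherry(net, leaf, step.pred_first, step.pred_second)
        u = net.subdivide(leaf, l1, "u", role="traceback_u")
        net.add_arc(v, u)
        net.remove_arc(v, xj)
        net.g.remove_node(xj)
        net.suppress(v)
    else:  # pragma: no cover - enum is exhaustive
        raise ProfileError(f"unknown case {step.case}")
    return net


def realize_profile(p: PloidyProfile, core: Network | None = None) -> Network:
    """Construct a network N(m) realizing profile *p*.

    The construction runs the simplification sequence, takes a core
    network for the terminal element (default: :func:`build_B`, or the
    single-vertex network when the terminal is the degenerate (1)), and
    traces the sequence back.  The result is checked to realize *p*.
    """
    seq = simplification_sequence(p)
    term = seq.terminal
    if core is None:
        if term.degenerate:
            core = Network.single_vertex(term.labels[0])
        else:
            core = build_B(term)
    else:
        if count_paths(core) != term.as_dict():
            raise NetworkError(
                f"core realizes {count_paths(core)}, terminal element is {term.as_dict()}"
            )
    net = core.copy()
    for step in reversed(seq.steps):
        net = traceback_step(net, step)
    got = count_paths(net)
    if got != p.as_dict():
        raise NetworkError(f"traceback produced {got}, expected {p.as_dict()}")
    return net


def prepend_bead(net: Network) -> Network:
    """Add a bead above the root; every root-to-leaf path count doubles.

    Models an autopolyploidization (whole-genome duplication) at the last
    common ancestor: an all-even profile (2m1, ..., 2mn) is realized by a
    bead over a realization of (m1, ..., mn).
    """
    out = net.copy()
    old_root = out.root if len(out.g) > 1 else next(iter(out.g))
    t = out.new_vertex("bt", role="prepend_t")
    h = out.new_vertex("bh", role="prepend_h")
    out.add_arc(t, h)
    out.add_arc(t, h)
    out.add_arc(h, old_root)
    return out


def _graft(base: Network, other: Network, prefix: str) -> str:
    """Copy *other*'s graph into *base* under fresh ids; return its root."""
    mapping = {v: f"{prefix}{v}" for v in other.g}
    for v in other.g:
        base.add_vertex(mapping[v], label=other.g.nodes[v].get("label"),
                        role=other.g.nodes[v].get("role"))
    for u, v, d in other.g.edges(data=True):
        for _ in range(d["mult"]):
            base.add_arc(mapping[u], mapping[v])
    old_root = other.root if len(other.g) > 1 else next(iter(other.g))
    return mapping[old_root]


def compose_scaled(net: Network, i: int, fresh_labels: list[str] | None = None) -> Network:
    """Realize (2**i * m1, ..., 2**i * mn, 2**(i-1), ..., 1) from N for m.

    A realization N'' of the powers-of-two profile (2**(i-1), ..., 2**0)
    on i fresh taxa is built; the incoming arc of its largest-count leaf
    is subdivided by s and s', both feeding a new vertex s'' whose arc
    into the root of N multiplies every count of N by 2**i.  For i = 1
    the powers-of-two part is a single taxon of ploidy one, and the
    doubling vertex is supplied by a bead under the new root instead.
    """
    if i < 1:
        raise ProfileError(f"scaling exponent must be >= 1, got {i}")
    counts = count_paths(net)
    existing = set(counts)
    if fresh_labels is None:
        fresh_labels, j = [], len(existing)
        while len(fresh_labels) < i:
            j += 1
            cand = f"x{j}"
            if cand not in existing:
                fresh_labels.append(cand)
    if len(fresh_labels) != i or set(fresh_labels) & existing:
        raise ProfileError("need i fresh labels distinct from the taxa of N")

    if i == 1:
        out = Network()
        r = out.add_vertex("cr", role="compose_root")
        leaf = out.add_vertex("cL", label=fresh_labels[0])
        t = out.add_vertex("ct", role="compose_t")
        h = out.add_vertex("ch", role="compose_h")
        out.add_arc(r, leaf)
        out.add_arc(r, t)
        out.add_arc(t, h)
        out.add_arc(t, h)
        inner_root = _graft(out, net, "N_")
        out.add_arc(h, inner_root)
        return out

    pow_profile = normalize([2**e for e in range(i - 1, -1, -1)], fresh_labels)
    out = realize_profile(pow_profile)
    top_leaf = out.vertex_with_label(fresh_labels[0])
    parent = next(iter(out.g.predecessors(top_leaf)))
    s = out.subdivide(parent, top_leaf, "cs", role="compose_s")
    sp = out.subdivide(s, top_leaf, "cs", role="compose_s'")
    spp = out.new_vertex("cs", role="compose_s''")
    out.add_arc(s, spp)
    out.add_arc(sp, spp)
    inner_root = _graft(out, net, "N_")
    out.add_arc(spp, inner_root)
    return out


def realization_summary(net: Network) -> dict[str, object]:
    """Reticulation/bead bookkeeping plus the realized profile."""
    rets = net.reticulations()
    bead_rets = [v for v in rets if net.is_bead_reticulation(v)]
    return {
        "counts": count_paths(net),
        "reticulations": len(rets),
        "bead_reticulations": len(bead_rets),
        "non_bead_reticulations": len(rets) - len(bead_rets),
        "beads": len(net.beads()),
    }


def realize_doubled(p: PloidyProfile) -> Network:
    """Realize an all-even profile as a bead over the halved profile."""
    return prepend_bead(realize_profile(halve(p)))
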