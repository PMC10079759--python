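"""Core networks realizing simple ploidy profiles.

A *core network* for a profile m is any network realizing the terminal
element of its simplification sequence; that terminal element is always
simple, i.e. of the form (m1, 1, ..., 1).  Two constructions are provided:

* :func:`naive_core` -- a directed path with chords; no horizontal arcs.
* :func:`build_B` -- the beaded construction B(m) driven by the binary
  representation of m1: a chain of i1 beads realizes 2**i1, and one cross
  arc per further exponent adds the remaining powers of two.  Almost all
  of its cross arcs can be drawn horizontally under a time labelling (see
  :mod:`ploidynet.timing`), which is what makes this construction the
  preferred initialization for the traceback.

Construction metadata (spine order, the role vertices s_k, s_j', w, the
caterpillar spine) is stored in ``Network.g.graph`` so the labelling
constructor can recover it; it carries no graph semantics.
"""

from __future__ import annotations

from .netgraph import Network, NetworkError, count_paths
from .profiles import PloidyProfile, ProfileError, binary_representation

__all__ = ["naive_core", "build_beaded_chain", "build_B", "caterpillar"]


def caterpillar(labels: tuple[str, ...] | list[str], net: Network | None = None,
                attach_to: str | None = None) -> Network:
    """Phylogenetic tree with the single cherry on the last two labels.

    The first label hangs directly below the root, the second below the
    next internal vertex, and so on.  With *net*/*attach_to* the tree is
    grown inside an existing network below the given vertex (used by
    :func:`build_B`); otherwise a standalone tree is returned.
    """
    labels = tuple(labels)
    if len(labels) < 2:
        raise ProfileError("a caterpillar tree needs at least two leaves")
    own = net is None
    if own:
        net = Network()
    spine: list[str] = []
    prev = attach_to
    for j in range(len(labels) - 1):
        wj = net.add_vertex(net.new_vertex("cw", role=f"cat_w{j + 1}"))
        if prev is not None:
            net.add_arc(prev, wj)
        leaf = net.new_vertex("cl")
        net.g.nodes[leaf]["label"] = labels[j]
        net.add_arc(wj, leaf)
        spine.append(wj)
        prev = wj
    last = net.new_vertex("cl")
    net.g.nodes[last]["label"] = labels[-1]
    net.add_arc(prev, last)
    net.g.graph.setdefault("cat_spine", spine)
    return net


def naive_core(p: PloidyProfile) -> Network:
    """Directed-path construction realizing a simple profile.

    A path of n + 2(m1 - 1) vertices carries chords (v_i, v_i') that each
    add the full upstream path count, and pendant leaves for the n - 1
    unit taxa.  The primed vertices appear in reverse order along the path
    (v'_{m1-1} first, v'_1 adjacent to x1), which is the arrangement under
    which each chord contributes exactly one extra unit to the x1 count.
    """
    if not p.simple:
        raise ProfileError(f"naive_core needs a simple profile, got {p}")
    m1, n = p.components[0], p.n
    net = Network()
    v = [net.add_vertex(f"v{i}", role=f"v{i}") for i in range(1, m1)]
    w = [net.add_vertex(f"w{i}", role=f"w{i}") for i in range(2, n + 1)]
    vp = [net.add_vertex(f"vp{i}", role=f"v{i}'") for i in range(m1 - 1, 0, -1)]
    x1 = net.add_vertex("L1", label=p.labels[0])
    path = v + w + vp + [x1]
    for a, b in zip(path, path[1:]):
        net.add_arc(a, b)
    for i in range(2, n + 1):
        leaf = net.add_vertex(f"L{i}", label=p.labels[i - 1])
        net.add_arc(w[i - 2], leaf)
    for i in range(1, m1):
        net.add_arc(f"v{i}", f"vp{i}")
    return net


def build_beaded_chain(i1: int, leaf_label: str = "x1") -> Network:
    """Chain of i1 beads with a pendant leaf: realizes (2**i1)."""
    if i1 < 1:
        raise ProfileError(f"need at least one bead, got {i1}")
    net = Network()
    spine: list[str] = []
    for i in range(1, i1 + 1):
        t = net.add_vertex(f"t{i}", role=f"t{i}")
        h = net.add_vertex(f"h{i}", role=f"h{i}")
        net.add_arc(t, h)
        net.add_arc(t, h)  # the parallel strand: a bead
        if i > 1:
            net.add_arc(f"h{i - 1}", t)
        spine.extend([t, h])
    leaf = net.add_vertex("L1", label=leaf_label)
    net.add_arc(f"h{i1}", leaf)
    spine.append(leaf)
    net.g.graph["spine"] = spine
    net.g.graph["n_beads"] = i1
    return net


def build_B(p: PloidyProfile) -> Network:
    """The beaded core network B(m) for a simple profile m.

    For m1 with binary representation (i1, ..., ik): start from the bead
    chain realizing 2**i1; for each further exponent ij, a cross arc from
    the chain s_k, s_2, ..., s_{k-1} below the root into a subdivision
    vertex s_j' placed where exactly ij bead reticulations remain below
    adds 2**ij paths.  A non-strictly-simple profile additionally hangs a
    caterpillar tree with the unit taxa from a vertex w placed just above
    s_k' (or on a root arc when m1 is a power of two).
    """
    if not p.simple:
        raise ProfileError(f"build_B needs a simple profile, got {p}")
    m1, n = p.components[0], p.n
    br = binary_representation(m1)
    i1, k = br.exponents[0], br.k
    net = build_beaded_chain(i1, leaf_label=p.labels[0])
    meta = net.g.graph
    meta["profile"] = p
    meta["binrep"] = br.exponents

    spine: list[str] = meta["spine"]

    def subdivide_spine_after(h: str, vid: str, role: str) -> None:
        succ = next(iter(net.g.successors(h)))
        net.remove_arc(h, succ)
        net.add_vertex(vid, role=role)
        net.add_arc(h, vid)
        net.add_arc(vid, succ)
        spine.insert(spine.index(h) + 1, vid)

    if k >= 2:
        # s_k on one strand of the root bead; the root bead ceases to be a
        # bead, its reticulation now satisfied by the horizontal (s_k, h1)
        net.remove_arc("t1", "h1")
        sk = net.add_vertex("sk", role="s_k")
        net.add_arc("t1", sk)
        net.add_arc(sk, "h1")
        meta["sk"] = sk
        # s_k' where exactly i_k bead reticulations lie strictly below
        ik = br.exponents[-1]
        subdivide_spine_after(f"h{i1 - ik}", "skp", "s_k'")
        meta["skp"] = "skp"
        chain_tail = sk
        meta["sj"] = {}
        meta["sjp"] = {}
        for j in range(2, k):
            sj = net.add_vertex(f"s{j}", role=f"s_{j}")
            net.add_arc(chain_tail, sj)
            chain_tail = sj
            meta["sj"][j] = sj
        net.add_arc(chain_tail, "skp")
        meta["chain_tail"] = chain_tail
        for j in range(2, k):
            ij = br.exponents[j - 1]
            subdivide_spine_after(f"h{i1 - ij}", f"s{j}p", f"s_{j}'")
            meta["sjp"][j] = f"s{j}p"
            net.add_arc(f"s{j}", f"s{j}p")

    if n >= 2:
        w = "w"
        if k == 1:
            # w on one strand of the root bead (h1 then satisfied by (w, h1))
            net.remove_arc("t1", "h1")
            net.add_vertex(w, role="w")
            net.add_arc("t1", w)
            net.add_arc(w, "h1")
        else:
            # w subdivides the last chain arc, just above s_k'
            tail = meta["chain_tail"]
            net.remove_arc(tail, "skp")
            net.add_vertex(w, role="w")
            net.add_arc(tail, w)
            net.add_arc(w, "skp")
        meta["w"] = w
        if n == 2:
            leaf = net.add_vertex("L2", label=p.labels[1])
            net.add_arc(w, leaf)
        else:
            caterpillar(p.labels[1:], net=net, attach_to=w)

    counts = count_paths(net)
    if counts != p.as_dict():
        raise NetworkError(f"B(m) construction off: {counts} != {p.as_dict()}")
    return net
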