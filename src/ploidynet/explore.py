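"""Ploidy-profile space: splits, unzipping, distance bounds, enumeration.

All multiple-labelled networks realizing a profile form the vertex set of
*ploidy-profile space*; two are adjacent when one arises from the other
by a single *split* of a reticulation, or when both are multiple-labelled
trees at edit distance one under a chosen MUL-tree metric.  Splitting
never changes the label-summed path counts, so the space is connected:
any realization unzips to a MUL tree, and the trees are connected by the
metric.  The shortest-path length is a distance between realizations; an
upper bound is computable from the two unzippings plus any plugged-in
tree metric (the exact metric, e.g. SPR, is deliberately a plug-in).

Also here: tree-basedness (via a bipartite matching between reticulation
arcs and otherwise-childless vertices), the extended tree-child test, and
a bounded exhaustive enumeration of realizations of tiny profiles.
"""

from __future__ import annotations

import itertools
from typing import Callable, Sequence

import networkx as nx

from .netgraph import (
    Network,
    NetworkError,
    count_paths,
    isomorphic,
    validate,
)
from .profiles import PloidyProfile, ProfileError

__all__ = [
    "split",
    "unzip_to_multree",
    "distance_upper_bound",
    "is_tree_based",
    "is_tree_child",
    "enumerate_realizations",
]


def _is_cut_arc(net: Network, u: str, v: str) -> bool:
    und = nx.MultiGraph()
    und.add_nodes_from(net.g)
    for a, b, d in net.g.edges(data=True):
        for _ in range(d["mult"]):
            und.add_edge(a, b)
    und.remove_edge(u, v)
    return not nx.has_path(und, u, v)


def _split_at(net: Network, h: str) -> Network:
    """Remove reticulation h, duplicating the subtree below its child."""
    c = next(iter(net.g.successors(h)))
    parents = []
    for u, _, d in net.g.in_edges(h, data=True):
        parents.extend([u] * d["mult"])
    p1, p2 = sorted(parents)
    out = net.copy()
    out.mul = True
    out.g.remove_node(h)
    below = net.below(c)
    mapping = {v: out.new_vertex("cp") for v in below}
    for v in below:
        lab = net.g.nodes[v].get("label")
        if lab is not None:
            out.g.nodes[mapping[v]]["label"] = lab
    for a, b, d in net.g.subgraph(below).edges(data=True):
        for _ in range(d["mult"]):
            out.add_arc(mapping[a], mapping[b])
    out.add_arc(p2, c)
    out.add_arc(p1, mapping[c])
    return out


def split(net: Network, h: str) -> Network:
    """Split at the non-bead reticulation h whose child arc is a cut-arc.

    The subgraph below h's child is duplicated; each former parent of h
    takes one copy.  Label-summed path counts are conserved.
    """
    if net.indeg(h) != 2 or net.outdeg(h) != 1:
        raise NetworkError(f"{h} is not a reticulation vertex")
    if net.is_bead_reticulation(h):
        raise NetworkError(f"{h} is in a bead; split needs distinct parents")
    c = next(iter(net.g.successors(h)))
    if not _is_cut_arc(net, h, c):
        raise NetworkError(f"({h},{c}) is not a cut-arc")
    return _split_at(net, h)


def unzip_to_multree(net: Network) -> tuple[Network, int]:
    """Split until no reticulations remain; returns (MUL tree, #splits).

    Always splits a lowest reticulation (none below it), whose child arc
    is necessarily a cut-arc and whose subtree is reticulation-free, so
    each split removes exactly one reticulation.  Beads are split the
    same way, the two copies hanging from the one bead parent.
    """
    cur = net.copy()
    cur.mul = True
    nsplits = 0
    while True:
        rets = cur.reticulations()
        if not rets:
            break
        lowest = None
        for h in rets:
            if not (set(nx.descendants(cur.g, h)) & set(rets)):
                lowest = h
                break
        assert lowest is not None  # a DAG always has a lowest reticulation
        cur = _split_at(cur, lowest)
        nsplits += 1
    return cur, nsplits


def _refuse_distance(t1: Network, t2: Network) -> int:
    if isomorphic(t1, t2):
        return 0
    raise NetworkError(
        "no MUL-tree metric plugged in; supply tree_distance= for non-isomorphic trees"
    )


def distance_upper_bound(
    n1: Network,
    n2: Network,
    tree_distance: Callable[[Network, Network], int] = _refuse_distance,
) -> int:
    """Upper bound on the profile-space distance between two realizations.

    Both networks are unzipped to MUL trees; the bound is the number of
    splits used on each side plus the plugged MUL-tree distance between
    the two trees.  The exact space distance is out of scope.
    """
    if count_paths(n1) != count_paths(n2):
        raise NetworkError("networks realize different ploidy profiles")
    t1, s1 = unzip_to_multree(n1)
    t2, s2 = unzip_to_multree(n2)
    return s1 + s2 + tree_distance(t1, t2)


def is_tree_based(net: Network) -> tuple[bool, Network | None]:
    """Is the network a phylogenetic tree with added linking arcs?

    Keeping exactly one incoming arc per reticulation always yields a
    spanning tree; the network is tree-based iff the arcs can be chosen
    so no vertex is left childless and unlabelled.  That is a bipartite
    matching between vertices whose children are all reticulations and
    the reticulations able to retain an arc from them.  Returns the base
    tree (suppressed to a phylogenetic tree on X) when one exists.
    """
    rep = validate(net)
    if not rep.ok:
        raise NetworkError(f"invalid network: {rep.violations}")
    if len(net.g) == 1:
        return True, net.copy()
    rets = set(net.reticulations())
    needy = [
        u
        for u in net.g
        if net.outdeg(u) > 0 and all(v in rets for v in net.g.successors(u))
    ]
    bip = nx.Graph()
    bip.add_nodes_from((("u", u) for u in needy), bipartite=0)
    bip.add_nodes_from((("r", r) for r in rets), bipartite=1)
    for u in needy:
        for r in net.g.successors(u):
            bip.add_edge(("u", u), ("r", r))
    matching = nx.bipartite.maximum_matching(bip, top_nodes=[("u", u) for u in needy])
    if any(("u", u) not in matching for u in needy):
        return False, None

    keep: dict[str, str] = {}
    for u in needy:
        _, r = matching[("u", u)]
        keep[r] = u
    tree = net.copy()
    for r in rets:
        parents = []
        for u, _, d in tree.g.in_edges(r, data=True):
            parents.extend([u] * d["mult"])
        chosen = keep.get(r, sorted(parents)[0])
        for u in sorted(set(parents)):
            m = tree.g[u][r]["mult"]
            drop = m if u != chosen else m - 1
            for _ in range(drop):
                tree.remove_arc(u, r)
    # suppress down to a phylogenetic tree on X
    changed = True
    while changed:
        changed = False
        for v in list(tree.g):
            if tree.indeg(v) == 1 and tree.outdeg(v) == 1:
                tree.suppress(v)
                changed = True
            elif tree.indeg(v) == 0 and tree.outdeg(v) == 1 and len(tree.g) > 1:
                tree.g.remove_node(v)
                changed = True
    return True, tree


def is_tree_child(net: Network) -> bool:
    """Every vertex reaches a leaf avoiding non-bead reticulations.

    The classical tree-child condition, extended to beaded networks by
    letting the escape path pass through bead reticulations (they have no
    hybridization reading).
    """
    good: dict[str, bool] = {}
    for v in reversed(net.topological_order()):
        if net.outdeg(v) == 0:
            good[v] = True
        else:
            good[v] = any(
                good[c]
                and not (net.indeg(c) == 2 and not net.is_bead_reticulation(c))
                for c in net.g.successors(v)
            )
    return all(good.values())


def _degree_multisets(n: int, r: int) -> tuple[list[tuple[str, int, int]], int] | None:
    """Vertex roles (id, indeg, outdeg) for a network on n leaves, r rets."""
    t = n + r - 2  # tree vertices forced by degree accounting
    if t < 0:
        return None
    vertices = [("R", 0, 2)]
    vertices += [(f"T{i}", 1, 2) for i in range(t)]
    vertices += [(f"H{i}", 2, 1) for i in range(r)]
    vertices += [(f"L{i}", 1, 0) for i in range(n)]
    arcs = 2 + 2 * t + r
    return vertices, arcs


def enumerate_realizations(
    p: PloidyProfile, max_reticulations: int
) -> list[Network]:
    """All realizations of a tiny profile, up to isomorphism.

    Exhaustive generation over degree-feasible arc assignments, filtered
    by validity and path counts.  Hard desk-scale guards: at most two
    taxa and three reticulations.
    """
    if p.n > 2 or max_reticulations > 3:
        raise ProfileError("enumeration guard: need n <= 2 and <= 3 reticulations")
    found: list[Network] = []
    target = p.as_dict()
    labels = list(p.labels)

    if p.n == 1 and p.components[0] == 1:
        found.append(Network.single_vertex(labels[0]))
        return found

    for r in range(max_reticulations + 1):
        roles = _degree_multisets(p.n, r)
        if roles is None:
            continue
        vertices, _ = roles
        indeg = {v: i for v, i, _ in vertices}
        outdeg = {v: o for v, _, o in vertices}
        heads = [v for v, i, _ in vertices if i > 0]

        def assign(idx: int, remaining: dict[str, int], arcs: list[tuple[str, str]]):
            if idx == len(heads):
                yield list(arcs)
                return
            v = heads[idx]
            tails = sorted(u for u, c in remaining.items() if c > 0 and u != v)
            for combo in itertools.combinations_with_replacement(tails, indeg[v]):
                cnt: dict[str, int] = {}
                for u in combo:
                    cnt[u] = cnt.get(u, 0) + 1
                if any(c > remaining[u] for u, c in cnt.items()):
                    continue
                if any(c > 2 for c in cnt.values()):
                    continue
                # multiplicity 2 only into reticulations
                if any(c == 2 and not v.startswith("H") for c in cnt.values()):
                    continue
                for u, c in cnt.items():
                    remaining[u] -= c
                arcs.extend((u, v) for u in combo)
                yield from assign(idx + 1, remaining, arcs)
                del arcs[len(arcs) - len(combo):]
                for u, c in cnt.items():
                    remaining[u] += c

        for arcset in assign(0, dict(outdeg), []):
            net = Network()
            for v, _, o in vertices:
                net.add_vertex(v)
            for i, lab in enumerate(labels):
                net.g.nodes[f"L{i}"]["label"] = lab
            ok = True
            for u, v in arcset:
                try:
                    net.add_arc(u, v)
                except NetworkError:
                    ok = False
                    break
            if not ok or not nx.is_directed_acyclic_graph(net.g):
                continue
            if not validate(net).ok:
                continue
            if count_paths(net) != target:
                continue
            if any(isomorphic(net, other) for other in found):
                continue
            found.append(net)
    return found
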