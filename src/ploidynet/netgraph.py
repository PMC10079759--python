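"""Rooted DAGs with beads: the network data model, validation and I/O.

A network here is a rooted directed acyclic multigraph in which every
non-root, non-leaf vertex is either a tree vertex (indegree 1, outdegree 2)
or a reticulation vertex (indegree 2, outdegree 1).  Unlike standard
phylogenetic networks, *beads* -- pairs of parallel arcs between a tree
vertex and a reticulation vertex -- are allowed; they model whole-genome
duplication (autopolyploidy), while non-bead reticulations model
hybridization (allopolyploidy).  A single labelled vertex with no arcs is
accepted as the degenerate network on one taxon.

Internally a :class:`Network` wraps a ``networkx.DiGraph`` whose edges
carry an integer ``mult`` attribute in {1, 2}; multiplicity 2 is a bead.
Leaf vertices carry a ``label`` attribute.  When ``mul`` is true the
network is multiple-labelled: distinct leaves may share a label.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator, Mapping

import networkx as nx

__all__ = [
    "Network",
    "NetworkError",
    "ValidationReport",
    "validate",
    "count_paths",
    "enumerate_root_leaf_paths",
    "reticulation_inventory",
    "isomorphic",
    "to_enewick",
    "from_enewick",
    "to_json",
    "from_json",
    "to_dot",
]


class NetworkError(ValueError):
    """Raised for structurally invalid networks or malformed input."""


class Network:
    """A rooted directed acyclic multigraph with beads.

    Vertex identifiers are opaque strings.  Construction-specific roles
    ("s_k", "h_i", ...) live in the node attribute ``role`` and carry no
    semantics.
    """

    def __init__(self, mul: bool = False) -> None:
        self.g = nx.DiGraph()
        self.mul = mul
        self._fresh = itertools.count(1)

    # -- construction helpers -------------------------------------------------

    def new_vertex(self, prefix: str = "v", role: str | None = None) -> str:
        while True:
            vid = f"{prefix}{next(self._fresh)}"
            if vid not in self.g:
                break
        self.g.add_node(vid)
        if role is not None:
            self.g.nodes[vid]["role"] = role
        return vid

    def add_vertex(self, vid: str, label: str | None = None, role: str | None = None) -> str:
        self.g.add_node(vid)
        if label is not None:
            self.g.nodes[vid]["label"] = label
        if role is not None:
            self.g.nodes[vid]["role"] = role
        return vid

    def add_arc(self, u: str, v: str) -> None:
        """Add one arc u->v, stacking onto a bead if the arc exists."""
        if self.g.has_edge(u, v):
            m = self.g[u][v]["mult"]
            if m >= 2:
                raise NetworkError(f"arc ({u},{v}) would exceed multiplicity 2")
            self.g[u][v]["mult"] = m + 1
        else:
            self.g.add_edge(u, v, mult=1)

    def remove_arc(self, u: str, v: str) -> None:
        """Remove one arc u->v (one strand of a bead if parallel)."""
        m = self.g[u][v]["mult"]
        if m > 1:
            self.g[u][v]["mult"] = m - 1
        else:
            self.g.remove_edge(u, v)

    def subdivide(self, u: str, v: str, prefix: str = "d", role: str | None = None) -> str:
        """Put a new vertex on one strand of arc (u, v); returns its id."""
        if not self.g.has_edge(u, v):
            raise NetworkError(f"no arc ({u},{v}) to subdivide")
        self.remove_arc(u, v)
        s = self.new_vertex(prefix, role=role)
        self.add_arc(u, s)
        self.add_arc(s, v)
        return s

    def suppress(self, v: str) -> tuple[str, str]:
        """Remove a vertex with indegree 1 and outdegree 1, merging its arcs."""
        if self.indeg(v) != 1 or self.outdeg(v) != 1:
            raise NetworkError(f"cannot suppress {v}: degrees ({self.indeg(v)},{self.outdeg(v)})")
        p = next(iter(self.g.predecessors(v)))
        c = next(iter(self.g.successors(v)))
        self.g.remove_node(v)
        self.add_arc(p, c)
        return p, c

    # -- basic accessors ------------------------------------------------------

    def indeg(self, v: str) -> int:
        return sum(d["mult"] for _, _, d in self.g.in_edges(v, data=True))

    def outdeg(self, v: str) -> int:
        return sum(d["mult"] for _, _, d in self.g.out_edges(v, data=True))

    @property
    def root(self) -> str:
        roots = [v for v in self.g if self.indeg(v) == 0]
        if len(roots) != 1:
            raise NetworkError(f"expected a unique root, found {sorted(roots)}")
        return roots[0]

    def leaves(self) -> list[str]:
        return sorted(v for v in self.g if self.outdeg(v) == 0 and self.indeg(v) >= 1) or (
            sorted(self.g) if len(self.g) == 1 else []
        )

    def label_of(self, v: str) -> str | None:
        return self.g.nodes[v].get("label")

    def leaf_labels(self) -> dict[str, str]:
        return {v: self.g.nodes[v]["label"] for v in self.leaves() if "label" in self.g.nodes[v]}

    def vertex_with_label(self, label: str) -> str:
        hits = [v for v in self.leaves() if self.label_of(v) == label]
        if len(hits) != 1:
            raise NetworkError(f"label {label!r} carried by {len(hits)} leaves")
        return hits[0]

    def reticulations(self) -> list[str]:
        return sorted(v for v in self.g if self.indeg(v) == 2 and self.outdeg(v) == 1)

    def is_bead_reticulation(self, v: str) -> bool:
        preds = list(self.g.predecessors(v))
        return (
            self.indeg(v) == 2
            and len(preds) == 1
            and self.g[preds[0]][v]["mult"] == 2
        )

    def beads(self) -> list[tuple[str, str]]:
        return sorted((u, v) for u, v, d in self.g.edges(data=True) if d["mult"] == 2)

    def arcs(self) -> list[tuple[str, str, int]]:
        return sorted((u, v, d["mult"]) for u, v, d in self.g.edges(data=True))

    def topological_order(self) -> list[str]:
        """Kahn's scheme with lexicographic tie-breaking (deterministic)."""
        return list(nx.lexicographical_topological_sort(self.g))

    def below(self, v: str) -> set[str]:
        """All vertices below v, including v itself."""
        return {v} | nx.descendants(self.g, v)

    def copy(self) -> "Network":
        other = Network(mul=self.mul)
        other.g = self.g.copy()
        return other

    def relabel_taxa(self, mapping: Mapping[str, str]) -> None:
        for v in self.g:
            lab = self.g.nodes[v].get("label")
            if lab is not None and lab in mapping:
                self.g.nodes[v]["label"] = mapping[lab]

    def __len__(self) -> int:
        return len(self.g)

    @classmethod
    def single_vertex(cls, label: str) -> "Network":
        """The degenerate network on one taxon: one labelled vertex, no arcs."""
        net = cls()
        net.add_vertex("v0", label=label)
        return net


@dataclass
class ValidationReport:
    ok: bool
    violations: list[tuple[str, str]]


def validate(net: Network) -> ValidationReport:
    """Check the degree/root/leaf/bead invariants; reports, never raises."""
    g = net.g
    bad: list[tuple[str, str]] = []
    if len(g) == 0:
        return ValidationReport(False, [("empty", "-")])
    if len(g) == 1:
        v = next(iter(g))
        if g.nodes[v].get("label") is None:
            bad.append(("single-vertex-unlabelled", v))
        return ValidationReport(not bad, bad)
    if not nx.is_directed_acyclic_graph(g):
        bad.append(("cyclic", "-"))
        return ValidationReport(False, bad)
    roots = [v for v in g if net.indeg(v) == 0]
    if len(roots) != 1:
        bad.append(("root-count", ",".join(sorted(roots))))
    else:
        if net.outdeg(roots[0]) != 2:
            bad.append(("root-outdegree", roots[0]))
    for u, v, d in g.edges(data=True):
        if d["mult"] > 2:
            bad.append(("triple-arc", f"({u},{v})"))
        elif d["mult"] == 2:
            # bead: tail a tree vertex (or root), head a reticulation
            if net.indeg(v) != 2 or net.outdeg(v) != 1:
                bad.append(("bead-head-degrees", v))
    labels_seen: list[str] = []
    for v in g:
        ind, outd = net.indeg(v), net.outdeg(v)
        if ind == 0:
            continue  # the root (or an extra root, reported via root-count)
        if outd == 0:
            if ind != 1:
                bad.append(("leaf-indegree", v))
            lab = g.nodes[v].get("label")
            if lab is None:
                bad.append(("leaf-unlabelled", v))
            else:
                labels_seen.append(lab)
        elif not ((ind, outd) == (1, 2) or (ind, outd) == (2, 1)):
            bad.append(("vertex-degrees", v))
    if not net.mul and len(labels_seen) != len(set(labels_seen)):
        bad.append(("label-not-injective", ",".join(sorted(labels_seen))))
    if len(roots) == 1 and nx.is_directed_acyclic_graph(g):
        reach = {roots[0]} | nx.descendants(g, roots[0])
        if reach != set(g):
            bad.append(("disconnected", ",".join(sorted(set(g) - reach))))
    return ValidationReport(not bad, bad)


def count_paths(net: Network) -> dict[str, int]:
    """Number of directed root-to-leaf paths per taxon label.

    Dynamic program over a topological order; a bead contributes factor 2.
    For multiple-labelled networks the counts of leaves sharing a label are
    summed.  This is the quantity a realization must match: the ploidy
    level of each taxon.
    """
    rep = validate(net)
    if not rep.ok:
        raise NetworkError(f"invalid network: {rep.violations}")
    if len(net.g) == 1:
        v = next(iter(net.g))
        return {net.g.nodes[v]["label"]: 1}
    counts: dict[str, int] = {}
    root = net.root
    acc = {root: 1}
    for v in net.topological_order():
        if v != root:
            acc[v] = sum(acc[u] * d["mult"] for u, _, d in net.g.in_edges(v, data=True))
        if net.outdeg(v) == 0:
            lab = net.g.nodes[v]["label"]
            counts[lab] = counts.get(lab, 0) + acc[v]
    return counts


def enumerate_root_leaf_paths(net: Network) -> dict[str, int]:
    """Brute-force path enumeration; independent oracle for count_paths.

    Walks every root-to-leaf path explicitly (parallel arcs walked twice).
    Exponential; intended for small fixtures only.
    """
    if len(net.g) == 1:
        v = next(iter(net.g))
        return {net.g.nodes[v]["label"]: 1}
    counts: dict[str, int] = {}
    root = net.root

    def walk(v: str) -> None:
        if net.outdeg(v) == 0:
            lab = net.g.nodes[v]["label"]
            counts[lab] = counts.get(lab, 0) + 1
            return
        for _, w, d in net.g.out_edges(v, data=True):
            for _ in range(d["mult"]):
                walk(w)

    walk(root)
    return counts


def reticulation_inventory(net: Network) -> list[tuple[str, bool]]:
    """All indegree-2 vertices with a flag marking bead membership."""
    return [(v, net.is_bead_reticulation(v)) for v in net.reticulations()]


# -- isomorphism --------------------------------------------------------------


def _node_match(a: dict, b: dict) -> bool:
    return a.get("label") == b.get("label") and a.get("_isroot") == b.get("_isroot")


def _edge_match(a: dict, b: dict) -> bool:
    return a["mult"] == b["mult"]


def isomorphic(n1: Network, n2: Network) -> bool:
    """Root-preserving, multiplicity- and label-respecting DAG isomorphism."""
    if len(n1.g) != len(n2.g):
        return False
    if len(n1.g) == 1:
        a = next(iter(n1.g)); b = next(iter(n2.g))
        return n1.g.nodes[a].get("label") == n2.g.nodes[b].get("label")
    g1, g2 = n1.g.copy(), n2.g.copy()
    g1.nodes[n1.root]["_isroot"] = True
    g2.nodes[n2.root]["_isroot"] = True
    gm = nx.algorithms.isomorphism.DiGraphMatcher(
        g1, g2, node_match=_node_match, edge_match=_edge_match
    )
    return gm.is_isomorphic()


def unfold_signature(net: Network) -> str:
    """Order-invariant string of the network's unfolding into a tree.

    Not injective across networks (sharing is lost), but a cheap invariant
    usable as a hash bucket for isomorphism-checked memoization.
    """
    if len(net.g) == 1:
        v = next(iter(net.g))
        return str(net.g.nodes[v].get("label"))
    memo: dict[str, str] = {}

    def enc(v: str) -> str:
        if v in memo:
            return memo[v]
        if net.outdeg(v) == 0:
            s = str(net.g.nodes[v].get("label"))
        else:
            parts: list[str] = []
            for _, w, d in net.g.out_edges(v, data=True):
                parts.extend([enc(w)] * d["mult"])
            s = "(" + ",".join(sorted(parts)) + ")"
        memo[v] = s
        return s

    return enc(net.root)


# -- extended Newick ----------------------------------------------------------


def to_enewick(net: Network) -> str:
    """Canonical extended-Newick serialization.

    Children are ordered lexicographically by their subtree string so that
    equal networks serialize identically; a reticulation appears once with
    its subtree as ``(...)#Hk`` and once as the bare reference ``#Hk``.  A
    bead serializes as the same ``#H`` child appearing twice under one
    parent.
    """
    rep = validate(net)
    if not rep.ok:
        raise NetworkError(f"refusing to serialize invalid network: {rep.violations}")
    if len(net.g) == 1:
        v = next(iter(net.g))
        return f"{net.g.nodes[v]['label']};"
    # hybrid numbers are assigned in emission order so the serialization
    # is independent of internal vertex identifiers
    hybrid_ids: dict[str, int] = {}

    full: dict[str, str] = {}

    def enc_full(v: str) -> str:
        # full (unfolded) encoding used only for deterministic ordering
        if v in full:
            return full[v]
        if net.outdeg(v) == 0:
            s = net.g.nodes[v].get("label", "")
        else:
            parts: list[str] = []
            for _, w, d in net.g.out_edges(v, data=True):
                parts.extend([enc_full(w)] * d["mult"])
            s = "(" + ",".join(sorted(parts)) + ")"
        full[v] = s
        return s

    enc_full(net.root)
    written: set[str] = set()

    def emit(v: str) -> str:
        if net.indeg(v) == 2:
            if v not in hybrid_ids:
                hybrid_ids[v] = len(hybrid_ids) + 1
            tag = f"#H{hybrid_ids[v]}"
            if v in written:
                return tag
            written.add(v)
            return _emit_sub(v) + tag
        return _emit_sub(v)

    def _emit_sub(v: str) -> str:
        if net.outdeg(v) == 0:
            return net.g.nodes[v].get("label", "")
        kids: list[tuple[str, str]] = []
        for _, w, d in net.g.out_edges(v, data=True):
            for _ in range(d["mult"]):
                kids.append((full[w], w))
        kids.sort(key=lambda t: t[0])
        return "(" + ",".join(emit(w) for _, w in kids) + ")"

    return emit(net.root) + ";"


_TOKEN = re.compile(r"\(|\)|,|;|[^(),;]+")


def from_enewick(text: str) -> Network:
    """Parse extended Newick with #H hybrid tags into a Network."""
    tokens = [t for t in _TOKEN.findall(text.strip()) if t.strip()]
    if not tokens or tokens[-1] != ";":
        raise NetworkError("eNewick must end with ';'")
    tokens = tokens[:-1]
    net = Network()
    hybrids: dict[str, str] = {}
    pos = 0

    def parse() -> str:
        nonlocal pos
        children: list[str] = []
        if pos < len(tokens) and tokens[pos] == "(":
            pos += 1
            while True:
                children.append(parse())
                if pos >= len(tokens):
                    raise NetworkError("unbalanced parentheses")
                if tokens[pos] == ",":
                    pos += 1
                    continue
                if tokens[pos] == ")":
                    pos += 1
                    break
                raise NetworkError(f"unexpected token {tokens[pos]!r} at {pos}")
        name = ""
        if pos < len(tokens) and tokens[pos] not in "(),;":
            name = tokens[pos]
            pos += 1
        hybrid = None
        if "#" in name:
            name, _, hybrid = name.partition("#")
        if hybrid is not None:
            if hybrid in hybrids:
                v = hybrids[hybrid]
            else:
                v = net.new_vertex("n")
                hybrids[hybrid] = v
        else:
            v = net.new_vertex("n")
        if name:
            net.g.nodes[v]["label"] = name
        for c in children:
            net.add_arc(v, c)
        return v

    parse()
    if pos != len(tokens):
        raise NetworkError(f"trailing tokens at position {pos}")
    for tag, v in hybrids.items():
        if net.indeg(v) < 2:
            raise NetworkError(f"hybrid referenced once: #{tag}")
    labels = [net.g.nodes[v].get("label") for v in net.leaves()]
    net.mul = len(labels) != len(set(labels))
    return net


# -- JSON graph ---------------------------------------------------------------


def to_json(net: Network) -> str:
    labels = {v: net.g.nodes[v]["label"] for v in net.g if "label" in net.g.nodes[v]}
    obj = {
        "vertices": sorted(net.g),
        "arcs": [[u, v, d["mult"]] for u, v, d in sorted(net.g.edges(data=True))],
        "root": next(iter(net.g)) if len(net.g) == 1 else net.root,
        "labels": labels,
        "mul": net.mul,
    }
    return json.dumps(obj, indent=2)


def from_json(text: str) -> Network:
    obj = json.loads(text)
    net = Network(mul=bool(obj.get("mul", False)))
    for v in obj["vertices"]:
        net.add_vertex(v)
    for u, v, m in obj["arcs"]:
        for _ in range(m):
            net.add_arc(u, v)
    for v, lab in obj.get("labels", {}).items():
        net.g.nodes[v]["label"] = lab
    return net


# -- DOT rendering ------------------------------------------------------------


def to_dot(net: Network, stamps: Mapping[str, Fraction] | None = None) -> str:
    """DOT digraph; reticulations drawn as squares.

    With *stamps*, vertices of equal time stamp are constrained to the same
    rank, so equal-stamp arcs render horizontally -- co-existing ancestral
    species line up.
    """
    lines = ["digraph N {", "  rankdir=TB;"]
    rets = set(net.reticulations())
    for v in sorted(net.g):
        lab = net.g.nodes[v].get("label")
        shape = "square" if v in rets else "circle"
        text = lab if lab is not None else ""
        lines.append(f'  "{v}" [shape={shape}, label="{text}"];')
    for u, v, d in sorted(net.g.edges(data=True)):
        for _ in range(d["mult"]):
            lines.append(f'  "{u}" -> "{v}";')
    if stamps:
        by_stamp: dict[Fraction, list[str]] = {}
        for v, t in stamps.items():
            by_stamp.setdefault(t, []).append(v)
        for t in sorted(by_stamp):
            group = " ".join(f'"{v}";' for v in sorted(by_stamp[t]))
            lines.append(f"  {{ rank=same; {group} }}")
    lines.append("}")
    return "\n".join(lines)
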