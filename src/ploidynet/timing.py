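"""Time-stamp maps: HGT-consistent labellings, verification, construction.

A time-stamp map assigns each vertex a non-negative time.  It is an
*HGT-consistent labelling* when

* (P1) time moves forward along every arc (weakly into reticulations,
  strictly otherwise);
* (P2) every non-leaf vertex has at least one strictly later child;
* (P3) every reticulation vertex *not in a bead* has precisely one parent
  with the same stamp -- the two ends of that arc co-existed, so the arc
  can be drawn horizontally.

The *weak* variant (P3') exempts at most one reticulation, provided its
parents are distinct and comparable (one below the other).  The verifier
is the sole authority here: both constructors' outputs are checked
against it in the test suite.

Stamps are exact rationals so that the equality tests in (P3) are exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Mapping, Sequence

import networkx as nx

from .netgraph import Network, NetworkError

__all__ = [
    "Strength",
    "LabellingReport",
    "verify_labelling",
    "label_core",
    "label_from_cherry_sequence",
    "horizontal_arcs",
]

TimeStampMap = dict[str, Fraction]


class Strength(str, Enum):
    HGT_CONSISTENT = "HGT_CONSISTENT"
    WEAK_HGT_CONSISTENT = "WEAK_HGT_CONSISTENT"
    NEITHER = "NEITHER"


@dataclass
class LabellingReport:
    p1_ok: bool
    p2_ok: bool
    #: non-bead reticulations with != 1 equal-stamp parent
    p3_violations: list[str]
    classification: Strength


def verify_labelling(net: Network, stamps: Mapping[str, Fraction]) -> LabellingReport:
    """Evaluate (P1), (P2), (P3)/(P3') exactly; classify the labelling."""
    missing = [v for v in net.g if v not in stamps]
    if missing:
        raise NetworkError(f"stamps missing for {sorted(missing)}")
    for v, t in stamps.items():
        if v in net.g and t < 0:
            raise NetworkError(f"negative stamp at {v}")
    if len(net.g) == 1:
        return LabellingReport(True, True, [], Strength.HGT_CONSISTENT)

    p1 = True
    for u, v, d in net.g.edges(data=True):
        if net.indeg(v) == 2:
            if stamps[u] > stamps[v]:
                p1 = False
        elif stamps[u] >= stamps[v]:
            p1 = False

    p2 = True
    for u in net.g:
        if net.outdeg(u) == 0:
            continue
        if not any(stamps[u] < stamps[v] for v in net.g.successors(u)):
            p2 = False

    violations: list[str] = []
    two_equal: set[str] = set()
    for v in net.reticulations():
        if net.is_bead_reticulation(v):
            continue
        parents = list(net.g.predecessors(v))
        equal = [u for u in parents if stamps[u] == stamps[v]]
        if len(equal) != 1:
            violations.append(v)
            if len(equal) == 2:
                two_equal.add(v)

    if p1 and p2 and not violations:
        cls = Strength.HGT_CONSISTENT
    elif p1 and p2 and len(violations) == 1 and not two_equal:
        v = violations[0]
        u1, u2 = list(net.g.predecessors(v))
        comparable = u2 in nx.descendants(net.g, u1) or u1 in nx.descendants(net.g, u2)
        cls = Strength.WEAK_HGT_CONSISTENT if comparable else Strength.NEITHER
    else:
        cls = Strength.NEITHER
    return LabellingReport(p1, p2, sorted(violations), cls)


def label_core(net: Network) -> TimeStampMap:
    """The labelling for a core network produced by ``build_B``.

    Unit stamps along the spine from the root to the big-ploidy leaf;
    each chain vertex s_j shares its stamp with its cross-arc partner
    s_j' (those arcs are horizontal), s_k shares the first bead
    reticulation's stamp, and w shares s_k' (making the caterpillar
    attachment horizontal too).  Caterpillar internals continue in unit
    steps; all unit-taxon leaves sit at a common later time.  The result
    verifies HGT_CONSISTENT for practical profiles and
    WEAK_HGT_CONSISTENT (sole violation at s_k') for arc-rich ones.
    """
    meta = net.g.graph
    if "spine" not in meta:
        raise NetworkError("label_core needs a network built by build_B")
    spine: Sequence[str] = meta["spine"]
    off_spine = {meta[key] for key in ("sk", "w") if key in meta}
    off_spine.update(meta.get("sj", {}).values())
    path = [v for v in spine if v not in off_spine]

    stamps: TimeStampMap = {}
    for idx, v in enumerate(path):
        stamps[v] = Fraction(idx)

    if "sk" in meta:
        stamps[meta["sk"]] = stamps["h1"]
    for j, sj in meta.get("sj", {}).items():
        stamps[sj] = stamps[meta["sjp"][j]]
    if "w" in meta:
        w = meta["w"]
        stamps[w] = stamps[meta["skp"]] if "skp" in meta else stamps["h1"]
        t = stamps[w]
        for wj in meta.get("cat_spine", []):
            t = t + 1
            stamps[wj] = t
        chi = t + 1
        for leaf, lab in net.leaf_labels().items():
            if leaf not in stamps:
                stamps[leaf] = chi
    missing = [v for v in net.g if v not in stamps]
    if missing:
        raise NetworkError(f"construction metadata incomplete; unstamped: {missing}")
    return stamps


def label_from_cherry_sequence(net: Network, seq, records=None) -> TimeStampMap:
    """Stamps for a network from a complete (weak) cherry sequence.

    The sequence is replayed forwards to learn which vertices each
    operation removes, then undone in reverse while stamps are assigned:
    vertices re-introduced later (closer to the leaves) get later times,
    the two suppressed vertices of an undone cutting operation share a
    stamp (their arc is the horizontal one of the new reticulate cherry),
    and an undone trimming places its exempt reticulation strictly later
    than both parents.  All taxa sit at a common final time.
    """
    from .cherries import replay_with_records

    if records is None:
        records = replay_with_records(net, seq)
    stamps: TimeStampMap = {}
    m = Fraction(0)  # max internal stamp so far

    def nxt() -> Fraction:
        nonlocal m
        m += 1
        return m

    for rec in reversed(records):
        kind = rec["kind"]
        if kind == "REDUCE":
            stamps[rec["p"]] = nxt()
        elif kind == "CUT":
            t = nxt()
            stamps[rec["pa"]] = t
            stamps[rec["pb"]] = t
        elif kind == "SIMP":
            stamps[rec["tb"]] = nxt()
            stamps[rec["hb"]] = nxt()
        elif kind == "TRIM":
            if rec["op"].tag in ("i", "ii-a"):
                qp = rec["q1_parent"]
                lo = stamps[qp] if qp is not None else Fraction(0)
                hi_v = rec["q1_child"]
                if net.outdeg(hi_v) == 0:
                    stamps[rec["q1"]] = nxt()
                elif net.indeg(hi_v) == 2:
                    # re-adding q1 above a reticulation strips that child of
                    # its previous (P3) partner; the new arc is horizontal
                    stamps[rec["q1"]] = stamps[hi_v]
                else:
                    hi = stamps[hi_v]
                    if lo >= hi:
                        raise NetworkError("cannot place trimmed vertex in time")
                    stamps[rec["q1"]] = (lo + hi) / 2
                stamps[rec["p"]] = nxt()
            else:  # ii-b
                lo, hi = stamps[rec["q1"]], stamps[rec["p"]]
                if lo >= hi:
                    raise NetworkError("cannot place trimmed vertices in time")
                step = (hi - lo) / 3
                stamps[rec["q"]] = lo + step
                stamps[rec["q2"]] = lo + 2 * step
        else:  # pragma: no cover
            raise NetworkError(f"unknown record kind {kind}")

    chi = m + 1
    for v in net.g:
        if v not in stamps:
            if net.outdeg(v) == 0:
                stamps[v] = chi
            else:
                raise NetworkError(f"sequence did not account for vertex {v}")
    return stamps


def horizontal_arcs(
    net: Network, stamps: Mapping[str, Fraction], require_valid: bool = True
) -> list[tuple[str, str]]:
    """All arcs whose end vertices share a stamp (co-existing ancestors)."""
    if require_valid:
        rep = verify_labelling(net, stamps)
        if rep.classification is Strength.NEITHER:
            raise NetworkError("labelling does not verify; no horizontal reading")
    return sorted(
        (u, v) for u, v, _ in net.g.edges(data=True) if stamps[u] == stamps[v]
    )
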