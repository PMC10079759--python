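"""Cherry-modification operations and orchard analysis.

A network is reduced towards a single vertex by repeatedly applying

* ``reduce(a, b)`` -- delete leaf b of the cherry {a, b};
* ``cut(a, b)``    -- delete the reticulation arc of the reticulate
  cherry {a, b} with reticulation leaf b;
* ``simp(a)``      -- when leaf a hangs from a bead reticulation, delete
  one strand of that bead;
* ``trim(a)``      -- when leaf a hangs from a non-bead reticulation p in
  one of the recognized degenerate-cherry configurations, delete the arc
  feeding p from its upper parent (or one strand of the grandparent
  bead).

A network admitting a complete sequence of the first three is an
*orchard*; allowing ``trim`` as well gives a *weak orchard*.  Operations
are identified by leaf labels (plus a structural tag for trim), so a
sequence found on one network replays on any label-isomorphic copy.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .netgraph import Network, NetworkError, unfold_signature, isomorphic
from .profiles import Case, PloidyProfile, simplification_sequence

__all__ = [
    "OpKind",
    "CherryOperation",
    "OrchardStatus",
    "OrchardCertificate",
    "find_applicable",
    "apply_operation",
    "replay",
    "replay_with_records",
    "orchard_status",
    "traceback_cherry_sequence",
]


class OpKind(str, Enum):
    CUT = "CUT"
    REDUCE = "REDUCE"
    SIMP = "SIMP"
    TRIM = "TRIM"


#: deterministic search/application order
_KIND_ORDER = {OpKind.CUT: 0, OpKind.REDUCE: 1, OpKind.SIMP: 2, OpKind.TRIM: 3}


@dataclass(frozen=True)
class CherryOperation:
    kind: OpKind
    a: str
    b: str | None = None
    #: structural case of a trim: "i" (one parent is a bead reticulation),
    #: "ii-a" (triangle above p), "ii-b" (bead above p)
    tag: str | None = None

    def sort_key(self) -> tuple:
        return (_KIND_ORDER[self.kind], self.a, self.b or "", self.tag or "")

    def rename(self, alias: dict[str, str]) -> "CherryOperation":
        return CherryOperation(
            self.kind,
            alias.get(self.a, self.a),
            alias.get(self.b, self.b) if self.b is not None else None,
            self.tag,
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        args = self.a if self.b is None else f"{self.a},{self.b}"
        return f"{self.kind.value.lower()}({args})"


class OrchardStatus(str, Enum):
    ORCHARD = "ORCHARD"
    WEAK_ORCHARD = "WEAK_ORCHARD"
    NEITHER = "NEITHER"


@dataclass
class OrchardCertificate:
    status: OrchardStatus
    sequence: list[CherryOperation]


def _leaf_map(net: Network) -> dict[str, str]:
    return {net.g.nodes[v]["label"]: v for v in net.leaves() if "label" in net.g.nodes[v]}


def find_applicable(net: Network) -> list[CherryOperation]:
    """All operations applicable to *net*, deterministically ordered."""
    if len(net.g) <= 1:
        return []
    ops: set[CherryOperation] = set()
    leaves = _leaf_map(net)
    parent_of = {lab: next(iter(net.g.predecessors(v))) for lab, v in leaves.items()}

    by_parent: dict[str, list[str]] = {}
    for lab, p in parent_of.items():
        by_parent.setdefault(p, []).append(lab)
    for labs in by_parent.values():
        if len(labs) == 2:
            a, b = sorted(labs)
            ops.add(CherryOperation(OpKind.REDUCE, a, b))
            ops.add(CherryOperation(OpKind.REDUCE, b, a))

    for lb, vb in leaves.items():
        pb = parent_of[lb]
        if net.indeg(pb) == 2 and not net.is_bead_reticulation(pb):
            for pa in net.g.predecessors(pb):
                for la in by_parent.get(pa, []):
                    if la != lb:
                        ops.add(CherryOperation(OpKind.CUT, la, lb))

    for la, va in leaves.items():
        p = parent_of[la]
        if net.is_bead_reticulation(p):
            ops.add(CherryOperation(OpKind.SIMP, la))
        elif net.indeg(p) == 2:
            q1, q2 = sorted(net.g.predecessors(p))
            for u1, u2 in ((q1, q2), (q2, q1)):
                # (ii-a) a triangle: q above both parents, arc u1 -> u2
                if net.g.has_edge(u1, u2) and (
                    set(net.g.predecessors(u1)) & set(net.g.predecessors(u2))
                ):
                    ops.add(CherryOperation(OpKind.TRIM, la, tag="ii-a"))
                # (ii-b) u1 above a bead whose reticulation is u2
                for q in net.g.successors(u1):
                    if net.g.has_edge(q, u2) and net.g[q][u2]["mult"] == 2:
                        ops.add(CherryOperation(OpKind.TRIM, la, tag="ii-b"))
            b1, b2 = net.is_bead_reticulation(q1), net.is_bead_reticulation(q2)
            if b1 != b2:
                ops.add(CherryOperation(OpKind.TRIM, la, tag="i"))
    return sorted(ops, key=CherryOperation.sort_key)


def _collapse_root_if_needed(net: Network, v: str) -> bool:
    """Collapse a root left with a single outgoing arc onto its child."""
    if net.indeg(v) == 0 and net.outdeg(v) == 1 and len(net.g) > 1:
        net.g.remove_node(v)
        return True
    return False


def _apply(net: Network, op: CherryOperation) -> tuple[Network, dict]:
    net = net.copy()
    leaves = _leaf_map(net)
    rec: dict = {"kind": op.kind.value, "op": op}

    if op.kind is OpKind.REDUCE:
        if op.a not in leaves or op.b not in leaves:
            raise NetworkError(f"{op}: leaves absent")
        va, vb = leaves[op.a], leaves[op.b]
        p = next(iter(net.g.predecessors(vb)))
        if p != next(iter(net.g.predecessors(va))):
            raise NetworkError(f"{op}: not a cherry")
        net.remove_arc(p, vb)
        net.g.remove_node(vb)
        rec["b"] = vb
        rec["p"] = p
        if not _collapse_root_if_needed(net, p):
            net.suppress(p)
        return net, rec

    if op.kind is OpKind.CUT:
        if op.a not in leaves or op.b not in leaves:
            raise NetworkError(f"{op}: leaves absent")
        va, vb = leaves[op.a], leaves[op.b]
        pb = next(iter(net.g.predecessors(vb)))
        pa = next(iter(net.g.predecessors(va)))
        if not (net.indeg(pb) == 2 and not net.is_bead_reticulation(pb)
                and net.g.has_edge(pa, pb)):
            raise NetworkError(f"{op}: not a reticulate cherry")
        net.remove_arc(pa, pb)
        net.suppress(pa)
        net.suppress(pb)
        rec["pa"] = pa
        rec["pb"] = pb
        return net, rec

    if op.kind is OpKind.SIMP:
        va = leaves[op.a]
        hb = next(iter(net.g.predecessors(va)))
        if not net.is_bead_reticulation(hb):
            raise NetworkError(f"{op}: parent is not a bead reticulation")
        tb = next(iter(net.g.predecessors(hb)))
        net.remove_arc(tb, hb)
        net.suppress(hb)
        if not _collapse_root_if_needed(net, tb):
            net.suppress(tb)
        rec["tb"] = tb
        rec["hb"] = hb
        return net, rec

    if op.kind is OpKind.TRIM:
        va = leaves[op.a]
        p = next(iter(net.g.predecessors(va)))
        if not (net.indeg(p) == 2 and not net.is_bead_reticulation(p)):
            raise NetworkError(f"{op}: parent is not a non-bead reticulation")
        q1, q2 = sorted(net.g.predecessors(p))
        if op.tag in ("i", "ii-a"):
            upper = None
            if op.tag == "i":
                b1, b2 = net.is_bead_reticulation(q1), net.is_bead_reticulation(q2)
                if b1 == b2:
                    raise NetworkError(f"{op}: case (i) shape absent")
                upper = q2 if b1 else q1  # delete the non-bead parent's arc
            else:
                for u1, u2 in ((q1, q2), (q2, q1)):
                    if net.g.has_edge(u1, u2) and (
                        set(net.g.predecessors(u1)) & set(net.g.predecessors(u2))
                    ):
                        upper = u1
                        break
                if upper is None:
                    raise NetworkError(f"{op}: case (ii-a) shape absent")
            net.remove_arc(upper, p)
            rec["q1"] = upper
            rec["p"] = p
            if _collapse_root_if_needed(net, upper):
                rec["q1_parent"] = None
                rec["q1_child"] = net.root
            else:
                q1p, q1c = net.suppress(upper)
                rec["q1_parent"] = q1p
                rec["q1_child"] = q1c
            net.suppress(p)
            return net, rec
        if op.tag == "ii-b":
            found = None
            for u1, u2 in ((q1, q2), (q2, q1)):
                for q in net.g.successors(u1):
                    if net.g.has_edge(q, u2) and net.g[q][u2]["mult"] == 2:
                        found = (u1, q, u2)
                        break
                if found:
                    break
            if found is None:
                raise NetworkError(f"{op}: case (ii-b) shape absent")
            u1, q, u2 = found
            net.remove_arc(q, u2)
            net.suppress(q)
            net.suppress(u2)
            rec["q1"] = u1
            rec["q"] = q
            rec["q2"] = u2
            rec["p"] = p
            return net, rec
    raise NetworkError(f"unknown operation {op}")  # pragma: no cover


def apply_operation(net: Network, op: CherryOperation) -> Network:
    """Apply a single cherry-modification operation; returns a new network."""
    out, _ = _apply(net, op)
    return out


def replay(net: Network, seq: list[CherryOperation]) -> Network:
    """Apply a whole sequence; returns the final network."""
    cur = net
    for op in seq:
        cur, _ = _apply(cur, op)
    return cur


def replay_with_records(net: Network, seq: list[CherryOperation]) -> list[dict]:
    """Replay, returning per-operation structural records for stamping.

    Raises unless the sequence is complete (ends in a single vertex).
    """
    cur = net
    records = []
    for op in seq:
        cur, rec = _apply(cur, op)
        records.append(rec)
    if len(cur.g) != 1:
        raise NetworkError("sequence is not complete: more than one vertex remains")
    return records


def orchard_status(net: Network, allow_trim: bool = False) -> OrchardCertificate:
    """Decide (weak-)orchard status by memoized backtracking search.

    Trim-free reducibility is tried first, so an ORCHARD verdict is never
    masked by an accidental early trim.  Memoization buckets states by an
    unfolding signature and resolves collisions with exact isomorphism.
    """

    def search(start: Network, use_trim: bool) -> list[CherryOperation] | None:
        memo: dict[tuple, list] = {}

        def rec(cur: Network) -> list[CherryOperation] | None:
            if len(cur.g) == 1:
                return []
            key = (unfold_signature(cur), len(cur.g))
            for known, result in memo.get(key, []):
                if isomorphic(cur, known):
                    return result
            out: list[CherryOperation] | None = None
            for op in find_applicable(cur):
                if op.kind is OpKind.TRIM and not use_trim:
                    continue
                try:
                    child, _ = _apply(cur, op)
                except NetworkError:
                    continue
                sub = rec(child)
                if sub is not None:
                    out = [op] + sub
                    break
            memo.setdefault(key, []).append((cur, out))
            return out

        return rec(start)

    seq = search(net, use_trim=False)
    if seq is not None:
        return OrchardCertificate(OrchardStatus.ORCHARD, seq)
    if allow_trim:
        seq = search(net, use_trim=True)
        if seq is not None:
            return OrchardCertificate(OrchardStatus.WEAK_ORCHARD, seq)
    return OrchardCertificate(OrchardStatus.NEITHER, [])


def traceback_cherry_sequence(p: PloidyProfile) -> OrchardCertificate:
    """Certificate for N(m) read off the simplification sequence directly.

    Each simplification step corresponds to one cherry operation on N(m)
    (REMOVE_EQUAL to a reduce, the two alpha > 0 cases to a cut); the
    remaining core network is handled by a searched sequence.  No search
    is needed for the traceback part.  The status is ORCHARD exactly when
    the core sequence needs no trim, which happens when the terminal
    element is practical (or degenerate).
    """
    from .corenet import build_B

    seq = simplification_sequence(p)
    ops: list[CherryOperation] = []
    alias: dict[str, str] = {lab: lab for lab in p.labels}
    for step in seq.steps:
        a = alias[step.pred_second]
        b = alias[step.pred_first]
        if step.case is Case.REMOVE_EQUAL:
            ops.append(CherryOperation(OpKind.REDUCE, a, b))
        else:
            ops.append(CherryOperation(OpKind.CUT, a, b))
            if step.case is Case.REMOVE_INSERT:
                assert step.inserted_label is not None
                alias[step.inserted_label] = b
    term = seq.terminal
    if term.degenerate:
        core_cert = OrchardCertificate(OrchardStatus.ORCHARD, [])
    else:
        core = build_B(term)
        core_cert = orchard_status(core, allow_trim=True)
    if core_cert.status is OrchardStatus.NEITHER:
        return OrchardCertificate(OrchardStatus.NEITHER, [])
    ops.extend(op.rename(alias) for op in core_cert.sequence)
    return OrchardCertificate(core_cert.status, ops)
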