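"""Ploidy profiles and their simplification sequences.

A ploidy profile records, for each taxon in a polyploid dataset, its ploidy
level (the number of complete chromosome-set copies it carries).  Profiles
are kept as descending vectors of positive integers, each component indexed
by a taxon label.  The central algorithm here is the *simplification
sequence*: a profile is iteratively reduced via the difference ``alpha`` of
its two largest components until a *simple* profile (one component >= 2,
all others 1) remains.  The sequence, together with a per-step record of
which reduction case fired, drives the traceback construction of a
realizing network (see :mod:`ploidynet.realize`).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PloidyProfile",
    "BinaryRepresentation",
    "Case",
    "SimplificationStep",
    "SimplificationSequence",
    "ProfileError",
    "normalize",
    "classify",
    "binary_representation",
    "simplify_step",
    "simplification_sequence",
    "halve",
    "read_profile_file",
    "sequence_to_json",
]


class ProfileError(ValueError):
    """Raised for malformed profiles or misapplied profile operations."""


# reserved namespace for components inserted during simplification; user
# taxa must not use it so the renaming bookkeeping stays reversible
FRESH_PREFIX = "_s"


@dataclass(frozen=True)
class PloidyProfile:
    """A descending vector of positive ploidy levels with taxon labels.

    ``components[i]`` is the ploidy level of taxon ``labels[i]``.
    """

    components: tuple[int, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.components) != len(self.labels):
            raise ProfileError(
                f"{len(self.components)} components but {len(self.labels)} labels"
            )
        if not self.components:
            raise ProfileError("a ploidy profile has at least one component")
        for m in self.components:
            if not isinstance(m, int) or m < 1:
                raise ProfileError(f"ploidy levels are positive integers, got {m!r}")
        for a, b in zip(self.components, self.components[1:]):
            if a < b:
                raise ProfileError(f"components not descending: {self.components}")
        if len(set(self.labels)) != len(self.labels):
            raise ProfileError(f"duplicate taxon labels in {self.labels}")

    @property
    def n(self) -> int:
        return len(self.components)

    @property
    def simple(self) -> bool:
        return self.components[0] >= 2 and all(m == 1 for m in self.components[1:])

    @property
    def strictly_simple(self) -> bool:
        return self.simple and self.n == 1

    @property
    def degenerate(self) -> bool:
        """The one-taxon profile (1), realized by a single-vertex network."""
        return self.n == 1 and self.components[0] == 1

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.labels, self.components))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return "(" + ",".join(map(str, self.components)) + ")"


@dataclass(frozen=True)
class BinaryRepresentation:
    """Strictly decreasing exponent vector of a powers-of-two decomposition.

    For ``m = sum(2**e for e in exponents)`` this is the vector
    ``(i_1, ..., i_k)`` with ``i_1 > i_2 > ... > i_k >= 0``; e.g. 77 ->
    (6, 3, 2, 0).  Unlike the bit-wise representation, zeros are skipped.
    """

    exponents: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.exponents:
            raise ProfileError("empty binary representation")
        for a, b in zip(self.exponents, self.exponents[1:]):
            if a <= b:
                raise ProfileError(f"exponents not strictly decreasing: {self.exponents}")
        if self.exponents[-1] < 0:
            raise ProfileError("negative exponent")

    @property
    def k(self) -> int:
        return len(self.exponents)

    @property
    def value(self) -> int:
        return sum(2**e for e in self.exponents)


class Case(str, Enum):
    """Which reduction rule produced a simplification step.

    With ``alpha = m1 - m2`` on the current profile:

    * ``REMOVE_EQUAL``  -- alpha == 0: drop the first component.
    * ``SUBTRACT``      -- alpha > m2: replace the first component by alpha.
    * ``REMOVE_INSERT`` -- 0 < alpha <= m2: drop the first component and
      insert alpha (freshly labelled) at its descending-order position.
    """

    REMOVE_EQUAL = "REMOVE_EQUAL"
    SUBTRACT = "SUBTRACT"
    REMOVE_INSERT = "REMOVE_INSERT"


@dataclass(frozen=True)
class SimplificationStep:
    case: Case
    alpha: int
    #: taxon indexing the predecessor's first (largest) component
    pred_first: str = ""
    #: taxon indexing the predecessor's second component
    pred_second: str = ""
    #: 1-based position of the inserted component in the successor profile
    #: (REMOVE_INSERT only).
    inserted_index: int | None = None
    #: fresh label given to the inserted component (REMOVE_INSERT only)
    inserted_label: str | None = None
    #: successor label -> predecessor label for surviving taxa.  Labels are
    #: carried through by identity here; the fresh label of an inserted
    #: component has no preimage and is absent from the map.
    label_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.inserted_index is not None) != (self.case is Case.REMOVE_INSERT):
            raise ProfileError("inserted_index present iff case is REMOVE_INSERT")
        if (self.inserted_label is not None) != (self.case is Case.REMOVE_INSERT):
            raise ProfileError("inserted_label present iff case is REMOVE_INSERT")


@dataclass(frozen=True)
class SimplificationSequence:
    """The full reduction trace of a profile down to its terminal element."""

    profiles: tuple[PloidyProfile, ...]
    steps: tuple[SimplificationStep, ...]

    def __post_init__(self) -> None:
        if len(self.steps) != len(self.profiles) - 1:
            raise ProfileError("need exactly one step between consecutive profiles")

    @property
    def initial(self) -> PloidyProfile:
        return self.profiles[0]

    @property
    def terminal(self) -> PloidyProfile:
        return self.profiles[-1]

    def __len__(self) -> int:
        return len(self.profiles)


def normalize(
    raw_components: Sequence[int], raw_labels: Sequence[str] | None = None
) -> PloidyProfile:
    """Sort components descending, permuting labels consistently.

    The sort is stable: equal components keep their input label order.
    When *raw_labels* is omitted, labels ``x1..xn`` are generated for the
    input order before sorting.
    """
    if raw_labels is None:
        raw_labels = [f"x{i + 1}" for i in range(len(raw_components))]
    if len(raw_components) != len(raw_labels):
        raise ProfileError("components and labels differ in length")
    order = sorted(range(len(raw_components)), key=lambda i: -raw_components[i])
    return PloidyProfile(
        components=tuple(raw_components[i] for i in order),
        labels=tuple(raw_labels[i] for i in order),
    )


def classify(p: PloidyProfile) -> dict[str, bool]:
    """Classification flags controlling which time labelling B(m) admits.

    ``practical`` profiles (simple non-strict, or a single power of two)
    yield a core network with a full HGT-consistent labelling; ``arc_rich``
    ones (single component whose binary representation has length >= 2)
    only a weak one.
    """
    simple = p.simple
    strictly = p.strictly_simple
    arc_rich = strictly and binary_representation(p.components[0]).k >= 2
    power_of_two = p.components[0] >= 2 and (p.components[0] & (p.components[0] - 1)) == 0
    practical = (simple and not strictly) or (p.n == 1 and power_of_two)
    return {
        "simple": simple,
        "strictly_simple": strictly,
        "practical": practical,
        "arc_rich": arc_rich,
    }


def binary_representation(m: int) -> BinaryRepresentation:
    """Decreasing powers-of-two decomposition of ``m >= 1``."""
    if not isinstance(m, int) or m < 1:
        raise ProfileError(f"need a positive integer, got {m!r}")
    exps = [e for e in range(m.bit_length() - 1, -1, -1) if m >> e & 1]
    return BinaryRepresentation(tuple(exps))


def _fresh_label(existing: Iterable[str], counter: list[int]) -> str:
    taken = set(existing)
    while True:
        counter[0] += 1
        cand = f"{FRESH_PREFIX}{counter[0]}"
        if cand not in taken:
            return cand


def simplify_step(
    p: PloidyProfile, _counter: list[int] | None = None
) -> tuple[PloidyProfile, SimplificationStep]:
    """One reduction of a non-simple profile; returns successor and record."""
    if p.simple or p.degenerate:
        raise ProfileError(f"cannot simplify the simple/degenerate profile {p}")
    counter = _counter if _counter is not None else [0]
    m1, m2 = p.components[0], p.components[1]
    alpha = m1 - m2
    if alpha == 0:
        succ = PloidyProfile(p.components[1:], p.labels[1:])
        step = SimplificationStep(
            Case.REMOVE_EQUAL,
            alpha=0,
            pred_first=p.labels[0],
            pred_second=p.labels[1],
            label_map={lab: lab for lab in succ.labels},
        )
    elif alpha > m2:
        succ = PloidyProfile((alpha,) + p.components[1:], p.labels)
        step = SimplificationStep(
            Case.SUBTRACT,
            alpha=alpha,
            pred_first=p.labels[0],
            pred_second=p.labels[1],
            label_map={lab: lab for lab in p.labels},
        )
    else:
        # drop m1, insert alpha directly after the last occurrence of alpha
        # (or at the unique descending-order slot when alpha is absent)
        a_comp = list(p.components[1:])
        a_lab = list(p.labels[1:])
        pos = len(a_comp)
        for i in range(len(a_comp) - 1, -1, -1):
            if a_comp[i] >= alpha:
                pos = i + 1
                break
        else:
            pos = 0
        fresh = _fresh_label(p.labels, counter)
        a_comp.insert(pos, alpha)
        a_lab.insert(pos, fresh)
        succ = PloidyProfile(tuple(a_comp), tuple(a_lab))
        step = SimplificationStep(
            Case.REMOVE_INSERT,
            alpha=alpha,
            pred_first=p.labels[0],
            pred_second=p.labels[1],
            inserted_index=pos + 1,
            inserted_label=fresh,
            label_map={lab: lab for lab in succ.labels if lab != fresh},
        )
    return succ, step


def simplification_sequence(p: PloidyProfile) -> SimplificationSequence:
    """Iterate :func:`simplify_step` until a simple profile is reached.

    A simple (or degenerate ``(1)``) input yields the one-element sequence.
    Termination is guaranteed: every step strictly decreases the component
    sum.
    """
    profiles = [p]
    steps: list[SimplificationStep] = []
    counter = [0]
    cur = p
    while not (cur.simple or cur.degenerate):
        cur, step = simplify_step(cur, counter)
        profiles.append(cur)
        steps.append(step)
    return SimplificationSequence(tuple(profiles), tuple(steps))


def halve(p: PloidyProfile) -> PloidyProfile:
    """Divide every component by two (all must be even); labels preserved.

    The inverse of prepending a bead above the root of a realization: an
    all-even profile signals an autopolyploidization at the last common
    ancestor, accounting for the shared factor of two.
    """
    for m in p.components:
        if m % 2:
            raise ProfileError(f"component {m} is odd; cannot halve {p}")
    return PloidyProfile(tuple(m // 2 for m in p.components), p.labels)


def read_profile_file(path: str | Path) -> PloidyProfile:
    """Read a two-column ``taxon,ploidy`` text/CSV file (header optional)."""
    rows: list[tuple[str, int]] = []
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "," if "," in sample else ("\t" if "\t" in sample else None)
        reader = csv.reader(fh, delimiter=delim) if delim else (
            [ln.split() for ln in fh if ln.strip()]
        )
        for rec in reader:
            rec = [c.strip() for c in rec if c.strip()]
            if not rec:
                continue
            if len(rec) != 2:
                raise ProfileError(f"expected two columns, got {rec}")
            try:
                rows.append((rec[0], int(rec[1])))
            except ValueError:
                if rows:
                    raise ProfileError(f"non-integer ploidy level {rec[1]!r}")
                # header line
    if not rows:
        raise ProfileError(f"no profile rows found in {path}")
    labels, comps = zip(*rows)
    return normalize(list(comps), list(labels))


def sequence_to_json(seq: SimplificationSequence) -> str:
    """Serialize a simplification sequence as a JSON array of records."""
    out = []
    for i, prof in enumerate(seq.profiles):
        rec: dict[str, object] = {
            "components": list(prof.components),
            "labels": list(prof.labels),
        }
        if i < len(seq.steps):
            step = seq.steps[i]
            rec["case"] = step.case.value
            rec["alpha"] = step.alpha
            rec["inserted_index"] = step.inserted_index
        out.append(rec)
    return json.dumps(out, indent=2)
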