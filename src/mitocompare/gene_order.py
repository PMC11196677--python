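"""Gene-order comparison: canonical circular orders, breakpoint distance and a
breadth-first search for a minimal rearrangement scenario.

The operation model is {contiguous-block relocation (internal order kept),
pairwise element swap}; inversions can be enabled but are off by default. BFS
explores scenarios level by level, so the first scenario reaching the target
is minimal within the model. States are pruned with the admissible bound
ceil(breakpoints / 4): a relocation changes at most 3 circular adjacencies and
a swap at most 4, so a state whose breakpoint distance to the target exceeds
4x the remaining depth cannot reach it.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

from .io import AnnotatedGenome

Element = tuple[str, str]  # (label, '+'|'-')


@dataclass
class GeneOrder:
    elements: list[Element]
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("empty gene order")
        labels = [lab for lab, _ in self.elements]
        if len(labels) != len(set(labels)):
            raise ValueError("gene-order labels must be unique")
        self.elements = [(str(lab), s) for lab, s in self.elements]
        if any(s not in "+-" for _, s in self.elements):
            raise ValueError("element strands must be '+' or '-'")

    def labels(self) -> set[str]:
        return {lab for lab, _ in self.elements}


@dataclass
class RearrangementScenario:
    ops: list[dict]
    achieved: bool
    source: list[Element] = field(default_factory=list)
    target: list[Element] = field(default_factory=list)
    dropped_labels: list[str] = field(default_factory=list)

    @property
    def op_count(self) -> int:
        return len(self.ops)

    def to_json(self) -> str:
        return json.dumps({
            "achieved": self.achieved, "op_count": self.op_count,
            "ops": self.ops,
            "source": ["".join(e[::-1]) for e in self.source],
            "target": ["".join(e[::-1]) for e in self.target],
            "dropped_labels": self.dropped_labels,
        }, indent=2)


# ---------------------------------------------------------------------------
# Order extraction

def _flip(elements: tuple[Element, ...]) -> tuple[Element, ...]:
    return tuple((lab, "+" if s == "-" else "-") for lab, s in reversed(elements))


def canonical_order(
    genome: AnnotatedGenome,
    anchor: str = "cox1",
    restrict_to: set[str] | None = None,
) -> GeneOrder:
    """Feature order around the circle, rotated to start at ``anchor`` on the
    plus strand (the whole order is strand-flipped first if the anchor lies on
    the minus strand), optionally restricted to a label subset."""
    feats = [f for f in genome.features if f.kind != "noncoding"]
    feats.sort(key=lambda f: f.start)
    elems: list[Element] = [(f.name, f.strand) for f in feats]
    if restrict_to is not None:
        elems = [e for e in elems if e[0] in restrict_to]
    labels = [lab for lab, _ in elems]
    if anchor not in labels:
        raise KeyError(f"anchor {anchor!r} not among features of {genome.sequence.id}")
    t = tuple(elems)
    i = labels.index(anchor)
    if t[i][1] == "-":
        t = _flip(t)
        i = [lab for lab, _ in t].index(anchor)
    t = t[i:] + t[:i]
    return GeneOrder(elements=list(t), circular=genome.sequence.topology == "circular")


def read_order(path) -> GeneOrder:
    """Read a plain-text order: one signed label per line (or one tab-separated
    line); a leading '-' marks the minus strand."""
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise ValueError(f"{path}: empty order file")
    elems = [(t[1:], "-") if t.startswith("-") else (t, "+") for t in tokens]
    return GeneOrder(elements=elems)


def write_order(order: GeneOrder, path) -> None:
    with open(path, "w") as fh:
        for lab, s in order.elements:
            fh.write(("-" if s == "-" else "") + lab + "\n")


# ---------------------------------------------------------------------------
# Breakpoint distance

def _adjacencies(elements: tuple[Element, ...], circular: bool) -> set[frozenset]:
    """Unordered, strand-aware adjacency set. The adjacency (a>, b>) read on
    the other strand is (b<, a<); both spellings canonicalise identically."""
    n = len(elements)
    pairs = [(elements[i], elements[(i + 1) % n])
             for i in range(n if circular else n - 1)]
    out = set()
    for x, y in pairs:
        alt = ((y[0], "+" if y[1] == "-" else "-"), (x[0], "+" if x[1] == "-" else "-"))
        out.add((x, y) if (x, y) <= alt else alt)
    return out


def _shared(a: GeneOrder, b: GeneOrder) -> tuple[tuple[Element, ...], tuple[Element, ...], list[str]]:
    shared = a.labels() & b.labels()
    dropped = sorted((a.labels() | b.labels()) - shared)
    ea = tuple(e for e in a.elements if e[0] in shared)
    eb = tuple(e for e in b.elements if e[0] in shared)
    if not ea:
        raise ValueError("no shared labels between orders")
    return ea, eb, dropped


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of adjacencies of ``a`` absent from ``b`` (labels restricted to
    the shared set first)."""
    ea, eb, _ = _shared(a, b)
    circ = a.circular and b.circular
    return len(_adjacencies(ea, circ) - _adjacencies(eb, circ))


# ---------------------------------------------------------------------------
# Minimal scenario search

def _canonical_state(elements: tuple[Element, ...], circular: bool) -> tuple:
    """Rotation- and reflection-with-strand-flip-invariant key."""
    if not circular:
        return min(elements, _flip(elements))
    cands = []
    for t in (elements, _flip(elements)):
        cands.extend(t[i:] + t[:i] for i in range(len(t)))
    return min(cands)


def apply_op(elements: tuple[Element, ...], op: dict) -> tuple[Element, ...]:
    lst = list(elements)
    if op["op"] == "relocate":
        i, j = op["block"]
        block = lst[i:j + 1]
        rest = lst[:i] + lst[j + 1:]
        k = op["dest"]
        return tuple(rest[:k] + block + rest[k:])
    if op["op"] == "swap":
        i, j = op["i"], op["j"]
        lst[i], lst[j] = lst[j], lst[i]
        return tuple(lst)
    if op["op"] == "invert":
        i, j = op["block"]
        seg = [(lab, "+" if s == "-" else "-") for lab, s in reversed(lst[i:j + 1])]
        return tuple(lst[:i] + seg + lst[j + 1:])
    raise ValueError(f"unknown op {op['op']!r}")


def _successors(elements: tuple[Element, ...], allow_inversion: bool):
    """Deterministic op order: relocations (block by start, then length, dests
    ascending), then swaps lexicographic, then inversions if enabled."""
    n = len(elements)
    for i in range(n):
        for j in range(i, n):
            if j - i + 1 == n:
                continue
            for k in range(n - (j - i + 1) + 1):
                if k == i:  # identity placement
                    continue
                op = {"op": "relocate", "block": [i, j], "dest": k}
                yield op, apply_op(elements, op)
    for i in range(n):
        for j in range(i + 1, n):
            op = {"op": "swap", "i": i, "j": j}
            yield op, apply_op(elements, op)
    if allow_inversion:
        for i in range(n):
            for j in range(i, n):
                op = {"op": "invert", "block": [i, j]}
                yield op, apply_op(elements, op)


def _bp(ea: tuple[Element, ...], adj_b: set, circular: bool) -> int:
    return len(_adjacencies(ea, circular) - adj_b)


def minimal_scenario(
    a: GeneOrder,
    b: GeneOrder,
    max_ops: int = 4,
    allow_inversion: bool = False,
) -> RearrangementScenario:
    """Shortest sequence of operations transforming ``a`` into ``b`` (circular
    equality up to rotation/reflection-with-flip), with ``op_count <=
    max_ops``; ``achieved=False`` signals the depth bound was hit.

    Iterative deepening: depth limits 0..max_ops are searched in turn, so the
    first scenario found is minimal within the operation model. At limit d a
    state whose breakpoint distance to the target exceeds 4*(d - depth) is
    pruned (admissible: one op changes at most 4 adjacencies). The goal test
    is breakpoint distance 0, which for unique signed labels holds iff the
    circular orders coincide up to rotation/reflection-with-strand-flip.
    """
    ea, eb, dropped = _shared(a, b)
    circ = a.circular and b.circular
    adj_b = _adjacencies(eb, circ)
    per_op = 4

    def make(ops):
        return RearrangementScenario(ops=ops, achieved=True, source=list(ea),
                                     target=list(eb), dropped_labels=dropped)

    if _bp(ea, adj_b, circ) == 0:
        return make([])
    for limit in range(1, max_ops + 1):
        # depth-limited BFS; visited maps canonical state -> shallowest depth
        visited = {_canonical_state(ea, circ): 0}
        queue = deque([(ea, [])])
        while queue:
            state, ops = queue.popleft()
            depth = len(ops)
            if depth >= limit:
                continue
            for op, nxt in _successors(state, allow_inversion):
                bp = _bp(nxt, adj_b, circ)
                if bp == 0:
                    return make(ops + [op])
                if bp > per_op * (limit - depth - 1):
                    continue
                key = _canonical_state(nxt, circ)
                prev = visited.get(key)
                if prev is not None and prev <= depth + 1:
                    continue
                visited[key] = depth + 1
                queue.append((nxt, ops + [op]))
    return RearrangementScenario(ops=[], achieved=False, source=list(ea),
                                 target=list(eb), dropped_labels=dropped)
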