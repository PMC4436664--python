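"""Secondary-structure parsing and the skeleton graph of typed elements.

An RNA secondary structure is decomposed into *stems* (maximal runs of
stacked canonical pairs, identified by their four corner nucleotides
c1 < c2 < c3 < c4), *hairpins*, *interior loops*, *multiloop segments*
and the 5'/3' unpaired regions.  The connectivity of these elements --
the skeleton graph -- directs the construction of the coarse-grain 3D
model: every non-stem element links at most two stems, and each
multiloop junction designates one segment (the longest) as the *break*
whose geometry is determined by the others rather than sampled.

Nucleotide indices are 1-based throughout and ranges are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UNPAIRED",
    "PairTable",
    "Element",
    "Connection",
    "SkeletonGraph",
    "ParseError",
    "LonelyPairError",
    "parse_dotbracket",
    "remove_pseudoknots",
    "build_skeleton_graph",
    "traversal_order",
]

#: sentinel partner index for unpaired positions
UNPAIRED = 0

_BRACKET_PAIRS = {"(": ")", "[": "]", "{": "}", "<": ">"}
_CLOSERS = {v: k for k, v in _BRACKET_PAIRS.items()}


class ParseError(ValueError):
    """Malformed dot-bracket input."""


class LonelyPairError(ValueError):
    """A 1-bp stem was encountered; isolated pairs have no cylinder axis."""


@dataclass(frozen=True)
class PairTable:
    """Per-position base-pairing partners of a secondary structure.

    ``partner`` has length ``n + 1``; index 0 is unused and unpaired
    positions carry the sentinel :data:`UNPAIRED`.
    """

    partner: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.partner, dtype=int)
        object.__setattr__(self, "partner", p)
        n = len(p) - 1
        for i in range(1, n + 1):
            j = p[i]
            if j == UNPAIRED:
                continue
            if not 1 <= j <= n or j == i or p[j] != i:
                raise ValueError(f"inconsistent partner table at position {i}")

    @property
    def length(self) -> int:
        return len(self.partner) - 1

    def pairs(self) -> list[tuple[int, int]]:
        """All pairs (i, j) with i < j, in 5'-first order."""
        return [
            (i, int(self.partner[i]))
            for i in range(1, self.length + 1)
            if self.partner[i] > i
        ]

    def is_nested(self) -> bool:
        ps = self.pairs()
        for a, (i, j) in enumerate(ps):
            for k, l in ps[a + 1 :]:
                if i < k < j < l:
                    return False
        return True

    @classmethod
    def from_pairs(cls, length: int, pairs) -> "PairTable":
        partner = np.zeros(length + 1, dtype=int)
        for i, j in pairs:
            if not (1 <= i <= length and 1 <= j <= length) or i == j:
                raise ValueError(f"invalid pair ({i}, {j})")
            if partner[i] or partner[j]:
                raise ValueError(f"position reused by pair ({i}, {j})")
            partner[i], partner[j] = j, i
        return cls(partner)


def parse_dotbracket(text: str) -> PairTable:
    """Parse a dot-bracket string (extended bracket alphabets allowed).

    Raises :class:`ParseError` naming the offending position for
    unbalanced input.
    """
    text = text.strip()
    stacks: dict[str, list[int]] = {b: [] for b in _BRACKET_PAIRS}
    partner = np.zeros(len(text) + 1, dtype=int)
    for pos, ch in enumerate(text, start=1):
        if ch == ".":
            continue
        if ch in _BRACKET_PAIRS:
            stacks[ch].append(pos)
        elif ch in _CLOSERS:
            opener = _CLOSERS[ch]
            if not stacks[opener]:
                raise ParseError(f"unmatched '{ch}' at position {pos}")
            i = stacks[opener].pop()
            partner[i], partner[pos] = pos, i
        else:
            raise ParseError(f"illegal character {ch!r} at position {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise ParseError(f"unmatched '{opener}' at position {stack[-1]}")
    return PairTable(partner)


def remove_pseudoknots(pt: PairTable) -> PairTable:
    """Conflict elimination: keep a maximum-cardinality nested pair subset.

    Dynamic programming over sequence intervals; among maximal subsets the
    5'-most pair is preferred at ties (a pair is taken whenever taking it
    does not reduce the attainable count).
    """
    n = pt.length
    partner = pt.partner
    # best[i][j]: max pairs using positions i..j only; take[i][j]: whether
    # the arc at i is used in an optimal solution for (i, j).
    best = np.zeros((n + 2, n + 2), dtype=int)
    take = np.zeros((n + 2, n + 2), dtype=bool)
    for length in range(2, n + 1):
        for i in range(1, n - length + 2):
            j = i + length - 1
            skip = best[i + 1][j]
            p = partner[i]
            if i < p <= j:
                cand = 1 + best[i + 1][p - 1] + best[p + 1][j]
                if cand >= skip:
                    best[i][j] = cand
                    take[i][j] = True
                    continue
            best[i][j] = skip
    kept: list[tuple[int, int]] = []
    stack = [(1, n)]
    while stack:
        i, j = stack.pop()
        while i < j:
            if take[i][j]:
                p = int(partner[i])
                kept.append((i, p))
                stack.append((p + 1, j))
                j = p - 1
                i += 1
            else:
                i += 1
    return PairTable.from_pairs(n, kept)


@dataclass(frozen=True)
class Element:
    """A typed secondary-structure element.

    ``anchor`` is the 5'-most boundary position used for deterministic
    ordering (c1 for stems, the position of the preceding corner for
    loop-type elements, 0 for the 5' region).
    """

    name: str
    kind: str
    nucleotides: tuple[int, ...]
    corners: tuple[int, int, int, int] | None = None
    anchor: int = 0
    #: stats-bucket key: ordered strand-length pair for interior loops,
    #: nucleotide count otherwise
    size_signature: tuple[int, int] | int | None = None

    def __post_init__(self):
        if self.kind == "stem":
            c1, c2, c3, c4 = self.corners
            if not c1 <= c2 < c3 <= c4:
                raise ValueError(f"bad stem corners {self.corners}")
            if c2 - c1 != c4 - c3:
                raise ValueError("stem strands of unequal length")
        elif self.corners is not None:
            raise ValueError("non-stem elements carry no corners")

    @property
    def n_bp(self) -> int:
        if self.kind != "stem":
            raise ValueError("n_bp defined for stems only")
        return self.corners[1] - self.corners[0] + 1

    @property
    def size(self) -> int:
        return len(self.nucleotides)


@dataclass(frozen=True)
class Connection:
    """How a connector element links stem ends.

    Each entry is ``(stem_name, end)`` with end 0 the outer (c1/c4) end
    and end 1 the inner (c2/c3) end; ``a`` is the stem the strand exits
    (5' side of the connector) and ``b``, when present, the stem it
    enters.  ``corner_a``/``corner_b`` are the corner numbers (1..4) the
    connector attaches to -- they select the strand-adjusted placement
    frame.  ``exit_corner``/``entry_corner`` name the corner nucleotides
    whose virtual O3'/P atoms define the junction gap; either may be
    None for elements that are not junction segments.
    """

    a: tuple[str, int]
    b: tuple[str, int] | None = None
    corner_a: int = 2
    corner_b: int | None = None
    exit_corner: tuple[str, int] | None = None
    entry_corner: tuple[str, int] | None = None

    @property
    def corners(self) -> tuple[int, int]:
        """(corner on a, corner on b) placement pattern."""
        return (self.corner_a, self.corner_b if self.corner_b else 1)


@dataclass
class SkeletonGraph:
    """Typed secondary-structure elements and their connectivity."""

    length: int
    elements: dict[str, Element]
    adjacency: list[tuple[str, str]]
    connections: dict[str, Connection]
    junctions: list[tuple[str, ...]] = field(default_factory=list)
    traversal: list[str] = field(default_factory=list)
    junction_breaks: dict[int, str] = field(default_factory=dict)
    sequence: str | None = None

    def neighbours(self, name: str) -> list[str]:
        out = []
        for a, b in self.adjacency:
            if a == name:
                out.append(b)
            elif b == name:
                out.append(a)
        return out

    def stems(self) -> list[str]:
        return [n for n, e in self.elements.items() if e.kind == "stem"]

    @property
    def break_names(self) -> set[str]:
        return set(self.junction_breaks.values())


_KIND_PREFIX = {
    "stem": "s",
    "hairpin": "h",
    "interior_loop": "i",
    "multiloop_segment": "m",
    "five_prime": "f",
    "three_prime": "t",
}


def _find_stems(pt: PairTable) -> list[tuple[int, int, int, int]]:
    """Maximal runs of stacked pairs as corner quadruples (c1, c2, c3, c4)."""
    stems = []
    partner = pt.partner
    seen = np.zeros(pt.length + 1, dtype=bool)
    for i in range(1, pt.length + 1):
        j = int(partner[i])
        if j <= i or seen[i]:
            continue
        k = 0
        while (
            i + k + 1 <= pt.length
            and partner[i + k + 1] == j - k - 1
            and j - k - 1 > i + k + 1
        ):
            k += 1
        for d in range(k + 1):
            seen[i + d] = seen[j - d] = True
        stems.append((i, i + k, j - k, j))
    return stems


def build_skeleton_graph(
    pt: PairTable, sequence: str | None = None
) -> SkeletonGraph:
    """Decompose a pseudoknot-free pair table into the skeleton graph.

    Raises :class:`LonelyPairError` for isolated (1-bp) stems -- a single
    pair has no defined helix axis; fold with lonely pairs disallowed.
    """
    if not pt.is_nested():
        raise ValueError("pair table contains pseudoknots; remove them first")
    n = pt.length
    stems = _find_stems(pt)
    for c1, c2, c3, c4 in stems:
        if c1 == c2:
            raise LonelyPairError(
                f"isolated base pair ({c1}, {c4}); structures without lonely "
                "pairs are required (refold with isolated pairs disallowed)"
            )
    stems.sort()
    stem_names = {corners: f"s{k}" for k, corners in enumerate(stems)}

    # nesting tree: parent stem is the innermost stem whose inner region
    # strictly contains this stem
    children: dict[object, list[tuple[int, int, int, int]]] = {None: []}
    for c in stems:
        children[c] = []
    stack: list[tuple[int, int, int, int]] = []
    for s in stems:
        while stack and not (stack[-1][1] < s[0] and s[3] < stack[-1][2]):
            stack.pop()
        children[stack[-1] if stack else None].append(s)
        stack.append(s)

    elements: dict[str, Element] = {}
    adjacency: list[tuple[str, str]] = []
    connections: dict[str, Connection] = {}
    junctions: list[tuple[str, ...]] = []
    pending: list[tuple[str, dict]] = []  # (kind, payload) awaiting numbering

    def rng_nts(a: int, b: int) -> tuple[int, ...]:
        return tuple(range(a, b + 1)) if a <= b else ()

    for corners in stems:
        c1, c2, c3, c4 = corners
        pending.append(
            (
                "stem",
                dict(
                    nucleotides=rng_nts(c1, c2) + rng_nts(c3, c4),
                    corners=corners,
                    anchor=c1,
                ),
            )
        )

    def add_loop(kind, nts, anchor, conn, size_sig=None):
        pending.append(
            (
                "_loop",
                dict(
                    kind=kind,
                    nucleotides=nts,
                    anchor=anchor,
                    conn=conn,
                    size_sig=len(nts) if size_sig is None else size_sig,
                ),
            )
        )
        return len(pending) - 1

    junction_groups: list[list[int]] = []  # indices into pending

    # inner faces
    for corners in stems:
        c1, c2, c3, c4 = corners
        sname = stem_names[corners]
        kids = children[corners]
        if not kids:
            add_loop(
                "hairpin",
                rng_nts(c2 + 1, c3 - 1),
                c2,
                Connection((sname, 1)),
            )
        elif len(kids) == 1:
            k = kids[0]
            kname = stem_names[k]
            nts = rng_nts(c2 + 1, k[0] - 1) + rng_nts(k[3] + 1, c3 - 1)
            add_loop(
                "interior_loop",
                nts,
                c2,
                Connection((sname, 1), (kname, 0), corner_a=2, corner_b=1),
                size_sig=(k[0] - c2 - 1, c3 - k[3] - 1),
            )
        else:
            group = []
            k1 = kids[0]
            group.append(
                add_loop(
                    "multiloop_segment",
                    rng_nts(c2 + 1, k1[0] - 1),
                    c2,
                    Connection(
                        (sname, 1),
                        (stem_names[k1], 0),
                        corner_a=2,
                        corner_b=1,
                        exit_corner=(sname, 2),
                        entry_corner=(stem_names[k1], 1),
                    ),
                )
            )
            for ka, kb in zip(kids, kids[1:]):
                group.append(
                    add_loop(
                        "multiloop_segment",
                        rng_nts(ka[3] + 1, kb[0] - 1),
                        ka[3],
                        Connection(
                            (stem_names[ka], 0),
                            (stem_names[kb], 0),
                            corner_a=4,
                            corner_b=1,
                            exit_corner=(stem_names[ka], 4),
                            entry_corner=(stem_names[kb], 1),
                        ),
                    )
                )
            km = kids[-1]
            group.append(
                add_loop(
                    "multiloop_segment",
                    rng_nts(km[3] + 1, c3 - 1),
                    km[3],
                    Connection(
                        (stem_names[km], 0),
                        (sname, 1),
                        corner_a=4,
                        corner_b=3,
                        exit_corner=(stem_names[km], 4),
                        entry_corner=(sname, 3),
                    ),
                )
            )
            junction_groups.append(group)

    # exterior face
    top = children[None]
    if not top:
        if n:
            add_loop("five_prime", rng_nts(1, n), 0, None)
    else:
        first, last = top[0], top[-1]
        if first[0] > 1:
            add_loop(
                "five_prime",
                rng_nts(1, first[0] - 1),
                0,
                Connection(
                    (stem_names[first], 0),
                    corner_a=1,
                    entry_corner=(stem_names[first], 1),
                ),
            )
        for ka, kb in zip(top, top[1:]):
            add_loop(
                "multiloop_segment",
                rng_nts(ka[3] + 1, kb[0] - 1),
                ka[3],
                Connection(
                    (stem_names[ka], 0),
                    (stem_names[kb], 0),
                    corner_a=4,
                    corner_b=1,
                    exit_corner=(stem_names[ka], 4),
                    entry_corner=(stem_names[kb], 1),
                ),
            )
        if last[3] < n:
            add_loop(
                "three_prime",
                rng_nts(last[3] + 1, n),
                last[3],
                Connection(
                    (stem_names[last], 0),
                    corner_a=4,
                    exit_corner=(stem_names[last], 4),
                ),
            )

    # assign names per kind in 5'->3' anchor order
    counters: dict[str, int] = {}
    names_by_index: dict[int, str] = {}
    order = sorted(
        range(len(pending)),
        key=lambda idx: (pending[idx][1].get("anchor", 0), idx),
    )
    for idx in order:
        tag, payload = pending[idx]
        kind = payload.get("kind", "stem") if tag == "_loop" else "stem"
        prefix = _KIND_PREFIX[kind]
        ordinal = counters.get(prefix, 0)
        counters[prefix] = ordinal + 1
        name = f"{prefix}{ordinal}"
        names_by_index[idx] = name
        if tag == "stem":
            elements[name] = Element(
                name,
                "stem",
                payload["nucleotides"],
                payload["corners"],
                payload["anchor"],
            )
        else:
            elements[name] = Element(
                name,
                kind,
                payload["nucleotides"],
                None,
                payload["anchor"],
                payload["size_sig"],
            )
            conn: Connection | None = payload["conn"]
            if conn is not None:
                connections[name] = conn
                adjacency.append((conn.a[0], name))
                if conn.b is not None:
                    adjacency.append((name, conn.b[0]))

    for group in junction_groups:
        junctions.append(tuple(names_by_index[i] for i in group))

    g = SkeletonGraph(
        length=n,
        elements=elements,
        adjacency=adjacency,
        connections=connections,
        junctions=junctions,
        sequence=sequence,
    )
    g.traversal, g.junction_breaks = traversal_order(g)
    return g


def _ordinal(name: str) -> tuple[str, int]:
    return (name[0], int(name[1:]))


def traversal_order(g: SkeletonGraph) -> tuple[list[str], dict[int, str]]:
    """Build order of elements plus the per-junction break segments.

    The order starts at the 5'-most stem; each subsequent stem follows a
    connector from an already-placed stem.  For every multiloop junction
    the segment with the most nucleotides is the break (5'-most at ties);
    break segments are excluded from the build order -- their closure is
    checked geometrically instead of being sampled.
    """
    breaks: dict[int, str] = {}
    for jidx, group in enumerate(g.junctions):
        best = max(
            group,
            key=lambda nm: (g.elements[nm].size, -g.elements[nm].anchor),
        )
        breaks[jidx] = best
    break_names = set(breaks.values())

    stems = sorted(g.stems(), key=_ordinal)
    order: list[str] = []
    if not stems:
        order.extend(sorted(g.elements, key=_ordinal))
        return order, breaks

    # connector -> (stems it joins), leaf loops per stem
    placed: set[str] = set()
    visited_conn: set[str] = set()

    def visit(stem: str):
        placed.add(stem)
        order.append(stem)
        for nm in sorted(g.neighbours(stem), key=_ordinal):
            if nm in visited_conn or nm in break_names:
                continue
            conn = g.connections[nm]
            if conn.b is None:
                visited_conn.add(nm)
                order.append(nm)
            else:
                other = conn.b[0] if conn.a[0] == stem else conn.a[0]
                if other not in placed:
                    visited_conn.add(nm)
                    order.append(nm)
                    visit(other)

    visit(stems[0])
    # any stems unreachable without crossing a break: reach them through the
    # break's partner chain (cannot happen for junctions, whose cycle keeps
    # all stems connected through the non-break segments)
    for s in stems:
        if s not in placed:  # pragma: no cover - junction cycles prevent this
            visit(s)
    return order, breaks
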