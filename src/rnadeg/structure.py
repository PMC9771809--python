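"""RNA secondary-structure primitives.

Dot-bracket strings are parsed into pair tables, pair tables are annotated
with loop types following the bpRNA nomenclature (S stem, H hairpin loop,
B bulge, I internal loop, M multiloop, X external loop, E end), and the
secondary structure is interpreted as a graph whose shortest-path hop
distances give a structure-aware notion of nucleotide proximity.

All coordinates are 0-based; intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import shortest_path

UNPAIRED = -1

LOOP_CLASSES = "SHIBMXE"

_BRACKETS = {"(": ")", "[": "]", "{": "}", "<": ">"}
_CLOSERS = {v: k for k, v in _BRACKETS.items()}


class DotBracketError(ValueError):
    """Raised for malformed dot-bracket input; carries the offending index."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


@dataclass(frozen=True)
class PairTable:
    """Base-pairing table: ``partner[i]`` is the pairing partner of position
    *i*, or :data:`UNPAIRED` (-1)."""

    partner: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.partner, dtype=int)
        object.__setattr__(self, "partner", p)
        paired = np.flatnonzero(p != UNPAIRED)
        if np.any(p[paired] == paired):
            raise ValueError("a position cannot pair with itself")
        if not np.array_equal(p[p[paired]], paired):
            raise ValueError("pair table is not an involution")

    def __len__(self) -> int:
        return len(self.partner)

    @property
    def length(self) -> int:
        return len(self.partner)

    def is_paired(self, i: int) -> bool:
        return self.partner[i] != UNPAIRED

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """Base pairs as (i, j) with i < j."""
        return [
            (i, int(j))
            for i, j in enumerate(self.partner)
            if j != UNPAIRED and i < j
        ]

    def is_nested(self) -> bool:
        """True when no two pairs cross (pseudoknot-free)."""
        stack: list[int] = []
        for i, j in enumerate(self.partner):
            if j == UNPAIRED:
                continue
            if j > i:
                stack.append(int(j))
            else:
                if not stack or stack[-1] != i:
                    return False
                stack.pop()
        return not stack

    def to_dotbracket(self) -> str:
        if not self.is_nested():
            raise ValueError("cannot render a pseudoknotted pair table with one bracket type")
        out = ["."] * len(self)
        for i, j in self.pairs:
            out[i], out[j] = "(", ")"
        return "".join(out)


def parse_dotbracket(db: str, allow_pseudoknots: bool = False) -> PairTable:
    """Parse a dot-bracket string into a :class:`PairTable`.

    Round brackets encode nested pairs.  When ``allow_pseudoknots`` is set the
    additional bracket alphabets ``[]``, ``{}`` and ``<>`` are accepted; pairs
    from each alphabet are nested within that alphabet but may cross the
    others.
    """
    partner = np.full(len(db), UNPAIRED, dtype=int)
    stacks: dict[str, list[int]] = {b: [] for b in _BRACKETS}
    allowed_open = set("(") if not allow_pseudoknots else set(_BRACKETS)
    for i, ch in enumerate(db):
        if ch == ".":
            continue
        if ch in _BRACKETS:
            if ch not in allowed_open:
                raise DotBracketError(
                    f"pseudoknot bracket {ch!r} at index {i} (enable allow_pseudoknots)", i
                )
            stacks[ch].append(i)
        elif ch in _CLOSERS:
            opener = _CLOSERS[ch]
            if opener not in allowed_open:
                raise DotBracketError(
                    f"pseudoknot bracket {ch!r} at index {i} (enable allow_pseudoknots)", i
                )
            if not stacks[opener]:
                raise DotBracketError(f"unbalanced {ch!r} at index {i}", i)
            j = stacks[opener].pop()
            partner[i], partner[j] = j, i
        else:
            raise DotBracketError(f"illegal character {ch!r} at index {i}", i)
    for opener, stack in stacks.items():
        if stack:
            raise DotBracketError(f"unmatched {opener!r} at index {stack[-1]}", stack[-1])
    return PairTable(partner)


@dataclass(frozen=True)
class LoopSegment:
    """One loop element of a nested structure.

    ``kind`` is a loop class letter (H/B/I/M/X/E), ``positions`` the unpaired
    positions belonging to the element, ``closing`` the enclosing pair or
    ``None`` for exterior elements, and ``sides`` the (5', 3') unpaired run
    lengths for internal loops.
    """

    kind: str
    positions: tuple[int, ...]
    closing: tuple[int, int] | None = None
    sides: tuple[int, int] | None = None


def _scan_interval(partner: np.ndarray, lo: int, hi: int):
    """Children pairs and unpaired runs inside [lo, hi] at the current level."""
    children: list[tuple[int, int]] = []
    runs: list[list[int]] = []
    run: list[int] = []
    k = lo
    while k <= hi:
        if partner[k] == UNPAIRED:
            run.append(k)
            k += 1
        else:
            if run:
                runs.append(run)
                run = []
            children.append((k, int(partner[k])))
            k = int(partner[k]) + 1
    if run:
        runs.append(run)
    return children, runs


def loop_segments(pt: PairTable) -> list[LoopSegment]:
    """Decompose a nested pair table into loop elements.

    Exterior unpaired runs touching a sequence terminus are ends (E); exterior
    runs flanked by helices on both sides are external loops (X).  A loop
    closed by a pair with no inner helix is a hairpin (H); with one inner helix
    it is a bulge (B, unpaired on one side) or internal loop (I, both sides);
    with two or more inner helices every unpaired position in it belongs to a
    multiloop (M).
    """
    if not pt.is_nested():
        raise ValueError("loop annotation requires a pseudoknot-free (nested) structure")
    partner = pt.partner
    n = len(partner)
    segs: list[LoopSegment] = []
    if n == 0:
        return segs
    top_children, top_runs = _scan_interval(partner, 0, n - 1)
    for run in top_runs:
        kind = "E" if run[0] == 0 or run[-1] == n - 1 else "X"
        segs.append(LoopSegment(kind, tuple(run)))
    stack = list(top_children)
    while stack:
        i, j = stack.pop()
        children, runs = _scan_interval(partner, i + 1, j - 1)
        if not children:
            segs.append(LoopSegment("H", tuple(runs[0]) if runs else (), closing=(i, j)))
        elif len(children) == 1:
            a, b = children[0]
            l5 = a - (i + 1)
            l3 = (j - 1) - b
            if l5 and l3:
                pos = tuple(range(i + 1, a)) + tuple(range(b + 1, j))
                segs.append(LoopSegment("I", pos, closing=(i, j), sides=(l5, l3)))
            elif l5 or l3:
                pos = tuple(range(i + 1, a)) if l5 else tuple(range(b + 1, j))
                segs.append(LoopSegment("B", pos, closing=(i, j)))
            # l5 == l3 == 0: stacked helix, no loop element
        else:
            pos = tuple(p for run in runs for p in run)
            segs.append(LoopSegment("M", pos, closing=(i, j)))
        stack.extend(children)
    return segs


def annotate_loop_types(pt: PairTable) -> str:
    """Per-position loop-class string over {S,H,I,B,M,X,E}.

    Paired positions are stems (S); every unpaired position receives the class
    of the loop element it belongs to (see :func:`loop_segments`).
    """
    classes = ["S" if pt.is_paired(i) else "" for i in range(len(pt))]
    for seg in loop_segments(pt):
        for p in seg.positions:
            classes[p] = seg.kind
    assert all(classes), "every position must receive a loop class"
    return "".join(classes)


@dataclass(frozen=True)
class StructureGraph:
    """Nucleotide graph: backbone edges (i, i+1) plus base-pair edges, with the
    all-pairs shortest-path hop-count matrix used as a proximity embedding."""

    edges: list[tuple[int, int]] = field(repr=False)
    dist: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return self.dist.shape[0]


def structure_graph(pt: PairTable) -> StructureGraph:
    n = len(pt)
    edges = [(i, i + 1) for i in range(n - 1)] + pt.pairs
    if n == 0:
        return StructureGraph(edges, np.zeros((0, 0), dtype=int))
    rows = np.array([e[0] for e in edges] + [e[1] for e in edges], dtype=int)
    cols = np.array([e[1] for e in edges] + [e[0] for e in edges], dtype=int)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = shortest_path(adj.tocsr(), method="D", unweighted=True)
    return StructureGraph(edges, dist.astype(int))


def graph_distance_matrix(pt: PairTable) -> np.ndarray:
    """All-pairs shortest-path hop distances over backbone plus pair edges."""
    return structure_graph(pt).dist


def unpaired_probability(bpp: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Per-position unpaired probability from a base-pair probability matrix.

    ``p_unpaired[i] = 1 - sum_j bpp[i, j]``, clipped to [0, 1].  The matrix
    must be square and symmetric with entries in [0, 1] and row sums at most
    ``1 + tol``.
    """
    m = np.asarray(bpp, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"bpp matrix must be square, got shape {m.shape}")
    if np.any(m < -tol) or np.any(m > 1 + tol):
        raise ValueError("bpp entries must lie in [0, 1]")
    if not np.allclose(m, m.T, atol=max(tol, 1e-8)):
        raise ValueError("bpp matrix must be symmetric")
    row_sums = m.sum(axis=1)
    bad = np.flatnonzero(row_sums > 1 + tol)
    if bad.size:
        raise ValueError(
            f"row sums exceed 1 at positions {bad[:5].tolist()} (max {row_sums.max():.6f})"
        )
    return np.clip(1.0 - row_sums, 0.0, 1.0)
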