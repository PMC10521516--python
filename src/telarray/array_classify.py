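"""Positional and compositional classification of repeat arrays.

An array is TERMINAL when it sits within ``edge_tol`` of a read end,
INTERSTITIAL otherwise. Compositionally, monomer calls collapse into blocks
(maximal runs of one monomer class); the block inventory decides between a
pure canonical array, a block-organized double-monomer (canonical +
TTTAAAA) array, a derivative (CCTGGG-family) array, or a mixed leftover
class. Junctions (a short canonical core flanked by oppositely oriented
derivative arrays) and ITR-DTR colocations are detected per read.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .motif_scan import (
    ArrayHit,
    MonomerCall,
    CANONICAL,
    VARIANT,
    DERIV_TTTAAAA,
    DERIV_CCTGGG,
    UNASSIGNED,
)

__all__ = [
    "PositionClass",
    "CompositionClass",
    "Block",
    "ClassifiedArray",
    "JunctionEvent",
    "ColocationEvent",
    "ClassifyParams",
    "classify_position",
    "detect_blocks",
    "classify_composition",
    "classify_array",
    "classify_read_arrays",
    "detect_junctions",
    "detect_colocations",
    "check_forbidden_combination",
]


class PositionClass(str, Enum):
    TERMINAL = "TERMINAL"
    INTERSTITIAL = "INTERSTITIAL"


class CompositionClass(str, Enum):
    PURE_TEL = "PURE_TEL"
    COMBINED_TEL_TTTAAAA = "COMBINED_TEL_TTTAAAA"
    DTR = "DTR"
    MIXED_OTHER = "MIXED_OTHER"


# block classes (canonical variants never start their own block)
BLOCK_CANONICAL = "canonical"
BLOCK_TTTAAAA = "TTTAAAA"
BLOCK_CCTGGG = "CCTGGG_family"

_BLOCK_OF = {
    CANONICAL: BLOCK_CANONICAL,
    VARIANT: BLOCK_CANONICAL,
    DERIV_TTTAAAA: BLOCK_TTTAAAA,
    DERIV_CCTGGG: BLOCK_CCTGGG,
}


@dataclass(frozen=True)
class ClassifyParams:
    edge_tol: int = 100  # bp from a read end still counted as terminal
    min_block_copies: int = 3
    core_max_copies: int = 10  # "a few copies" of the canonical motif
    max_flank_gap: int = 50  # bp between a junction core and its flanks
    max_coloc_gap: int = 1000  # bp between colocated ITR and DTR arrays


@dataclass(frozen=True)
class Block:
    monomer_class: str
    copy_count: int
    start: int  # bp, forward-read coordinates
    end: int


@dataclass
class ClassifiedArray:
    hit: ArrayHit
    position_class: PositionClass
    composition_class: CompositionClass
    blocks: list[Block]

    @property
    def read_id(self) -> str:
        return self.hit.read_id

    @property
    def is_itr_like(self) -> bool:
        """Telomere-motif array (canonical-containing), as opposed to DTR."""
        return self.composition_class in (
            CompositionClass.PURE_TEL,
            CompositionClass.COMBINED_TEL_TTTAAAA,
        )


@dataclass(frozen=True)
class JunctionEvent:
    read_id: str
    core_start: int
    core_end: int
    core_copies: int
    left_strand: str
    right_strand: str
    left_index: int  # indices into the classified-array list of the read
    core_index: int
    right_index: int


@dataclass(frozen=True)
class ColocationEvent:
    read_id: str
    itr_index: int
    dtr_index: int
    gap: int


def classify_position(
    hit: ArrayHit, read_length: int, edge_tol: int = 100
) -> PositionClass:
    """TERMINAL iff the array lies within ``edge_tol`` bp of either read end."""
    if not (0 <= hit.start < hit.end <= read_length):
        raise ValueError(
            f"array [{hit.start},{hit.end}) outside read of length {read_length}"
        )
    if hit.start <= edge_tol or read_length - hit.end <= edge_tol:
        return PositionClass.TERMINAL
    return PositionClass.INTERSTITIAL


def detect_blocks(
    monomer_calls: Sequence[MonomerCall], min_block_copies: int = 3
) -> list[tuple[str, int, int, int]]:
    """Maximal runs of one block class; short runs absorbed into flanks.

    Returns (block_class, copy_count, oriented_start, oriented_end) tuples in
    oriented-array coordinates. Copy counts always sum to the number of
    monomer calls. A run whose number of *assigned* calls (unassigned calls
    ride along with the preceding run but carry no class evidence) is below
    ``min_block_copies`` merges into the flanking run with more calls
    (tie -> left).
    """
    if not monomer_calls:
        raise ValueError("monomer_calls is empty")
    # map calls to block classes; unassigned inherits from a neighbour but
    # contributes no evidence toward keeping a block alive
    classes: list[str | None] = [
        _BLOCK_OF.get(c.monomer_class) for c in monomer_calls
    ]
    assigned = [cl is not None for cl in classes]
    last = None
    for i, cl in enumerate(classes):
        if cl is None:
            classes[i] = last
        else:
            last = classes[i]
    first = next((c for c in classes if c is not None), BLOCK_CANONICAL)
    classes = [c if c is not None else first for c in classes]

    ends = [c.offset + len(c.seq) for c in monomer_calls]
    starts = [c.offset for c in monomer_calls]
    runs: list[list] = []  # [class, count, assigned_count, start, end]
    for i, cl in enumerate(classes):
        if runs and runs[-1][0] == cl:
            runs[-1][1] += 1
            runs[-1][2] += assigned[i]
            runs[-1][4] = ends[i]
        else:
            runs.append([cl, 1, int(assigned[i]), starts[i], ends[i]])

    def merge(i: int, j: int) -> None:
        """Absorb run i into adjacent run j, keeping j's class."""
        lo, hi = (i, j) if i < j else (j, i)
        cls = runs[j][0]
        runs[lo][1] += runs[hi][1]
        runs[lo][2] += runs[hi][2]
        runs[lo][4] = runs[hi][4]
        runs[lo][0] = cls
        del runs[hi]

    changed = True
    while changed and len(runs) > 1:
        changed = False
        for i, run in enumerate(runs):
            if run[2] >= min_block_copies:
                continue
            left = runs[i - 1] if i > 0 else None
            right = runs[i + 1] if i + 1 < len(runs) else None
            if left is not None and (right is None or left[1] >= right[1]):
                merge(i, i - 1)
            else:
                merge(i, i + 1)
            changed = True
            break
        # fuse adjacent equal-class runs created by absorption
        i = 0
        while i + 1 < len(runs):
            if runs[i][0] == runs[i + 1][0]:
                runs[i][1] += runs[i + 1][1]
                runs[i][2] += runs[i + 1][2]
                runs[i][4] = runs[i + 1][4]
                del runs[i + 1]
            else:
                i += 1
    return [(r[0], r[1], r[3], r[4]) for r in runs]


def classify_composition(blocks: Iterable[tuple | Block]) -> CompositionClass:
    """Composition from the block-class inventory."""
    classes = set()
    for b in blocks:
        classes.add(b.monomer_class if isinstance(b, Block) else b[0])
    if not classes:
        raise ValueError("no blocks")
    if classes == {BLOCK_CANONICAL}:
        return CompositionClass.PURE_TEL
    if classes == {BLOCK_CANONICAL, BLOCK_TTTAAAA}:
        return CompositionClass.COMBINED_TEL_TTTAAAA
    if classes <= {BLOCK_CCTGGG}:
        return CompositionClass.DTR
    return CompositionClass.MIXED_OTHER


def _oriented_to_read(hit: ArrayHit, ostart: int, oend: int) -> tuple[int, int]:
    if hit.strand == "+":
        return hit.start + ostart, hit.start + oend
    return hit.end - oend, hit.end - ostart


def classify_array(
    hit: ArrayHit, read_length: int, params: ClassifyParams | None = None
) -> ClassifiedArray:
    params = params or ClassifyParams()
    pos = classify_position(hit, read_length, params.edge_tol)
    raw = detect_blocks(hit.monomer_calls, params.min_block_copies)
    blocks = []
    for cl, count, os_, oe in raw:
        s, e = _oriented_to_read(hit, os_, oe)
        blocks.append(Block(cl, count, s, e))
    if hit.strand == "-":
        blocks = list(reversed(blocks))
    comp = classify_composition(raw)
    hit.array_class = comp.value
    return ClassifiedArray(hit, pos, comp, blocks)


def classify_read_arrays(
    hits: Sequence[ArrayHit], read_length: int, params: ClassifyParams | None = None
) -> list[ClassifiedArray]:
    params = params or ClassifyParams()
    out = [classify_array(h, read_length, params) for h in hits]
    out.sort(key=lambda c: c.hit.start)
    return out


def detect_junctions(
    arrays: Sequence[ClassifiedArray], params: ClassifyParams | None = None
) -> list[JunctionEvent]:
    """DTR / short-canonical-core / DTR patterns with opposite flank strands.

    Scans every ordered triple of arrays on the read; flank-to-core gaps must
    be within ``max_flank_gap`` and the core must be a pure canonical array of
    at most ``core_max_copies`` monomers.
    """
    params = params or ClassifyParams()
    arrs = sorted(arrays, key=lambda c: c.hit.start)
    events: list[JunctionEvent] = []
    used_cores: set[int] = set()
    n = len(arrs)
    for j in range(n):
        core = arrs[j]
        if j in used_cores:
            continue
        if core.composition_class != CompositionClass.PURE_TEL:
            continue
        if core.hit.n_monomers > params.core_max_copies:
            continue
        # candidate flanks: nearest DTR on each side within the gap
        left = None
        for i in range(j - 1, -1, -1):
            gap = core.hit.start - arrs[i].hit.end
            if gap > params.max_flank_gap:
                break
            if arrs[i].composition_class == CompositionClass.DTR:
                left = i
                break
        right = None
        for k in range(j + 1, n):
            gap = arrs[k].hit.start - core.hit.end
            if gap > params.max_flank_gap:
                break
            if arrs[k].composition_class == CompositionClass.DTR:
                right = k
                break
        if left is None or right is None:
            continue
        if arrs[left].hit.strand == arrs[right].hit.strand:
            continue
        events.append(
            JunctionEvent(
                read_id=core.read_id,
                core_start=core.hit.start,
                core_end=core.hit.end,
                core_copies=core.hit.n_monomers,
                left_strand=arrs[left].hit.strand,
                right_strand=arrs[right].hit.strand,
                left_index=left,
                core_index=j,
                right_index=right,
            )
        )
        used_cores.add(j)
    return events


def detect_colocations(
    arrays: Sequence[ClassifiedArray],
    params: ClassifyParams | None = None,
    junctions: Sequence[JunctionEvent] | None = None,
) -> list[ColocationEvent]:
    """Nearest-pair greedy matching of interstitial ITR and DTR arrays.

    Arrays that take part in a junction are excluded: a junction core is by
    construction an interstitial canonical array next to a DTR, and would
    otherwise always double-report as a colocation.
    """
    params = params or ClassifyParams()
    arrs = sorted(arrays, key=lambda c: c.hit.start)
    excluded: set[int] = set()
    for ev in junctions or ():
        excluded.update((ev.left_index, ev.core_index, ev.right_index))
    itrs = [
        i
        for i, a in enumerate(arrs)
        if i not in excluded
        and a.position_class == PositionClass.INTERSTITIAL
        and a.is_itr_like
    ]
    dtrs = [
        i
        for i, a in enumerate(arrs)
        if i not in excluded
        and a.position_class == PositionClass.INTERSTITIAL
        and a.composition_class == CompositionClass.DTR
    ]
    pairs = []
    for i in itrs:
        for j in dtrs:
            a, b = arrs[i].hit, arrs[j].hit
            gap = max(b.start - a.end, a.start - b.end, 0)
            if gap <= params.max_coloc_gap:
                pairs.append((gap, min(a.start, b.start), i, j))
    pairs.sort()
    used: set[int] = set()
    events: list[ColocationEvent] = []
    for gap, _, i, j in pairs:
        if i in used or j in used:
            continue
        used.update((i, j))
        events.append(ColocationEvent(arrs[i].read_id, i, j, gap))
    events.sort(key=lambda e: (e.itr_index, e.dtr_index))
    return events


def check_forbidden_combination(
    arrays: Iterable[ClassifiedArray], max_gap: int = 14
) -> int:
    """Derivative-only arrays joining TTTAAAA and CCTGGG-family blocks.

    The studied libraries never show this combination; the count is reported
    as a statistic, never enforced as a filter. Because the scanner keeps
    telomeric and CCTGGG-family seed groups in separate arrays, the pattern
    can surface either as a single mixed array (both block classes, no
    canonical) or as a TTTAAAA-only array directly abutting a DTR array;
    both forms are counted.
    """

    def classes_of(a):
        return {b.monomer_class for b in a.blocks}

    count = 0
    by_read: dict[str, list[ClassifiedArray]] = {}
    for a in arrays:
        cl = classes_of(a)
        if BLOCK_TTTAAAA in cl and BLOCK_CCTGGG in cl and BLOCK_CANONICAL not in cl:
            count += 1
        by_read.setdefault(a.read_id, []).append(a)
    for read_arrays in by_read.values():
        read_arrays = sorted(read_arrays, key=lambda a: a.hit.start)
        for prev, nxt in zip(read_arrays, read_arrays[1:]):
            if nxt.hit.start - prev.hit.end > max_gap:
                continue
            pair = (classes_of(prev), classes_of(nxt))
            if ({BLOCK_TTTAAAA}, {BLOCK_CCTGGG}) in (pair, pair[::-1]):
                count += 1
    return count
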