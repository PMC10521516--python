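"""Exact motif seeding and array assembly for telomeric repeats.

The scanner mirrors the two-stage logic used on the *Chenopodium* nanopore
libraries: a strict, zero-mismatch query of three tandem motif copies finds
seed matches on both strands; seeds are then merged and extended
monomer-by-monomer with a small edit-distance tolerance, because real arrays
carry a few percent of monomers deviating by one or two nucleotides.

Three motif queries are scanned: the canonical plant telomere heptamer
TTTAGGG, its terminal derivative TTTAAAA, and the interstitial derivative
CCTGGG. Family variants (CCCTGGG, CCTAGG, CCCAGG, and the degenerate
canonical forms TTTAGG / TTAGGG) participate only in monomer decomposition
and array extension, never as seed queries: CCTGGG read on the minus strand
is the same string as CCCAGG on plus, so admitting the variants as queries
would erase the orientation signal that junction detection relies on.

Arrays are reported on the G-rich strand: a minus-strand hit keeps its
forward-read coordinates but its monomer decomposition is computed on the
reverse complement of the hit interval.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace
from typing import Sequence

import edlib

from .seqio import Read, revcomp

__all__ = [
    "MotifCatalog",
    "ScanParams",
    "SeedMatch",
    "MonomerCall",
    "ArrayHit",
    "CANONICAL",
    "VARIANT",
    "DERIV_TTTAAAA",
    "DERIV_CCTGGG",
    "UNASSIGNED",
    "compile_seed",
    "find_exact_seeds",
    "assemble_arrays",
    "decompose_array",
    "scan_read",
]

# monomer-call classes
CANONICAL = "canonical"
VARIANT = "variant"
DERIV_TTTAAAA = "derivative_TTTAAAA"
DERIV_CCTGGG = "derivative_CCTGGG_family"
UNASSIGNED = "unassigned"

# merge groups: which motifs may share one array
GROUP_TEL = "tel"
GROUP_DTR = "dtr"


@dataclass(frozen=True)
class MotifCatalog:
    """The motif inventory: canonical telomere repeat plus its derivatives."""

    canonical: str = "TTTAGGG"
    derivative_terminal: str = "TTTAAAA"
    derivative_interstitial_primary: str = "CCTGGG"
    derivative_interstitial_variants: tuple[str, ...] = (
        "CCCTGGG",
        "CCTAGG",
        "CCCAGG",
    )
    degenerate_canonical: tuple[str, ...] = ("TTTAGG", "TTAGGG")

    @property
    def c_strand(self) -> str:
        return revcomp(self.canonical)

    @property
    def seed_motifs(self) -> tuple[str, ...]:
        """Motifs used as exact seed queries (the scanned query set)."""
        return (
            self.canonical,
            self.derivative_terminal,
            self.derivative_interstitial_primary,
        )

    @property
    def tel_group(self) -> tuple[str, ...]:
        return (
            (self.canonical,)
            + self.degenerate_canonical
            + (self.derivative_terminal,)
        )

    @property
    def dtr_group(self) -> tuple[str, ...]:
        return (
            self.derivative_interstitial_primary,
        ) + self.derivative_interstitial_variants

    def group_of(self, motif: str) -> str:
        if motif in self.tel_group:
            return GROUP_TEL
        if motif in self.dtr_group:
            return GROUP_DTR
        raise KeyError(motif)

    def group_monomers(self, group: str) -> tuple[str, ...]:
        return self.tel_group if group == GROUP_TEL else self.dtr_group

    def class_of(self, monomer: str, distance: int) -> str:
        if monomer == self.canonical:
            return CANONICAL if distance == 0 else VARIANT
        if monomer in self.degenerate_canonical:
            return VARIANT
        if monomer == self.derivative_terminal:
            return DERIV_TTTAAAA
        if monomer in self.dtr_group:
            return DERIV_CCTGGG
        raise KeyError(monomer)


@dataclass(frozen=True)
class ScanParams:
    min_seed_copies: int = 3
    max_monomer_edit_distance: int = 2
    max_variant_fraction: float = 0.05
    max_intra_array_gap: int = 14  # bp; 2 x canonical monomer length

    def __post_init__(self):
        if self.min_seed_copies < 1:
            raise ValueError("min_seed_copies must be >= 1")
        if not 0.0 <= self.max_variant_fraction <= 1.0:
            raise ValueError("max_variant_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SeedMatch:
    read_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    motif: str


@dataclass(frozen=True)
class MonomerCall:
    """One tiled monomer inside an array (offsets in the oriented array)."""

    offset: int
    seq: str
    monomer_class: str
    best_monomer: str | None = None
    distance: int = 0


@dataclass
class ArrayHit:
    """A contiguous repeat array on a read.

    ``start``/``end`` are forward-read coordinates (0-based half-open);
    ``monomer_calls`` and ``oriented_seq`` are in the G-rich orientation
    (the reverse complement of the interval when ``strand`` is '-').
    """

    read_id: str
    start: int
    end: int
    strand: str
    group: str
    monomer_calls: list[MonomerCall]
    oriented_seq: str
    array_class: str | None = None  # filled by array_classify

    @property
    def n_monomers(self) -> int:
        return sum(1 for c in self.monomer_calls if c.monomer_class != UNASSIGNED)

    @property
    def variant_fraction(self) -> float:
        assigned = [c for c in self.monomer_calls if c.monomer_class != UNASSIGNED]
        if not assigned:
            return 0.0
        return sum(c.monomer_class == VARIANT for c in assigned) / len(assigned)

    def degenerate_rich(self, params: ScanParams) -> bool:
        return self.variant_fraction > params.max_variant_fraction

    @property
    def length(self) -> int:
        return self.end - self.start


def compile_seed(motif: str, copies: int) -> str:
    """Tandem query string: the motif repeated ``copies`` times."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    return motif * copies


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (overlapping) occurrence starts of needle in haystack."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def find_exact_seeds(
    read: Read, catalog: MotifCatalog | None = None, params: ScanParams | None = None
) -> list[SeedMatch]:
    """Every exact, zero-mismatch occurrence of each compiled seed query.

    Both strands are scanned; a reverse-complement match is reported with
    strand '-' and forward-read coordinates. Overlapping occurrences are all
    reported; output is sorted by (start, strand, motif).
    """
    catalog = catalog or MotifCatalog()
    params = params or ScanParams()
    if not read.sequence:
        raise ValueError("read is empty")
    seeds: list[SeedMatch] = []
    for motif in catalog.seed_motifs:
        query = compile_seed(motif, params.min_seed_copies)
        for s in _find_all(read.sequence, query):
            seeds.append(SeedMatch(read.read_id, s, s + len(query), "+", motif))
        rc = revcomp(query)
        if rc != query:
            for s in _find_all(read.sequence, rc):
                seeds.append(SeedMatch(read.read_id, s, s + len(query), "-", motif))
    seeds.sort(key=lambda m: (m.start, m.strand, m.motif))
    return seeds


# ---------------------------------------------------------------------------
# monomer decomposition

_WINDOW_LENGTHS = (6, 7, 8)


def _edit(a: str, b: str) -> int:
    if a == b:
        return 0
    return edlib.align(a, b)["editDistance"]


@functools.lru_cache(maxsize=1_000_000)
def _best_call_cached(
    region: str, monomers: tuple[str, ...], primaries: tuple[str, ...], max_edit: int
) -> tuple[int, str | None, int]:
    """Best (consumed_length, monomer, distance) for the next window.

    ``region`` holds the next <= 8 bases. Candidates are every catalog
    monomer against windows of length 6/7/8; ties broken by primary motif
    first (canonical before its degenerate forms, CCTGGG before CCCTGGG —
    this keeps the tiling phase anchored to the dominant monomer), then
    longer monomer, then lexicographic monomer, then window length closest
    to the monomer length.
    """
    best = None  # key tuple -> (L, monomer, d)
    for monomer in monomers:
        for L in _WINDOW_LENGTHS:
            if L > len(region):
                continue
            d = _edit(region[:L], monomer)
            key = (
                d,
                0 if monomer in primaries else 1,
                -len(monomer),
                monomer,
                abs(L - len(monomer)),
                -L,
            )
            if best is None or key < best[0]:
                best = (key, L, monomer, d)
    if best is None:  # region shorter than 6 bp
        return (len(region), None, max_edit + 1)
    _, L, monomer, d = best
    if d > max_edit:
        return (min(7, len(region)), None, d)
    return (L, monomer, d)


def decompose_array(
    seq: str,
    catalog: MotifCatalog | None = None,
    params: ScanParams | None = None,
    monomers: Sequence[str] | None = None,
) -> list[MonomerCall]:
    """Greedy left-to-right tiling of an array sequence into monomer calls.

    The concatenation of the observed call sequences always reconstructs the
    input exactly. Windows with no catalog monomer within the edit-distance
    tolerance become ``unassigned`` calls (7 bp, or the remainder).
    """
    if not seq:
        raise ValueError("array sequence is empty")
    catalog = catalog or MotifCatalog()
    params = params or ScanParams()
    cand = tuple(monomers) if monomers is not None else (
        catalog.tel_group + catalog.dtr_group
    )
    calls: list[MonomerCall] = []
    pos = 0
    n = len(seq)
    while pos < n:
        region = seq[pos : pos + 8]
        L, monomer, d = _best_call_cached(
            region, cand, catalog.seed_motifs, params.max_monomer_edit_distance
        )
        if monomer is None:
            calls.append(MonomerCall(pos, seq[pos : pos + L], UNASSIGNED, None, d))
        else:
            calls.append(
                MonomerCall(
                    pos, seq[pos : pos + L], catalog.class_of(monomer, d), monomer, d
                )
            )
        pos += L
    return calls


# ---------------------------------------------------------------------------
# array assembly


def _merge_intervals(
    intervals: list[tuple[int, int]], max_gap: int
) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _can_extend(region: str, cand: tuple[str, ...], catalog, params) -> int | None:
    """Length consumed if the next window extends the array, else None."""
    if len(region) < min(len(m) for m in cand) - params.max_monomer_edit_distance:
        return None
    L, monomer, d = _best_call_cached(
        region, cand, catalog.seed_motifs, params.max_monomer_edit_distance
    )
    if monomer is None or d > params.max_monomer_edit_distance:
        return None
    return L


def _can_extend_left(oseq: str, pos: int, cand, catalog, params) -> int | None:
    """Length consumed extending leftward (window ends at ``pos``)."""
    best = None
    for monomer in cand:
        for L in _WINDOW_LENGTHS:
            if L > pos:
                continue
            d = _edit(oseq[pos - L : pos], monomer)
            key = (
                d,
                0 if monomer in catalog.seed_motifs else 1,
                -len(monomer),
                monomer,
                abs(L - len(monomer)),
                -L,
            )
            if best is None or key < best[0]:
                best = (key, L, d)
    if best is None:
        return None
    _, L, d = best
    if d > params.max_monomer_edit_distance:
        return None
    return L


def _jump_right(oriented: str, e: int, cand: tuple[str, ...], max_gap: int) -> int | None:
    """Offset (1..max_gap) of the next exact monomer start, else None.

    Lets extension cross short unassignable stretches — broken monomers or
    the spacers of elongated units — but only when it lands on an exact
    monomer copy, which re-anchors the tiling phase.
    """
    for k in range(1, max_gap + 1):
        for m in cand:
            if oriented[e + k : e + k + len(m)] == m:
                return k
    return None


def _jump_left(oriented: str, s: int, cand: tuple[str, ...], max_gap: int) -> int | None:
    """Offset such that an exact monomer ends at s - offset, else None."""
    for k in range(1, max_gap + 1):
        for m in cand:
            if s - k - len(m) >= 0 and oriented[s - k - len(m) : s - k] == m:
                return k
    return None


def _build_hit(
    read: Read,
    ostart: int,
    oend: int,
    strand: str,
    group: str,
    catalog: MotifCatalog,
    params: ScanParams,
    oriented: str,
) -> ArrayHit | None:
    cand = catalog.group_monomers(group)
    L = len(read.sequence)
    # extend right (forward-greedy, phase-stable)
    while True:
        step = _can_extend(oriented[oend : oend + 8], cand, catalog, params)
        if step is not None and oend + step <= L:
            oend += step
            continue
        k = _jump_right(oriented, oend, cand, params.max_intra_array_gap)
        if step is None and k is not None and oend + k <= L:
            oend += k
            continue
        break
    # extend left: the walk starts at a seed-anchored monomer boundary
    while True:
        step = _can_extend_left(oriented, ostart, cand, catalog, params)
        if step is not None:
            ostart -= step
            continue
        k = _jump_left(oriented, ostart, cand, params.max_intra_array_gap)
        if k is not None:
            ostart -= k
            continue
        break
    calls = decompose_array(oriented[ostart:oend], catalog, params, monomers=cand)
    # trim unassigned calls at both ends (ragged boundaries)
    while calls and calls[0].monomer_class == UNASSIGNED:
        ostart += len(calls[0].seq)
        calls = calls[1:]
    while calls and calls[-1].monomer_class == UNASSIGNED:
        oend -= len(calls[-1].seq)
        calls = calls[:-1]
    if not calls:
        return None
    base = calls[0].offset
    calls = [replace(c, offset=c.offset - base) for c in calls]
    n_assigned = sum(1 for c in calls if c.monomer_class != UNASSIGNED)
    if n_assigned < params.min_seed_copies:
        return None
    if strand == "+":
        start, end = ostart, oend
    else:
        start, end = L - oend, L - ostart
    return ArrayHit(
        read_id=read.read_id,
        start=start,
        end=end,
        strand=strand,
        group=group,
        monomer_calls=calls,
        oriented_seq=oriented[ostart:oend],
    )


def assemble_arrays(
    read: Read,
    seeds: list[SeedMatch],
    catalog: MotifCatalog | None = None,
    params: ScanParams | None = None,
) -> list[ArrayHit]:
    """Merge compatible seeds and extend them into full arrays.

    Seeds merge when they share strand and motif group and lie within
    ``max_intra_array_gap``. Boundaries are extended outward while the next
    6-8 bp window stays within the per-monomer edit tolerance of a group
    monomer. Overlapping same-group/strand arrays are re-merged; overlapping
    arrays of different groups keep the longer one.
    """
    catalog = catalog or MotifCatalog()
    params = params or ScanParams()
    for s in seeds:
        if s.read_id != read.read_id:
            raise ValueError(
                f"seed read_id {s.read_id!r} does not match read {read.read_id!r}"
            )
    L = len(read.sequence)
    rc_seq: str | None = None
    hits: list[ArrayHit] = []
    buckets: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for s in seeds:
        buckets.setdefault((s.strand, catalog.group_of(s.motif)), []).append(
            (s.start, s.end)
        )
    for (strand, group), ivs in sorted(buckets.items()):
        if strand == "+":
            oriented = read.sequence
            o_ivs = ivs
        else:
            if rc_seq is None:
                rc_seq = revcomp(read.sequence)
            oriented = rc_seq
            o_ivs = [(L - e, L - s) for s, e in ivs]
        islands = _merge_intervals(o_ivs, params.max_intra_array_gap)
        # fuse islands reachable from each other by forward extension
        # (forward-greedy walking is phase-stable; backward walking is not)
        cand = catalog.group_monomers(group)
        fused: list[tuple[int, int]] = []
        cur_s, cur_e = islands[0]
        for nxt_s, nxt_e in islands[1:]:
            e = cur_e
            while e < nxt_s:
                step = _can_extend(oriented[e : e + 8], cand, catalog, params)
                if step is not None:
                    e += step
                    continue
                # bounded jump over unassignable bases (broken monomers,
                # elongated-unit spacers); only valid because a further seed
                # island is known to lie ahead
                if nxt_s - e <= params.max_intra_array_gap:
                    e = nxt_s
                    continue
                for k in range(1, params.max_intra_array_gap + 1):
                    st = _can_extend(
                        oriented[e + k : e + k + 8], cand, catalog, params
                    )
                    if st is not None:
                        e += k + st
                        break
                else:
                    break
            if e >= nxt_s:
                cur_e = max(e, nxt_e)
            else:
                fused.append((cur_s, cur_e))
                cur_s, cur_e = nxt_s, nxt_e
        fused.append((cur_s, cur_e))
        for os_, oe in fused:
            hit = _build_hit(read, os_, oe, strand, group, catalog, params, oriented)
            if hit is not None:
                hits.append(hit)
    # resolve residual overlaps across groups/strands: keep the longer array
    hits.sort(key=lambda h: (h.start, -(h.end - h.start), h.strand))
    resolved: list[ArrayHit] = []
    for h in hits:
        if not resolved or h.start >= resolved[-1].end:
            resolved.append(h)
        elif h.length > resolved[-1].length:
            resolved[-1] = h
    resolved.sort(key=lambda h: h.start)
    return resolved


def scan_read(
    read: Read,
    catalog: MotifCatalog | None = None,
    params: ScanParams | None = None,
) -> list[ArrayHit]:
    """Convenience: seeds + assembly in one call."""
    catalog = catalog or MotifCatalog()
    params = params or ScanParams()
    return assemble_arrays(read, find_exact_seeds(read, catalog, params), catalog, params)
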