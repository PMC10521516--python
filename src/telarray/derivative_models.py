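"""Strand-exchange recombinant model for derivative telomeric monomers.

A derivative monomer is explained as the concatenation of a substring of the
cyclic G-rich telomeric strand (TTTAGGG) and a substring of the cyclic
C-rich strand (CCCTAAA), in either order — the signature expected if a
double-strand break was repaired by exchange between the two strands of the
telomeric duplex. Both named derivatives decompose this way:
TTTAAAA = TTTA (G-strand) + AAA (C-strand), and CCTGGG = CCT (C-strand) +
GGG (G-strand).

Segments are substrings of the *cyclic* monomer (a telomeric tract has no
distinguished phase), each at least 1 base and at most two monomer lengths.

The module also provides the two generative events the simulator uses:
``strand_exchange_event`` (replace one monomer by a random valid
recombinant) and ``amplify_block`` (tandem amplification of one monomer,
the t-loop / rolling-circle style block growth).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .motif_scan import (
    MotifCatalog,
    MonomerCall,
    ScanParams,
    UNASSIGNED,
    decompose_array,
)
from .seqio import revcomp

__all__ = [
    "RecombinantDecomposition",
    "recombinant_decomposition",
    "derivative_products",
    "strand_exchange_event",
    "amplify_block",
    "retile",
]

_DNA = set("ACGT")


@dataclass(frozen=True)
class RecombinantDecomposition:
    monomer: str
    g_segment: str
    c_segment: str
    g_phase: int
    c_phase: int
    order: str  # "GC": G-segment first; "CG": C-segment first
    valid: bool = True

    def __post_init__(self):
        if self.valid:
            if self.order == "GC":
                assert self.g_segment + self.c_segment == self.monomer
            else:
                assert self.c_segment + self.g_segment == self.monomer
            assert self.g_segment and self.c_segment


def _cyclic_find(part: str, unit: str) -> int:
    """Phase of ``part`` as a substring of the cyclic ``unit``, else -1."""
    if not part or len(part) > 2 * len(unit):
        return -1
    reps = unit * (2 + len(part) // len(unit))
    idx = reps.find(part)
    if idx == -1 or idx >= len(unit):
        # any cyclic occurrence starts at a phase < |unit|
        return -1
    return idx


def recombinant_decomposition(
    monomer: str,
    g_monomer: str = "TTTAGGG",
    c_monomer: str = "CCCTAAA",
) -> list[RecombinantDecomposition]:
    """All ways to write ``monomer`` as G-strand piece + C-strand piece.

    Enumerates every split position and both segment orders (the exchange
    scheme is symmetric, so G-first and C-first are both admitted); each
    piece must be a nonempty substring of the corresponding cyclic monomer
    of length at most two monomer lengths. Deterministic order: split
    position ascending, G-first before C-first.
    """
    if len(monomer) < 2:
        raise ValueError("monomer must be at least 2 bases")
    if not set(monomer) <= _DNA:
        raise ValueError(f"non-DNA characters in {monomer!r}")
    out: list[RecombinantDecomposition] = []
    for split in range(1, len(monomer)):
        left, right = monomer[:split], monomer[split:]
        gp, cp = _cyclic_find(left, g_monomer), _cyclic_find(right, c_monomer)
        if gp != -1 and cp != -1:
            out.append(
                RecombinantDecomposition(monomer, left, right, gp, cp, "GC")
            )
        cp, gp = _cyclic_find(left, c_monomer), _cyclic_find(right, g_monomer)
        if cp != -1 and gp != -1:
            out.append(
                RecombinantDecomposition(monomer, right, left, gp, cp, "CG")
            )
    return out


def derivative_products(
    base_monomer: str = "TTTAGGG",
    lengths: Sequence[int] = (6, 7, 8),
) -> list[str]:
    """All recombinant products of the given lengths, sorted.

    Constructed directly from (cyclic G-substring, cyclic C-substring)
    pairs, where the C strand is the reverse complement of the base monomer;
    every product is recombinant_decomposition-valid by construction. The
    base monomer itself is excluded.
    """
    g = base_monomer
    c = revcomp(base_monomer)
    n = len(g)

    def cyclic_subs(unit: str, L: int) -> set[str]:
        reps = unit * (2 + L // len(unit))
        return {reps[i : i + L] for i in range(len(unit))}

    products: set[str] = set()
    for L in lengths:
        for a in range(1, L):
            b = L - a
            if a > 2 * n or b > 2 * n:
                continue
            for left in cyclic_subs(g, a):
                for right in cyclic_subs(c, b):
                    products.add(left + right)
                    products.add(right + left)
    products.discard(base_monomer)
    return sorted(products)


def retile(seqs_and_classes: Sequence[tuple[str, str]]) -> list[MonomerCall]:
    """Rebuild monomer calls with consistent offsets from (seq, class) pairs."""
    calls = []
    pos = 0
    for seq, cls in seqs_and_classes:
        calls.append(MonomerCall(pos, seq, cls))
        pos += len(seq)
    return calls


def strand_exchange_event(
    monomer_calls: Sequence[MonomerCall],
    position: int,
    rng: np.random.Generator,
    catalog: MotifCatalog | None = None,
) -> list[MonomerCall]:
    """Replace the monomer at ``position`` by a random recombinant product.

    The product is drawn uniformly from the recombinant products of the
    monomer class occupying that position (its best-matching catalog
    monomer); all other calls are untouched, and offsets are retiled. The
    new call's class is re-derived by decomposition.
    """
    if not monomer_calls:
        raise ValueError("empty array")
    if not 0 <= position < len(monomer_calls):
        raise IndexError(f"position {position} out of range")
    catalog = catalog or MotifCatalog()
    target = monomer_calls[position]
    base = target.best_monomer or target.seq
    products = derivative_products(base)
    new_seq = products[int(rng.integers(len(products)))]
    new_call = decompose_array(new_seq, catalog)[0]
    pairs = [
        (c.seq, c.monomer_class) if i != position else (new_seq, new_call.monomer_class)
        for i, c in enumerate(monomer_calls)
    ]
    return retile(pairs)


def amplify_block(
    monomer_calls: Sequence[MonomerCall],
    position: int,
    added_copies: int,
    rng: np.random.Generator | None = None,
) -> list[MonomerCall]:
    """Insert ``added_copies`` tandem copies of the monomer at ``position``.

    Models local block amplification (t-loop / rolling-circle style): the
    array grows by exactly ``added_copies`` monomers, inserted adjacent to
    the template monomer.
    """
    if not 0 <= position < len(monomer_calls):
        raise IndexError(f"position {position} out of range")
    if added_copies < 1:
        raise ValueError("added_copies must be >= 1")
    tpl = monomer_calls[position]
    pairs = [(c.seq, c.monomer_class) for c in monomer_calls]
    for _ in range(added_copies):
        pairs.insert(position + 1, (tpl.seq, tpl.monomer_class))
    return retile(pairs)
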