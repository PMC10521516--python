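"""Synthetic nanopore-like long-read libraries with planted telomeric
architectures and exact truth annotations.

The generator emulates the read-level features of the studied ON libraries:

* reads of ~10-25 kb (lognormal, median 12 kb, clipped to 5-25 kb);
* terminal arrays of pure TTTAGGG, flush to a read end (left-end arrays are
  written as the C-rich strand, as a sequencer would see them);
* terminal block-organized double-monomer arrays: TTTAGGG blocks
  interleaved with TTTAAAA blocks;
* interstitial TTTAGGG (ITR) arrays carrying a few percent of monomers that
  deviate by one or two nucleotides;
* interstitial derivative (DTR) arrays of CCTGGG interspersed with CCTAGG
  and CCCTGGG, on either strand;
* ITR-DTR colocations, opposite-orientation DTR/core/DTR junctions, and
  arrays of elongated telomere-motif-based units (incipient higher-order
  repeats);
* an i.i.d. per-base error model with the deletion / mismatch / insertion
  rates reported for R9.4 nanopore data.

Truth coordinates are propagated through the error edits rather than
re-discovered, so boundary-accuracy checks are exact. The random backbone
is screened so that no seed query occurs by chance and no window adjacent
to a planted array lies within the scanner's per-monomer edit tolerance of
any catalog monomer: at zero error rates, scan -> classify reproduces the
truth table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np

from .motif_scan import (
    MotifCatalog,
    ScanParams,
    CANONICAL,
    VARIANT,
    _best_call_cached,
    _edit,
    compile_seed,
    decompose_array,
)
from .seqio import Read, revcomp

__all__ = [
    "ErrorModel",
    "ZERO_ERRORS",
    "SimConfig",
    "TruthArray",
    "TruthEvent",
    "TruthRecord",
    "simulate_read",
    "simulate_library",
    "apply_errors",
    "measure_error_rates",
    "safe_variant_pool",
    "write_truth",
    "read_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ErrorModel:
    """Per-truth-base marginal event rates (R9.4 nanopore ranges:
    deletions 1.6-2.7%, mismatches 1.2-2.2%, insertions 1.1-2.4%)."""

    deletion_rate: float = 0.021
    mismatch_rate: float = 0.017
    insertion_rate: float = 0.017

    def __post_init__(self):
        for name in ("deletion_rate", "mismatch_rate", "insertion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.1:
                raise ValueError(f"{name}={v} outside [0, 0.1]")

    @property
    def is_zero(self) -> bool:
        return self.deletion_rate == self.mismatch_rate == self.insertion_rate == 0.0


ZERO_ERRORS = ErrorModel(0.0, 0.0, 0.0)

DEFAULT_CLASS_FREQS: dict[str, float] = {
    "pure_terminal": 0.16,
    "combined_terminal": 0.10,
    "itr": 0.16,
    "dtr": 0.12,
    "colocated": 0.06,
    "junction": 0.04,
    "hor": 0.04,
    "none": 0.32,
}


@dataclass
class SimConfig:
    n_reads: int = 100
    median_read_length: int = 12_000
    read_length_sigma: float = 0.30  # lognormal sigma
    min_read_length: int = 5_000
    max_read_length: int = 25_000
    class_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FREQS)
    )
    error_model: ErrorModel = field(default_factory=ErrorModel)
    variant_fraction: float = 0.03  # deviant-monomer fraction inside ITRs
    array_copies: tuple[int, int] = (30, 150)  # monomers per plain array
    dtr_copies: tuple[int, int] = (20, 80)
    block_count: tuple[int, int] = (2, 6)  # blocks per combined array
    block_mean_copies: int = 8  # geometric block length, min 3
    interstitial_margin: int = 2_000  # bp kept clear of read ends
    adversarial: bool = False  # plant TTTAAAA+CCTGGG-only arrays (never by default)

    def __post_init__(self):
        total = sum(self.class_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class frequencies sum to {total}, expected 1")


@dataclass
class TruthArray:
    start: int  # post-error forward-read coordinates, 0-based half-open
    end: int
    strand: str
    position_class: str  # TERMINAL / INTERSTITIAL
    composition_class: str  # PURE_TEL / COMBINED_TEL_TTTAAAA / DTR / MIXED_OTHER
    blocks: list[tuple[str, int]]  # (block class, copies) in oriented order
    n_monomers: int
    variant_fraction: float = 0.0
    elongated_unit: str = ""  # planted higher-order unit, if any


@dataclass
class TruthEvent:
    kind: str  # "junction" | "colocation"
    gap: int = 0
    detail: str = ""


@dataclass
class TruthRecord:
    read_id: str
    arrays: list[TruthArray] = field(default_factory=list)
    events: list[TruthEvent] = field(default_factory=list)
    architecture: str = "none"


# ---------------------------------------------------------------------------
# screened random sequence


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _screen_seeds(arr: np.ndarray, rng: np.random.Generator, queries: list[str]) -> None:
    """Re-randomize any chance occurrence of a seed query (in place)."""
    s = arr.tobytes().decode()
    for q in queries:
        for probe in (q, revcomp(q)):
            i = s.find(probe)
            while i != -1:
                arr[i : i + len(probe)] = _random_dna(rng, len(probe))
                s = arr.tobytes().decode()
                i = s.find(probe)


def _all_monomers_with_rc(catalog: MotifCatalog) -> tuple[str, ...]:
    mono = catalog.tel_group + catalog.dtr_group
    return tuple(sorted(set(mono) | {revcomp(m) for m in mono}))


def _region_matches(region: str, monomers: tuple[str, ...], max_edit: int) -> bool:
    """True if some window at the start of region is within max_edit of a monomer."""
    if len(region) < 4:
        return False
    _, best, _ = _best_call_cached(region[:8], monomers, (), max_edit)
    return best is not None


def _left_matches(context: str, monomers: tuple[str, ...], max_edit: int) -> bool:
    """True if some 6-8 bp window ending at the end of context matches."""
    for L in (6, 7, 8):
        if L > len(context):
            continue
        w = context[-L:]
        for m in monomers:
            if _edit(w, m) <= max_edit:
                return True
    return False


def safe_variant_pool(
    catalog: MotifCatalog | None = None, params: ScanParams | None = None
) -> list[str]:
    """Deviant canonical monomers that decompose cleanly as 'variant'.

    Candidates are the degenerate forms (TTTAGG, TTAGGG) plus every single
    substitution of the canonical heptamer; a candidate is kept only if,
    embedded between canonical monomers, greedy decomposition returns it as
    one variant call with the planted sequence.
    """
    catalog = catalog or MotifCatalog()
    params = params or ScanParams()
    can = catalog.canonical
    candidates = list(catalog.degenerate_canonical)
    for i in range(len(can)):
        for b in "ACGT":
            if b != can[i]:
                candidates.append(can[:i] + b + can[i + 1 :])
    pool = []
    for v in candidates:
        calls = decompose_array(can * 2 + v + can * 2, catalog, params,
                                monomers=catalog.tel_group)
        classes = [c.monomer_class for c in calls]
        seqs = [c.seq for c in calls]
        if classes == [CANONICAL] * 2 + [VARIANT] + [CANONICAL] * 2 and seqs[2] == v:
            pool.append(v)
    return pool


# ---------------------------------------------------------------------------
# architecture construction (pre-error, exact truth)


def _geometric_block(rng: np.random.Generator, mean: int) -> int:
    # minimum 3 copies so a block is never absorbed by the classifier
    return 3 + int(rng.geometric(1.0 / max(1, mean - 3)))


def _pure_tract(rng, copies: int) -> tuple[str, list[tuple[str, int]]]:
    return "TTTAGGG" * copies, [("canonical", copies)]


def _combined_tract(rng, cfg: SimConfig) -> tuple[str, list[tuple[str, int]]]:
    n_blocks = int(rng.integers(cfg.block_count[0], cfg.block_count[1] + 1))
    if n_blocks % 2 == 0 and rng.random() < 0.5:
        start_with = "TTTAAAA"
    else:
        start_with = "TTTAGGG"
    seq, blocks = [], []
    motif = start_with
    for _ in range(n_blocks):  # alternation guarantees both classes appear
        k = _geometric_block(rng, cfg.block_mean_copies)
        seq.append(motif * k)
        blocks.append(("canonical" if motif == "TTTAGGG" else "TTTAAAA", k))
        motif = "TTTAAAA" if motif == "TTTAGGG" else "TTTAGGG"
    return "".join(seq), blocks


def _itr_tract(
    rng, cfg: SimConfig, pool: list[str]
) -> tuple[str, list[tuple[str, int]], float]:
    copies = int(rng.integers(cfg.array_copies[0], cfg.array_copies[1] + 1))
    is_variant = rng.random(copies) < cfg.variant_fraction
    # never allow 3+ adjacent variants: they can open a seed gap wider than
    # the merge tolerance and split the array
    for i in range(2, copies):
        if is_variant[i] and is_variant[i - 1] and is_variant[i - 2]:
            is_variant[i] = False
    # edges stay canonical (3 copies: one full seed) so boundaries are
    # anchored by an exact seed on both sides
    k = min(3, copies)
    is_variant[:k] = False
    is_variant[-k:] = False
    monomers = [
        pool[int(rng.integers(len(pool)))] if v else "TTTAGGG" for v in is_variant
    ]
    frac = float(np.mean([m != "TTTAGGG" for m in monomers]))
    return "".join(monomers), [("canonical", copies)], frac


_DTR_CHOICES = ("CCTGGG", "CCTAGG", "CCCTGGG")
_DTR_WEIGHTS = (0.85, 0.10, 0.05)


def _dtr_tract(rng, copies: int) -> tuple[str, list[tuple[str, int]]]:
    picks = rng.choice(len(_DTR_CHOICES), size=copies, p=_DTR_WEIGHTS)
    k = min(3, copies)  # crisp CCTGGG edges: one exact seed at each boundary
    picks[:k] = 0
    picks[-k:] = 0
    return (
        "".join(_DTR_CHOICES[i] for i in picks),
        [("CCTGGG_family", copies)],
    )


def _hor_tract(rng, cfg: SimConfig, screen_monomers, params) -> tuple[str, str, int]:
    """(tract, unit, copies): unit = (TTTAGGG)x3 + screened 7-bp spacer."""
    g3 = "TTTAGGG" * 3
    while True:
        spacer = _random_dna(rng, 7).tobytes().decode()
        region = (spacer + "TTTAGGG")[:8]
        if not _region_matches(region, screen_monomers, params.max_monomer_edit_distance):
            if not _left_matches(g3[-8:] + spacer, screen_monomers,
                                 params.max_monomer_edit_distance):
                break
    unit = g3 + spacer
    copies = int(rng.integers(8, 16))
    return unit * (copies - 1) + g3, unit, copies


# ---------------------------------------------------------------------------
# error model


_BASE_IDX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_IDX[_b] = _i


def apply_errors(
    seq: str, em: ErrorModel, rng: np.random.Generator, with_counts: bool = False
):
    """Apply i.i.d. per-base errors; return (read, truth->read position map).

    ``pos_map`` has length len(seq)+1; truth interval [s, e) maps to read
    interval [pos_map[s], pos_map[e]). Deletion removes the base; mismatch
    substitutes one of the other three bases (drawn conditionally on
    survival so the marginal mismatch rate equals the parameter); insertion
    adds one uniform base after the position, independent of deletion.

    With ``with_counts`` a third element holds the planted event counts
    {"del", "mm", "ins"} — the exact ground truth, free of the slight
    degeneracy of alignment-based re-estimation (an adjacent deletion and
    insertion are indistinguishable from one substitution).
    """
    n = len(seq)
    if em.is_zero:
        pm = np.arange(n + 1, dtype=np.int64)
        return (seq, pm, {"del": 0, "mm": 0, "ins": 0}) if with_counts else (seq, pm)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    dele = rng.random(n) < em.deletion_rate
    mm_eff = em.mismatch_rate / (1.0 - em.deletion_rate)
    mism = (rng.random(n) < mm_eff) & ~dele
    ins = rng.random(n) < em.insertion_rate
    idx = _BASE_IDX[arr].astype(np.int64)
    shift = rng.integers(1, 4, size=n)
    final = arr.copy()
    final[mism] = _BASES[(idx[mism] + shift[mism]) % 4]
    ins_bases = _BASES[rng.integers(0, 4, size=n)]
    keep = (~dele).astype(np.int64)
    counts = keep + ins
    pos_map = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=pos_map[1:])
    out = np.empty(int(pos_map[-1]), dtype=np.uint8)
    kept_slots = pos_map[:-1][~dele]
    out[kept_slots] = final[~dele]
    ins_slots = (pos_map[:-1] + keep)[ins]
    out[ins_slots] = ins_bases[ins]
    read = out.tobytes().decode()
    if with_counts:
        counts = {
            "del": int(dele.sum()),
            "mm": int(mism.sum()),
            "ins": int(ins.sum()),
        }
        return read, pos_map, counts
    return read, pos_map


def measure_error_rates(read_seq: str, truth_seq: str) -> tuple[float, float, float]:
    """(deletion, mismatch, insertion) fractions per truth base, by global
    alignment of the read against its truth sequence."""
    res = edlib.align(read_seq, truth_seq, mode="NW", task="path")
    counts = {"=": 0, "X": 0, "I": 0, "D": 0, "M": 0}
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            counts[ch] += int(num)
            num = ""
    n = len(truth_seq)
    return counts["D"] / n, counts["X"] / n, counts["I"] / n


# ---------------------------------------------------------------------------
# read / library simulation


def _sample_read_length(cfg: SimConfig, rng) -> int:
    mu = np.log(cfg.median_read_length)
    L = int(np.exp(rng.normal(mu, cfg.read_length_sigma)))
    return int(np.clip(L, cfg.min_read_length, cfg.max_read_length))


def _place_segments(
    rng,
    read_len: int,
    segments: list[tuple[str, dict]],
    gaps: list[int],
    terminal_side: str | None,
    margin: int,
) -> list[tuple[int, int, str, dict]]:
    """Assign forward coordinates to tract segments separated by fixed gaps."""
    total = sum(len(s) for s, _ in segments) + sum(gaps)
    if terminal_side == "left":
        start = 0
    elif terminal_side == "right":
        start = read_len - total
    else:
        lo, hi = margin, read_len - margin - total
        if hi < lo:
            raise ValueError("architecture longer than read")
        start = int(rng.integers(lo, hi + 1))
    placed = []
    pos = start
    for k, (s, meta) in enumerate(segments):
        placed.append((pos, pos + len(s), s, meta))
        pos += len(s)
        if k < len(gaps):
            pos += gaps[k]
    return placed


def _build_architecture(cfg: SimConfig, rng, arch: str, read_len: int, pool, params):
    """Return (segments, gaps, terminal_side, events, elongated_unit)."""
    segs: list[tuple[str, dict]] = []
    gaps: list[int] = []
    events: list[TruthEvent] = []
    side = None
    if arch == "none":
        return segs, gaps, side, events
    if arch in ("pure_terminal", "combined_terminal"):
        side = "left" if rng.random() < 0.5 else "right"
        if arch == "pure_terminal":
            copies = int(rng.integers(*cfg.array_copies))
            tract, blocks = _pure_tract(rng, copies)
            comp = "PURE_TEL"
            vf = 0.0
        else:
            tract, blocks = _combined_tract(rng, cfg)
            comp = "COMBINED_TEL_TTTAAAA"
            vf = 0.0
        strand = "-" if side == "left" else "+"
        seq = revcomp(tract) if strand == "-" else tract
        segs.append(
            (seq, dict(strand=strand, position="TERMINAL", comp=comp,
                       blocks=blocks, vf=vf, unit=""))
        )
    elif arch == "itr":
        tract, blocks, vf = _itr_tract(rng, cfg, pool)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = revcomp(tract) if strand == "-" else tract
        segs.append(
            (seq, dict(strand=strand, position="INTERSTITIAL", comp="PURE_TEL",
                       blocks=blocks, vf=vf, unit=""))
        )
    elif arch == "dtr":
        copies = int(rng.integers(*cfg.dtr_copies))
        tract, blocks = _dtr_tract(rng, copies)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = revcomp(tract) if strand == "-" else tract
        segs.append(
            (seq, dict(strand=strand, position="INTERSTITIAL", comp="DTR",
                       blocks=blocks, vf=0.0, unit=""))
        )
    elif arch == "colocated":
        tract, blocks, vf = _itr_tract(rng, cfg, pool)
        s1 = "+" if rng.random() < 0.5 else "-"
        itr_seg = (revcomp(tract) if s1 == "-" else tract,
                   dict(strand=s1, position="INTERSTITIAL", comp="PURE_TEL",
                        blocks=blocks, vf=vf, unit=""))
        copies = int(rng.integers(*cfg.dtr_copies))
        dtract, dblocks = _dtr_tract(rng, copies)
        s2 = "+" if rng.random() < 0.5 else "-"
        dtr_seg = (revcomp(dtract) if s2 == "-" else dtract,
                   dict(strand=s2, position="INTERSTITIAL", comp="DTR",
                        blocks=dblocks, vf=0.0, unit=""))
        gap = int(rng.integers(50, 801))
        if rng.random() < 0.5:
            segs = [itr_seg, dtr_seg]
        else:
            segs = [dtr_seg, itr_seg]
        gaps = [gap]
        events.append(TruthEvent(kind="colocation", gap=gap))
    elif arch == "junction":
        s1 = "+" if rng.random() < 0.5 else "-"
        s2 = "-" if s1 == "+" else "+"
        k1 = int(rng.integers(15, 26))
        k2 = int(rng.integers(15, 26))
        core_copies = int(rng.integers(3, 9))
        left_tract, lb = _dtr_tract(rng, k1)
        right_tract, rb = _dtr_tract(rng, k2)
        core, cb = _pure_tract(rng, core_copies)
        segs = [
            (revcomp(left_tract) if s1 == "-" else left_tract,
             dict(strand=s1, position="INTERSTITIAL", comp="DTR", blocks=lb,
                  vf=0.0, unit="")),
            (core, dict(strand="+", position="INTERSTITIAL", comp="PURE_TEL",
                        blocks=cb, vf=0.0, unit="")),
            (revcomp(right_tract) if s2 == "-" else right_tract,
             dict(strand=s2, position="INTERSTITIAL", comp="DTR", blocks=rb,
                  vf=0.0, unit="")),
        ]
        gaps = [int(rng.integers(10, 41)), int(rng.integers(10, 41))]
        events.append(
            TruthEvent(kind="junction", detail=f"{s1}/core{core_copies}/{s2}")
        )
    elif arch == "hor":
        screen = _all_monomers_with_rc(MotifCatalog())
        tract, unit, copies = _hor_tract(rng, cfg, screen, params)
        # block copy counts include the (copies-1) unassigned spacer calls,
        # which the classifier absorbs into the canonical run
        segs.append(
            (tract, dict(strand="+", position="INTERSTITIAL", comp="PURE_TEL",
                         blocks=[("canonical", copies * 4 - 1)], vf=0.0, unit=unit))
        )
    elif arch == "forbidden":
        # adversarial only: TTTAAAA block directly joined to CCTGGG block
        k1, k2 = int(rng.integers(5, 12)), int(rng.integers(5, 12))
        tract = "TTTAAAA" * k1 + "CCTGGG" * k2
        segs.append(
            (tract, dict(strand="+", position="INTERSTITIAL", comp="MIXED_OTHER",
                         blocks=[("TTTAAAA", k1), ("CCTGGG_family", k2)],
                         vf=0.0, unit="")))
    else:
        raise ValueError(f"unknown architecture {arch!r}")
    return segs, gaps, side, events


_FLANK = 22  # bp of flank the scanner can reach via its bounded exact-jump


def _boundaries_ok(
    seq: str, s: int, e: int, monomers, exact_set, max_edit: int
) -> bool:
    """No window crossing an array boundary may extend or re-anchor a scan."""
    if _region_matches(seq[e : e + 8], monomers, max_edit):
        return False
    if _left_matches(seq[max(0, s - 8) : s], monomers, max_edit):
        return False
    right = seq[e : e + _FLANK]
    left = seq[max(0, s - _FLANK) : s]
    for m in exact_set:
        if m in right or m in left:
            return False
    return True


def simulate_read(
    cfg: SimConfig,
    rng: np.random.Generator,
    read_id: str = "sim_read",
    architecture: str | None = None,
    catalog: MotifCatalog | None = None,
    params: ScanParams | None = None,
    _pool: list[str] | None = None,
) -> tuple[Read, TruthRecord]:
    """One read plus its truth record.

    The architecture class is sampled from ``cfg.class_freqs`` unless given.
    Backbone bases adjacent to planted arrays are resampled until no 6-8 bp
    window crossing an array boundary lies within the scanner's edit
    tolerance of any catalog monomer (or its reverse complement), so planted
    boundaries are the exact boundaries the scanner can recover.
    """
    catalog = catalog or MotifCatalog()
    params = params or ScanParams()
    pool = _pool if _pool is not None else safe_variant_pool(catalog, params)
    names = sorted(cfg.class_freqs)
    if architecture is None:
        freqs = np.array([cfg.class_freqs[k] for k in names])
        architecture = names[int(rng.choice(len(names), p=freqs))]
    queries = [compile_seed(m, params.min_seed_copies) for m in catalog.seed_motifs]
    screen_monomers = _all_monomers_with_rc(catalog)

    for _attempt in range(100):
        read_len = _sample_read_length(cfg, rng)
        try:
            segs, gaps, side, events = _build_architecture(
                cfg, rng, architecture, read_len, pool, params
            )
        except ValueError:
            continue
        backbone = _random_dna(rng, read_len)
        _screen_seeds(backbone, rng, queries)
        placed = (
            _place_segments(rng, read_len, segs, gaps, side, cfg.interstitial_margin)
            if segs
            else []
        )
        arr = backbone.copy()
        protected = np.zeros(read_len, dtype=bool)
        exact_sets = []
        for s, e, tract, meta in placed:
            arr[s:e] = np.frombuffer(tract.encode(), dtype=np.uint8)
            protected[s:e] = True
            if meta["comp"] == "DTR":
                grp = catalog.dtr_group
            elif meta["comp"] == "MIXED_OTHER":
                grp = catalog.tel_group + catalog.dtr_group
            else:
                grp = catalog.tel_group
            exact_sets.append(tuple(sorted(set(grp) | {revcomp(m) for m in grp})))
        # settle boundary screening
        ok = not placed
        for _round in range(200):
            seq = arr.tobytes().decode()
            bad = [
                (s, e)
                for (s, e, _, _), exact in zip(placed, exact_sets)
                if not _boundaries_ok(
                    seq, s, e, screen_monomers, exact,
                    params.max_monomer_edit_distance,
                )
            ]
            if not bad:
                ok = True
                break
            for s, e in bad:
                for lo, hi in (
                    (max(0, s - _FLANK), s),
                    (e, min(read_len, e + _FLANK)),
                ):
                    sel = ~protected[lo:hi]
                    if sel.any():
                        repl = _random_dna(rng, int(sel.sum()))
                        seg = arr[lo:hi]
                        seg[sel] = repl
                        arr[lo:hi] = seg
        if not ok:
            continue
        truth_seq = arr.tobytes().decode()
        read_seq, pos_map = apply_errors(truth_seq, cfg.error_model, rng)
        if len(read_seq) == 0:
            continue
        arrays = []
        for s, e, tract, meta in placed:
            arrays.append(
                TruthArray(
                    start=int(pos_map[s]),
                    end=int(pos_map[e]),
                    strand=meta["strand"],
                    position_class=meta["position"],
                    composition_class=meta["comp"],
                    blocks=list(meta["blocks"]),
                    n_monomers=sum(k for _, k in meta["blocks"]),
                    variant_fraction=meta["vf"],
                    elongated_unit=meta["unit"],
                )
            )
        record = TruthRecord(
            read_id=read_id, arrays=arrays, events=events, architecture=architecture
        )
        return Read(read_id=read_id, sequence=read_seq), record
    raise RuntimeError(
        f"could not build architecture {architecture!r} within 100 attempts"
    )


def simulate_library(
    cfg: SimConfig,
    seed: int | np.random.Generator,
    out_fasta: str | Path | None = None,
    out_truth: str | Path | None = None,
) -> tuple[list[Read], list[TruthRecord]]:
    """A full library: identical seed gives byte-identical outputs."""
    if cfg.n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    freqs = dict(cfg.class_freqs)
    if cfg.adversarial:
        freqs = {k: v * 0.9 for k, v in freqs.items()}
        freqs["forbidden"] = 0.1
    cfg_local = SimConfig(**{**asdict_config(cfg), "class_freqs": freqs})
    pool = safe_variant_pool()
    reads, truths = [], []
    for i in range(cfg.n_reads):
        r, t = simulate_read(cfg_local, rng, read_id=f"read_{i:05d}", _pool=pool)
        reads.append(r)
        truths.append(t)
    if out_fasta is not None:
        from .seqio import write_library

        write_library(reads, out_fasta)
    if out_truth is not None:
        write_truth(truths, out_truth, seed=seed if isinstance(seed, int) else None)
    return reads, truths


def asdict_config(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["error_model"] = cfg.error_model
    return d


def write_truth(truths: Sequence[TruthRecord], path: str | Path, seed=None) -> None:
    """Truth table TSV: one row per planted array or event."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write(
            "read_id\tkind\tstart\tend\tstrand\tposition_class\t"
            "composition_class\tblocks\tn_monomers\tvariant_fraction\t"
            "elongated_unit\tarchitecture\tgap\tdetail\n"
        )
        for t in truths:
            if not t.arrays and not t.events:
                fh.write(
                    f"{t.read_id}\tnone\t\t\t\t\t\t\t\t\t\t{t.architecture}\t\t\n"
                )
            for a in t.arrays:
                blocks = ",".join(f"{c}:{k}" for c, k in a.blocks)
                fh.write(
                    f"{t.read_id}\tarray\t{a.start}\t{a.end}\t{a.strand}\t"
                    f"{a.position_class}\t{a.composition_class}\t{blocks}\t"
                    f"{a.n_monomers}\t{a.variant_fraction:.4f}\t"
                    f"{a.elongated_unit}\t{t.architecture}\t\t\n"
                )
            for ev in t.events:
                fh.write(
                    f"{t.read_id}\tevent\t\t\t\t\t\t\t\t\t\t{t.architecture}\t"
                    f"{ev.gap}\t{ev.kind}:{ev.detail}\n"
                )


def read_truth(path: str | Path) -> list[TruthRecord]:
    records: dict[str, TruthRecord] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("read_id"):
                continue
            f = line.rstrip("\n").split("\t")
            rid, kind = f[0], f[1]
            rec = records.setdefault(rid, TruthRecord(read_id=rid, architecture=f[11]))
            if kind == "array":
                blocks = [
                    (c, int(k))
                    for c, k in (b.split(":") for b in f[7].split(",") if b)
                ]
                rec.arrays.append(
                    TruthArray(
                        start=int(f[2]),
                        end=int(f[3]),
                        strand=f[4],
                        position_class=f[5],
                        composition_class=f[6],
                        blocks=blocks,
                        n_monomers=int(f[8]),
                        variant_fraction=float(f[9]),
                        elongated_unit=f[10],
                    )
                )
            elif kind == "event":
                k, _, detail = f[13].partition(":")
                rec.events.append(TruthEvent(kind=k, gap=int(f[12]), detail=detail))
    return list(records.values())
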