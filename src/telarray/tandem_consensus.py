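"""Tandem-repeat consensus monomers via wraparound alignment.

This module carries the consensus-building role that Tandem Repeats
Finder played in the original read analysis, as a simplified engine:

1. ``estimate_periods`` — candidate repeat unit lengths from the histogram
   of distances between successive identical k-words (the same signal that
   shows up as parallel diagonals in a self dot plot: the spacing between
   diagonals equals the unit length).
2. ``wraparound_consensus`` — dynamic-programming alignment of the array
   against a *cyclic* template of the candidate period. The template starts
   as the first period-length window and is refined by column majority vote
   over the aligned copies until it is stable. Scores default to match +2,
   mismatch -3, indel -5.
3. ``detect_elongated_monomers`` — for interstitial arrays, consensus
   monomers are built at every supported period of at least twice the base
   motif length; units that still contain a (possibly slightly mutated) copy
   of the base motif are reported. In the studied libraries such
   telomere-motif-based units grow up to 195 bp.

The consensus is reported in its lexicographically smallest rotation, since
a tandem tract carries no distinguished phase.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np

from .motif_scan import ArrayHit
from .seqio import revcomp

__all__ = [
    "ConsensusReport",
    "DotPlot",
    "estimate_periods",
    "wraparound_consensus",
    "detect_elongated_monomers",
    "self_dotplot",
    "render_dotplot",
    "canonical_rotation",
]

DEFAULT_WEIGHTS = (2, -3, -5)  # match, mismatch, indel


@dataclass
class ConsensusReport:
    consensus: str
    period: int
    copy_number: float
    percent_identity: float
    indel_rate: float
    distinct_consensus_count: int = 1
    support: int = 0  # k-word support for the underlying period candidate

    def __post_init__(self):
        assert self.period == len(self.consensus)


def canonical_rotation(seq: str) -> str:
    """Lexicographically smallest rotation (Booth would do; n is tiny)."""
    return min(seq[i:] + seq[:i] for i in range(len(seq)))


def estimate_periods(
    seq: str,
    word: int = 8,
    max_period: int = 210,
    min_support: int = 5,
) -> list[tuple[int, int]]:
    """Ranked candidate periods as (period, support) pairs.

    Support of period d = number of k-word positions whose *next* identical
    occurrence lies exactly d bases downstream. Ranked by support descending,
    ties by smaller period.
    """
    if len(seq) < 2 * word:
        raise ValueError("sequence shorter than two words")
    hist: Counter[int] = Counter()
    last: dict[str, int] = {}
    for i in range(len(seq) - word + 1):
        w = seq[i : i + word]
        j = last.get(w)
        if j is not None:
            d = i - j
            if d <= max_period:
                hist[d] += 1
        last[w] = i
    cands = [(p, s) for p, s in hist.items() if s >= min_support]
    cands.sort(key=lambda ps: (-ps[1], ps[0]))
    return cands


# ---------------------------------------------------------------------------
# wraparound DP

_BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(_BASES)}


def _encode(seq: str) -> np.ndarray:
    return np.array([_B2I.get(c, 4) for c in seq], dtype=np.int8)


def _wrap_align(seq_i: np.ndarray, tpl_i: np.ndarray, weights):
    """One wraparound alignment pass of seq against cyclic template.

    Returns (score_matrix S of shape (n+1, p), final score). Row 0 is free
    (alignment may start at any template phase); the end is free as well.
    Horizontal (template-consuming) moves wrap around the template cycle;
    the in-row cyclic dependency is resolved exactly with a prefix-max scan
    over the doubled column axis, valid because gap penalties are negative.
    """
    m, mm, g = weights
    n, p = len(seq_i), len(tpl_i)
    S = np.zeros((n + 1, p), dtype=np.float32)
    jj = np.arange(p, dtype=np.float32)
    for i in range(1, n + 1):
        sub = np.where(tpl_i == seq_i[i - 1], np.float32(m), np.float32(mm))
        diag = np.roll(S[i - 1], 1) + sub
        up = S[i - 1] + g
        cur = np.maximum(diag, up)
        # exact left-move closure on the cycle: two prefix-max sweeps
        a = np.concatenate([cur - g * jj, cur - g * (jj + p)])
        run = np.maximum.accumulate(a)
        best_left = np.empty(p, dtype=np.float32)
        best_left[0] = run[p - 1] + g * np.float32(p)  # wrap from column p-1
        best_left[1:] = run[: p - 1]
        cur = np.maximum(cur, best_left + g * jj + g)
        # one more forward fix-up for chains crossing the seam twice is not
        # needed: the doubled scan already covers a full extra cycle
        a = np.concatenate([cur - g * jj, cur - g * (jj + p)])
        run = np.maximum.accumulate(a)
        best_left[0] = run[p - 1] + g * np.float32(p)
        best_left[1:] = run[: p - 1]
        cur = np.maximum(cur, best_left + g * jj + g)
        S[i] = cur
    return S


def _traceback(S: np.ndarray, seq_i: np.ndarray, tpl_i: np.ndarray, weights):
    """Recover column statistics from a filled wraparound matrix.

    Returns (col_chars counts (p,5): A,C,G,T,gap; ins_chars list of Counters;
    stats dict with match/mismatch/ins/del counts).
    """
    m, mm, g = weights
    n, p = len(seq_i), len(tpl_i)
    col = np.zeros((p, 5), dtype=np.int64)
    ins: list[Counter] = [Counter() for _ in range(p)]
    stats = {"match": 0, "mismatch": 0, "ins": 0, "del": 0}
    i = n
    j = int(np.argmax(S[n]))
    eps = 1e-3
    while i > 0:
        jm1 = (j - 1) % p
        sub = m if tpl_i[j] == seq_i[i - 1] else mm
        if abs(S[i, j] - (S[i - 1, jm1] + sub)) < eps:
            col[j, seq_i[i - 1]] += 1
            stats["match" if sub == m else "mismatch"] += 1
            i -= 1
            j = jm1
        elif abs(S[i, j] - (S[i, jm1] + g)) < eps:
            col[j, 4] += 1  # template column skipped: deletion in the copy
            stats["del"] += 1
            j = jm1
        elif abs(S[i, j] - (S[i - 1, j] + g)) < eps:
            ins[j][int(seq_i[i - 1])] += 1
            stats["ins"] += 1
            i -= 1
        else:  # numerical fallback: take the best predecessor
            opts = [
                (S[i - 1, jm1] + sub, "diag"),
                (S[i, jm1] + g, "left"),
                (S[i - 1, j] + g, "up"),
            ]
            _, move = max(opts)
            if move == "diag":
                col[j, seq_i[i - 1]] += 1
                stats["match" if sub == m else "mismatch"] += 1
                i -= 1
                j = jm1
            elif move == "left":
                col[j, 4] += 1
                stats["del"] += 1
                j = jm1
            else:
                ins[j][int(seq_i[i - 1])] += 1
                stats["ins"] += 1
                i -= 1
    return col, ins, stats


def _consensus_from_columns(col: np.ndarray, ins, copies: float) -> str:
    out = []
    p = col.shape[0]
    for j in range(p):
        counts = col[j]
        if counts.sum() == 0:
            continue
        k = int(np.argmax(counts))
        if k != 4:  # majority is a base, not a gap
            out.append(_BASES[k])
        # insertions after this column shared by most copies become columns
        if ins[j]:
            base, cnt = ins[j].most_common(1)[0]
            if cnt > copies / 2:
                out.append(_BASES[base])
    return "".join(out)


def wraparound_consensus(
    seq: str,
    period: int,
    weights: tuple[int, int, int] = DEFAULT_WEIGHTS,
    max_iter: int = 5,
) -> ConsensusReport:
    """Consensus monomer of ``seq`` under a cyclic template of ``period`` bp.

    The initial template is the first period-length window; each iteration
    realigns the full sequence and replaces the template by the column
    majority (dropping majority-gap columns, adding majority insertions),
    so the period may drift toward the true unit length. Identity is
    matches / aligned columns; the indel rate is indels / sequence length.
    """
    if period > len(seq):
        raise ValueError("period exceeds sequence length")
    if period < 1:
        raise ValueError("period must be positive")
    seq_i = _encode(seq)
    tpl = seq[:period]
    for _ in range(max_iter):
        tpl_i = _encode(tpl)
        S = _wrap_align(seq_i, tpl_i, weights)
        col, ins, stats = _traceback(S, seq_i, tpl_i, weights)
        new = _consensus_from_columns(col, ins, len(seq) / max(1, len(tpl)))
        if not new:
            break
        if new == tpl:
            break
        tpl = new
    # final alignment against the stable template for reported statistics
    tpl_i = _encode(tpl)
    S = _wrap_align(seq_i, tpl_i, weights)
    col, ins, stats = _traceback(S, seq_i, tpl_i, weights)
    aligned_cols = stats["match"] + stats["mismatch"] + stats["ins"] + stats["del"]
    identity = stats["match"] / aligned_cols if aligned_cols else 0.0
    indel_rate = (stats["ins"] + stats["del"]) / len(seq)
    return ConsensusReport(
        consensus=canonical_rotation(tpl),
        period=len(tpl),
        copy_number=len(seq) / len(tpl),
        percent_identity=identity,
        indel_rate=indel_rate,
    )


def _contains_motif(consensus: str, motif: str, max_edit: int = 2) -> bool:
    """Does the cyclic consensus hold a copy of the motif within max_edit?"""
    doubled = consensus + consensus[: len(motif)]
    res = edlib.align(motif, doubled, mode="HW", task="distance")
    return res["editDistance"] <= max_edit


def detect_elongated_monomers(
    hit: ArrayHit | str,
    base_motif: str = "TTTAGGG",
    word: int = 8,
    max_period: int = 210,
    min_support: int = 5,
    weights: tuple[int, int, int] = DEFAULT_WEIGHTS,
    max_candidates: int = 10,
) -> list[ConsensusReport]:
    """Consensus monomers longer than the base motif that still contain it.

    Runs period estimation plus wraparound consensus at every supported
    period >= 2x the base motif length and keeps consensus units holding at
    least one copy of the base motif within edit distance 2. Each report
    carries ``distinct_consensus_count`` = number of distinct unit sequences
    found for the array.
    """
    seq = hit.oriented_seq if isinstance(hit, ArrayHit) else hit
    if len(seq) < 2 * word:
        return []
    cands = estimate_periods(seq, word=word, max_period=max_period, min_support=min_support)
    cands = [ps for ps in cands if ps[0] >= 2 * len(base_motif)]
    reports: dict[str, ConsensusReport] = {}
    for period, support in cands[:max_candidates]:
        if period > len(seq):
            continue
        rep = wraparound_consensus(seq, period, weights=weights)
        if len(rep.consensus) < 2 * len(base_motif):
            continue
        if not _contains_motif(rep.consensus, base_motif):
            continue
        rep.support = support
        reports.setdefault(rep.consensus, rep)
    out = list(reports.values())
    for rep in out:
        rep.distinct_consensus_count = len(out)
    out.sort(key=lambda r: (-r.period, r.consensus))
    return out


# ---------------------------------------------------------------------------
# self dot plot


@dataclass
class DotPlot:
    word: int
    length: int
    forward: list[tuple[int, int]]
    reverse: list[tuple[int, int]]

    def offset_histogram(self) -> Counter:
        """Histogram of diagonal offsets (j - i) over forward matches, i<j."""
        return Counter(j - i for i, j in self.forward if j > i)

    def offset_mode(self) -> int | None:
        hist = self.offset_histogram()
        if not hist:
            return None
        top = max(hist.values())
        return min(d for d, c in hist.items() if c == top)


def self_dotplot(
    seq: str, word: int = 8, allow_rc: bool = True, max_offset: int | None = None
) -> DotPlot:
    """Sparse self-comparison: identical k-words give forward dots, k-words
    matching a reverse-complemented k-word give reverse dots.

    The main diagonal (i, i) is included in the forward set. ``max_offset``
    bounds |j - i| to keep whole-read plots sparse.
    """
    if word < 4:
        raise ValueError("word must be >= 4")
    n = len(seq)
    positions: dict[str, list[int]] = {}
    for i in range(n - word + 1):
        positions.setdefault(seq[i : i + word], []).append(i)
    forward: list[tuple[int, int]] = [(i, i) for i in range(n - word + 1)]
    for pos in positions.values():
        for a in range(len(pos)):
            for b in range(a + 1, len(pos)):
                if max_offset is not None and pos[b] - pos[a] > max_offset:
                    break
                forward.append((pos[a], pos[b]))
    reverse: list[tuple[int, int]] = []
    if allow_rc:
        for w, pos in positions.items():
            rc = revcomp(w)
            if rc < w:
                continue  # visit each unordered word pair once
            rpos = positions.get(rc)
            if not rpos:
                continue
            for i in pos:
                for j in rpos:
                    if rc == w and j <= i:
                        continue
                    if max_offset is not None and abs(j - i) > max_offset:
                        continue
                    reverse.append((min(i, j), max(i, j)))
    return DotPlot(word=word, length=n, forward=forward, reverse=reverse)


def render_dotplot(dp: DotPlot, png_path: str | Path, tsv_path: str | Path | None = None):
    """Write the dot plot as an image plus an optional TSV of matches."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if dp.forward:
        xs, ys = zip(*dp.forward)
        ax.scatter(xs, ys, s=0.5, c="green", label="forward", rasterized=True)
        ax.scatter(ys, xs, s=0.5, c="green", rasterized=True)
    if dp.reverse:
        xs, ys = zip(*dp.reverse)
        ax.scatter(xs, ys, s=0.5, c="red", label="reverse", rasterized=True)
        ax.scatter(ys, xs, s=0.5, c="red", rasterized=True)
    ax.set_xlim(0, dp.length)
    ax.set_ylim(0, dp.length)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("position (bp)")
    ax.legend(loc="upper left", markerscale=10)
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("i\tj\tkind\n")
            for i, j in dp.forward:
                fh.write(f"{i}\t{j}\tforward\n")
            for i, j in dp.reverse:
                fh.write(f"{i}\t{j}\treverse\n")
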