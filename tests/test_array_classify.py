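"""Positional/compositional classification, junctions and colocations."""

import itertools

import numpy as np
import pytest

from telarray.array_classify import (
    BLOCK_CANONICAL,
    BLOCK_CCTGGG,
    BLOCK_TTTAAAA,
    ClassifyParams,
    CompositionClass,
    PositionClass,
    check_forbidden_combination,
    classify_composition,
    classify_position,
    classify_read_arrays,
    detect_blocks,
    detect_colocations,
    detect_junctions,
)
from telarray.motif_scan import ArrayHit, MonomerCall, decompose_array, scan_read
from telarray.seqio import Read
from telarray.synthetic_data import SimConfig, ZERO_ERRORS, simulate_read
from conftest import PROBE_70BP


def _hit(start, end, read_id="r", strand="+"):
    return ArrayHit(read_id, start, end, strand, "tel", [], "")


class TestClassifyPosition:
    def test_edge_array_is_terminal(self):
        assert classify_position(_hit(0, 2000), 19_572, 100) == PositionClass.TERMINAL

    def test_mid_read_array_is_interstitial(self):
        assert (
            classify_position(_hit(10_000, 10_400), 24_378, 100)
            == PositionClass.INTERSTITIAL
        )

    def test_boundary_is_inclusive(self):
        # end exactly edge_tol from the read end counts as terminal
        assert classify_position(_hit(5_000, 9_900), 10_000, 100) == PositionClass.TERMINAL
        assert (
            classify_position(_hit(5_000, 9_899), 10_000, 100)
            == PositionClass.INTERSTITIAL
        )

    def test_interval_outside_read_rejected(self):
        with pytest.raises(ValueError):
            classify_position(_hit(0, 2000), 1000, 100)

    def test_monotone_in_edge_tol(self, rng):
        """Growing edge_tol never flips TERMINAL back to INTERSTITIAL."""
        for _ in range(50):
            L = int(rng.integers(1000, 20_000))
            s = int(rng.integers(0, L - 10))
            e = s + int(rng.integers(1, L - s))
            prev = None
            for tol in (0, 10, 100, 1000, L):
                cls = classify_position(_hit(s, e), L, tol)
                if prev == PositionClass.TERMINAL:
                    assert cls == PositionClass.TERMINAL
                prev = cls


def _calls(spec):
    """Build monomer calls from [(seq, class, n), ...]."""
    calls, pos = [], 0
    for seq, cls, n in spec:
        for _ in range(n):
            calls.append(MonomerCall(pos, seq, cls))
            pos += len(seq)
    return calls


class TestDetectBlocks:
    def test_probe_blocks(self, catalog, params):
        calls = decompose_array(PROBE_70BP, catalog, params)
        blocks = detect_blocks(calls)
        assert [(b[0], b[1]) for b in blocks] == [
            (BLOCK_CANONICAL, 5),
            (BLOCK_TTTAAAA, 5),
        ]

    def test_homogeneous_single_block(self):
        calls = _calls([("TTTAGGG", "canonical", 50)])
        assert [(b[0], b[1]) for b in detect_blocks(calls)] == [(BLOCK_CANONICAL, 50)]

    def test_planted_four_block_pattern(self):
        calls = _calls(
            [
                ("TTTAGGG", "canonical", 10),
                ("TTTAAAA", "derivative_TTTAAAA", 5),
                ("TTTAGGG", "canonical", 8),
                ("TTTAAAA", "derivative_TTTAAAA", 7),
            ]
        )
        assert [(b[0], b[1]) for b in detect_blocks(calls)] == [
            (BLOCK_CANONICAL, 10),
            (BLOCK_TTTAAAA, 5),
            (BLOCK_CANONICAL, 8),
            (BLOCK_TTTAAAA, 7),
        ]

    def test_short_runs_absorbed_into_longer_flank(self):
        calls = _calls(
            [
                ("TTTAGGG", "canonical", 10),
                ("TTTAAAA", "derivative_TTTAAAA", 2),  # below min_block_copies
                ("TTTAGGG", "canonical", 4),
            ]
        )
        assert [(b[0], b[1]) for b in detect_blocks(calls)] == [(BLOCK_CANONICAL, 16)]

    def test_variants_never_start_blocks(self):
        calls = _calls(
            [
                ("TTTAGGG", "canonical", 5),
                ("TTTAGG", "variant", 4),
                ("TTTAGGG", "canonical", 5),
            ]
        )
        assert [(b[0], b[1]) for b in detect_blocks(calls)] == [(BLOCK_CANONICAL, 14)]

    def test_counts_always_sum_to_calls(self, rng):
        classes = ["canonical", "variant", "derivative_TTTAAAA",
                   "derivative_CCTGGG_family", "unassigned"]
        for _ in range(30):
            spec = [
                ("TTTAGGG", classes[int(rng.integers(5))], int(rng.integers(1, 6)))
                for _ in range(int(rng.integers(1, 8)))
            ]
            calls = _calls(spec)
            blocks = detect_blocks(calls)
            assert sum(b[1] for b in blocks) == len(calls)


class TestClassifyComposition:
    def test_pure(self):
        assert classify_composition([(BLOCK_CANONICAL, 50)]) == CompositionClass.PURE_TEL

    def test_combined(self):
        assert (
            classify_composition([(BLOCK_CANONICAL, 5), (BLOCK_TTTAAAA, 5)])
            == CompositionClass.COMBINED_TEL_TTTAAAA
        )

    def test_dtr_family_with_variants(self):
        blocks = [(BLOCK_CCTGGG, 30), (BLOCK_CCTGGG, 4), (BLOCK_CCTGGG, 12)]
        assert classify_composition(blocks) == CompositionClass.DTR

    def test_exhaustive_over_class_multisets(self):
        """Enumeration over every nonempty block-class combination."""
        all_classes = [BLOCK_CANONICAL, BLOCK_TTTAAAA, BLOCK_CCTGGG]
        for r in range(1, 4):
            for combo in itertools.combinations(all_classes, r):
                blocks = [(c, 5) for c in combo]
                got = classify_composition(blocks)
                s = set(combo)
                if s == {BLOCK_CANONICAL}:
                    assert got == CompositionClass.PURE_TEL
                elif s == {BLOCK_CANONICAL, BLOCK_TTTAAAA}:
                    assert got == CompositionClass.COMBINED_TEL_TTTAAAA
                elif s == {BLOCK_CCTGGG}:
                    assert got == CompositionClass.DTR
                else:
                    assert got == CompositionClass.MIXED_OTHER


def _brute_force_junctions(arrays, params):
    """Oracle: every ordered triple satisfying the junction definition."""
    arrs = sorted(arrays, key=lambda a: a.hit.start)
    out = []
    for i, j, k in itertools.permutations(range(len(arrs)), 3):
        if not (arrs[i].hit.start < arrs[j].hit.start < arrs[k].hit.start):
            continue
        a, b, c = arrs[i], arrs[j], arrs[k]
        if a.composition_class != CompositionClass.DTR:
            continue
        if c.composition_class != CompositionClass.DTR:
            continue
        if a.hit.strand == c.hit.strand:
            continue
        if b.composition_class != CompositionClass.PURE_TEL:
            continue
        if b.hit.n_monomers > params.core_max_copies:
            continue
        if b.hit.start - a.hit.end > params.max_flank_gap:
            continue
        if c.hit.start - b.hit.end > params.max_flank_gap:
            continue
        out.append((b.hit.start, b.hit.end))
    return sorted(set(out))


class TestJunctions:
    def _junction_read(self, rng, n_junctions=1):
        cfg = SimConfig(error_model=ZERO_ERRORS)
        read, truth = simulate_read(cfg, rng, "jr", architecture="junction")
        return read, truth

    def test_planted_junction_found(self, rng):
        read, truth = self._junction_read(rng)
        arrays = classify_read_arrays(scan_read(read), read.length)
        events = detect_junctions(arrays)
        assert len(events) == 1
        ev = events[0]
        assert {ev.left_strand, ev.right_strand} == {"+", "-"}
        core = truth.arrays[1]
        assert (ev.core_start, ev.core_end) == (core.start, core.end)

    def test_single_flank_gives_nothing(self, catalog, params, rng):
        from conftest import plant_read

        seq = plant_read(rng, 2500, "CCTGGG" * 20, 30, "TTTAGGG" * 4, 2500)
        read = Read("r", seq)
        arrays = classify_read_arrays(scan_read(read), read.length)
        assert detect_junctions(arrays) == []

    def test_matches_brute_force_on_simulated_reads(self, rng):
        params = ClassifyParams()
        n_events = 0
        for i in range(25):
            read, _ = simulate_read(
                SimConfig(error_model=ZERO_ERRORS),
                rng,
                f"r{i}",
                architecture="junction" if i % 2 == 0 else "colocated",
            )
            arrays = classify_read_arrays(scan_read(read), read.length, params)
            got = sorted((e.core_start, e.core_end) for e in detect_junctions(arrays, params))
            assert got == _brute_force_junctions(arrays, params)
            n_events += len(got)
        assert n_events >= 10  # planted junctions were actually exercised

    def test_two_junctions_on_one_read(self, catalog, rng):
        """Two planted junction cassettes give two non-overlapping events."""
        from conftest import plant_read
        from telarray.seqio import revcomp

        seq = plant_read(
            rng,
            2500, "CCTGGG" * 20, 25, "TTTAGGG" * 4, 25, revcomp("CCTGGG" * 18),
            3000, revcomp("CCTGGG" * 15), 25, "TTTAGGG" * 5, 25, "CCTGGG" * 22,
            2500,
        )
        read = Read("r", seq)
        arrays = classify_read_arrays(scan_read(read), read.length)
        events = detect_junctions(arrays)
        assert len(events) == 2
        assert events[0].core_end <= events[1].core_start


class TestColocations:
    def test_planted_colocation_gap(self, rng):
        read, truth = simulate_read(
            SimConfig(error_model=ZERO_ERRORS), rng, "cr", architecture="colocated"
        )
        arrays = classify_read_arrays(scan_read(read), read.length)
        events = detect_colocations(arrays)
        assert len(events) == 1
        truth_gap = truth.events[0].gap
        assert events[0].gap == truth_gap

    def test_far_apart_arrays_not_colocated(self, rng):
        from conftest import plant_read

        seq = plant_read(rng, 2500, "TTTAGGG" * 40, 10_000, "CCTGGG" * 30, 2500)
        read = Read("r", seq)
        arrays = classify_read_arrays(scan_read(read), read.length)
        assert detect_colocations(arrays, ClassifyParams(max_coloc_gap=1000)) == []

    def test_nearest_dtr_paired_when_flanked(self, rng):
        """An ITR flanked by two DTRs pairs with the nearer one; pairing
        matches exhaustive minimum-gap assignment."""
        from conftest import plant_read

        seq = plant_read(
            rng, 2500, "CCTGGG" * 20, 400, "TTTAGGG" * 40, 150, "CCTGGG" * 20, 2500
        )
        read = Read("r", seq)
        arrays = classify_read_arrays(scan_read(read), read.length)
        events = detect_colocations(arrays)
        assert len(events) == 1
        ev = events[0]
        arrs = sorted(arrays, key=lambda a: a.hit.start)
        # the chosen DTR is the downstream (closer, 150 bp) one
        assert arrs[ev.dtr_index].hit.start > arrs[ev.itr_index].hit.start
        assert ev.gap == pytest.approx(150, abs=2)


class TestForbiddenCombination:
    def test_adversarial_array_counted(self, catalog, params):
        seq = "TTTAAAA" * 5 + "CCTGGG" * 5
        calls = decompose_array(seq, catalog, params)
        hit = ArrayHit("r", 0, len(seq), "+", "tel", calls, seq)
        arrays = classify_read_arrays([hit], 20_000, ClassifyParams(edge_tol=0))
        assert arrays[0].composition_class == CompositionClass.MIXED_OTHER
        assert check_forbidden_combination(arrays) == 1

    def test_mixed_library_exact_planted_count(self, rng):
        cfg = SimConfig(error_model=ZERO_ERRORS, adversarial=True)
        count_truth = 0
        arrays = []
        for i in range(40):
            read, truth = simulate_read(
                cfg, rng, f"r{i}",
                architecture="forbidden" if i % 4 == 0 else "itr",
            )
            count_truth += truth.architecture == "forbidden"
            arrays.extend(classify_read_arrays(scan_read(read), read.length))
        assert check_forbidden_combination(arrays) == count_truth == 10
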