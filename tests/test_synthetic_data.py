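"""Synthetic library generator: determinism, truth fidelity, error model."""

import numpy as np
import pytest

from telarray.array_classify import classify_read_arrays, detect_colocations, detect_junctions
from telarray.motif_scan import scan_read
from telarray.seqio import read_sequences, open_library
from telarray.synthetic_data import (
    ErrorModel,
    SimConfig,
    ZERO_ERRORS,
    apply_errors,
    measure_error_rates,
    read_truth,
    safe_variant_pool,
    simulate_library,
    simulate_read,
)
from conftest import random_dna


class TestErrorModel:
    def test_defaults_within_cited_ranges(self):
        em = ErrorModel()
        assert 0.016 <= em.deletion_rate <= 0.027
        assert 0.012 <= em.mismatch_rate <= 0.022
        assert 0.011 <= em.insertion_rate <= 0.024

    def test_rates_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            ErrorModel(deletion_rate=0.2)

    def test_zero_error_is_identity_with_identity_map(self, rng):
        seq = random_dna(rng, 500)
        read, pos_map = apply_errors(seq, ZERO_ERRORS, rng)
        assert read == seq
        assert (pos_map == np.arange(501)).all()

    def test_position_map_tracks_intervals(self, rng):
        seq = random_dna(rng, 2000)
        read, pos_map = apply_errors(seq, ErrorModel(), rng)
        assert pos_map[-1] == len(read)
        assert (np.diff(pos_map) >= 0).all()
        # an interval's mapped length stays within the indel budget
        s, e = 500, 1500
        mapped = pos_map[e] - pos_map[s]
        assert abs(mapped - 1000) < 100

    def test_measure_zero_error(self, rng):
        seq = random_dna(rng, 300)
        assert measure_error_rates(seq, seq) == (0.0, 0.0, 0.0)

    def test_planted_counts_match_binomial_oracle(self, rng):
        """Planted per-channel event counts are binomial at the configured
        marginal rates (exact generator bookkeeping, no alignment)."""
        em = ErrorModel()
        n = 200_000
        seq = random_dna(rng, n)
        _, _, counts = apply_errors(seq, em, rng, with_counts=True)
        for key, p in (("del", em.deletion_rate), ("mm", em.mismatch_rate),
                       ("ins", em.insertion_rate)):
            se = (p * (1 - p) * n) ** 0.5
            assert abs(counts[key] - p * n) <= 3 * se, key

    def test_deletion_only_alignment_measurement_is_exact(self, rng):
        """With only deletions active the edlib re-measurement equals the
        planted count exactly (the optimal alignment is forced)."""
        em = ErrorModel(0.027, 0.0, 0.0)
        seq = random_dna(rng, 50_000)
        read, _, counts = apply_errors(seq, em, rng, with_counts=True)
        d, m, i = measure_error_rates(read, seq)
        assert d == pytest.approx(counts["del"] / 50_000)
        assert m == 0.0 and i == 0.0

    def test_alignment_measurement_close_to_planted_at_defaults(self, rng):
        """With all channels on, alignment re-measurement agrees with the
        planted rates to a few percent relative (adjacent deletion+insertion
        pairs are alignment-degenerate with substitutions)."""
        em = ErrorModel()
        seq = random_dna(rng, 100_000)
        read, _, counts = apply_errors(seq, em, rng, with_counts=True)
        d, m, i = measure_error_rates(read, seq)
        assert d == pytest.approx(counts["del"] / 100_000, rel=0.10)
        assert m == pytest.approx(counts["mm"] / 100_000, rel=0.10)
        assert i == pytest.approx(counts["ins"] / 100_000, rel=0.10)


class TestSimulateRead:
    def test_zero_error_truth_roundtrip_all_architectures(self, zero_error_config, rng):
        """scan -> classify on noiseless reads reproduces intervals, strands,
        position/composition classes, block structure and events exactly."""
        for arch in ("pure_terminal", "combined_terminal", "itr", "dtr",
                     "colocated", "junction", "hor"):
            for i in range(5):
                read, truth = simulate_read(
                    zero_error_config, rng, f"{arch}_{i}", architecture=arch
                )
                arrays = classify_read_arrays(scan_read(read), read.length)
                det = [
                    (
                        a.hit.start,
                        a.hit.end,
                        a.hit.strand,
                        a.position_class.value,
                        a.composition_class.value,
                        tuple(
                            (b.monomer_class, b.copy_count)
                            for b in (
                                a.blocks
                                if a.hit.strand == "+"
                                else list(reversed(a.blocks))
                            )
                        ),
                    )
                    for a in arrays
                ]
                tru = [
                    (t.start, t.end, t.strand, t.position_class,
                     t.composition_class, tuple(t.blocks))
                    for t in truth.arrays
                ]
                assert det == tru, arch
                junctions = detect_junctions(arrays)
                colocs = detect_colocations(arrays, junctions=junctions)
                assert len(junctions) == sum(e.kind == "junction" for e in truth.events)
                assert len(colocs) == sum(e.kind == "colocation" for e in truth.events)

    def test_terminal_arrays_flush_to_read_end(self, zero_error_config, rng):
        for i in range(10):
            read, truth = simulate_read(
                zero_error_config, rng, f"t{i}", architecture="pure_terminal"
            )
            (t,) = truth.arrays
            assert t.start == 0 or t.end == read.length

    def test_interstitial_margin_respected(self, zero_error_config, rng):
        for i in range(10):
            read, truth = simulate_read(
                zero_error_config, rng, f"i{i}", architecture="itr"
            )
            (t,) = truth.arrays
            assert t.start >= 2000 and read.length - t.end >= 2000

    def test_variant_pool_members_decompose_as_single_variants(self, catalog, params):
        pool = safe_variant_pool(catalog, params)
        assert "TTTAGG" in pool and "TTAGGG" in pool
        assert len(pool) > 10


class TestSimulateLibrary:
    def test_seeded_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(n_reads=25)
        fa1, tr1 = tmp_path / "a.fasta", tmp_path / "a.tsv"
        fa2, tr2 = tmp_path / "b.fasta", tmp_path / "b.tsv"
        simulate_library(cfg, 42, fa1, tr1)
        simulate_library(cfg, 42, fa2, tr2)
        assert fa1.read_bytes() == fa2.read_bytes()
        assert tr1.read_bytes() == tr2.read_bytes()

    def test_single_read_library_is_valid_fasta(self, tmp_path):
        cfg = SimConfig(n_reads=1)
        fa = tmp_path / "one.fasta"
        simulate_library(cfg, 7, fa, tmp_path / "one.tsv")
        reads = list(read_sequences(open_library(fa)))
        assert len(reads) == 1
        assert set(reads[0].sequence) <= set("ACGT")

    def test_truth_table_roundtrip(self, tmp_path):
        cfg = SimConfig(n_reads=15, error_model=ZERO_ERRORS)
        fa, tr = tmp_path / "lib.fasta", tmp_path / "truth.tsv"
        _, truths = simulate_library(cfg, 3, fa, tr)
        back = {t.read_id: t for t in read_truth(tr)}
        for t in truths:
            b = back[t.read_id]
            assert [(a.start, a.end, a.strand, a.composition_class, a.blocks)
                    for a in b.arrays] == [
                (a.start, a.end, a.strand, a.composition_class, a.blocks)
                for a in t.arrays
            ]

    def test_class_counts_binomially_distributed(self):
        """With 50/50 pure-terminal/itr frequencies the planted counts land
        inside the exact binomial 99% interval."""
        from scipy import stats

        freqs = {k: 0.0 for k in SimConfig().class_freqs}
        freqs["pure_terminal"] = 0.5
        freqs["itr"] = 0.5
        cfg = SimConfig(n_reads=300, class_freqs=freqs, error_model=ZERO_ERRORS)
        _, truths = simulate_library(cfg, 11)
        n_pure_terminal = sum(t.architecture == "pure_terminal" for t in truths)
        lo, hi = stats.binom.interval(0.99, 300, 0.5)
        assert lo <= n_pure_terminal <= hi

    def test_no_forbidden_arrays_without_adversarial_flag(self):
        cfg = SimConfig(n_reads=60, error_model=ZERO_ERRORS)
        _, truths = simulate_library(cfg, 5)
        assert all(t.architecture != "forbidden" for t in truths)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError, match="frequencies"):
            SimConfig(class_freqs={"itr": 0.5})

    def test_read_lengths_within_clip_bounds(self):
        cfg = SimConfig(n_reads=40, error_model=ZERO_ERRORS)
        reads, _ = simulate_library(cfg, 2)
        # post-error length can drift ~2% around the clipped truth length
        assert all(4800 <= r.length <= 25_500 for r in reads)


class TestDetectionUnderErrors:
    def test_boundary_error_within_two_monomers(self, rng):
        """At default error rates, detected boundaries of plain arrays stay
        within 14 bp (two monomers) of the planted truth."""
        cfg = SimConfig()
        devs = []
        for i in range(60):
            read, truth = simulate_read(cfg, rng, f"r{i}", architecture="itr")
            (t,) = truth.arrays
            hits = [
                h for h in scan_read(read)
                if min(h.end, t.end) - max(h.start, t.start) > 0
            ]
            if not hits:
                continue
            start = min(h.start for h in hits)
            end = max(h.end for h in hits)
            devs.append(max(abs(start - t.start), abs(end - t.end)))
        assert len(devs) >= 55
        assert float(np.quantile(devs, 0.95)) <= 14

    def test_array_detection_recall(self, rng):
        """Arrays of >= 30 monomers are recovered (>= 50% overlap, any
        class) at >= 0.98 at the default error rates."""
        cfg = SimConfig()
        found = missed = 0
        for i in range(300):
            read, truth = simulate_read(cfg, rng, f"r{i}")
            hits = scan_read(read)
            for t in truth.arrays:
                if t.n_monomers < 30:
                    continue
                ok = any(
                    min(h.end, t.end) - max(h.start, t.start)
                    > 0.5 * (t.end - t.start)
                    for h in hits
                )
                found += ok
                missed += not ok
        assert found / (found + missed) >= 0.98
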