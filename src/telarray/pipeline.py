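"""Pipeline orchestration: scan -> classify -> consensus -> report.

``run_pipeline`` is deterministic given its configuration (there is no
randomness anywhere in the analysis path) and writes, next to the summary,
a verbatim snapshot of the configuration used, so any count in the output
can be reproduced exactly.

``summarize_library`` builds the per-library frequency table: the number of
reads carrying arrays of each composition class (a read with two pure
arrays counts once), with a parallel array-level table, since the source
tabulation's counting unit is ambiguous. Zero counts are reported
explicitly — two of the studied genotypes carry no combined arrays at all,
and that zero is a finding, not a missing value.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import seqio
from .array_classify import (
    ClassifyParams,
    ClassifiedArray,
    CompositionClass,
    PositionClass,
    check_forbidden_combination,
    classify_read_arrays,
    detect_colocations,
    detect_junctions,
)
from .motif_scan import MotifCatalog, ScanParams, scan_read
from .seqio import Read, read_sequences, select_longest, write_annotations
from .tandem_consensus import detect_elongated_monomers, estimate_periods, wraparound_consensus

__all__ = ["RunConfig", "LibrarySummary", "run_pipeline", "summarize_library"]

log = logging.getLogger("telarray")


@dataclass
class RunConfig:
    input_path: str
    out_dir: str
    top_n: int | None = 50_000
    scan: ScanParams = field(default_factory=ScanParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    consensus: bool = True
    consensus_word: int = 8
    consensus_max_period: int = 210
    max_consensus_arrays: int | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("scan"), dict):
            d["scan"] = ScanParams(**d["scan"])
        if isinstance(d.get("classify"), dict):
            d["classify"] = ClassifyParams(**d["classify"])
        return cls(**d)


@dataclass
class LibrarySummary:
    library_id: str
    n_reads_scanned: int
    n_reads_with_arrays: int
    reads_with_pure_TTTAGGG_arrays: int
    reads_with_combined_TTTAGGG_TTTAAAA_arrays: int
    reads_with_CCTGGG_family_arrays: int
    reads_with_mixed_other_arrays: int
    array_counts: dict[str, int]  # array-level, by composition class
    position_counts: dict[str, int]  # array-level, TERMINAL / INTERSTITIAL
    n_junctions: int
    n_colocations: int
    forbidden_combination_count: int
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize_library(
    classified_by_read: dict[str, list[ClassifiedArray]],
    n_reads_scanned: int,
    library_id: str = "library",
    n_junctions: int = 0,
    n_colocations: int = 0,
    parameters: dict | None = None,
) -> LibrarySummary:
    """Read-level class-presence counts plus the array-level table."""
    read_counts = {c: 0 for c in CompositionClass}
    array_counts = {c.value: 0 for c in CompositionClass}
    position_counts = {p.value: 0 for p in PositionClass}
    n_with = 0
    all_arrays: list[ClassifiedArray] = []
    for rid, arrays in classified_by_read.items():
        if arrays:
            n_with += 1
        present = set()
        for a in arrays:
            present.add(a.composition_class)
            array_counts[a.composition_class.value] += 1
            position_counts[a.position_class.value] += 1
            all_arrays.append(a)
        for c in present:
            read_counts[c] += 1
    return LibrarySummary(
        library_id=library_id,
        n_reads_scanned=n_reads_scanned,
        n_reads_with_arrays=n_with,
        reads_with_pure_TTTAGGG_arrays=read_counts[CompositionClass.PURE_TEL],
        reads_with_combined_TTTAGGG_TTTAAAA_arrays=read_counts[
            CompositionClass.COMBINED_TEL_TTTAAAA
        ],
        reads_with_CCTGGG_family_arrays=read_counts[CompositionClass.DTR],
        reads_with_mixed_other_arrays=read_counts[CompositionClass.MIXED_OTHER],
        array_counts=array_counts,
        position_counts=position_counts,
        n_junctions=n_junctions,
        n_colocations=n_colocations,
        forbidden_combination_count=check_forbidden_combination(all_arrays),
        parameters=parameters or {},
    )


def _write_tables(out: Path, classified_by_read, junctions, colocations):
    hits = [a.hit for arrays in classified_by_read.values() for a in arrays]
    write_annotations(hits, out / "arrays.bed", "bed")
    write_annotations(hits, out / "arrays.gff3", "gff3")
    with open(out / "arrays.tsv", "w") as fh:
        fh.write(
            "read_id\tstart\tend\tstrand\tposition_class\tcomposition_class\t"
            "n_monomers\tvariant_fraction\tblocks\n"
        )
        for arrays in classified_by_read.values():
            for a in arrays:
                blocks = ",".join(
                    f"{b.monomer_class}:{b.copy_count}" for b in a.blocks
                )
                fh.write(
                    f"{a.read_id}\t{a.hit.start}\t{a.hit.end}\t{a.hit.strand}\t"
                    f"{a.position_class.value}\t{a.composition_class.value}\t"
                    f"{a.hit.n_monomers}\t{a.hit.variant_fraction:.4f}\t{blocks}\n"
                )
    with open(out / "junctions.tsv", "w") as fh:
        fh.write("read_id\tcore_start\tcore_end\tcore_copies\tleft_strand\tright_strand\n")
        for ev in junctions:
            fh.write(
                f"{ev.read_id}\t{ev.core_start}\t{ev.core_end}\t{ev.core_copies}\t"
                f"{ev.left_strand}\t{ev.right_strand}\n"
            )
    with open(out / "colocations.tsv", "w") as fh:
        fh.write("read_id\titr_index\tdtr_index\tgap\n")
        for ev in colocations:
            fh.write(f"{ev.read_id}\t{ev.itr_index}\t{ev.dtr_index}\t{ev.gap}\n")


def run_pipeline(config: RunConfig) -> LibrarySummary:
    """Run the full analysis over one library and write all outputs."""
    t0 = time.time()
    inp = Path(config.input_path)
    if not inp.exists():
        raise FileNotFoundError(inp)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    catalog = MotifCatalog()

    reads = list(read_sequences(seqio.open_library(inp)))
    if config.top_n is not None:
        reads = select_longest(reads, config.top_n)
    log.info("scanning %d reads from %s", len(reads), inp)

    classified_by_read: dict[str, list[ClassifiedArray]] = {}
    junctions = []
    colocations = []
    consensus_records = []
    n_consensus = 0
    for read in reads:
        try:
            hits = scan_read(read, catalog, config.scan)
        except Exception as exc:  # keep going; failures are per read
            log.warning("read %s failed: %s", read.read_id, exc)
            continue
        if not hits:
            classified_by_read[read.read_id] = []
            continue
        arrays = classify_read_arrays(hits, read.length, config.classify)
        classified_by_read[read.read_id] = arrays
        evs = detect_junctions(arrays, config.classify)
        junctions.extend(evs)
        colocations.extend(detect_colocations(arrays, config.classify, evs))
        if config.consensus:
            for a in arrays:
                if a.position_class != PositionClass.INTERSTITIAL:
                    continue
                if (
                    config.max_consensus_arrays is not None
                    and n_consensus >= config.max_consensus_arrays
                ):
                    break
                n_consensus += 1
                seq = a.hit.oriented_seq
                if len(seq) < 2 * config.consensus_word:
                    continue
                cands = estimate_periods(
                    seq, config.consensus_word, config.consensus_max_period
                )
                if cands:
                    rep = wraparound_consensus(seq, cands[0][0])
                    consensus_records.append((a, rep, "top_period"))
                for rep in detect_elongated_monomers(
                    a.hit,
                    catalog.canonical,
                    word=config.consensus_word,
                    max_period=config.consensus_max_period,
                ):
                    consensus_records.append((a, rep, "elongated"))

    summary = summarize_library(
        classified_by_read,
        n_reads_scanned=len(reads),
        library_id=inp.stem,
        n_junctions=len(junctions),
        n_colocations=len(colocations),
        parameters=config.to_dict(),
    )

    _write_tables(out, classified_by_read, junctions, colocations)
    with open(out / "consensus.fasta", "w") as fh:
        for a, rep, kind in consensus_records:
            fh.write(
                f">{a.read_id}:{a.hit.start}-{a.hit.end}|{kind}|period={rep.period}"
                f"|copies={rep.copy_number:.1f}|identity={rep.percent_identity:.3f}\n"
                f"{rep.consensus}\n"
            )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("finished in %.1f s", time.time() - t0)
    return summary
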