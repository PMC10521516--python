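"""Reading long-read libraries and writing annotation files.

FASTA/FASTQ parsing goes through Biopython; gzip is detected from the file
magic. Internal coordinates are 0-based half-open everywhere; conversion to
1-based closed happens only in the GFF3 writer.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "Read",
    "LibraryHandle",
    "ParseError",
    "open_library",
    "read_sequences",
    "select_longest",
    "write_annotations",
    "read_annotations",
]

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """A malformed record in a sequence library."""


@dataclass(frozen=True)
class Read:
    """One long read: identifier plus an upper-case DNA sequence."""

    read_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has empty sequence")


@dataclass
class LibraryHandle:
    """A sequence library on disk: path, format and compression state."""

    path: Path
    format: str  # "fasta" | "fastq"
    compressed: bool
    n_reads: int | None = None


def _is_gzip(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def _sniff_format(path: Path, compressed: bool) -> str:
    opener = gzip.open if compressed else open
    with opener(path, "rt") as fh:
        for line in fh:
            if line.strip():
                first = line[0]
                break
        else:
            return "fasta"  # empty file: treat as an empty FASTA
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ParseError(f"{path}: cannot infer format from first character {first!r}")


def open_library(path: str | Path, fmt: str | None = None) -> LibraryHandle:
    """Build a :class:`LibraryHandle`, inferring format and compression."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    compressed = _is_gzip(path)
    if fmt is None:
        fmt = _sniff_format(path, compressed)
    fmt = fmt.lower()
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    return LibraryHandle(path=path, format=fmt, compressed=compressed)


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_sequences(handle: LibraryHandle | str | Path) -> Iterator[Read]:
    """Yield every record of a library once, in file order.

    Sequences are upper-cased and U is mapped to T. An empty file yields an
    empty stream. A malformed record raises :class:`ParseError` naming the
    index of the record where parsing failed.
    """
    if not isinstance(handle, LibraryHandle):
        handle = open_library(handle)
    opener = gzip.open if handle.compressed else open
    count = 0
    with opener(handle.path, "rt") as fh:
        parser = SeqIO.parse(fh, handle.format)
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ParseError(
                    f"{handle.path}: malformed record at index {count}: {exc}"
                ) from exc
            seq = _normalize(str(rec.seq))
            if not seq:
                raise ParseError(
                    f"{handle.path}: malformed record at index {count}: empty sequence"
                )
            yield Read(read_id=rec.id, sequence=seq)
            count += 1
    handle.n_reads = count


def select_longest(reads: Iterable[Read], n: int) -> list[Read]:
    """The ``n`` longest reads, length-descending, ties broken by read_id."""
    if n < 0:
        raise ValueError("n must be >= 0")
    ordered = sorted(reads, key=lambda r: (-r.length, r.read_id))
    return ordered[:n]


def write_library(reads: Iterable[Read], path: str | Path, fmt: str = "fasta") -> None:
    """Write reads as FASTA/FASTQ (gzip if the path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in reads:
            if fmt == "fasta":
                fh.write(f">{r.read_id}\n{r.sequence}\n")
            elif fmt == "fastq":
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * r.length}\n")
            else:
                raise ValueError(f"unsupported format {fmt!r}")


# ---------------------------------------------------------------------------
# Annotation output. `hits` may be ArrayHit objects or anything exposing
# read_id/start/end/strand and optionally a label.

_ANNOT_FORMATS = ("bed", "gff3", "tsv")


def _hit_fields(hit) -> tuple[str, int, int, str, str]:
    label = getattr(hit, "array_class", None) or getattr(hit, "label", None) or "array"
    label = str(getattr(label, "value", label))
    return (hit.read_id, hit.start, hit.end, str(hit.strand), label)


def write_annotations(hits, path: str | Path, fmt: str) -> None:
    """Write array hits as BED (0-based half-open), GFF3 (1-based closed) or TSV."""
    fmt = fmt.lower()
    if fmt not in _ANNOT_FORMATS:
        raise ValueError(f"unknown annotation format {fmt!r}")
    path = Path(path)
    with open(path, "wt") as fh:
        if fmt == "bed":
            for h in hits:
                rid, s, e, strand, label = _hit_fields(h)
                fh.write(f"{rid}\t{s}\t{e}\t{label}\t0\t{strand}\n")
        elif fmt == "gff3":
            fh.write("##gff-version 3\n")
            for h in hits:
                rid, s, e, strand, label = _hit_fields(h)
                fh.write(
                    f"{rid}\ttelarray\trepeat_array\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"class={label}\n"
                )
        else:
            fh.write("read_id\tstart\tend\tstrand\tclass\n")
            for h in hits:
                rid, s, e, strand, label = _hit_fields(h)
                fh.write(f"{rid}\t{s}\t{e}\t{strand}\t{label}\n")


@dataclass(frozen=True)
class AnnotationRecord:
    read_id: str
    start: int  # 0-based half-open, regardless of on-disk convention
    end: int
    strand: str
    label: str


def read_annotations(path: str | Path, fmt: str) -> list[AnnotationRecord]:
    """Parse annotation files back into internal 0-based half-open records."""
    fmt = fmt.lower()
    if fmt not in _ANNOT_FORMATS:
        raise ValueError(f"unknown annotation format {fmt!r}")
    out: list[AnnotationRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if fmt == "bed":
                rid, s, e, label, _score, strand = parts[:6]
                out.append(AnnotationRecord(rid, int(s), int(e), strand, label))
            elif fmt == "gff3":
                rid, _src, _type, s, e, _score, strand, _phase, attrs = parts[:9]
                label = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                ).get("class", "array")
                out.append(AnnotationRecord(rid, int(s) - 1, int(e), strand, label))
            else:
                if parts[0] == "read_id":
                    continue
                rid, s, e, strand, label = parts[:5]
                out.append(AnnotationRecord(rid, int(s), int(e), strand, label))
    return out
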