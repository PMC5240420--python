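"""Raw-read handling: qseq/FASTQ parsing, demultiplexing, adapter clipping,
length filtering and collapsing of identical reads.

Reads are demultiplexed on a perfect match to the index barcode, the 3'
adapter is clipped, clean reads of 18-30 nt are retained, and identical
reads are collapsed to unique sequences with a multiplicity.  Quality
strings are carried along but play no role in filtering.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, TextIO

__all__ = [
    "RawRead",
    "UniqueRead",
    "TRUSEQ_SMALL_RNA_ADAPTER",
    "read_fastq",
    "write_fastq",
    "read_qseq",
    "write_qseq",
    "demultiplex",
    "trim_adapter",
    "length_filter",
    "collapse_reads",
    "write_collapsed_fasta",
    "read_collapsed_fasta",
]

#: Illumina TruSeq small-RNA 3' adapter (RA3), the default clip sequence.
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass(slots=True)
class RawRead:
    read_id: str
    sequence: str
    qualities: str | None = None
    barcode: str | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True, slots=True)
class UniqueRead:
    """A distinct read sequence and how many identical raw reads it represents."""

    sequence: str
    multiplicity: int


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# formats


def read_fastq(src: str | Path | TextIO) -> Iterator[RawRead]:
    """Parse 4-line FASTQ (Sanger Phred+33); gzip-transparent for paths.

    An index barcode embedded in the header in the classic Illumina style
    (``@id#BARCODE/1``) is extracted into :attr:`RawRead.barcode`.
    """
    fh = _open_text(src) if isinstance(src, (str, Path)) else src
    close = isinstance(src, (str, Path))
    try:
        while True:
            header = fh.readline()
            if not header:
                break
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ header: {header!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record at {header!r}")
            name = header[1:].split()[0]
            barcode = None
            if "#" in name:
                name, tail = name.split("#", 1)
                barcode = tail.split("/", 1)[0] or None
                if barcode == "0":
                    barcode = None
            yield RawRead(name, seq.upper(), qual or None, barcode)
    finally:
        if close:
            fh.close()


def write_fastq(reads: Iterable[RawRead], dest: str | Path | TextIO) -> None:
    fh = _open_text(dest, "wt") if isinstance(dest, (str, Path)) else dest
    close = isinstance(dest, (str, Path))
    try:
        for read in reads:
            name = read.read_id
            if read.barcode:
                name = f"{name}#{read.barcode}/1"
            qual = read.qualities if read.qualities is not None else "I" * len(read.sequence)
            fh.write(f"@{name}\n{read.sequence}\n+\n{qual}\n")
    finally:
        if close:
            fh.close()


def read_qseq(src: str | Path | TextIO) -> Iterator[RawRead]:
    """Parse the tab-separated Illumina qseq dialect (11 columns).

    Uncalled bases ('.') become 'N'; the index column populates the barcode.
    """
    fh = _open_text(src) if isinstance(src, (str, Path)) else src
    close = isinstance(src, (str, Path))
    try:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 11:
                raise ValueError(f"qseq line {line_no}: expected 11 columns, got {len(cols)}")
            machine, run, lane, tile, x, y, index, read_no, seq, qual, _flag = cols
            read_id = ":".join([machine, run, lane, tile, x, y])
            barcode = None if index in ("", "0") else index
            yield RawRead(read_id, seq.replace(".", "N").upper(), qual or None, barcode)
    finally:
        if close:
            fh.close()


def write_qseq(reads: Iterable[RawRead], dest: str | Path | TextIO) -> None:
    fh = _open_text(dest, "wt") if isinstance(dest, (str, Path)) else dest
    close = isinstance(dest, (str, Path))
    try:
        for read in reads:
            parts = read.read_id.split(":")
            parts += ["0"] * (6 - len(parts))
            qual = read.qualities if read.qualities is not None else "I" * len(read.sequence)
            fh.write(
                "\t".join(
                    parts[:6]
                    + [read.barcode or "0", "1", read.sequence.replace("N", "."), qual, "1"]
                )
                + "\n"
            )
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# pipeline stages


def demultiplex(
    reads: Iterable[RawRead], barcode_map: Mapping[str, str]
) -> tuple[dict[str, list[RawRead]], int]:
    """Split reads by exact barcode match.

    ``barcode_map`` maps index sequence to library label.  Reads whose
    barcode matches no index exactly (including reads without a barcode)
    are counted as unassigned.  All indices must have equal length.
    """
    if not barcode_map:
        raise ValueError("empty barcode map")
    lengths = {len(b) for b in barcode_map}
    if len(lengths) != 1:
        raise ValueError("barcodes must all have the same length")
    # several indices pointing at one library label is legitimate (re-pooling)
    out: dict[str, list[RawRead]] = {lib: [] for lib in barcode_map.values()}
    unassigned = 0
    for read in reads:
        lib = barcode_map.get(read.barcode or "")
        if lib is None:
            unassigned += 1
        else:
            out[lib].append(read)
    return out, unassigned


def find_adapter(sequence: str, adapter: str, min_overlap: int = 3) -> int:
    """Return the leftmost clip position, or -1 if the adapter is absent.

    A clip position is where a full adapter occurrence begins, or where a
    prefix of the adapter of length >= ``min_overlap`` runs to the read end
    (a partially sequenced adapter).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    n, m = len(sequence), len(adapter)
    cut = sequence.find(adapter)
    if cut != -1:
        return cut
    for pos in range(max(0, n - m + 1), n - min_overlap + 1):
        if sequence[pos:] == adapter[: n - pos]:
            return pos
    return -1


def trim_adapter(read: RawRead, adapter: str, min_overlap: int = 3) -> RawRead:
    """Clip the 3' adapter; reads without a detectable adapter are unchanged."""
    cut = find_adapter(read.sequence, adapter, min_overlap)
    if cut == -1:
        return read
    return replace(
        read,
        sequence=read.sequence[:cut],
        qualities=read.qualities[:cut] if read.qualities is not None else None,
    )


def length_filter(
    reads: Iterable[RawRead], min_len: int = 18, max_len: int = 30
) -> list[RawRead]:
    """Retain clean reads of ``min_len``..``max_len`` nt inclusive."""
    return [r for r in reads if min_len <= len(r.sequence) <= max_len]


def collapse_reads(reads: Iterable[RawRead]) -> list[UniqueRead]:
    """Collapse identical sequences; multiplicities sum to the input count.

    Output is ordered by decreasing multiplicity, ties broken by sequence,
    so identical inputs give identical outputs regardless of chunking.
    """
    counts = Counter(r.sequence for r in reads)
    return [
        UniqueRead(seq, mult)
        for seq, mult in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def write_collapsed_fasta(unique_reads: Iterable[UniqueRead], dest: str | Path | TextIO) -> None:
    """Write collapsed reads as ``>seq<i>_x<multiplicity>`` FASTA records."""
    fh = _open_text(dest, "wt") if isinstance(dest, (str, Path)) else dest
    close = isinstance(dest, (str, Path))
    try:
        for i, ur in enumerate(unique_reads):
            fh.write(f">seq{i}_x{ur.multiplicity}\n{ur.sequence}\n")
    finally:
        if close:
            fh.close()


def read_collapsed_fasta(src: str | Path | TextIO) -> list[UniqueRead]:
    fh = _open_text(src) if isinstance(src, (str, Path)) else src
    close = isinstance(src, (str, Path))
    out: list[UniqueRead] = []
    try:
        header = None
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:]
            else:
                if header is None or "_x" not in header:
                    raise ValueError(f"malformed collapsed-read header before {line!r}")
                mult = int(header.rsplit("_x", 1)[1])
                out.append(UniqueRead(line.upper(), mult))
                header = None
    finally:
        if close:
            fh.close()
    return out
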