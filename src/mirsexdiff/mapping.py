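"""Ungapped short-read alignment with at most one mismatch.

The mapping contract is: a read hits a target at every offset where the read
is fully contained in the target and the Hamming distance is 0 or 1, with no
indels.  A target position masked to ``N`` never matches any read base (and
an ``N`` in the read never matches anything), so a read overlapping two or
more masked bases cannot hit at all — this is what makes precursor masking
airtight.

Completeness without a heuristic aligner: the read is split into two halves;
with at most one mismatch, at least one half matches the target exactly
(pigeonhole), so looking up the leading k-mer of each half in an exact k-mer
index of the targets and verifying the full read by Hamming distance finds
every valid placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .reference import Reference
from .readproc import UniqueRead

__all__ = ["Hit", "ReadAligner", "align_read", "map_unique_reads", "mapping_rate"]


@dataclass(frozen=True, slots=True)
class Hit:
    target_name: str
    offset: int  # 0-based start of the read within the target
    mismatches: int  # 0 or 1


def _mismatches(read: str, target: str, offset: int, limit: int = 1) -> int:
    mm = 0
    for i, base in enumerate(read):
        t = target[offset + i]
        if base != t or base == "N":  # N==N still counts as a mismatch
            mm += 1
            if mm > limit:
                return mm
    return mm


class ReadAligner:
    """k-mer seed index over a :class:`Reference` for <=1-mismatch lookup."""

    def __init__(self, reference: Reference, k: int = 9):
        if k < 1:
            raise ValueError("k must be positive")
        self.reference = reference
        self.k = k
        self._targets = [(t.target_name, t.sequence) for t in reference.targets]
        index: dict[str, list[tuple[int, int]]] = {}
        for tidx, (_, seq) in enumerate(self._targets):
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue  # masked seeds can never match exactly
                index.setdefault(kmer, []).append((tidx, i))
        self._index = index

    def align(self, seq: str) -> list[Hit]:
        """All (target, offset) placements with Hamming distance <= 1."""
        L = len(seq)
        k = self.k
        if L < 2 * k:
            return self._align_scan(seq)
        half = L // 2
        seeds = ((seq[:k], 0), (seq[half : half + k], half))
        hits: dict[tuple[int, int], int] = {}
        for kmer, roff in seeds:
            for tidx, pos in self._index.get(kmer, ()):
                off = pos - roff
                if off < 0:
                    continue
                key = (tidx, off)
                if key in hits:
                    continue
                tseq = self._targets[tidx][1]
                if off + L > len(tseq):
                    continue
                mm = _mismatches(seq, tseq, off)
                if mm <= 1:
                    hits[key] = mm
        return sorted(
            (Hit(self._targets[t][0], off, mm) for (t, off), mm in hits.items()),
            key=lambda h: (h.target_name, h.offset),
        )

    def _align_scan(self, seq: str) -> list[Hit]:
        # fallback for reads too short to carry two seeds; exact same contract
        L = len(seq)
        out = []
        for name, tseq in self._targets:
            for off in range(len(tseq) - L + 1):
                mm = _mismatches(seq, tseq, off)
                if mm <= 1:
                    out.append(Hit(name, off, mm))
        return sorted(out, key=lambda h: (h.target_name, h.offset))


def align_read(seq: str, ref: Reference | ReadAligner) -> list[Hit]:
    """Align one read; builds (and caches) an aligner when given a Reference."""
    if isinstance(ref, ReadAligner):
        return ref.align(seq)
    aligner = getattr(ref, "_aligner", None)
    if aligner is None:
        aligner = ReadAligner(ref)
        ref._aligner = aligner
    return aligner.align(seq)


def map_unique_reads(
    unique_reads: Iterable[UniqueRead],
    aligner: ReadAligner,
    cache: dict[str, list[Hit]] | None = None,
) -> dict[str, list[Hit]]:
    """Map collapsed reads, returning ``{sequence: hits}``.

    ``cache`` may be shared across libraries of one experiment: hits depend
    only on the sequence and the reference.
    """
    hits_by_seq: dict[str, list[Hit]] = {}
    for ur in unique_reads:
        seq = ur.sequence
        if cache is not None:
            found = cache.get(seq)
            if found is None:
                found = aligner.align(seq)
                cache[seq] = found
        else:
            found = aligner.align(seq)
        hits_by_seq[seq] = found
    return hits_by_seq


def mapping_rate(
    unique_reads: Iterable[UniqueRead], hits_by_seq: Mapping[str, list[Hit]]
) -> float:
    """Multiplicity-weighted fraction of reads with at least one hit."""
    total = 0
    mapped = 0
    for ur in unique_reads:
        total += ur.multiplicity
        if hits_by_seq.get(ur.sequence):
            mapped += ur.multiplicity
    if total == 0:
        raise ValueError("mapping rate undefined for zero reads")
    return mapped / total
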