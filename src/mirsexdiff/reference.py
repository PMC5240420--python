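"""Mapping-reference construction from mature and hairpin miRNA FASTA.

Several miRNA genes can give rise to an identical mature sequence, so
quantification is done at the level of distinct mature sequences rather than
genes.  The reference is built in three steps:

1. *Collapse* — every distinct mature sequence becomes one target; the genes
   that share it are recorded as ``member_genes`` and the target is named
   after the lexicographically first member.
2. *Masking* — within each hairpin (precursor), the sequences of its own
   annotated mature products are replaced by ``N`` so that a mature-length
   read can never map both to the mature target and to the precursor.
   Precursor targets therefore only collect reads from loop/flank regions.
3. *Nested pairs* — two distinct mature targets where one is a contiguous
   substring of the other and exactly one base shorter are registered as a
   nested pair.  Reads of the shorter sequence necessarily map to both
   targets; the counting stage resolves them by subtraction (see
   :mod:`mirsexdiff.quantify`).

Sequences are converted from RNA to DNA alphabet (U→T) at parse time; all
downstream mapping happens in DNA space because sequencing reads are DNA.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MatureRecord",
    "PrecursorRecord",
    "ReferenceTarget",
    "NestedPair",
    "Reference",
    "ReferenceError",
    "parse_mirbase_fasta",
    "collapse_identical_matures",
    "mask_matures_in_precursors",
    "detect_nested_pairs",
    "build_reference",
]

_DNA = frozenset("ACGT")
_DNA_N = frozenset("ACGTN")


class ReferenceError(ValueError):
    """Raised for malformed or inconsistent reference inputs."""


@dataclass(frozen=True)
class MatureRecord:
    """A mature miRNA sequence as annotated to one gene."""

    gene_name: str
    sequence: str


@dataclass
class PrecursorRecord:
    """A hairpin (precursor) sequence with the names of its mature products."""

    gene_name: str
    sequence: str
    mature_children: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ReferenceTarget:
    """One countable unit of the reference.

    ``member_genes`` has more than one entry exactly when several genes yield
    the same mature sequence; precursor targets always have a single member.
    Precursor sequences may contain ``N`` runs from masking.
    """

    target_name: str
    sequence: str
    kind: str  # "mature" | "precursor"
    member_genes: tuple[str, ...]


@dataclass(frozen=True)
class NestedPair:
    """Two mature targets where ``short`` is ``long`` minus one terminal base."""

    short_target: str
    long_target: str


@dataclass
class Reference:
    """Collapsed mature targets, masked precursor targets and nested pairs."""

    targets: list[ReferenceTarget]
    nested_pairs: list[NestedPair]

    def __post_init__(self) -> None:
        names = [t.target_name for t in self.targets]
        if len(names) != len(set(names)):
            raise ReferenceError("duplicate target names in reference")
        self._by_name = {t.target_name: t for t in self.targets}
        for pair in self.nested_pairs:
            for name in (pair.short_target, pair.long_target):
                if name not in self._by_name:
                    raise ReferenceError(f"nested pair references unknown target {name!r}")
        self._nested_lookup = {
            frozenset((p.short_target, p.long_target)): p for p in self.nested_pairs
        }

    # -- lookups ---------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Reference):
            return NotImplemented
        return self.targets == other.targets and set(self.nested_pairs) == set(other.nested_pairs)

    def get(self, name: str) -> ReferenceTarget:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def mature_targets(self) -> list[ReferenceTarget]:
        return [t for t in self.targets if t.kind == "mature"]

    @property
    def precursor_targets(self) -> list[ReferenceTarget]:
        return [t for t in self.targets if t.kind == "precursor"]

    def nested_pair_for(self, names: Iterable[str]) -> NestedPair | None:
        """Return the registered pair matching exactly this set of two names."""
        return self._nested_lookup.get(frozenset(names))

    # -- serialization ---------------------------------------------------
    def write(self, fasta_path: str | Path, meta_path: str | Path) -> None:
        """Write the reference as FASTA plus a metadata TSV.

        The TSV has columns ``target_name``, ``kind``, ``length``,
        ``member_genes`` (comma-joined) and ``nested_partner``.
        """
        records = [
            SeqRecord(Seq(t.sequence), id=t.target_name, description="")
            for t in self.targets
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        partner: dict[str, str] = {}
        for p in self.nested_pairs:
            partner[p.short_target] = p.long_target
            partner[p.long_target] = p.short_target
        with open(meta_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["target_name", "kind", "length", "member_genes", "nested_partner"])
            for t in self.targets:
                writer.writerow(
                    [t.target_name, t.kind, len(t.sequence), ",".join(t.member_genes), partner.get(t.target_name, "")]
                )

    @classmethod
    def read(cls, fasta_path: str | Path, meta_path: str | Path) -> "Reference":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
        targets: list[ReferenceTarget] = []
        pair_rows: list[tuple[str, str]] = []
        with open(meta_path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                name = row["target_name"]
                if name not in seqs:
                    raise ReferenceError(f"metadata target {name!r} missing from FASTA")
                targets.append(
                    ReferenceTarget(
                        target_name=name,
                        sequence=seqs[name],
                        kind=row["kind"],
                        member_genes=tuple(row["member_genes"].split(",")) if row["member_genes"] else (name,),
                    )
                )
                if row["nested_partner"]:
                    pair_rows.append((name, row["nested_partner"]))
        by_name = {t.target_name: t for t in targets}
        pairs: set[NestedPair] = set()
        for a, b in pair_rows:
            if b not in by_name:
                raise ReferenceError(f"nested partner {b!r} missing from metadata")
            short, long_ = (a, b) if len(by_name[a].sequence) < len(by_name[b].sequence) else (b, a)
            pairs.add(NestedPair(short, long_))
        ordered = sorted(pairs, key=lambda p: (p.short_target, p.long_target))
        return cls(targets=targets, nested_pairs=ordered)


# ---------------------------------------------------------------------------
# parsing


def _clean_sequence(raw: str, name: str, allow_n: bool = False) -> str:
    seq = raw.upper().replace("U", "T")
    if not seq:
        raise ReferenceError(f"record {name!r} has an empty sequence")
    allowed = _DNA_N if allow_n else _DNA
    bad = set(seq) - allowed
    if bad:
        raise ReferenceError(f"record {name!r} contains invalid characters {sorted(bad)}")
    return seq


def _norm(name: str) -> str:
    return name.lower()


def _resolve_children(
    matures: list[MatureRecord],
    precursors: list[PrecursorRecord],
    child_map: Mapping[str, str] | None,
) -> None:
    """Attach mature products to hairpins.

    By naming convention a mature name extends its hairpin name (compared
    case-insensitively, so ``miR``/``mir`` capitalisation does not matter):
    either identical, or hairpin name plus a ``-`` suffix such as ``-5p``.
    An explicit mature→hairpin mapping overrides/extends the convention,
    because real-world FASTA headers do not encode the relation uniformly.
    """
    by_norm: dict[str, list[PrecursorRecord]] = {}
    for prec in precursors:
        by_norm.setdefault(_norm(prec.gene_name), []).append(prec)
    prec_by_name = {p.gene_name: p for p in precursors}
    explicit = dict(child_map or {})
    for mat in matures:
        if mat.gene_name in explicit:
            hp = explicit[mat.gene_name]
            if hp not in prec_by_name:
                raise ReferenceError(f"child map names unknown hairpin {hp!r}")
            prec_by_name[hp].mature_children.append(mat.gene_name)
            continue
        m = _norm(mat.gene_name)
        # exact match, then progressively strip '-' suffixes: miR-1-5p -> mir-1
        stem = m
        while True:
            for prec in by_norm.get(stem, []):
                prec.mature_children.append(mat.gene_name)
            if stem in by_norm:
                break
            if "-" not in stem:
                break
            stem = stem.rsplit("-", 1)[0]


def parse_mirbase_fasta(
    mature_src: str | Path | TextIO,
    hairpin_src: str | Path | TextIO,
    child_map: Mapping[str, str] | str | Path | None = None,
) -> tuple[list[MatureRecord], list[PrecursorRecord]]:
    """Parse mature and hairpin FASTA streams.

    ``child_map`` may be a mapping ``{mature_name: hairpin_name}`` or a path
    to a two-column TSV with the same content.  U is converted to T; record
    order is preserved; duplicate gene names raise :class:`ReferenceError`.
    """
    if isinstance(child_map, (str, Path)):
        mapping: dict[str, str] = {}
        with open(child_map, newline="") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ReferenceError(f"malformed child-map line: {line!r}")
                mapping[parts[0]] = parts[1]
        child_map = mapping

    def _read(src, allow_n: bool) -> list[tuple[str, str]]:
        out: list[tuple[str, str]] = []
        seen: set[str] = set()
        for rec in SeqIO.parse(src if not isinstance(src, Path) else str(src), "fasta"):
            name = rec.id
            if name in seen:
                raise ReferenceError(f"duplicate gene name {name!r}")
            seen.add(name)
            out.append((name, _clean_sequence(str(rec.seq), name, allow_n=allow_n)))
        return out

    matures = [MatureRecord(n, s) for n, s in _read(mature_src, allow_n=False)]
    precursors = [PrecursorRecord(n, s) for n, s in _read(hairpin_src, allow_n=False)]
    _resolve_children(matures, precursors, child_map if isinstance(child_map, Mapping) else None)
    mat_len = {m.gene_name: len(m.sequence) for m in matures}
    for prec in precursors:
        for child in prec.mature_children:
            if mat_len[child] > len(prec.sequence):
                raise ReferenceError(
                    f"mature {child!r} is longer than its hairpin {prec.gene_name!r}"
                )
    return matures, precursors


# ---------------------------------------------------------------------------
# collapsing, masking, nesting


def collapse_identical_matures(matures: list[MatureRecord]) -> list[ReferenceTarget]:
    """One target per distinct mature sequence.

    The target is named after the lexicographically first member gene; all
    members are recorded.  First-appearance order of sequences is preserved.
    """
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for mat in matures:
        if mat.sequence not in groups:
            groups[mat.sequence] = []
            order.append(mat.sequence)
        groups[mat.sequence].append(mat.gene_name)
    targets = []
    for seq in order:
        members = tuple(sorted(groups[seq]))
        targets.append(
            ReferenceTarget(target_name=members[0], sequence=seq, kind="mature", member_genes=members)
        )
    return targets


def mask_matures_in_precursors(
    precursors: list[PrecursorRecord], matures: list[MatureRecord]
) -> list[PrecursorRecord]:
    """Replace every occurrence of a precursor's own mature products with N.

    Only a hairpin's annotated children are masked.  A child that cannot be
    found as a substring of its hairpin triggers a warning and is left
    unmasked.  Output sequences have the same length as the input.
    """
    seq_by_name = {m.gene_name: m.sequence for m in matures}
    out: list[PrecursorRecord] = []
    for prec in precursors:
        seq = prec.sequence
        for child in prec.mature_children:
            child_seq = seq_by_name.get(child)
            if child_seq is None:
                warnings.warn(f"precursor {prec.gene_name!r}: unknown child {child!r}")
                continue
            if child_seq not in prec.sequence:
                warnings.warn(
                    f"mature {child!r} not found within precursor {prec.gene_name!r}; left unmasked"
                )
                continue
            start = 0
            while True:
                idx = seq.find(child_seq, start)
                if idx == -1:
                    # also mask occurrences present in the original sequence that
                    # were partially overwritten by a previous child's mask
                    break
                seq = seq[:idx] + "N" * len(child_seq) + seq[idx + len(child_seq):]
                start = idx + 1
        out.append(PrecursorRecord(prec.gene_name, seq, list(prec.mature_children)))
    return out


def detect_nested_pairs(
    targets: list[ReferenceTarget], warn_longer: bool = True
) -> list[NestedPair]:
    """Find mature target pairs where one is the other minus one base.

    Only length-difference-1 containments receive the subtraction treatment;
    containments of two or more bases are reported as warnings (``warn_longer``)
    but not registered.
    """
    matures = [t for t in targets if t.kind == "mature"]
    by_len: dict[int, list[ReferenceTarget]] = {}
    for t in matures:
        by_len.setdefault(len(t.sequence), []).append(t)
    pairs: list[NestedPair] = []
    for short in matures:
        for long_ in by_len.get(len(short.sequence) + 1, []):
            if short.sequence in long_.sequence:
                pairs.append(NestedPair(short.target_name, long_.target_name))
    if warn_longer:
        for short in matures:
            for diff_len, bucket in by_len.items():
                if diff_len < len(short.sequence) + 2:
                    continue
                for long_ in bucket:
                    if short.sequence in long_.sequence:
                        warnings.warn(
                            f"{short.target_name!r} nests inside {long_.target_name!r} "
                            f"with length difference {diff_len - len(short.sequence)}; "
                            "not treated as a nested pair"
                        )
    return pairs


def build_reference(
    matures: list[MatureRecord], precursors: list[PrecursorRecord]
) -> Reference:
    """Compose collapse, masking and nested-pair detection into a Reference."""
    mature_targets = collapse_identical_matures(matures)
    masked = mask_matures_in_precursors(precursors, matures)
    mature_names = {t.target_name for t in mature_targets}
    precursor_targets = []
    for prec in masked:
        if prec.gene_name in mature_names:
            raise ReferenceError(
                f"precursor name {prec.gene_name!r} collides with a mature target name"
            )
        precursor_targets.append(
            ReferenceTarget(
                target_name=prec.gene_name,
                sequence=prec.sequence,
                kind="precursor",
                member_genes=(prec.gene_name,),
            )
        )
    nested = detect_nested_pairs(mature_targets, warn_longer=False)
    return Reference(targets=mature_targets + precursor_targets, nested_pairs=nested)
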