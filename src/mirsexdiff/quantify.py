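"""Hit-to-count conversion, nested-pair subtraction, and abundance tables.

Counting priority per read (weighted by its collapse multiplicity):

1. If the read has any perfect (0-mismatch) hit, its 1-mismatch hits are
   discarded — reads with both perfect and imperfect matches count only
   toward the perfect-match target.
2. Precursor hits are discarded whenever a mature hit remains; precursor
   counts comprise reads mapping exclusively to precursor sequences.
3. If the remaining hits name a single target, the read counts there.
4. If they name exactly the two members of a registered nested pair, the
   read counts toward the longer target's total and is flagged as shared;
   the subtraction step then attributes shared reads to the shorter target
   (short = total-on-long minus unique-on-long, long = unique-on-long),
   conserving the pair total.
5. Otherwise the read is ambiguous: it stays in the mapped total but is not
   assigned to any target.

Reads counted via a 1-mismatch hit are additionally tallied in the mismatch
sub-counts, which are a subset of the totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .mapping import Hit
from .readproc import UniqueRead
from .reference import NestedPair, Reference

__all__ = [
    "LibraryCounts",
    "CountTable",
    "AbundanceTable",
    "assign_counts",
    "nested_subtraction",
    "build_count_table",
    "cpm_normalize",
    "filter_highly_expressed",
    "pooling_correlation",
]


@dataclass
class LibraryCounts:
    """Per-library counting result, before or after nested subtraction."""

    totals: dict[str, int] = field(default_factory=dict)
    mismatch: dict[str, int] = field(default_factory=dict)
    shared_totals: dict[NestedPair, int] = field(default_factory=dict)
    shared_mismatch: dict[NestedPair, int] = field(default_factory=dict)
    ambiguous: int = 0
    mapped_total: int = 0
    unmapped: int = 0
    subtracted: bool = False

    @property
    def assigned(self) -> int:
        return sum(self.totals.values())

    @property
    def total_reads(self) -> int:
        """Multiplicity-weighted filtered reads that entered counting."""
        return self.mapped_total + self.unmapped


def assign_counts(
    unique_reads: Iterable[UniqueRead],
    hits_by_seq: Mapping[str, Sequence[Hit]],
    reference: Reference,
) -> LibraryCounts:
    """Apply the counting priority rules to mapped, collapsed reads."""
    lc = LibraryCounts()
    for ur in unique_reads:
        hits = hits_by_seq.get(ur.sequence, ())
        for h in hits:
            if h.target_name not in reference:
                raise KeyError(f"hit references unknown target {h.target_name!r}")
        if not hits:
            lc.unmapped += ur.multiplicity
            continue
        lc.mapped_total += ur.multiplicity
        best_mm = min(h.mismatches for h in hits)
        kept = [h for h in hits if h.mismatches == best_mm]
        mature = [h for h in kept if reference.get(h.target_name).kind == "mature"]
        if mature:
            kept = mature
        names = {h.target_name for h in kept}
        if len(names) == 1:
            target = next(iter(names))
            lc.totals[target] = lc.totals.get(target, 0) + ur.multiplicity
            if best_mm == 1:
                lc.mismatch[target] = lc.mismatch.get(target, 0) + ur.multiplicity
        elif len(names) == 2:
            pair = reference.nested_pair_for(names)
            if pair is None:
                lc.ambiguous += ur.multiplicity
            else:
                lc.totals[pair.long_target] = (
                    lc.totals.get(pair.long_target, 0) + ur.multiplicity
                )
                lc.shared_totals[pair] = lc.shared_totals.get(pair, 0) + ur.multiplicity
                if best_mm == 1:
                    lc.mismatch[pair.long_target] = (
                        lc.mismatch.get(pair.long_target, 0) + ur.multiplicity
                    )
                    lc.shared_mismatch[pair] = (
                        lc.shared_mismatch.get(pair, 0) + ur.multiplicity
                    )
        else:
            lc.ambiguous += ur.multiplicity
    return lc


def nested_subtraction(counts: LibraryCounts, nested_pairs: Iterable[NestedPair]) -> LibraryCounts:
    """Attribute nested-pair shared reads to the shorter target.

    For each pair: short := total mapping to long minus unique mappings to
    long (i.e. the shared reads); long := unique mappings to long.  The pair
    total is conserved.  A negative result signals an accounting bug.
    """
    if counts.subtracted:
        raise ValueError("counts have already been nested-subtracted")
    out = LibraryCounts(
        totals=dict(counts.totals),
        mismatch=dict(counts.mismatch),
        shared_totals=dict(counts.shared_totals),
        shared_mismatch=dict(counts.shared_mismatch),
        ambiguous=counts.ambiguous,
        mapped_total=counts.mapped_total,
        unmapped=counts.unmapped,
        subtracted=True,
    )
    for pair in nested_pairs:
        shared = counts.shared_totals.get(pair, 0)
        if shared == 0:
            continue
        total_long = out.totals.get(pair.long_target, 0)
        unique_long = total_long - shared
        if unique_long < 0:
            raise ValueError(
                f"nested subtraction for {pair} yields negative unique count "
                f"({total_long} total, {shared} shared)"
            )
        out.totals[pair.long_target] = unique_long
        out.totals[pair.short_target] = out.totals.get(pair.short_target, 0) + shared
        shared_mm = counts.shared_mismatch.get(pair, 0)
        if shared_mm:
            out.mismatch[pair.long_target] = out.mismatch.get(pair.long_target, 0) - shared_mm
            out.mismatch[pair.short_target] = (
                out.mismatch.get(pair.short_target, 0) + shared_mm
            )
    return out


# ---------------------------------------------------------------------------
# tables


@dataclass
class CountTable:
    """Targets x libraries totals with 1-mismatch sub-counts."""

    total: pd.DataFrame
    mismatch: pd.DataFrame
    mapped_total: pd.Series
    meta: pd.DataFrame | None = None  # kind, member_genes per target

    def __post_init__(self) -> None:
        if not self.total.index.equals(self.mismatch.index) or not self.total.columns.equals(
            self.mismatch.columns
        ):
            raise ValueError("total and mismatch tables must share shape and labels")
        if (self.mismatch.values > self.total.values).any():
            raise ValueError("mismatch counts exceed total counts")

    @property
    def targets(self) -> list[str]:
        return list(self.total.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.total.columns)

    def equals(self, other: "CountTable") -> bool:
        return (
            self.total.equals(other.total)
            and self.mismatch.equals(other.mismatch)
            and self.mapped_total.equals(other.mapped_total)
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write the wide TSV layout; the mapped totals ride in a header line."""
        with open(path, "w") as fh:
            pairs = ",".join(f"{lib}={int(v)}" for lib, v in self.mapped_total.items())
            fh.write(f"# mapped_total: {pairs}\n")
            wide = pd.DataFrame(index=self.total.index)
            wide.index.name = "target"
            if self.meta is not None:
                wide["kind"] = self.meta["kind"]
                wide["member_genes"] = self.meta["member_genes"]
            else:
                wide["kind"] = ""
                wide["member_genes"] = ""
            for lib in self.libraries:
                wide[f"{lib}_total"] = self.total[lib]
                wide[f"{lib}_mismatch"] = self.mismatch[lib]
            wide.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# mapped_total:"):
                raise ValueError("count table TSV missing mapped_total header line")
            mapped = {}
            payload = header.split(":", 1)[1].strip()
            if payload:
                for item in payload.split(","):
                    lib, val = item.split("=")
                    mapped[lib] = int(val)
            wide = pd.read_csv(fh, sep="\t", index_col="target", keep_default_na=False)
        libs = [c[: -len("_total")] for c in wide.columns if c.endswith("_total")]
        total = pd.DataFrame({lib: wide[f"{lib}_total"].astype(int) for lib in libs})
        mismatch = pd.DataFrame({lib: wide[f"{lib}_mismatch"].astype(int) for lib in libs})
        meta = wide[["kind", "member_genes"]].astype(str) if "kind" in wide else None
        return cls(
            total=total,
            mismatch=mismatch,
            mapped_total=pd.Series(mapped, dtype=int).reindex(libs),
            meta=meta,
        )


def build_count_table(
    per_library: Mapping[str, LibraryCounts],
    reference: Reference | None = None,
) -> CountTable:
    """Assemble per-library counts into one table.

    Target order follows the reference when given, otherwise the sorted
    union of targets seen across libraries (missing entries are zero).
    """
    if not per_library:
        raise ValueError("at least one library is required")
    if reference is not None:
        order = [t.target_name for t in reference.targets]
    else:
        order = sorted({t for lc in per_library.values() for t in lc.totals})
    libs = list(per_library)
    total = pd.DataFrame(0, index=pd.Index(order, name="target"), columns=libs, dtype=int)
    mismatch = total.copy()
    mapped = pd.Series(0, index=libs, dtype=int)
    for lib, lc in per_library.items():
        for t, v in lc.totals.items():
            if t not in total.index:
                raise KeyError(f"library {lib!r} counts unknown target {t!r}")
            total.loc[t, lib] = v
        for t, v in lc.mismatch.items():
            mismatch.loc[t, lib] = v
        mapped[lib] = lc.mapped_total
    meta = None
    if reference is not None:
        meta = pd.DataFrame(
            {
                "kind": [t.kind for t in reference.targets],
                "member_genes": [",".join(t.member_genes) for t in reference.targets],
            },
            index=pd.Index(order, name="target"),
        )
    return CountTable(total=total, mismatch=mismatch, mapped_total=mapped, meta=meta)


@dataclass
class AbundanceTable:
    """Counts-per-million and percent abundance per target and library."""

    cpm: pd.DataFrame
    percent: pd.DataFrame


def cpm_normalize(table: CountTable) -> AbundanceTable:
    """Normalize each library to counts per million and percent abundance.

    The denominator is the per-library sum of counted target reads (the
    total reads mapped for all miRNAs), so CPM columns sum to 1e6 and
    percent columns to 100.
    """
    col_sums = table.total.sum(axis=0)
    zero = col_sums[col_sums == 0]
    if len(zero):
        raise ValueError(f"zero-count libraries: {list(zero.index)}")
    cpm = table.total / col_sums * 1e6
    percent = table.total / col_sums * 100.0
    return AbundanceTable(cpm=cpm, percent=percent)


def filter_highly_expressed(
    abundance: AbundanceTable, threshold: float = 100.0, min_libraries: int = 1
) -> list[str]:
    """Targets with CPM strictly above ``threshold`` in >= ``min_libraries``."""
    passing = (abundance.cpm > threshold).sum(axis=1) >= min_libraries
    return list(abundance.cpm.index[passing])


def pooling_correlation(
    individual_tables: Sequence[CountTable],
    pooled_table: CountTable,
    subset: Sequence[str],
) -> tuple[float, float]:
    """Pearson r-squared of mean individual counts vs pooled counts.

    Used to judge whether a pooled library is a faithful stand-in for
    separately sequenced biological replicates.  Returns (r_squared,
    two-sided p-value).
    """
    if len(individual_tables) < 2:
        raise ValueError("need at least two individual libraries")
    subset = list(subset)
    means = np.mean(
        [t.total.loc[subset].mean(axis=1).to_numpy(dtype=float) for t in individual_tables],
        axis=0,
    )
    pooled = pooled_table.total.loc[subset].mean(axis=1).to_numpy(dtype=float)
    if np.ptp(means) == 0 or np.ptp(pooled) == 0:
        raise ValueError("correlation undefined for constant count vectors")
    r, p = _stats.pearsonr(means, pooled)
    return float(r * r), float(p)
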