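"""End-to-end orchestration: reference build -> map -> count -> filter -> stats.

The pipeline is driven by a :class:`PipelineConfig` (constructible from a
YAML file with CLI overrides), writes TSV/JSON outputs plus a run manifest
with parameters and input checksums, and is deterministic: re-running on
identical inputs reproduces identical output bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from . import __version__
from .mapping import ReadAligner, Hit, map_unique_reads, mapping_rate
from .quantify import (
    CountTable,
    assign_counts,
    build_count_table,
    cpm_normalize,
    filter_highly_expressed,
    nested_subtraction,
)
from .ratiostats import (
    CONTRASTS,
    bin_ratios,
    compare_conditions,
    group_log2_ratio,
    median_ratio,
    pca_libraries,
    sign_bias_test,
    load_design,
)
from .readproc import (
    RawRead,
    TRUSEQ_SMALL_RNA_ADAPTER,
    collapse_reads,
    demultiplex,
    length_filter,
    read_fastq,
    read_qseq,
    trim_adapter,
)
from .reference import Reference, build_reference, parse_mirbase_fasta

__all__ = ["PipelineConfig", "PipelineResult", "StageError", "run_pipeline", "quantify_libraries"]

log = logging.getLogger("mirsexdiff")


class StageError(RuntimeError):
    """A pipeline stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    mature_fasta: str = ""
    hairpin_fasta: str = ""
    design: str = ""
    out_dir: str = "mirsexdiff_out"
    #: multiplexed reads file (qseq/fastq); per-library paths come from the
    #: design sheet 'path' column when this is empty
    reads: str = ""
    child_map: str = ""
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    min_len: int = 18
    max_len: int = 30
    mismatches: int = 1
    cpm_threshold: float = 100.0
    min_libraries: int = 1
    pseudocount: float = 0.5
    pca_transform: str = "log2cpm1"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.mismatches != 1:
            raise ValueError("only the 1-mismatch mapping mode is supported")
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")


@dataclass
class PipelineResult:
    reference: Reference
    count_table: CountTable
    abundance: object
    highly_expressed: list[str]
    stats: dict
    mapping_rates: dict[str, float]
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_any(path: Path) -> Iterable[RawRead]:
    name = path.name.removesuffix(".gz")
    if name.endswith(".qseq") or name.endswith(".txt"):
        return read_qseq(path)
    return read_fastq(path)


def quantify_libraries(
    reference: Reference,
    reads_by_lib: Mapping[str, Iterable[RawRead]],
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER,
    min_len: int = 18,
    max_len: int = 30,
    hit_cache: dict[str, list[Hit]] | None = None,
) -> tuple[CountTable, dict[str, float], dict[str, dict]]:
    """Trim, filter, collapse, map and count each library against a reference.

    The in-memory workhorse behind ``run_pipeline``; the hit cache may be
    shared across libraries since hits depend only on sequence + reference.
    Returns (count table, per-library mapping rate, per-library accounting).
    """
    aligner = ReadAligner(reference)
    if hit_cache is None:
        hit_cache = {}
    per_lib = {}
    rates: dict[str, float] = {}
    accounting: dict[str, dict] = {}
    for lib, reads in reads_by_lib.items():
        trimmed = (trim_adapter(r, adapter) for r in reads)
        filtered = length_filter(trimmed, min_len, max_len)
        unique = collapse_reads(filtered)
        hits = map_unique_reads(unique, aligner, cache=hit_cache)
        counts = assign_counts(unique, hits, reference)
        counts = nested_subtraction(counts, reference.nested_pairs)
        n_filtered = sum(u.multiplicity for u in unique)
        if counts.assigned + counts.ambiguous + counts.unmapped != n_filtered:
            raise StageError(
                "count", f"library {lib!r}: read conservation violated"
            )
        per_lib[lib] = counts
        rates[lib] = mapping_rate(unique, hits) if unique else float("nan")
        accounting[lib] = {
            "filtered_reads": n_filtered,
            "mapped": counts.mapped_total,
            "assigned": counts.assigned,
            "ambiguous": counts.ambiguous,
            "unmapped": counts.unmapped,
        }
        log.info(
            "library %s: %d filtered, %d mapped (%.1f%%), %d assigned, %d ambiguous",
            lib,
            n_filtered,
            counts.mapped_total,
            100.0 * rates[lib] if unique else float("nan"),
            counts.assigned,
            counts.ambiguous,
        )
    table = build_count_table(per_lib, reference)
    return table, rates, accounting


def _stats_stage(
    abundance,
    design: pd.DataFrame,
    highly_expressed: list[str],
    pseudocount: float,
    pca_transform: str,
) -> dict:
    if not highly_expressed:
        return {"error": "no targets pass the CPM threshold; statistics not computed"}
    conditions = sorted(
        {(s, d) for s, d in zip(design["gonadal_state"], design["diet"])},
        key=lambda c: ("intact", "GDX").index(c[0]) * 2 + ("chow", "HFD").index(c[1]),
    )
    out: dict = {"conditions": ["/".join(c) for c in conditions], "contrasts": {}}
    profiles = {}
    for contrast in CONTRASTS:
        per_cond = {}
        for cond in conditions:
            profile = group_log2_ratio(
                abundance, design, contrast, cond,
                targets=highly_expressed, pseudocount=pseudocount,
            )
            profiles[(contrast, cond)] = profile
            sign = sign_bias_test(profile)
            edges, counts = bin_ratios(profile)
            per_cond["/".join(cond)] = {
                "n": len(profile),
                "median": median_ratio(profile),
                "n_positive": sign.n_positive,
                "n_negative": sign.n_negative,
                "binomial_p": sign.p_value,
                "direction": sign.direction,
                "histogram": {"edges": edges.tolist(), "counts": counts.tolist()},
                "pseudocount_flagged": len(profile.pseudocount_flagged),
            }
        shifts = {}
        for i in range(len(conditions)):
            for j in range(i + 1, len(conditions)):
                a, b = conditions[i], conditions[j]
                shifts["/".join(a) + " vs " + "/".join(b)] = compare_conditions(
                    profiles[(contrast, a)], profiles[(contrast, b)]
                )
        out["contrasts"][contrast] = {"by_condition": per_cond, "wilcoxon_shift_p": shifts}
    scores, frac = pca_libraries(abundance, highly_expressed, transform=pca_transform)
    out["pca"] = {
        "scores": {lib: scores.loc[lib].round(6).tolist() for lib in scores.index},
        "variance_fraction": [round(float(f), 6) for f in frac],
    }
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write its result bundle to disk."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = [Path(p) for p in (config.mature_fasta, config.hairpin_fasta, config.design) if p]

    log.info("building reference from %s + %s", config.mature_fasta, config.hairpin_fasta)
    try:
        matures, precursors = parse_mirbase_fasta(
            Path(config.mature_fasta),
            Path(config.hairpin_fasta),
            child_map=config.child_map or None,
        )
        reference = build_reference(matures, precursors)
    except Exception as exc:  # re-raise with stage context
        raise StageError("build-ref", str(exc)) from exc
    reference.write(out / "reference.fa", out / "reference_meta.tsv")

    design = load_design(config.design)
    if config.reads:
        barcode_map = dict(zip(design["barcode"], design["library"]))
        libs, unassigned = demultiplex(_read_any(Path(config.reads)), barcode_map)
        log.info("demultiplexed %s: %d unassigned", config.reads, unassigned)
        reads_by_lib: Mapping[str, Iterable[RawRead]] = libs
        inputs.append(Path(config.reads))
    else:
        if "path" not in design.columns:
            raise StageError("map", "design sheet lacks a 'path' column and no multiplexed reads file was given")
        base = Path(config.design).parent
        paths = {row["library"]: base / row["path"] for _, row in design.iterrows()}
        inputs.extend(paths.values())
        reads_by_lib = {lib: _read_any(p) for lib, p in paths.items()}

    table, rates, accounting = quantify_libraries(
        reference,
        reads_by_lib,
        adapter=config.adapter,
        min_len=config.min_len,
        max_len=config.max_len,
    )
    table.to_tsv(out / "counts.tsv")
    abundance = cpm_normalize(table)
    abundance.cpm.round(4).to_csv(out / "abundance_cpm.tsv", sep="\t")
    abundance.percent.round(6).to_csv(out / "abundance_percent.tsv", sep="\t")

    highly = filter_highly_expressed(abundance, config.cpm_threshold, config.min_libraries)
    (out / "highly_expressed.txt").write_text("".join(f"{t}\n" for t in highly))
    log.info("%d of %d targets above %.0f CPM", len(highly), len(table.targets), config.cpm_threshold)

    stats = _stats_stage(
        abundance, design, highly, config.pseudocount, config.pca_transform
    )
    if "error" in stats:
        log.error("stats stage: %s", stats["error"])
    with open(out / "stats.json", "w") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True)
        fh.write("\n")

    manifest = {
        "tool": "mirsexdiff",
        "version": __version__,
        "parameters": asdict(config),
        "inputs": {str(p): _sha256(p) for p in inputs},
        "libraries": list(design["library"]),
        "accounting": accounting,
        "mapping_rate": {k: round(v, 6) for k, v in rates.items()},
        "n_targets": len(table.targets),
        "n_highly_expressed": len(highly),
        "outputs": sorted(
            p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return PipelineResult(
        reference=reference,
        count_table=table,
        abundance=abundance,
        highly_expressed=highly,
        stats=stats,
        mapping_rates=rates,
        manifest=manifest,
    )
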