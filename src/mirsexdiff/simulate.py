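"""Synthetic miRNA sequencing experiments with known ground truth.

The generator emulates the study design end to end: a mature/hairpin
reference with gene families sharing one mature sequence and 1-nt-nested
mature pairs, then twelve pooled libraries — one per Four Core Genotypes
cell (XX-F, XX-M, XY-F, XY-M) under each of three physiological conditions
(gonadally intact on chow, gonadectomized on chow, gonadectomized on high
fat diet) — with adapter-contaminated, error-bearing reads and per-library
index barcodes.

Expression model
----------------
A heavy-tailed log-normal baseline (sigma defaults to 2.0) is shared across
libraries, reproducing the dominance structure of adipose miRNA data where
a handful of species carry about half of all reads.  Planted sex,
chromosome-complement and diet effects are multiplicative in expression
(additive in log2) so they map directly onto the ratio profiles the
analysis computes.  Effects are planted on a random subset of miRNAs drawn
from outside the top decile of baseline expression mass: CPM normalization
is compositional, and an effect planted on the dominant miRNAs would shift
the per-library denominator by nearly the full effect size and cancel the
bias it was meant to create.  Reads are drawn multinomially at the
configured depth, the 3' adapter is appended, and uniform substitution
errors are applied to the insert (no indels; the mapper is ungapped — the
error rate is the single knob standing in for everything that keeps 10-20%
of real reads from mapping).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .readproc import RawRead, TRUSEQ_SMALL_RNA_ADAPTER, write_fastq, write_qseq
from .reference import (
    MatureRecord,
    PrecursorRecord,
    Reference,
    build_reference,
)

__all__ = [
    "EffectSpec",
    "GeneratorConfig",
    "SyntheticReference",
    "ExperimentTruth",
    "SimulatedExperiment",
    "paper_like_config",
    "generate_reference",
    "generate_library",
    "generate_fcg_experiment",
    "generate_pooling_study",
    "write_experiment",
    "TRUSEQ_INDEXES",
]

_BASES = "ACGT"

#: the twelve Illumina TruSeq index sequences used to barcode the libraries
TRUSEQ_INDEXES = [
    "ATCACG", "CGATGT", "TTAGGC", "TGACCA", "ACAGTG", "GCCAAT",
    "CAGATC", "ACTTGA", "GATCAG", "TAGCTT", "GGCTAC", "CTTGTA",
]

#: genotype cells of the Four Core Genotypes cross
GENOTYPES = [("F", "XX"), ("M", "XX"), ("F", "XY"), ("M", "XY")]

#: the three physiological conditions, as (gonadal_state, diet)
CONDITIONS = [("intact", "chow"), ("GDX", "chow"), ("GDX", "HFD")]


@dataclass(frozen=True)
class EffectSpec:
    """A planted multiplicative effect: log2 size and fraction of miRNAs hit."""

    log2_size: float = 0.0
    fraction: float = 0.7


@dataclass
class GeneratorConfig:
    n_mature_genes: int = 300
    n_shared_families: int = 6
    family_size: int = 2
    n_nested_pairs: int = 7
    mature_len_range: tuple[int, int] = (18, 24)
    precursor_flank_range: tuple[int, int] = (12, 25)
    depth: int = 100_000
    error_rate: float = 0.03
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    effect_sex: EffectSpec = field(default_factory=EffectSpec)
    effect_chromosome: EffectSpec = field(default_factory=lambda: EffectSpec(0.0, 0.7))
    effect_diet: EffectSpec = field(default_factory=lambda: EffectSpec(0.0, 0.4))
    #: per-condition overrides of the sex/chromosome log2 effect sizes
    condition_effects: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    #: fraction of baseline-expression mass ranks protected from effects
    protect_top: float = 0.1
    dispersion: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        reserved = self.n_shared_families * self.family_size + 2 * self.n_nested_pairs
        if reserved > self.n_mature_genes:
            raise ValueError(
                f"infeasible config: families and nested pairs need {reserved} genes, "
                f"only {self.n_mature_genes} available"
            )
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.depth < 0 or self.n_mature_genes < 0 or self.n_nested_pairs < 0:
            raise ValueError("counts must be non-negative")
        for spec in (self.effect_sex, self.effect_chromosome, self.effect_diet):
            if not 0.0 <= spec.fraction <= 1.0:
                raise ValueError("effect fractions must be in [0, 1]")
        if self.mature_len_range[0] > self.mature_len_range[1] or self.mature_len_range[0] < 2:
            raise ValueError("invalid mature length range")


def paper_like_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Preset planting the study's qualitative pattern.

    Male bias in the intact-chow condition, a smaller female bias after
    gonadectomy, male plus XY bias under high fat diet, and a strong global
    diet effect that dominates library covariance.
    """
    cfg = GeneratorConfig(
        effect_sex=EffectSpec(0.5, 0.8),
        effect_chromosome=EffectSpec(0.0, 0.8),
        effect_diet=EffectSpec(1.5, 0.4),
        condition_effects={
            ("intact", "chow"): {"sex": 0.5, "chromosome": 0.0},
            ("GDX", "chow"): {"sex": -0.4, "chromosome": 0.0},
            ("GDX", "HFD"): {"sex": 0.5, "chromosome": 0.5},
        },
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


# ---------------------------------------------------------------------------
# reference generation


@dataclass
class SyntheticReference:
    """Generated FASTA inputs plus the truth registry of planted structure."""

    mature_records: list[MatureRecord]
    precursor_records: list[PrecursorRecord]  # unmasked, as a hairpin FASTA would be
    #: collapsed target name -> member mature gene names (the truth registry)
    families: dict[str, tuple[str, ...]]
    #: planted (short_target, long_target) collapsed-name pairs
    nested: list[tuple[str, str]]
    #: collapsed target name -> mature sequence, in emission order
    target_seqs: dict[str, str]

    @property
    def target_names(self) -> list[str]:
        return list(self.target_seqs)

    def build(self) -> Reference:
        """Run the reference builder on the generated records."""
        return build_reference(self.mature_records, self.precursor_records)

    def write_fasta(self, mature_path: str | Path, hairpin_path: str | Path) -> None:
        with open(mature_path, "w") as fh:
            for rec in self.mature_records:
                fh.write(f">{rec.gene_name}\n{rec.sequence.replace('T', 'U')}\n")
        with open(hairpin_path, "w") as fh:
            for rec in self.precursor_records:
                fh.write(f">{rec.gene_name}\n{rec.sequence.replace('T', 'U')}\n")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _conflicts(seq: str, pool: Iterable[str]) -> bool:
    """True if seq equals, contains or is contained in any sequence in pool."""
    for other in pool:
        if seq == other or seq in other or other in seq:
            return True
    return False


def generate_reference(config: GeneratorConfig) -> SyntheticReference:
    """Emit mature+hairpin records with planted families and nested pairs.

    Deterministic under ``config.seed``: the same seed yields byte-identical
    FASTA output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.mature_len_range

    # distinct collapsed sequences: regular + family + nested(long, short)
    n_family_seqs = config.n_shared_families
    n_regular = (
        config.n_mature_genes
        - config.n_shared_families * config.family_size
        - 2 * config.n_nested_pairs
    )
    sequences: list[str] = []

    def _draw(length: int) -> str:
        for _ in range(1000):
            seq = _random_seq(rng, length)
            if not _conflicts(seq, sequences):
                sequences.append(seq)
                return seq
        raise RuntimeError("could not draw a non-conflicting mature sequence")

    regular_seqs = [_draw(int(rng.integers(lo, hi + 1))) for _ in range(n_regular)]
    family_seqs = [_draw(int(rng.integers(lo, hi + 1))) for _ in range(n_family_seqs)]
    nested_seqs: list[tuple[str, str]] = []  # (short, long)
    for _ in range(config.n_nested_pairs):
        for _ in range(1000):
            long_seq = _random_seq(rng, int(rng.integers(max(lo + 1, 19), hi + 1)))
            short_seq = long_seq[:-1] if rng.random() < 0.5 else long_seq[1:]
            others = sequences + [s for pair in nested_seqs for s in pair]
            if not (_conflicts(long_seq, others) or _conflicts(short_seq, others)):
                nested_seqs.append((short_seq, long_seq))
                break
        else:
            raise RuntimeError("could not draw a non-conflicting nested pair")
    all_mature_seqs = sequences + [s for pair in nested_seqs for s in pair]

    # assign sequences to genes; families get family_size genes each
    matures: list[MatureRecord] = []
    precursors: list[PrecursorRecord] = []
    families: dict[str, tuple[str, ...]] = {}
    target_seqs: dict[str, str] = {}
    gene_no = 0

    def _add_gene(seq: str) -> str:
        nonlocal gene_no
        gene_no += 1
        hairpin_name = f"syn-mir-{gene_no:04d}"
        mature_name = f"syn-miR-{gene_no:04d}-3p"
        matures.append(MatureRecord(mature_name, seq))
        flank5 = _random_seq(rng, int(rng.integers(*config.precursor_flank_range)))
        flank3 = _random_seq(rng, int(rng.integers(*config.precursor_flank_range)))
        precursors.append(
            PrecursorRecord(hairpin_name, flank5 + seq + flank3, [mature_name])
        )
        return mature_name

    for seq in regular_seqs:
        name = _add_gene(seq)
        families[name] = (name,)
        target_seqs[name] = seq
    for seq in family_seqs:
        members = tuple(sorted(_add_gene(seq) for _ in range(config.family_size)))
        families[members[0]] = members
        target_seqs[members[0]] = seq
    nested_names: list[tuple[str, str]] = []
    for short_seq, long_seq in nested_seqs:
        short_name = _add_gene(short_seq)
        long_name = _add_gene(long_seq)
        families[short_name] = (short_name,)
        families[long_name] = (long_name,)
        target_seqs[short_name] = short_seq
        target_seqs[long_name] = long_seq
        nested_names.append((short_name, long_name))

    # keep precursor flanks free of accidental mature occurrences; the only
    # permitted containments are each hairpin's own product (and, for the
    # long member of a nested pair, the short sequence it embeds by design)
    seq_by_mature = {m.gene_name: m.sequence for m in matures}
    for prec in precursors:
        own = seq_by_mature[prec.mature_children[0]]
        for _ in range(1000):
            clash = any(
                s in prec.sequence
                for s in all_mature_seqs
                if s != own and s not in own
            )
            if not clash:
                break
            flank5 = _random_seq(rng, int(rng.integers(*config.precursor_flank_range)))
            flank3 = _random_seq(rng, int(rng.integers(*config.precursor_flank_range)))
            prec.sequence = flank5 + own + flank3
        else:
            raise RuntimeError("could not build a clash-free precursor")
    return SyntheticReference(
        mature_records=matures,
        precursor_records=precursors,
        families=families,
        nested=nested_names,
        target_seqs=target_seqs,
    )


# ---------------------------------------------------------------------------
# expression and reads


@dataclass
class ExperimentTruth:
    """Ground truth of a simulated experiment.

    ``truth_counts`` are the realized multinomial draws (the counts a
    perfect pipeline would report per collapsed target and library, summing
    to the depth); ``expected_expression`` are the underlying relative
    expression levels.  ``planted_directions`` give the sign of the planted
    log2 ratio bias per contrast and condition (+1 numerator group higher,
    -1 denominator group higher, 0 none).
    """

    expected_expression: pd.DataFrame
    truth_counts: pd.DataFrame
    planted_directions: dict[str, dict[tuple[str, str], int]]
    affected: dict[str, list[str]]
    error_reads: dict[str, int]

    def library_depth_ok(self, depth: int) -> bool:
        return bool((self.truth_counts.sum(axis=0) == depth).all())


@dataclass
class SimulatedExperiment:
    reference: SyntheticReference
    design: pd.DataFrame
    libraries: dict[str, list[RawRead]]
    truth: ExperimentTruth
    config: GeneratorConfig


def _effect_sizes(config: GeneratorConfig, condition: tuple[str, str]) -> tuple[float, float]:
    override = config.condition_effects.get(condition, {})
    sex = override.get("sex", config.effect_sex.log2_size)
    chrom = override.get("chromosome", config.effect_chromosome.log2_size)
    return sex, chrom


def _baseline_and_masks(
    synref: SyntheticReference, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray]:
    n = len(synref.target_seqs)
    baseline = rng.lognormal(mean=0.0, sigma=config.dispersion, size=n)
    # protect the top expression ranks from planted effects (see module docs)
    n_protected = int(np.ceil(config.protect_top * n))
    protected = np.zeros(n, dtype=bool)
    protected[np.argsort(baseline)[::-1][:n_protected]] = True
    eligible = ~protected
    masks: dict[str, np.ndarray] = {}
    for key, spec in (
        ("sex", config.effect_sex),
        ("chromosome", config.effect_chromosome),
        ("diet", config.effect_diet),
    ):
        mask = (rng.random(n) < spec.fraction) & eligible
        masks[key] = mask
    diet_signs = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    return baseline, masks, diet_signs


def _library_expression(
    baseline: np.ndarray,
    masks: dict[str, np.ndarray],
    diet_signs: np.ndarray,
    config: GeneratorConfig,
    gonadal_sex: str,
    chromosomes: str,
    condition: tuple[str, str],
) -> np.ndarray:
    expr = baseline.copy()
    sex_delta, chrom_delta = _effect_sizes(config, condition)
    if gonadal_sex == "M" and sex_delta != 0.0:
        expr[masks["sex"]] *= 2.0 ** sex_delta
    if chromosomes == "XY" and chrom_delta != 0.0:
        expr[masks["chromosome"]] *= 2.0 ** chrom_delta
    if condition[1] == "HFD" and config.effect_diet.log2_size != 0.0:
        expr[masks["diet"]] *= 2.0 ** (diet_signs[masks["diet"]] * config.effect_diet.log2_size)
    return expr


def _mutate(seq: str, k: int, rng: np.random.Generator) -> str:
    positions = rng.choice(len(seq), size=k, replace=False)
    chars = list(seq)
    for pos in positions:
        old = chars[pos]
        new = _BASES[int(rng.integers(0, 3))]
        if new == old:
            new = _BASES[3] if old != _BASES[3] else "G"
        chars[pos] = new
    return "".join(chars)


def generate_library(
    synref: SyntheticReference,
    expression: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
    lib_name: str,
    barcode: str | None = None,
) -> tuple[list[RawRead], np.ndarray, int]:
    """Sample one library's reads from a relative-expression vector.

    Returns (reads, truth counts per collapsed target, number of reads
    carrying at least one planted error).
    """
    names = synref.target_names
    probs = expression / expression.sum()
    counts = rng.multinomial(config.depth, probs)
    reads: list[RawRead] = []
    n_error_reads = 0
    adapter = config.adapter
    for tidx, c in enumerate(counts):
        if c == 0:
            continue
        insert = synref.target_seqs[names[tidx]]
        L = len(insert)
        if config.error_rate > 0.0:
            n_errs = rng.binomial(L, config.error_rate, size=c)
        else:
            n_errs = np.zeros(c, dtype=int)
        for j in range(c):
            k = int(n_errs[j])
            seq = insert if k == 0 else _mutate(insert, k, rng)
            if k:
                n_error_reads += 1
            full = seq + adapter
            reads.append(
                RawRead(
                    read_id=f"{lib_name}|{names[tidx]}|{j}|e{k}",
                    sequence=full,
                    qualities="I" * len(full),
                    barcode=barcode,
                )
            )
    return reads, counts, n_error_reads


def generate_fcg_experiment(
    config: GeneratorConfig | None = None, out_dir: str | Path | None = None
) -> SimulatedExperiment:
    """Simulate the full 12-library Four Core Genotypes experiment.

    One library per genotype x condition; deterministic under the config
    seed.  When ``out_dir`` is given the experiment is also written to disk
    (see :func:`write_experiment`).
    """
    config = config or GeneratorConfig()
    config.validate()
    synref = generate_reference(config)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31) + 1)
    baseline, masks, diet_signs = _baseline_and_masks(synref, config, rng)
    names = synref.target_names

    rows = []
    libraries: dict[str, list[RawRead]] = {}
    expected = {}
    truth_counts = {}
    error_reads = {}
    idx = 0
    for condition in CONDITIONS:
        state, diet = condition
        for sex, chrom in GENOTYPES:
            lib = f"{chrom}{sex}_{state}_{diet}"
            barcode = TRUSEQ_INDEXES[idx % len(TRUSEQ_INDEXES)]
            idx += 1
            expr = _library_expression(
                baseline, masks, diet_signs, config, sex, chrom, condition
            )
            reads, counts, n_err = generate_library(
                synref, expr, config, rng, lib, barcode
            )
            libraries[lib] = reads
            expected[lib] = expr / expr.sum()
            truth_counts[lib] = counts
            error_reads[lib] = n_err
            rows.append(
                {
                    "library": lib,
                    "gonadal_sex": sex,
                    "chromosomes": chrom,
                    "gonadal_state": state,
                    "diet": diet,
                    "barcode": barcode,
                }
            )
    design = pd.DataFrame(rows)
    planted: dict[str, dict[tuple[str, str], int]] = {"F_vs_M": {}, "XX_vs_XY": {}}
    for condition in CONDITIONS:
        sex_delta, chrom_delta = _effect_sizes(config, condition)
        # effect applied to M (resp. XY): positive delta biases the profile
        # toward the denominator group, so the planted F/M direction is -sign
        planted["F_vs_M"][condition] = -int(np.sign(sex_delta))
        planted["XX_vs_XY"][condition] = -int(np.sign(chrom_delta))
    truth = ExperimentTruth(
        expected_expression=pd.DataFrame(expected, index=names),
        truth_counts=pd.DataFrame(truth_counts, index=names),
        planted_directions=planted,
        affected={k: [names[i] for i in np.flatnonzero(v)] for k, v in masks.items()},
        error_reads=error_reads,
    )
    exp = SimulatedExperiment(
        reference=synref, design=design, libraries=libraries, truth=truth, config=config
    )
    if out_dir is not None:
        write_experiment(exp, out_dir)
    return exp


def generate_pooling_study(
    config: GeneratorConfig | None = None,
    n_replicates: int = 3,
    replicate_sigma: float = 0.3,
) -> tuple[dict[str, list[RawRead]], list[RawRead], SyntheticReference]:
    """Individual replicate libraries plus their pooled counterpart.

    Emulates the pooling-feasibility check: ``n_replicates`` biological
    replicates of one genotype (XX females on high fat diet) are sequenced
    individually, and a pooled library is drawn from the mean of their
    expression profiles at matched depth.  Per-replicate biology is a
    log-normal jitter of the shared baseline.
    """
    config = config or GeneratorConfig()
    config.validate()
    synref = generate_reference(config)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31) + 2)
    baseline, masks, diet_signs = _baseline_and_masks(synref, config, rng)
    condition = ("GDX", "HFD")
    base_expr = _library_expression(
        baseline, masks, diet_signs, config, "F", "XX", condition
    )
    individuals: dict[str, list[RawRead]] = {}
    profiles = []
    for i in range(n_replicates):
        jitter = rng.lognormal(mean=0.0, sigma=replicate_sigma, size=base_expr.size)
        expr = base_expr * jitter
        profiles.append(expr / expr.sum())
        lib = f"XXF_HFD_rep{i + 1}"
        reads, _, _ = generate_library(synref, expr, config, rng, lib)
        individuals[lib] = reads
    pooled_expr = np.mean(profiles, axis=0)
    pooled_reads, _, _ = generate_library(synref, pooled_expr, config, rng, "XXF_HFD_pool")
    return individuals, pooled_reads, synref


# ---------------------------------------------------------------------------
# on-disk form


def write_experiment(
    exp: SimulatedExperiment, out_dir: str | Path, read_format: str = "fastq"
) -> None:
    """Write mature.fa, hairpin.fa, per-library reads, design.tsv, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exp.reference.write_fasta(out / "mature.fa", out / "hairpin.fa")
    writer = {"fastq": (write_fastq, ".fastq"), "qseq": (write_qseq, ".qseq")}
    if read_format not in writer:
        raise ValueError(f"unknown read format {read_format!r}")
    write_fn, ext = writer[read_format]
    design = exp.design.copy()
    paths = []
    for lib in design["library"]:
        path = out / f"{lib}{ext}"
        write_fn(exp.libraries[lib], path)
        paths.append(path.name)
    design["path"] = paths
    design.to_csv(out / "design.tsv", sep="\t", index=False)
    truth = {
        "planted_directions": {
            contrast: {"/".join(cond): int(d) for cond, d in dirs.items()}
            for contrast, dirs in exp.truth.planted_directions.items()
        },
        "families": {k: list(v) for k, v in exp.reference.families.items()},
        "nested_pairs": [list(p) for p in exp.reference.nested],
        "truth_counts": {
            lib: exp.truth.truth_counts[lib].to_dict() for lib in exp.truth.truth_counts
        },
        "expected_expression": {
            lib: exp.truth.expected_expression[lib].round(10).to_dict()
            for lib in exp.truth.expected_expression
        },
        "affected": exp.truth.affected,
        "error_reads": exp.truth.error_reads,
        "config": {
            k: v
            for k, v in asdict(exp.config).items()
            if k != "condition_effects"
        },
        "condition_effects": {
            "/".join(cond): eff for cond, eff in exp.config.condition_effects.items()
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_multiplexed_qseq(exp: SimulatedExperiment, path: str | Path) -> None:
    """Write all libraries' reads into one barcoded qseq stream."""
    def _all_reads():
        for lib in exp.design["library"]:
            yield from exp.libraries[lib]

    write_qseq(_all_reads(), path)
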