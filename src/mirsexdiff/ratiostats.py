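"""Four Core Genotypes group-ratio statistics.

The FCG design decouples gonadal sex (F/M, via the Sry transgene) from the
sex chromosome complement (XX/XY).  For one physiological condition
(gonadal state x diet) each contrast averages the two libraries on each
side — e.g. "female" = mean(XX-F, XY-F) CPM — and the per-miRNA log2 ratio
of those group means is the unit of analysis.  With one pooled library per
genotype cell there is no power for per-miRNA testing; instead each miRNA
is treated as an independent contributor to the profile, and the tests are
distribution-level: an exact binomial test on the sign split of the ratios
within a condition, a Wilcoxon rank-sum test between conditions, and PCA
across libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.decomposition import PCA

from .quantify import AbundanceTable

__all__ = [
    "CONTRASTS",
    "RatioProfile",
    "SignBiasResult",
    "load_design",
    "validate_fcg_design",
    "group_log2_ratio",
    "bin_ratios",
    "sign_bias_test",
    "compare_conditions",
    "median_ratio",
    "pca_libraries",
]

#: contrast name -> (design column, numerator level, denominator level)
CONTRASTS: dict[str, tuple[str, str, str]] = {
    "F_vs_M": ("gonadal_sex", "F", "M"),
    "XX_vs_XY": ("chromosomes", "XX", "XY"),
}

_DESIGN_COLUMNS = ["library", "gonadal_sex", "chromosomes", "gonadal_state", "diet"]
_LEVELS = {
    "gonadal_sex": {"F", "M"},
    "chromosomes": {"XX", "XY"},
    "gonadal_state": {"intact", "GDX"},
    "diet": {"chow", "HFD"},
}


def load_design(path: str | Path) -> pd.DataFrame:
    """Read and validate a design sheet TSV."""
    design = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design sheet missing columns: {missing}")
    for col, levels in _LEVELS.items():
        bad = set(design[col]) - levels
        if bad:
            raise ValueError(f"design column {col!r} has invalid values {sorted(bad)}")
    if design["library"].duplicated().any():
        raise ValueError("duplicate library labels in design sheet")
    return design


def validate_fcg_design(design: pd.DataFrame) -> None:
    """Check the 12-library layout: one library per genotype x condition cell."""
    cells = design.groupby(["gonadal_sex", "chromosomes", "gonadal_state", "diet"]).size()
    if (cells > 1).any():
        raise ValueError("more than one library in a genotype/condition cell")


@dataclass
class RatioProfile:
    """Per-miRNA log2 group ratios for one contrast under one condition."""

    contrast: str
    condition: tuple[str, str]  # (gonadal_state, diet)
    log2_ratios: pd.Series
    pseudocount_flagged: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.log2_ratios)


def group_log2_ratio(
    abundance: AbundanceTable | pd.DataFrame,
    design: pd.DataFrame,
    contrast: str,
    condition: tuple[str, str],
    targets: Sequence[str] | None = None,
    pseudocount: float = 0.5,
) -> RatioProfile:
    """log2 ratio of genotype-group mean CPM for one contrast and condition.

    The numerator is the arithmetic mean of the two numerator-group
    libraries' CPM, likewise the denominator.  miRNAs where either group
    mean is zero get ``pseudocount`` CPM added to both means and are flagged.
    """
    cpm = abundance.cpm if isinstance(abundance, AbundanceTable) else abundance
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {list(CONTRASTS)}")
    column, num_level, den_level = CONTRASTS[contrast]
    state, diet = condition
    cond = design[(design["gonadal_state"] == state) & (design["diet"] == diet)]
    for sex in ("F", "M"):
        for chrom in ("XX", "XY"):
            cell = cond[(cond["gonadal_sex"] == sex) & (cond["chromosomes"] == chrom)]
            if len(cell) == 0:
                raise ValueError(
                    f"condition {condition} is missing the {chrom}{sex} genotype library"
                )
    num_libs = cond.loc[cond[column] == num_level, "library"].tolist()
    den_libs = cond.loc[cond[column] == den_level, "library"].tolist()
    sub = cpm.loc[list(targets)] if targets is not None else cpm
    num = sub[num_libs].mean(axis=1)
    den = sub[den_libs].mean(axis=1)
    zero = (num == 0) | (den == 0)
    flagged = list(sub.index[zero])
    num = num.where(~zero, num + pseudocount)
    den = den.where(~zero, den + pseudocount)
    ratios = np.log2(num / den)
    ratios.name = f"log2_{contrast}"
    return RatioProfile(
        contrast=contrast, condition=condition, log2_ratios=ratios, pseudocount_flagged=flagged
    )


def bin_ratios(
    profile: RatioProfile | Sequence[float], width: float = 0.5, clamp: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of log2 ratios in ``width`` increments over [-clamp, clamp].

    Bins are half-open ``[a, a+width)``; values below -clamp fall into the
    first bin and values of clamp or above into the last.  Returns
    (edges, counts) with ``len(edges) == len(counts) + 1``.
    """
    values = (
        profile.log2_ratios.to_numpy() if isinstance(profile, RatioProfile) else np.asarray(profile, dtype=float)
    )
    n_bins = int(round(2 * clamp / width))
    edges = -clamp + width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    if values.size:
        idx = np.floor((values + clamp) / width).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        np.add.at(counts, idx, 1)
    return edges, counts


@dataclass(frozen=True)
class SignBiasResult:
    n_positive: int
    n_negative: int
    p_value: float
    direction: int  # +1 numerator-biased, -1 denominator-biased, 0 tie


def sign_bias_test(profile: RatioProfile | Sequence[float]) -> SignBiasResult:
    """Exact two-sided binomial test of positive vs negative log2 ratios.

    Ratios exactly zero are excluded.  The p-value depends only on the sign
    split, so it is invariant under any monotone rescaling of the ratios.
    """
    values = (
        profile.log2_ratios.to_numpy() if isinstance(profile, RatioProfile) else np.asarray(profile, dtype=float)
    )
    n_pos = int((values > 0).sum())
    n_neg = int((values < 0).sum())
    if n_pos + n_neg == 0:
        raise ValueError("sign bias undefined: all ratios are exactly zero")
    res = _stats.binomtest(n_pos, n_pos + n_neg, 0.5, alternative="two-sided")
    direction = 0 if n_pos == n_neg else (1 if n_pos > n_neg else -1)
    return SignBiasResult(n_pos, n_neg, float(res.pvalue), direction)


def compare_conditions(
    profile_a: RatioProfile | Sequence[float], profile_b: RatioProfile | Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum p-value for a shift between two profiles.

    Exact when both samples have at most 20 untied observations; otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    a = (
        profile_a.log2_ratios.to_numpy()
        if isinstance(profile_a, RatioProfile)
        else np.asarray(profile_a, dtype=float)
    )
    b = (
        profile_b.log2_ratios.to_numpy()
        if isinstance(profile_b, RatioProfile)
        else np.asarray(profile_b, dtype=float)
    )
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot compare empty ratio profiles")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) else "asymptotic"
    res = _stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def median_ratio(profile: RatioProfile | Sequence[float]) -> float:
    """Sample median of the log2 ratios (mean of the central pair for even n)."""
    values = (
        profile.log2_ratios.to_numpy() if isinstance(profile, RatioProfile) else np.asarray(profile, dtype=float)
    )
    if values.size == 0:
        raise ValueError("median undefined for an empty profile")
    return float(np.median(values))


def pca_libraries(
    abundance: AbundanceTable | pd.DataFrame,
    targets: Sequence[str] | None = None,
    transform: str = "log2cpm1",
    n_components: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA with libraries as observations and miRNAs as features.

    ``transform`` is ``log2cpm1`` (log2(CPM+1), the default) or ``cpm``;
    features are mean-centered, not variance-scaled.  Component signs follow
    a deterministic convention: the loading of largest magnitude is positive.
    Returns (scores: libraries x components, variance fractions summing to 1).
    """
    cpm = abundance.cpm if isinstance(abundance, AbundanceTable) else abundance
    sub = cpm.loc[list(targets)] if targets is not None else cpm
    if sub.shape[1] < 3:
        raise ValueError("PCA needs at least three libraries")
    if n_components is not None and n_components > sub.shape[1]:
        raise ValueError("more components requested than libraries available")
    if transform == "log2cpm1":
        X = np.log2(sub.to_numpy(dtype=float).T + 1.0)
    elif transform == "cpm":
        X = sub.to_numpy(dtype=float).T
    else:
        raise ValueError(f"unknown transform {transform!r}")
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(X)
    # deterministic sign: flip components whose largest-|loading| is negative
    for j in range(scores.shape[1]):
        loadings = pca.components_[j]
        lead = np.argmax(np.abs(loadings))
        if loadings[lead] < 0:
            scores[:, j] = -scores[:, j]
            pca.components_[j] = -loadings
    frac = pca.explained_variance_ratio_
    k = scores.shape[1] if n_components is None else n_components
    score_df = pd.DataFrame(
        scores[:, :k],
        index=sub.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return score_df, frac
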