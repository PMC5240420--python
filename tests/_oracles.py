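"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: alignment is a full scan
over every target and offset, and the rank-sum p-value is an exhaustive
enumeration over rank assignments.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_hits(read: str, targets: list[tuple[str, str]], max_mm: int = 1):
    """Every (target_name, offset, mismatches) with Hamming distance <= max_mm.

    A position where either base is N counts as a mismatch; the read must be
    fully contained in the target; no gaps.
    """
    out = []
    L = len(read)
    for name, tseq in targets:
        for off in range(len(tseq) - L + 1):
            mm = 0
            for i in range(L):
                a, b = read[i], tseq[off + i]
                if a != b or a == "N" or b == "N":
                    mm += 1
            if mm <= max_mm:
                out.append((name, off, mm))
    return sorted(out)


def exhaustive_ranksum_p(a, b) -> float:
    """Two-sided rank-sum p by enumerating all assignments of ranks to group a.

    Valid for untied samples; the p-value is the fraction of rank subsets
    whose rank-sum deviates from its mean at least as much as the observed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    assert len(np.unique(pooled)) == len(pooled), "oracle requires untied data"
    ranks = pooled.argsort().argsort() + 1
    obs = ranks[: len(a)].sum()
    n, m = len(a), len(b)
    mean = n * (n + m + 1) / 2
    dev = abs(obs - mean)
    count = 0
    total = 0
    for subset in combinations(range(1, n + m + 1), n):
        total += 1
        if abs(sum(subset) - mean) >= dev - 1e-9:
            count += 1
    return count / total
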