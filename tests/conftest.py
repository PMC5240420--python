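import numpy as np
import pytest

from mirsexdiff.reference import (
    MatureRecord,
    NestedPair,
    PrecursorRecord,
    Reference,
    ReferenceTarget,
    build_reference,
)


@pytest.fixture
def toy_records():
    """Three genes: two sharing a mature sequence, plus a nested pair."""
    matures = [
        MatureRecord("syn-miR-0001-3p", "TGAGGTAGTAGGTTGTAT"),
        MatureRecord("syn-miR-0002-3p", "TGAGGTAGTAGGTTGTAT"),  # family twin
        MatureRecord("syn-miR-0003-3p", "CCCTGAGACCCTTTAACC"),
        MatureRecord("syn-miR-0004-3p", "ACCCGTAGATCCGAACTT"),   # nested short
        MatureRecord("syn-miR-0005-3p", "ACCCGTAGATCCGAACTTG"),  # nested long
    ]
    precursors = [
        PrecursorRecord("syn-mir-0001", "AACCTGAGGTAGTAGGTTGTATAGTTTT", ["syn-miR-0001-3p"]),
        PrecursorRecord("syn-mir-0002", "GGGTGAGGTAGTAGGTTGTATCCAA", ["syn-miR-0002-3p"]),
        PrecursorRecord("syn-mir-0003", "TTCCCTGAGACCCTTTAACCGGAA", ["syn-miR-0003-3p"]),
        PrecursorRecord("syn-mir-0004", "ATACCCGTAGATCCGAACTTCGTA", ["syn-miR-0004-3p"]),
        PrecursorRecord("syn-mir-0005", "GGACCCGTAGATCCGAACTTGCAT", ["syn-miR-0005-3p"]),
    ]
    return matures, precursors


@pytest.fixture
def toy_reference(toy_records) -> Reference:
    matures, precursors = toy_records
    return build_reference(matures, precursors)


@pytest.fixture
def two_target_reference() -> Reference:
    """A minimal reference: two unrelated matures and one masked precursor."""
    targets = [
        ReferenceTarget("mirA", "TGAGGTAGTAGGTTGTATAGTT", "mature", ("mirA",)),
        ReferenceTarget("mirB", "CCCTGAGACCCTTTAACCGGTA", "mature", ("mirB",)),
        ReferenceTarget(
            "hairpinA", "AACC" + "N" * 22 + "GGTTCCAGCATTAA", "precursor", ("hairpinA",)
        ),
    ]
    return Reference(targets=targets, nested_pairs=[])


@pytest.fixture
def rng():
    return np.random.default_rng(20170117)
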