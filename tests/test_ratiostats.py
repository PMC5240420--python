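"""Group ratios, binning, sign-bias and rank-sum tests, library PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirsexdiff.ratiostats import (
    RatioProfile,
    bin_ratios,
    compare_conditions,
    group_log2_ratio,
    load_design,
    median_ratio,
    pca_libraries,
    sign_bias_test,
    validate_fcg_design,
)

from _oracles import exhaustive_ranksum_p


def _design():
    rows = []
    for state, diet in [("intact", "chow"), ("GDX", "chow"), ("GDX", "HFD")]:
        for sex in "FM":
            for chrom in ("XX", "XY"):
                rows.append(
                    {
                        "library": f"{chrom}{sex}_{state}_{diet}",
                        "gonadal_sex": sex,
                        "chromosomes": chrom,
                        "gonadal_state": state,
                        "diet": diet,
                    }
                )
    return pd.DataFrame(rows)


def _cpm(values_by_genotype, condition=("intact", "chow"), targets=("m1",)):
    state, diet = condition
    data = {}
    for chrom_sex, vals in values_by_genotype.items():
        data[f"{chrom_sex}_{state}_{diet}"] = vals
    return pd.DataFrame(data, index=list(targets), dtype=float)


class TestGroupRatio:
    def test_female_double_male_gives_one(self):
        cpm = _cpm({"XXF": [2.0], "XYF": [2.0], "XXM": [1.0], "XYM": [1.0]})
        profile = group_log2_ratio(cpm, _design(), "F_vs_M", ("intact", "chow"))
        assert profile.log2_ratios.iloc[0] == pytest.approx(1.0)

    def test_all_equal_gives_zero(self):
        cpm = _cpm({"XXF": [3.0], "XYF": [3.0], "XXM": [3.0], "XYM": [3.0]})
        profile = group_log2_ratio(cpm, _design(), "F_vs_M", ("intact", "chow"))
        assert profile.log2_ratios.iloc[0] == 0.0

    def test_chromosome_contrast(self):
        cpm = _cpm({"XXF": [4.0], "XXM": [4.0], "XYF": [1.0], "XYM": [1.0]})
        profile = group_log2_ratio(cpm, _design(), "XX_vs_XY", ("intact", "chow"))
        assert profile.log2_ratios.iloc[0] == pytest.approx(2.0)

    def test_zero_denominator_uses_pseudocount_and_flags(self):
        cpm = _cpm({"XXF": [2.0], "XYF": [2.0], "XXM": [0.0], "XYM": [0.0]})
        profile = group_log2_ratio(cpm, _design(), "F_vs_M", ("intact", "chow"))
        assert profile.pseudocount_flagged == ["m1"]
        assert profile.log2_ratios.iloc[0] == pytest.approx(np.log2(2.5 / 0.5))

    def test_missing_genotype_rejected(self):
        design = _design()
        design = design[design["library"] != "XYM_intact_chow"]
        cpm = _cpm({"XXF": [1.0], "XYF": [1.0], "XXM": [1.0], "XYM": [1.0]})
        with pytest.raises(ValueError, match="missing the XYM"):
            group_log2_ratio(cpm, design, "F_vs_M", ("intact", "chow"))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(*[st.floats(0.5, 1e4) for _ in range(4)]), min_size=1, max_size=20
        )
    )
    def test_antisymmetry_under_group_swap(self, rows):
        targets = [f"m{i}" for i in range(len(rows))]
        vals = np.array(rows)
        cpm = _cpm(
            {"XXF": vals[:, 0], "XYF": vals[:, 1], "XXM": vals[:, 2], "XYM": vals[:, 3]},
            targets=targets,
        )
        design = _design()
        fm = group_log2_ratio(cpm, design, "F_vs_M", ("intact", "chow")).log2_ratios
        # swapping the groups == relabeling gonadal sex in the design
        swapped = design.replace({"gonadal_sex": {"F": "M", "M": "F"}})
        mf = group_log2_ratio(cpm, swapped, "F_vs_M", ("intact", "chow")).log2_ratios
        assert np.allclose(fm.values, -mf.values)


class TestBinning:
    def test_extreme_values_clamped_into_terminal_bins(self):
        edges, counts = bin_ratios([-5.2, 4.7])
        assert counts[0] == 1 and counts[-1] == 1
        assert len(counts) == 16
        assert edges[0] == -4.0 and edges[-1] == 4.0

    def test_half_open_convention(self):
        edges, counts = bin_ratios([0.3])
        idx = np.flatnonzero(counts)[0]
        assert (edges[idx], edges[idx + 1]) == (0.0, 0.5)
        # 0.5 itself belongs to the next bin
        _, counts2 = bin_ratios([0.5])
        assert np.flatnonzero(counts2)[0] == idx + 1

    def test_empty_profile_all_zero(self):
        _, counts = bin_ratios([])
        assert counts.sum() == 0

    def test_counts_sum_to_profile_length(self, rng):
        values = rng.normal(0, 3, 500)
        _, counts = bin_ratios(values)
        assert counts.sum() == 500


class TestSignBias:
    def test_ten_of_ten_closed_form(self):
        res = sign_bias_test([0.1] * 10)
        assert res.p_value == pytest.approx(2 * 0.5**10)
        assert res.n_positive == 10 and res.direction == 1

    def test_balanced_split_p_one(self):
        res = sign_bias_test([1, 1, 1, 1, 1, -1, -1, -1, -1, -1])
        assert res.p_value == 1.0 and res.direction == 0

    def test_zeros_excluded(self):
        res = sign_bias_test([0.0, 0.0, 2.0, 3.0])
        assert res.n_positive == 2 and res.n_negative == 0
        assert res.p_value == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sign_bias_test([0.0, 0.0])

    def test_invariant_under_monotone_rescaling(self, rng):
        values = rng.normal(0.2, 1.0, 101)
        a = sign_bias_test(values)
        b = sign_bias_test(np.sinh(values) * 7)
        assert a.p_value == b.p_value and a.direction == b.direction

    def test_one_sided_monotone_in_positives(self):
        from scipy.stats import binomtest

        n = 40
        ps = [
            binomtest(k, n, 0.5, alternative="greater").pvalue for k in range(20, 41)
        ]
        assert all(x > y for x, y in zip(ps, ps[1:]))


class TestCompareConditions:
    def test_identical_samples_p_one(self):
        p = compare_conditions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 20.0, 30.0]
        assert compare_conditions(a, b) == pytest.approx(exhaustive_ranksum_p(a, b))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        a=st.lists(st.integers(0, 10_000), min_size=2, max_size=8, unique=True),
        b=st.lists(st.integers(10_001, 20_000), min_size=2, max_size=8, unique=True),
    )
    def test_exact_equals_permutation_oracle(self, a, b):
        # irrational scaling interleaves the samples without creating ties
        a = [x * np.sqrt(2.0) for x in a]
        b = [float(x) * 0.25 for x in b]
        assert compare_conditions(a, b) == pytest.approx(exhaustive_ranksum_p(a, b))

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([], [1.0])

    def test_shift_detected_at_study_scale(self, rng):
        a = rng.normal(0.0, 1.0, 183)
        b = rng.normal(0.5, 1.0, 183)
        assert compare_conditions(a, b) < 0.05


class TestMedian:
    def test_odd_n(self):
        assert median_ratio([-1.0, 0.0, 1.0]) == 0.0

    def test_even_n_mean_of_central_pair(self):
        assert median_ratio([1.0, 2.0, 3.0, 4.0]) == 2.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_ratio([])


class TestPCA:
    def _cpm12(self, rng):
        design = _design()
        data = rng.lognormal(3, 1, size=(40, 12))
        return pd.DataFrame(data, index=[f"m{i}" for i in range(40)], columns=design["library"]), design

    def test_duplicate_libraries_put_all_variance_on_pc1(self):
        base = np.array([100.0, 300.0, 600.0])
        cpm = pd.DataFrame(
            {"lib1": base, "lib2": base, "lib3": base * 4},
            index=["a", "b", "c"],
        )
        scores, frac = pca_libraries(cpm)
        assert frac[0] == pytest.approx(1.0, abs=1e-9)
        assert scores.loc["lib1", "PC1"] == pytest.approx(scores.loc["lib2", "PC1"])

    def test_variance_fractions_sum_to_one(self, rng):
        cpm, _ = self._cpm12(rng)
        _, frac = pca_libraries(cpm)
        assert frac.sum() == pytest.approx(1.0)

    def test_deterministic_sign_convention(self, rng):
        cpm, _ = self._cpm12(rng)
        s1, _ = pca_libraries(cpm)
        s2, _ = pca_libraries(cpm.copy())
        pd.testing.assert_frame_equal(s1, s2)

    def test_too_few_libraries_rejected(self):
        cpm = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError, match="three"):
            pca_libraries(cpm)

    def test_too_many_components_rejected(self, rng):
        cpm, _ = self._cpm12(rng)
        with pytest.raises(ValueError, match="components"):
            pca_libraries(cpm, n_components=13)


class TestDesignSheet:
    def test_load_and_validate(self, tmp_path):
        path = tmp_path / "design.tsv"
        _design().to_csv(path, sep="\t", index=False)
        design = load_design(path)
        validate_fcg_design(design)
        assert len(design) == 12

    def test_invalid_level_rejected(self, tmp_path):
        df = _design()
        df.loc[0, "diet"] = "keto"
        path = tmp_path / "design.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="diet"):
            load_design(path)
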