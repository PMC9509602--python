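"""Paired Wilcoxon, LDA effect sizes and Spearman correlation contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import wilcoxon_exact_oracle
from urotag import synthdata
from urotag.diffabund import (
    UndefinedTestError,
    differential_table,
    lda_effect_size,
    paired_wilcoxon,
    spearman_matrix,
)


class TestPairedWilcoxon:
    def test_six_positive_differences_exact_p(self):
        x = np.arange(1.0, 7.0)
        _, p = paired_wilcoxon(x + 1.0, x)
        assert p == pytest.approx(2 / 64)

    def test_all_zero_differences_undefined(self):
        with pytest.raises(UndefinedTestError):
            paired_wilcoxon([1.0, 2.0], [1.0, 2.0])

    def test_swap_symmetry(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        _, p_xy = paired_wilcoxon(x, y)
        _, p_yx = paired_wilcoxon(y, x)
        assert p_xy == pytest.approx(p_yx)

    @given(st.integers(0, 10_000), st.integers(4, 10))
    @settings(max_examples=60, deadline=None)
    def test_matches_exact_enumeration_small_n(self, seed, n):
        """Implementation equals the brute-force sign-enumeration null for n <= 10."""
        r = np.random.default_rng(seed)
        d = r.normal(size=n)
        while len(np.unique(np.abs(d))) < n or (d == 0).any():
            d = r.normal(size=n)
        _, p = paired_wilcoxon(d, np.zeros(n))
        assert p == pytest.approx(wilcoxon_exact_oracle(d), abs=1e-12)

    def test_zero_differences_dropped(self):
        # pairs with zero difference do not contribute
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = x.copy()
        y[:6] -= 1.0  # six informative pairs, one zero
        _, p = paired_wilcoxon(x, y)
        assert p == pytest.approx(2 / 64)


class TestDifferentialTable:
    @pytest.fixture
    def planted_design(self):
        species = [f"s{i:02d}" for i in range(20)]
        return synthdata.make_paired_design(
            species, n_subjects=30, effects={"s05": 8.0}, sample_sd=0.5, seed=21
        )

    def test_planted_species_flagged_with_direction(self, planted_design):
        table = differential_table(
            {"species": planted_design.abundances}, planted_design
        )
        row = table[table["taxon"] == "s05"].iloc[0]
        assert row["significant"] and row["direction"] == "stone"
        assert row["p_value"] < 0.05

    def test_taxon_present_in_one_sample_still_tested(self, planted_design):
        mat = planted_design.abundances.copy()
        extra = pd.Series(0.0, index=mat.columns, name="rare")
        extra.iloc[0] = 1e-4
        mat = pd.concat([mat, extra.to_frame().T])
        table = differential_table({"species": mat}, planted_design)
        assert "rare" in set(table["taxon"])

    def test_incomplete_pair_names_subject(self, planted_design):
        broken = synthdata.PairedDesign(
            planted_design.samples.iloc[:-1], planted_design.abundances, {}
        )
        with pytest.raises(ValueError, match="subj"):
            differential_table({"species": planted_design.abundances}, broken)

    def test_null_calibration_near_alpha(self):
        """Type-I error of the table is close to alpha on a null design."""
        rng = np.random.default_rng(77)
        n_features, n_subjects = 1000, 30
        species = [f"f{i}" for i in range(n_features)]
        design = synthdata.make_paired_design(species, n_subjects=n_subjects, seed=1,
                                              sample_sd=0.0)
        # independent per-sample noise, no side effect: the exact null
        mat = pd.DataFrame(
            rng.lognormal(0, 1, size=(n_features, 2 * n_subjects)),
            index=species, columns=design.sample_ids(),
        )
        mat = mat / mat.sum(axis=0)
        table = differential_table({"species": mat}, design, alpha=0.05)
        rate = table["significant"].mean()
        se = np.sqrt(0.05 * 0.95 / n_features)
        assert abs(rate - 0.05) < 2.5 * se


class TestLdaEffectSize:
    @pytest.fixture
    def labels(self):
        return ["stone"] * 10 + ["non_stone"] * 10

    def test_identical_feature_never_reported(self, labels, rng):
        mat = pd.DataFrame(
            {
                "flat": np.ones(20) * 0.5,
                "noise": rng.uniform(0.4, 0.6, 20),
            }
        ).T
        mat.columns = [f"s{i}" for i in range(20)]
        res = lda_effect_size(mat, labels, seed=0)
        assert "flat" not in set(res["taxon"])

    def test_non_overlapping_supports_strongly_scored(self, labels, rng):
        low = rng.uniform(0.5e-5, 1.5e-5, 10)
        high = rng.uniform(0.09, 0.11, 10)
        mat = pd.DataFrame(
            {
                "marker": np.concatenate([high, low]),
                "filler": 1 - np.concatenate([high, low]),
            }
        ).T
        mat.columns = [f"s{i}" for i in range(20)]
        res = lda_effect_size(mat, labels, seed=1)
        row = res[res["taxon"] == "marker"].iloc[0]
        assert abs(row["lda_score"]) >= 2.0
        # the marker is high in the first ten samples, which carry the stone label
        assert row["enriched_group"] == "stone"

    def test_threshold_monotone(self, labels, rng):
        mat = pd.DataFrame(
            rng.lognormal(0, 1, size=(30, 20)),
            index=[f"t{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(20)],
        )
        mat.iloc[0, :10] *= 50
        mat = mat / mat.sum(axis=0)
        reported = {
            thr: set(lda_effect_size(mat, labels, lda_threshold=thr, seed=2)["taxon"])
            for thr in (1.0, 2.0, 3.0)
        }
        assert reported[3.0] <= reported[2.0] <= reported[1.0]

    def test_reported_respect_both_gates(self, labels, rng):
        mat = pd.DataFrame(
            rng.lognormal(0, 1, size=(20, 20)),
            index=[f"t{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(20)],
        )
        mat.iloc[0, :10] *= 30
        mat = mat / mat.sum(axis=0)
        res = lda_effect_size(mat, labels, seed=3)
        assert (res["kw_p"] < 0.05).all()
        assert (res["lda_score"].abs() >= 2.0).all()

    def test_null_reported_count_bounded(self, labels):
        rng = np.random.default_rng(8)
        n_features = 200
        mat = pd.DataFrame(
            rng.lognormal(0, 1, size=(n_features, 20)),
            index=[f"t{i}" for i in range(n_features)],
            columns=[f"s{i}" for i in range(20)],
        )
        mat = mat / mat.sum(axis=0)
        res = lda_effect_size(mat, labels, seed=9)
        # stage-1 false positives bound the report under the null
        assert len(res) <= 0.05 * n_features + 3 * np.sqrt(n_features * 0.05 * 0.95)

    def test_small_class_rejected(self, rng):
        mat = pd.DataFrame(rng.random((5, 5)), columns=[f"s{i}" for i in range(5)])
        with pytest.raises(ValueError):
            lda_effect_size(mat, ["a", "a", "b", "b", "b"])


class TestSpearman:
    def test_monotone_pair_rho_one(self):
        mat = pd.DataFrame(
            {"s1": [1, 2.0], "s2": [2, 4.0], "s3": [3, 9.0]}, index=["x", "y"]
        )
        res = spearman_matrix(mat, top_n=2)
        assert res.rho.loc["x", "y"] == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        mat = pd.DataFrame(
            {"s1": [1, 3.0], "s2": [2, 2.0], "s3": [3, 1.0]}, index=["x", "y"]
        )
        assert spearman_matrix(mat, top_n=2).rho.loc["x", "y"] == pytest.approx(-1.0)

    def test_hand_example_rho(self):
        mat = pd.DataFrame(
            {f"s{i}": [x, y] for i, (x, y) in enumerate(zip([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]))},
            index=["x", "y"],
        ).astype(float)
        assert spearman_matrix(mat, top_n=2).rho.loc["x", "y"] == pytest.approx(0.8)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=8)
        y = r.normal(size=8)
        mat1 = pd.DataFrame([x, y], index=["x", "y"],
                            columns=[f"s{i}" for i in range(8)])
        mat2 = pd.DataFrame([np.exp(x), y**3 + 5 * y], index=["x", "y"],
                            columns=[f"s{i}" for i in range(8)])
        r1 = spearman_matrix(mat1, top_n=2).rho.loc["x", "y"]
        r2 = spearman_matrix(mat2, top_n=2).rho.loc["x", "y"]
        assert r1 == pytest.approx(r2)

    def test_constant_taxon_missing(self):
        mat = pd.DataFrame(
            {"s1": [1.0, 0.2], "s2": [1.0, 0.4], "s3": [1.0, 0.3]}, index=["c", "v"]
        )
        res = spearman_matrix(mat, top_n=2)
        assert np.isnan(res.rho.loc["c", "v"])

    def test_top_n_selection(self, rng):
        mat = pd.DataFrame(
            rng.random((10, 5)), index=[f"t{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(5)],
        )
        res = spearman_matrix(mat, top_n=4)
        assert len(res.taxa) == 4
        means = mat.mean(axis=1)
        assert set(res.taxa) == set(means.nlargest(4).index)
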