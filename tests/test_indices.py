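"""Facet-index computations against brute-force and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from facet2function.indices import (
    biomass_summary,
    diversity_indices,
    gene_scores,
    pielou,
    rarefy,
    shannon,
    sir_efficiency,
    sir_range,
    soil_stoichiometry,
    substrate_sensitivity,
)

positive_vectors = st.lists(
    st.floats(min_value=0.01, max_value=1e4), min_size=2, max_size=30
)


class TestDiversity:
    def test_uniform_community(self):
        counts = pd.DataFrame({"s": [5] * 8}, index=[f"t{i}" for i in range(8)])
        out = diversity_indices(counts).loc["s"]
        assert out.H == pytest.approx(np.log(8), abs=1e-12)
        assert out.J == pytest.approx(1.0, abs=1e-12)
        assert out.S == 8
        assert out.G == pytest.approx(1 / 8, abs=1e-12)

    def test_monodominant_community(self):
        counts = pd.DataFrame({"s": [7, 0, 0]}, index=list("abc"))
        out = diversity_indices(counts).loc["s"]
        assert out.H == 0.0 and out.J == 0.0 and out.S == 1 and out.G == 1.0

    def test_shannon_matches_direct_summation(self):
        counts = np.array([5, 3, 2])
        p = counts / counts.sum()
        expected = -(p * np.log(p)).sum()
        assert shannon(counts) == pytest.approx(expected, abs=1e-12)
        table = pd.DataFrame({"s": counts})
        assert diversity_indices(table).loc["s", "H"] == pytest.approx(
            expected, abs=1e-12
        )

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            diversity_indices(pd.DataFrame({"s": [0, 0]}))

    @given(positive_vectors)
    def test_pielou_bounds(self, vec):
        j = pielou(np.array(vec))
        assert -1e-12 <= j <= 1 + 1e-12

    def test_skbio_cross_check(self, rng):
        """Shannon agrees with the independent scikit-bio implementation."""
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        counts = rng.integers(0, 50, size=20)
        counts[0] = 3  # ensure non-empty
        ours = shannon(counts)
        theirs = float(skbio_alpha.shannon(counts, base=np.e))
        assert ours == pytest.approx(theirs, abs=1e-10)


class TestRarefy:
    def test_identity_when_total_equals_depth(self, toy_counts):
        out = rarefy(toy_counts[["s2"]], depth=20, seed=0)
        pd.testing.assert_frame_equal(out, toy_counts[["s2"]].astype(np.int64))

    def test_single_taxon_forced(self):
        counts = pd.DataFrame({"s": [50]}, index=["t"])
        out = rarefy(counts, depth=10, seed=0)
        assert out.loc["t", "s"] == 10

    def test_sums_exactly_depth(self, toy_counts):
        out = rarefy(toy_counts, depth=5, seed=1)
        assert (out.sum(axis=0) == 5).all()

    def test_hypergeometric_mean(self):
        """Expected retained count of taxon 1 in (6,3,1) at depth 5 is 3.0."""
        counts = pd.DataFrame({"s": [6, 3, 1]})
        rng = np.random.default_rng(2024)
        draws = np.array(
            [rarefy(counts, depth=5, seed=rng)["s"].iloc[0] for _ in range(100_000)]
        )
        assert draws.mean() == pytest.approx(3.0, abs=0.02)

    def test_small_samples_dropped_with_warning(self, toy_counts, caplog):
        out = rarefy(toy_counts, depth=15, seed=0)
        assert list(out.columns) == ["s2"]
        with pytest.raises(ValueError, match="below rarefaction depth"):
            rarefy(toy_counts, depth=15, seed=0, on_small="error")

    def test_bad_depth(self, toy_counts):
        with pytest.raises(ValueError, match="positive"):
            rarefy(toy_counts, depth=0)

    def test_deterministic_under_seed(self, toy_counts):
        a = rarefy(toy_counts, depth=5, seed=42)
        b = rarefy(toy_counts, depth=5, seed=42)
        pd.testing.assert_frame_equal(a, b)


class TestBiomass:
    GROUPS = {"m1": "gp", "m2": "gn", "m3": "sap", "m4": "gen"}
    KINGDOM = {"gp": "bacteria", "gn": "bacteria", "sap": "fungi", "gen": "other"}

    def test_symmetry_and_additivity(self):
        plfa = pd.DataFrame({"s": [4.0, 3.0, 2.0, 1.0]}, index=list(self.GROUPS))
        out = biomass_summary(plfa, self.GROUPS, self.KINGDOM)
        assert out.loc["s", "total_biomass"] == pytest.approx(10.0)
        assert out.loc["s", "bf_ratio"] == pytest.approx(7.0 / 2.0)

    def test_bf_equal_sums(self):
        plfa = pd.DataFrame({"s": [10.0, 0.0, 10.0, 0.0]}, index=list(self.GROUPS))
        out = biomass_summary(plfa, self.GROUPS, self.KINGDOM)
        assert out.loc["s", "bf_ratio"] == pytest.approx(1.0)

    def test_zero_fungal_sum_flagged_missing(self):
        plfa = pd.DataFrame({"s": [1.0, 1.0, 0.0, 1.0]}, index=list(self.GROUPS))
        out = biomass_summary(plfa, self.GROUPS, self.KINGDOM)
        assert np.isnan(out.loc["s", "bf_ratio"])
        assert np.isfinite(out.loc["s", "total_biomass"])

    def test_random_table_matches_manual_sums(self, rng):
        plfa = pd.DataFrame(
            rng.uniform(0, 5, size=(4, 6)),
            index=list(self.GROUPS),
            columns=[f"s{i}" for i in range(6)],
        )
        out = biomass_summary(plfa, self.GROUPS, self.KINGDOM)
        np.testing.assert_allclose(out.total_biomass, plfa.sum(axis=0))
        np.testing.assert_allclose(
            out.bf_ratio, (plfa.loc["m1"] + plfa.loc["m2"]) / plfa.loc["m3"]
        )

    def test_unmapped_marker_rejected(self):
        plfa = pd.DataFrame({"s": [1.0]}, index=["mx"])
        with pytest.raises(ValueError, match="without group"):
            biomass_summary(plfa, self.GROUPS, self.KINGDOM)


class TestGeneScores:
    def test_two_point_scaling(self):
        genes = pd.DataFrame([[0.0, 10.0]], index=["g1"], columns=["a", "b"])
        out = gene_scores(genes, catabolic=["g1"])
        assert out.loc["a", "cata_score"] == pytest.approx(0.0)
        assert out.loc["b", "cata_score"] == pytest.approx(1.0)

    def test_uniform_gene_vector_has_evenness_one(self):
        genes = pd.DataFrame(
            [[3.0, 1.0], [3.0, 2.0], [3.0, 4.0]],
            index=["g1", "g2", "g3"], columns=["a", "b"],
        )
        out = gene_scores(genes, catabolic=["g1"])
        assert out.loc["a", "fg_evenness"] == pytest.approx(1.0, abs=1e-12)

    def test_minmax_matches_hand_computation(self):
        genes = pd.DataFrame(
            [[1.0, 3.0, 5.0], [2.0, 2.0, 2.0], [0.0, 4.0, 8.0]],
            index=["g1", "g2", "g3"], columns=["a", "b", "c"],
        )
        out = gene_scores(genes, catabolic=["g1", "g3"])
        # g1 scales to (0, .5, 1); g2 constant -> 0; g3 to (0, .5, 1)
        np.testing.assert_allclose(out.cata_score, [0.0, 1.0, 2.0])

    def test_cata_bounded_by_gene_count(self, rng):
        genes = pd.DataFrame(
            rng.uniform(0, 100, size=(5, 8)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(8)],
        )
        out = gene_scores(genes, catabolic=["g0", "g1", "g2"])
        assert (out.cata_score >= -1e-12).all()
        assert (out.cata_score <= 3 + 1e-12).all()

    def test_zscore_alternative(self):
        genes = pd.DataFrame(
            [[1.0, 2.0, 3.0]], index=["g1"], columns=["a", "b", "c"]
        )
        out = gene_scores(genes, catabolic=["g1"], scaling="zscore")
        np.testing.assert_allclose(out.cata_score, [-1.0, 0.0, 1.0])


class TestSIR:
    def test_perfect_evenness(self):
        resp = pd.DataFrame({"s": [2.0] * 14}, index=[f"sub{i}" for i in range(14)])
        assert sir_efficiency(resp)["s"] == pytest.approx(1.0)

    def test_one_hot_profile(self):
        resp = pd.DataFrame(
            {"s": [5.0] + [0.0] * 13}, index=[f"sub{i}" for i in range(14)]
        )
        assert sir_efficiency(resp)["s"] == pytest.approx(0.0)

    def test_direct_formula_oracle(self):
        resp = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=list("abc"))
        p = np.array([1, 2, 3]) / 6
        expected = -(p * np.log(p)).sum() / np.log(3)
        assert sir_efficiency(resp)["s"] == pytest.approx(expected, abs=1e-12)

    def test_range_definition_and_antisymmetry(self, rng):
        resp = pd.DataFrame(
            {"s1": [5.0, 5.0], "s2": [5.0, 2.0]}, index=["oxalic acid", "alanine"]
        )
        out = sir_range(resp)
        assert out["s1"] == 0.0 and out["s2"] == pytest.approx(3.0)
        rand = pd.DataFrame(
            rng.uniform(0, 4, size=(2, 10)), index=["oxalic acid", "alanine"]
        )
        np.testing.assert_allclose(
            sir_range(rand),
            -sir_range(rand, upper="alanine", lower="oxalic acid"),
        )

    def test_missing_substrate_named(self):
        resp = pd.DataFrame({"s": [1.0]}, index=["glucose"])
        with pytest.raises(KeyError, match="oxalic acid"):
            sir_range(resp)

    def test_efficiency_permutation_invariant(self, rng):
        resp = pd.DataFrame(
            rng.uniform(0.1, 3, size=(6, 4)), index=[f"sub{i}" for i in range(6)]
        )
        shuffled = resp.sample(frac=1, random_state=0)
        np.testing.assert_allclose(sir_efficiency(resp), sir_efficiency(shuffled))


class TestSubstrateSensitivity:
    def _toy(self, rng, n_sub=4, n_samp=12):
        return pd.DataFrame(
            rng.uniform(0.2, 3, size=(n_sub, n_samp)),
            index=["oxalic acid", "alanine", "glucose", "citric acid"][:n_sub],
            columns=[f"s{i}" for i in range(n_samp)],
        )

    def test_identity_subset(self, rng):
        resp = self._toy(rng)
        out = substrate_sensitivity(resp, scheme="random", k=4, reps=3, seed=0)
        np.testing.assert_allclose(out.r_sir_efficiency, 1.0, atol=1e-12)

    def test_leave_one_out_matches_enumeration(self, rng):
        resp = self._toy(rng)
        out = substrate_sensitivity(resp, scheme="leave-one-out")
        assert len(out) == 4
        from scipy.stats import pearsonr

        full = sir_efficiency(resp)
        for _, row in out.iterrows():
            dropped = row.subset.split(":", 1)[1]
            sub = resp.drop(index=dropped)
            expected = pearsonr(full, sir_efficiency(sub))[0]
            assert row.r_sir_efficiency == pytest.approx(expected, abs=1e-12)

    def test_random_scheme_deterministic(self, rng):
        resp = self._toy(rng)
        a = substrate_sensitivity(resp, scheme="random", k=3, reps=5, seed=9)
        b = substrate_sensitivity(resp, scheme="random", k=3, reps=5, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_subset_too_small(self, rng):
        with pytest.raises(ValueError, match="k >= 2"):
            substrate_sensitivity(self._toy(rng), scheme="random", k=1, reps=2)


class TestStoichiometry:
    def test_forced_by_definition(self):
        out = soil_stoichiometry([20.0], [2.0], [0.5])
        assert out.loc[0, "cn_ratio"] == pytest.approx(10.0)
        assert out.loc[0, "cp_ratio"] == pytest.approx(40.0)

    def test_identity_ratio(self):
        out = soil_stoichiometry([3.0], [3.0], [3.0])
        assert out.loc[0, "cn_ratio"] == pytest.approx(1.0)

    def test_vectorized_equals_scalar_loop(self, rng):
        toc, tn, tp = rng.uniform(1, 30, (3, 25))
        out = soil_stoichiometry(toc, tn, tp)
        for i in range(25):
            assert out.cn_ratio.iloc[i] == pytest.approx(toc[i] / tn[i])
            assert out.cp_ratio.iloc[i] == pytest.approx(toc[i] / tp[i])

    def test_zero_denominator_missing(self):
        out = soil_stoichiometry([10.0, 10.0], [0.0, 2.0], [1.0, 0.0])
        assert np.isnan(out.cn_ratio.iloc[0]) and np.isnan(out.cp_ratio.iloc[1])
        assert np.isfinite(out.cp_ratio.iloc[0]) and np.isfinite(out.cn_ratio.iloc[1])
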