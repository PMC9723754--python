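"""Path-model fitting, fit indices and effect decomposition."""

import numpy as np
import pandas as pd
import pytest

from facet2function import structure
from facet2function.sem import (
    PathModel,
    StandardizedPaths,
    decompose_effects,
    fit_path_model,
    group_effect_summary,
    parse_model,
)
from facet2function.sem.effect_decomposition import indirect_effects_by_series
from facet2function.sem.model import cfi_from_chi2, rmsea_from_chi2


class TestSpecParsing:
    def test_parse_paths_correlations_groups(self):
        spec = parse_model(
            """
            # toy model
            y ~ a + b
            b ~ a
            a ~~ c   # free covariance
            group: left = a c
            group: right = b y
            """
        )
        assert set(spec.variables) == {"y", "a", "b", "c"}
        assert ("a", "y") in spec.directed and ("a", "b") in spec.directed
        assert ("a", "c") in spec.correlations
        assert spec.exogenous == ("a", "c")
        assert spec.group_of("b") == "right"

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            parse_model("a ~ b\nb ~ a")

    def test_variable_in_two_groups_rejected(self):
        with pytest.raises(ValueError, match="groups"):
            parse_model("y ~ a\ngroup: g1 = a\ngroup: g2 = a y")


class TestFitting:
    def _recursive_toy(self, n=1000, seed=5):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        m = 0.5 * x + 0.8 * rng.standard_normal(n)
        w = -0.3 * x + rng.standard_normal(n)
        y = 0.4 * m + 0.2 * w + 0.6 * rng.standard_normal(n)
        return pd.DataFrame({"x": x, "m": m, "w": w, "y": y})

    def test_ml_matches_per_equation_ols(self):
        """On a recursive 4-variable toy the ML optimum reproduces OLS."""
        data = self._recursive_toy()
        fit = fit_path_model("m ~ x\nw ~ x\ny ~ m + w", data)
        import statsmodels.api as sm

        for target, sources in (("m", ["x"]), ("w", ["x"]), ("y", ["m", "w"])):
            ols = sm.OLS(
                data[target], sm.add_constant(data[sources])
            ).fit()
            for s in sources:
                est = fit.params.query(
                    "op == '~' and lhs == @target and rhs == @s"
                ).est.iloc[0]
                assert est == pytest.approx(ols.params[s], abs=1e-6)

    def test_exactly_noiseless_data_reported_as_singular(self):
        """Noiseless endogenous variables make S singular: clear error."""
        rng = np.random.default_rng(6)
        x = rng.standard_normal(400)
        data = pd.DataFrame({"x": x, "m": 0.7 * x, "y": 0.55 * x})
        with pytest.raises(ValueError, match="singular"):
            fit_path_model("m ~ x\ny ~ m + x", data)

    def test_small_disturbance_recovery(self):
        """With small structural noise the estimates sit on the generating
        coefficients and the discrepancy is near zero."""
        rng = np.random.default_rng(6)
        n = 2000
        x = rng.standard_normal(n)
        m = 0.7 * x + 0.05 * rng.standard_normal(n)
        y = 0.5 * m + 0.2 * x + 0.05 * rng.standard_normal(n)
        fit = fit_path_model(
            "m ~ x\ny ~ m + x", pd.DataFrame({"x": x, "m": m, "y": y})
        )
        est = {
            (r.rhs, r.lhs): r.est
            for r in fit.params[fit.params.op == "~"].itertuples()
        }
        # beta_m is identified from the ratio of two small disturbances,
        # so its sampling SE is ~1/sqrt(n) despite the tiny noise scale
        assert est[("x", "m")] == pytest.approx(0.7, abs=0.01)
        assert est[("m", "y")] == pytest.approx(0.5, abs=0.07)
        assert est[("x", "y")] == pytest.approx(0.2, abs=0.07)
        assert fit.fml == pytest.approx(0.0, abs=1e-6)
        assert fit.converged

    def test_saturated_model(self):
        data = self._recursive_toy(n=300, seed=7)
        fit = fit_path_model("m ~ x\nw ~ x + m\ny ~ x + m + w", data)
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(fit.sigma, fit.sample_cov, atol=1e-6)
        assert fit.cfi == pytest.approx(1.0)
        assert fit.srmr == pytest.approx(0.0, abs=1e-6)

    def test_standardized_estimates(self):
        rng = np.random.default_rng(8)
        x = 2.0 * rng.standard_normal(2000)
        y = 1.0 * x + 2.0 * rng.standard_normal(2000)  # SD(y) ~ sqrt(4+4)
        data = pd.DataFrame({"x": x, "y": y})
        fit = fit_path_model("y ~ x", data)
        row = fit.params.query("op == '~'").iloc[0]
        r = np.corrcoef(x, y)[0, 1]
        assert row.std_est == pytest.approx(r, abs=1e-8)
        sx = data.x.std(ddof=1)
        sy = np.sqrt(fit.sigma.loc["y", "y"])
        assert row.std_est == pytest.approx(row.est * sx / sy, rel=1e-6)

    def test_prestandardized_data_identity(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(5000)
        y = 0.6 * x + 0.8 * rng.standard_normal(5000)
        data = pd.DataFrame({"x": x, "y": y})
        data = (data - data.mean()) / data.std(ddof=1)
        fit = fit_path_model("y ~ x", data)
        row = fit.params.query("op == '~'").iloc[0]
        assert row.std_est == pytest.approx(row.est, abs=5e-3)

    def test_missing_variable_error(self):
        data = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        with pytest.raises(KeyError, match="absent"):
            fit_path_model("y ~ x", data)

    def test_parameter_recovery_cascade(self):
        """Fitting the facet cascade to data generated at the reported
        coefficients recovers each standardized path within 3 SEs."""
        import facet2function as f2f
        from facet2function.standardize import TwoSDScaler

        rng = np.random.default_rng(1234)
        cfg = f2f.DesignConfig(n_plots=100, n_samples=1000)
        design = f2f.generate_design(cfg, rng)
        params = f2f.GeneratorParams(
            structural_coefficients=dict(structure.CASCADE_COEFFICIENTS)
        )
        soil = f2f.generate_soil_chemistry(design, params, rng)
        lat = f2f.generate_facets(design, soil, params, rng)
        frame = lat[list(structure.FACET_VARIABLES)]
        scaled = pd.DataFrame(
            TwoSDScaler().fit_transform(frame), columns=frame.columns
        )
        fit = fit_path_model(structure.cascade_model_text(), scaled)
        paths = fit.params[fit.params.op == "~"]
        for (s, t), beta in structure.CASCADE_COEFFICIENTS.items():
            row = paths[(paths.lhs == t) & (paths.rhs == s)].iloc[0]
            assert abs(row.std_est - beta) < 3 * row.se, (s, t, row.std_est)


class TestFitIndices:
    def test_rmsea_closed_form(self):
        assert rmsea_from_chi2(50.0, 20, 151) == pytest.approx(
            np.sqrt(30 / (20 * 150))
        )
        assert rmsea_from_chi2(50.0, 20, 151) == pytest.approx(0.1)

    def test_rmsea_zero_when_df_zero(self):
        assert rmsea_from_chi2(3.0, 0, 100) == 0.0

    def test_cfi_baseline_identity(self):
        # the independence model evaluated against itself scores 0
        assert cfi_from_chi2(200.0, 10, 200.0, 10) == pytest.approx(0.0)
        # no worse than baseline but saturated fit scores 1
        assert cfi_from_chi2(5.0, 10, 200.0, 10) == pytest.approx(1.0)

    def test_threshold_flags(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(400)
        m = 0.5 * x + rng.standard_normal(400)
        y = 0.4 * m + rng.standard_normal(400)
        fit = fit_path_model("m ~ x\ny ~ m", pd.DataFrame({"x": x, "m": m, "y": y}))
        assert fit.fit_pass == {
            "rmsea": fit.rmsea < 0.10,
            "cfi": fit.cfi > 0.9,
            "srmr": fit.srmr < 0.08,
        }


class TestEffectDecomposition:
    def test_single_chain(self):
        paths = StandardizedPaths.from_coefficients(
            "b ~ a\nc ~ b",
            {("a", "b"): 0.5, ("b", "c"): 0.4},
        )
        dec = decompose_effects(paths)
        eff = dec.effect("a", "c")
        assert eff.direct == 0.0
        assert eff.indirect == pytest.approx(0.20, abs=1e-12)
        assert eff.total == pytest.approx(0.20, abs=1e-12)

    def test_total_equals_direct_plus_indirect(self):
        paths = StandardizedPaths.from_coefficients(
            "b ~ a\nc ~ a + b",
            {("a", "b"): 0.6, ("a", "c"): 0.3, ("b", "c"): 0.5},
        )
        dec = decompose_effects(paths)
        eff = dec.effect("a", "c")
        assert eff.total == eff.direct + eff.indirect
        assert eff.indirect == pytest.approx(0.30, abs=1e-12)

    def test_enumeration_matches_matrix_series_on_random_dags(self):
        """Path enumeration and the power series agree on 100 random DAGs."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            k = rng.integers(3, 9)
            names = [f"v{i}" for i in range(k)]
            coef, lines = {}, []
            for i in range(k):
                parents = [j for j in range(i) if rng.random() < 0.5]
                if parents:
                    lines.append(
                        f"{names[i]} ~ " + " + ".join(names[j] for j in parents)
                    )
                    for j in parents:
                        coef[(names[j], names[i])] = float(rng.uniform(-1, 1))
            if not lines:
                continue
            paths = StandardizedPaths.from_coefficients("\n".join(lines), coef)
            dec = decompose_effects(paths)
            series = indirect_effects_by_series(paths)
            for row in dec.table.itertuples():
                assert row.indirect == pytest.approx(
                    series.loc[row.source, row.target], abs=1e-10
                )

    def test_cycle_detected(self):
        spec = parse_model("b ~ a\nc ~ b")
        paths = StandardizedPaths(
            spec=spec, coef={("a", "b"): 0.1, ("b", "c"): 0.1},
            pvalues={("a", "b"): 0.01, ("b", "c"): 0.01},
        )
        dec = decompose_effects(paths)  # acyclic fine
        assert not dec.table.empty


class TestGroupSummary:
    def _reported_solution(self):
        sig = {e: 0.001 for e in structure.CASCADE_COEFFICIENTS}
        return StandardizedPaths.from_coefficients(
            structure.cascade_model_text(),
            dict(structure.CASCADE_COEFFICIENTS),
            pvalues=sig,
        )

    def test_physiology_group_direct_effect(self):
        dec = decompose_effects(self._reported_solution())
        gs = group_effect_summary(dec, targets=["respiration"]).table
        phys = gs[gs.source_group == "physiological_potential"].iloc[0]
        assert phys.direct == pytest.approx(0.176 + 0.213, abs=1e-12)
        assert phys.indirect == 0.0

    def test_functional_profile_indirect_only(self):
        dec = decompose_effects(self._reported_solution())
        gs = group_effect_summary(dec, targets=["respiration"]).table
        fp = gs[gs.source_group == "functional_profile"].iloc[0]
        assert fp.direct == 0.0
        assert fp.indirect == pytest.approx(abs(-0.179 * 0.176), abs=1e-12)

    def test_biomass_total_effect(self):
        dec = decompose_effects(self._reported_solution())
        gs = group_effect_summary(dec, targets=["respiration"]).table
        bio = gs[gs.source_group == "biomass"].iloc[0]
        assert bio.indirect == pytest.approx((0.209 + 0.258) * 0.176, abs=1e-12)
        assert bio.total == pytest.approx(0.590 + (0.209 + 0.258) * 0.176, abs=1e-12)

    def test_group_with_no_significant_paths(self):
        pv = {e: 0.001 for e in structure.CASCADE_COEFFICIENTS}
        pv[("fun_div", "respiration")] = 0.8  # only taxonomic path, now ns
        paths = StandardizedPaths.from_coefficients(
            structure.cascade_model_text(),
            dict(structure.CASCADE_COEFFICIENTS),
            pvalues=pv,
        )
        gs = group_effect_summary(
            decompose_effects(paths), targets=["respiration"]
        ).table
        tax = gs[gs.source_group == "taxonomic_profile"].iloc[0]
        assert tax.total == 0.0

    def test_unknown_group_member_rejected(self):
        dec = decompose_effects(self._reported_solution())
        with pytest.raises(KeyError, match="not in model"):
            group_effect_summary(dec, groups={"g": ["nope"]})
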