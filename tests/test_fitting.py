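"""Grid-search fitting: correlations, screening, adjustment, selection."""

import numpy as np
import pytest
from scipy import stats

from dielflux import ExperimentDesign, ModelParameters
from dielflux.fitting import (ParamGrid, ZeroVarianceError, adjusted_r,
                              default_grid, evaluate_params, grid_search,
                              pearson, select_variant, VariantResult, FitRecord)
from dielflux.synthetic import generate_from_model


def _series_with_exact_r(r, n=9):
    """Two n-vectors whose sample correlation is exactly r."""
    z1 = np.sin(np.arange(n))
    z2 = np.cos(3 * np.arange(n))
    z1 = z1 - z1.mean()
    z2 = z2 - (z2 @ z1) / (z1 @ z1) * z1  # orthogonalise
    z2 = z2 - z2.mean()
    z1 /= np.linalg.norm(z1)
    z2 /= np.linalg.norm(z2)
    return z1, r * z1 + np.sqrt(1 - r**2) * z2


class TestPearson:
    def test_affine_invariance_gives_unit_correlation(self):
        x = np.arange(1.0, 10.0)
        r, p = pearson(x, 2 * x + 3)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)
        r, _ = pearson(x, x[::-1])
        assert r == pytest.approx(-1.0)

    def test_matches_scipy_on_random_series(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 9))
            r, p = pearson(x, y)
            r_ref, p_ref = stats.pearsonr(x, y)
            assert r == pytest.approx(r_ref, rel=1e-10)
            assert p == pytest.approx(p_ref, rel=1e-8)

    def test_significance_threshold_at_n9(self):
        # df = 7: |r| just above ~0.666 is significant at two-sided 0.05
        t_crit = stats.t.ppf(0.975, 7)
        r_crit = t_crit / np.sqrt(t_crit**2 + 7)
        assert r_crit == pytest.approx(0.6664, abs=5e-4)
        _, p_hi = pearson(*_series_with_exact_r(r_crit + 1e-3))
        _, p_lo = pearson(*_series_with_exact_r(r_crit - 1e-3))
        assert p_hi < 0.05 < p_lo

    def test_zero_variance_flagged(self):
        with pytest.raises(ZeroVarianceError):
            pearson(np.ones(9), np.arange(9.0))


class TestAdjustedR:
    def test_standard_mode_identities(self):
        assert adjusted_r(1.0, 9, 3, "standard") == pytest.approx(1.0)
        for r in (-0.5, 0.0, 0.3, 0.9):
            assert adjusted_r(r, 9, 0, "standard") == pytest.approx(r)
        # penalty grows with k
        assert adjusted_r(0.9, 9, 2) < adjusted_r(0.9, 9, 1) < 0.9

    def test_printed_mode_direct_evaluation(self):
        assert adjusted_r(0.8, 9, 3, "printed") == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            adjusted_r(0.0, 9, 1, "printed")

    def test_degrees_of_freedom_guard(self):
        with pytest.raises(ValueError):
            adjusted_r(0.5, 4, 3)


class TestEvaluateParams:
    def test_noiseless_self_generated_data_recovered_exactly(self, design):
        p = ModelParameters(t_frac=0.1, r_diff=0.2, u_vmax=2.0, u_km=1.0)
        data = generate_from_model(p, "base", design, noise_sd=0.0)
        rec = evaluate_params(p, "base", design, data["met_series"],
                              data["gene_series"])
        assert rec is not None
        assert rec.r_met == pytest.approx(1.0, abs=1e-9)
        assert rec.r_gene == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_is_rejected_not_raised(self, design):
        p = ModelParameters()
        rec = evaluate_params(p, "base", design, np.ones(9), np.arange(9.0))
        assert rec is None

    def test_dual_requirement_both_must_be_significant(self, design):
        p = ModelParameters(t_frac=0.1, r_diff=0.2, u_vmax=2.0, u_km=1.0)
        data = generate_from_model(p, "base", design, noise_sd=0.0)
        shuffled = np.random.default_rng(0).permutation(data["met_series"])
        rec = evaluate_params(p, "base", design, shuffled, data["gene_series"])
        assert rec is None  # gene side fits, metabolite side does not


class TestGridSearch:
    def test_exhaustive_product_count(self, design):
        grid = ParamGrid("base", {
            "n_scale": [0.02, 0.04], "t_frac": [0.1, 0.2], "r_diff": [0.1, 0.3],
            "u_vmax": [1.0], "u_km": [1.0], "c_frac": [0.1]})
        assert grid.n_combinations == 8
        assert len(grid.expand()["n_scale"]) == 8

    def test_value_order_does_not_change_saved_set(self, design):
        p = ModelParameters(t_frac=0.1, r_diff=0.2, u_vmax=2.0, u_km=1.0)
        data = generate_from_model(p, "base", design, noise_sd=0.2, seed=1)
        vals = {"n_scale": [0.02], "t_frac": [0.05, 0.1, 0.3],
                "r_diff": [0.1, 0.2], "u_vmax": [2.0], "u_km": [1.0],
                "c_frac": [0.1]}
        shuffled = {k: list(reversed(v)) for k, v in vals.items()}
        res1 = grid_search(ParamGrid("base", vals), design,
                           data["met_series"], data["gene_series"])
        res2 = grid_search(ParamGrid("base", shuffled), design,
                           data["met_series"], data["gene_series"])
        key = lambda r: tuple(getattr(r.params, f) for f in ModelParameters.BASE_FIELDS)
        assert sorted(map(key, res1.records)) == sorted(map(key, res2.records))

    def test_truth_in_grid_attains_maximal_mean_r(self, design):
        p = ModelParameters(t_frac=0.1, r_diff=0.2, u_vmax=2.0, u_km=1.0)
        data = generate_from_model(p, "base", design, noise_sd=0.0)
        vals = {"n_scale": [0.02], "t_frac": [0.05, 0.1, 0.3],
                "r_diff": [0.1, 0.2, 0.4], "u_vmax": [1.0, 2.0],
                "u_km": [0.5, 1.0], "c_frac": [0.1]}
        res = grid_search(ParamGrid("base", vals), design,
                          data["met_series"], data["gene_series"])
        assert res.best.mean_r == pytest.approx(1.0, abs=1e-9)
        assert res.best.params.t_frac == 0.1
        assert res.best.params.r_diff == 0.2

    def test_screening_invariant_to_zscoring_of_experimental_series(self, design):
        p = ModelParameters(t_frac=0.1, r_diff=0.2, u_vmax=2.0, u_km=1.0)
        data = generate_from_model(p, "base", design, noise_sd=0.3, seed=7)
        grid = ParamGrid("base", {
            "n_scale": [0.02], "t_frac": [0.05, 0.1], "r_diff": [0.1, 0.2],
            "u_vmax": [2.0], "u_km": [1.0], "c_frac": [0.1]})

        def z(a):
            return (a - a.mean()) / a.std(ddof=1)

        raw = grid_search(grid, design, data["met_series"], data["gene_series"])
        scaled = grid_search(grid, design, z(data["met_series"]),
                             z(data["gene_series"]))
        for r1, r2 in zip(raw.records, scaled.records):
            assert r1.r_met == pytest.approx(r2.r_met, abs=1e-12)
            assert r1.r_gene == pytest.approx(r2.r_gene, abs=1e-12)

    def test_loosening_alpha_only_adds_records(self, design):
        p = ModelParameters(t_frac=0.1, r_diff=0.2, u_vmax=2.0, u_km=1.0)
        data = generate_from_model(p, "base", design, noise_sd=0.5, seed=3)
        grid = default_grid("base")
        strict = grid_search(grid, design, data["met_series"],
                             data["gene_series"], alpha=0.01)
        loose = grid_search(grid, design, data["met_series"],
                            data["gene_series"], alpha=0.10)
        key = lambda r: tuple(getattr(r.params, f) for f in ModelParameters.BASE_FIELDS)
        assert set(map(key, strict.records)) <= set(map(key, loose.records))

    def test_default_grid_validation(self):
        with pytest.raises(ValueError):
            ParamGrid("o", {"n_scale": [0.02]})  # missing fields
        with pytest.raises(ValueError):
            ParamGrid("base", {**default_grid("base").values, "t_frac": []})


class TestSelectVariant:
    @staticmethod
    def _result(variant, mean_r, n_records=1):
        half = mean_r  # symmetric record
        rec = FitRecord(params=ModelParameters(), variant=variant,
                        r_met=half, p_met=0.01, r_gene=half, p_gene=0.01)
        return VariantResult(variant=variant, n_combinations=10,
                             records=[rec] * n_records)

    def test_only_fitting_variant_wins(self):
        results = {"base": self._result("base", 0.9),
                   "o": VariantResult("o", 10, [])}
        report = select_variant(results, n=9)
        assert report.winner == "base"
        assert any(row["status"] == "no fit" for row in report.rows)

    def test_tie_broken_toward_fewer_terms(self):
        # equal adjusted r only possible via exact construction: r=1 both
        results = {"base": self._result("base", 1.0), "o": self._result("o", 1.0)}
        report = select_variant(results, n=9, mode="standard")
        assert report.winner == "base"

    def test_all_no_fit_yields_null_winner(self):
        results = {"base": VariantResult("base", 10, []),
                   "h": VariantResult("h", 30, [])}
        assert select_variant(results, n=9).winner is None

    def test_printed_mode_requires_large_relative_improvement(self):
        # one-term variant must exceed base r by the factor (n-1)/(n-2)
        results = {"base": self._result("base", 0.90),
                   "o": self._result("o", 0.99)}
        assert select_variant(results, n=9, mode="printed").winner == "base"
        results = {"base": self._result("base", 0.80),
                   "o": self._result("o", 0.99)}
        assert select_variant(results, n=9, mode="printed").winner == "o"

    def test_printed_mode_excludes_nonpositive_fits(self):
        results = {"h": self._result("h", -0.5), "b": self._result("b", 0.4)}
        report = select_variant(results, n=9, mode="printed")
        assert report.winner == "b"
        assert any(row["status"] == "no positive fit" for row in report.rows)
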