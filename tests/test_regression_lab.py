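"""Goodness-of-fit metrics, model fitting, coherence and selection rules."""

import numpy as np
import pytest

from cbmap.exceptions import DomainError, FitError, InputError, InsufficientDataError
from cbmap.regression_lab import (
    FALLACY_VARIANCE_RATIO,
    ModelSpec,
    Standardizer,
    coherence_analysis,
    fit,
    r_squared,
    r_squared_resistant,
    select_model,
    standardize,
)


class TestRSquared:
    def test_perfect_and_null_fits(self):
        y = np.array([1.0, 2.0, 4.0, 7.0])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        assert r_squared([1, 2, 3], [1, 2, 2]) == pytest.approx(0.5)

    def test_constant_response_undefined(self):
        with pytest.raises(DomainError):
            r_squared([2, 2, 2], [1, 2, 3])

    def test_equals_squared_correlation_for_simple_ols(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 40)
        y = 1.2 + 0.7 * x + rng.normal(0, 1, 40)
        m = fit(ModelSpec("Y", terms=("X",)), {"Y": y, "X": x})
        yhat = m.predict({"X": x})
        r = np.corrcoef(y, yhat)[0, 1]
        assert m.r2 == pytest.approx(r**2, abs=1e-12)


class TestResistantRSquared:
    def test_perfect_fit(self):
        y = [1.0, 2.0, 3.0, 4.0]
        assert r_squared_resistant(y, y) == pytest.approx(1.0)

    def test_single_gross_outlier_ignored(self):
        """A lone wild observation cannot drag the resistant score down."""
        assert r_squared_resistant([1, 2, 3, 100], [1, 2, 3, 3]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # |resid| = [.5,.5,.5,.5] -> median .5; center = median(y) = 1.5;
        # |y - 1.5| = [1.5,.5,.5,1.5] -> median 1.0
        val = r_squared_resistant([0, 1, 2, 3], [0.5, 1.5, 1.5, 2.5])
        assert val == pytest.approx(1 - (0.5 / 1.0) ** 2)

    def test_resistance_property_vs_plain_r2(self):
        rng = np.random.default_rng(8)
        x = np.linspace(1, 10, 30)
        y = 2 * x + rng.normal(0, 0.3, 30)
        yhat = 2 * x
        base = r_squared_resistant(y, yhat)
        y_out = y.copy()
        y_out[-1] += 1e6  # already the extreme: its ranks stay above the median
        assert r_squared_resistant(y_out, yhat) == pytest.approx(base, abs=1e-9)
        assert r_squared(y_out, yhat) < 0  # the classic score collapses

    def test_zero_mad_undefined(self):
        with pytest.raises(DomainError):
            r_squared_resistant([1, 1, 1, 5], [1, 1, 1, 5])


class TestFit:
    def test_simple_regression_closed_form(self):
        """x=1..4, y=[1,2,2,3]: slope 0.6, intercept 0.5, SSR 1.8, F=18."""
        m = fit(ModelSpec("Y", terms=("X",)), {"X": [1, 2, 3, 4], "Y": [1, 2, 2, 3]})
        assert m.params["X"] == pytest.approx(0.6)
        assert m.params["const"] == pytest.approx(0.5)
        assert m.anova.ss_reg == pytest.approx(1.8)
        assert m.anova.ss_err == pytest.approx(0.2)
        assert m.anova.f_stat == pytest.approx(18.0)
        assert (m.anova.df_reg, m.anova.df_err) == (1, 2)
        assert m.anova.df_total == m.n - 1
        assert m.anova.ss_total == pytest.approx(m.anova.ss_reg + m.anova.ss_err)

    def test_anova_matches_brute_force_on_random_designs(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(15, 40))
            x1, x2 = rng.normal(0, 1, (2, n))
            y = 1 + x1 - 2 * x2 + rng.normal(0, 0.7, n)
            m = fit(ModelSpec("Y", terms=("X1", "X2")), {"Y": y, "X1": x1, "X2": x2})
            X = np.column_stack([np.ones(n), x1, x2])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            yhat = X @ beta
            sse = np.sum((y - yhat) ** 2)
            ssr = np.sum((yhat - y.mean()) ** 2)
            f = (ssr / 2) / (sse / (n - 3))
            assert m.anova.f_stat == pytest.approx(f, abs=1e-8 * max(1, f))
            assert m.anova.ss_reg == pytest.approx(ssr)

    def test_power_family_noise_free_recovery(self):
        x = np.arange(1.0, 51.0)
        y = 2.0 * np.sqrt(x)
        m = fit(ModelSpec("Y", family="power", predictor="X"), {"X": x, "Y": y})
        assert m.params["a"] == pytest.approx(2.0, abs=1e-8)
        assert m.params["b"] == pytest.approx(0.5, abs=1e-8)
        assert m.r2 == pytest.approx(1.0)

    def test_power_family_rejects_nonpositive_domain(self):
        with pytest.raises(DomainError):
            fit(ModelSpec("Y", family="power", predictor="X"),
                {"X": [0.0, 1, 2, 3], "Y": [1.0, 2, 3, 4]})

    def test_listwise_missing_row_exclusion(self):
        data = {"X": [1.0, 2, np.nan, 4, 5], "Y": [1.0, np.nan, 3, 4, 5]}
        m = fit(ModelSpec("Y", terms=("X",)), data)
        assert m.n == 3

    def test_singular_design_is_fit_error(self):
        x = np.ones(10)
        with pytest.raises(FitError):
            fit(ModelSpec("Y", terms=("X",)), {"X": x, "Y": np.arange(10.0)})

    def test_term_transforms_round_trip(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(1, 5, 30)
        z = rng.uniform(1, 5, 30)
        y = 1 + 2 * x**2 + 0.5 * np.log(z) + 3 / x + 0.1 * x * z
        m = fit(ModelSpec("Y", terms=("X^2", "ln(Z)", "1/X", "X*Z")),
                {"X": x, "Z": z, "Y": y})
        assert m.r2 == pytest.approx(1.0)
        assert m.params["X^2"] == pytest.approx(2.0, abs=1e-8)
        assert m.params["X*Z"] == pytest.approx(0.1, abs=1e-8)


class TestStandardize:
    def test_fixed_scaler_values(self):
        s = Standardizer(center=85.4, scale=97.3)
        assert standardize(85.4, s) == pytest.approx(0.0)
        assert standardize(182.7, s) == pytest.approx(1.0)
        assert standardize(280.0, s) == pytest.approx((280 - 85.4) / 97.3)

    def test_from_data_and_nonpositive_scale(self):
        s = Standardizer.from_data([1.0, 2.0, 3.0])
        assert s.center == pytest.approx(2.0) and s.scale == pytest.approx(1.0)
        with pytest.raises(InputError):
            Standardizer(center=0.0, scale=0.0)


class TestCoherence:
    def test_identical_traits_flag_fallacy(self):
        rng = np.random.default_rng(14)
        x = rng.normal(40, 10, 60)
        res = coherence_analysis(x, x)
        linear = next(m for m in res.fits if m.spec.name.startswith("linear"))
        assert linear.params["B"] == pytest.approx(1.0, abs=1e-8)
        assert linear.params["const"] == pytest.approx(0.0, abs=1e-6)
        assert linear.r2 == pytest.approx(1.0)
        assert res.variance_ratio == pytest.approx(1.0)
        assert res.fallacy_flag

    def test_dissimilar_variances_do_not_flag(self):
        rng = np.random.default_rng(15)
        b = rng.normal(4.8, 1.4, 80)   # e.g. maximum soil resistance
        a = 0.3 + 0.35 * b + rng.normal(0, 0.2, 80)
        res = coherence_analysis(a, b)
        assert res.variance_ratio < FALLACY_VARIANCE_RATIO
        assert not res.fallacy_flag

    def test_cubic_truth_prefers_cubic_over_linear(self, field):
        """V-12 generated cubically from V-8: the cubic family must not lose
        to the straight line on the resistant score."""
        frame, _ = field
        res = coherence_analysis(frame["X2"], frame["X1"], symbols=("V12", "V8"))
        by_name = {m.spec.name.split()[0]: m for m in res.fits}
        assert by_name["cubic"].r2_res >= by_name["linear"].r2_res - 1e-9

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            coherence_analysis(np.arange(5.0), np.arange(5.0))


class TestSelectModel:
    def _toy_candidates(self):
        rng = np.random.default_rng(20)
        x = rng.uniform(5, 95, 120)
        y = 0.6 * x**0.5 + rng.normal(0, 0.15, 120)
        data = {"X1": x, "Y": y}
        return [
            fit(ModelSpec("Y", terms=("X1",), name="linear"), data),
            fit(ModelSpec("Y", terms=("X1", "X1^2"), name="quadratic"), data),
            fit(ModelSpec("Y", family="power", predictor="X1", name="power"), data),
        ]

    def test_nonsignificant_term_discards_candidate(self):
        """A clean candidate beats a higher-R2 one carrying a dead term."""
        from cbmap.regression_lab import AnovaTable, FittedModel

        def anova(f):
            return AnovaTable(1, 1.0, 1.0, 10, 1.0, 0.1, 11, 2.0, f, 0.01)

        clean = FittedModel(
            spec=ModelSpec("Y", terms=("X1",), name="clean"),
            params={"const": 0.1, "X1": 1.0},
            pvalues={"const": 0.01, "X1": 0.001},
            r2=0.3, r2_res=0.3, anova=anova(10.0), n=12)
        dirty = FittedModel(
            spec=ModelSpec("Y", terms=("X1", "X1^2"), name="dirty"),
            params={"const": 0.1, "X1": 1.0, "X1^2": 0.2},
            pvalues={"const": 0.01, "X1": 0.001, "X1^2": 0.4},
            r2=0.9, r2_res=0.9, anova=anova(50.0), n=12)
        sel = select_model([clean, dirty])
        assert sel.winner is clean
        assert any("non-significant" in r for r in sel.reasons["dirty"])

    def test_boundary_check_filters_physically_invalid(self):
        cands = self._toy_candidates()
        sel = select_model(cands, boundary_checks=[(0.0, lambda y: abs(y) < 0.2)])
        # only the power law passes through the origin
        assert sel.winner.spec.name == "power"
        linear_log = " ".join(sel.reasons["linear"])
        assert "boundary" in linear_log or "non-significant" in linear_log

    def test_single_candidate_wins(self):
        cands = self._toy_candidates()[:1]
        sel = select_model(cands)
        assert sel.winner is cands[0]

    def test_empty_candidates_rejected(self):
        with pytest.raises(InputError):
            select_model([])
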