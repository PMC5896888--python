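"""Thermodynamic model: inverses, prediction, grid fit, cross-validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deeppca import thermo as th


def bisect_ddg(ppi: float, params: th.ThermoParams, tol: float = 1e-14) -> float:
    """Independent inversion of the forward map by bisection on ddG."""
    lo, hi = -80.0, 80.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if th.ppi_from_ddg(mid, params) > ppi:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


params_strategy = st.builds(
    th.ThermoParams,
    a_total=st.floats(1.05, 3.0),
    b_total=st.floats(1.05, 3.0),
    bg=st.floats(0.1, 1.5),
)


class TestForwardInverse:
    def test_wild_type_is_exactly_one(self, default_params):
        assert th.ppi_from_ddg(0.0, default_params) == 1.0
        assert th.ddg_from_ppi(1.0, default_params) == 0.0

    def test_asymptotes(self, default_params):
        p = default_params
        assert th.ppi_from_ddg(np.inf, p) == pytest.approx(p.lower)
        assert th.ppi_from_ddg(-np.inf, p) == pytest.approx(p.upper)
        assert th.ddg_from_ppi(p.lower, p) == np.inf
        assert th.ddg_from_ppi(p.upper, p) == -np.inf
        assert th.ddg_from_ppi(p.lower - 0.05, p) == np.inf

    @given(params=params_strategy, u=st.floats(1e-6, 1 - 1e-6))
    @settings(max_examples=200, derandomize=True)
    def test_roundtrip_on_open_interval(self, params, u):
        x = params.lower + u * (params.upper - params.lower)
        back = th.ppi_from_ddg(th.ddg_from_ppi(x, params), params)
        assert back == pytest.approx(x, rel=1e-10, abs=1e-10)

    def test_roundtrip_bulk(self, default_params):
        rng = np.random.default_rng(0)
        p = default_params
        x = rng.uniform(p.lower + 1e-9, p.upper - 1e-9, 1000)
        back = th.ppi_from_ddg(th.ddg_from_ppi(x, p), p)
        assert np.abs(back - x).max() < 1e-10

    def test_strictly_decreasing_inside_interval(self, default_params):
        ddg = np.linspace(-20, 20, 4001)
        out = th.ppi_from_ddg(ddg, default_params)
        assert np.all(np.diff(out) < 0)
        assert out.min() > default_params.lower
        assert out.max() < default_params.upper

    def test_forward_matches_bisection_oracle(self):
        params = th.ThermoParams(1.3, 1.25, 0.7)
        for ddg in (-2.0, -0.5, 0.3, 1.0, 4.0):
            p = th.ppi_from_ddg(ddg, params)
            assert bisect_ddg(p, params) == pytest.approx(ddg, abs=1e-10)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            th.ThermoParams(0.9, 1.2, 0.5)
        with pytest.raises(ValueError):
            th.ThermoParams(1.2, 1.2, 0.0)


class TestDoublePrediction:
    def test_neutral_identities(self, default_params):
        assert th.predict_double_ppi(1.0, 1.0, default_params) == 1.0
        for p in (0.6, 0.85, 1.05):
            assert th.predict_double_ppi(p, 1.0, default_params) == pytest.approx(
                p, rel=1e-10
            )

    @given(
        params=params_strategy,
        u1=st.floats(1e-4, 1 - 1e-4),
        u2=st.floats(1e-4, 1 - 1e-4),
    )
    @settings(max_examples=200, derandomize=True)
    def test_symmetric_and_matches_composition(self, params, u1, u2):
        s1 = params.lower + u1 * (params.upper - params.lower)
        s2 = params.lower + u2 * (params.upper - params.lower)
        direct = th.predict_double_ppi(s1, s2, params)
        swapped = th.predict_double_ppi(s2, s1, params)
        composed = th.ppi_from_ddg(
            th.ddg_from_ppi(s1, params) + th.ddg_from_ppi(s2, params), params
        )
        assert direct == pytest.approx(swapped, rel=1e-12)
        assert direct == pytest.approx(composed, rel=1e-10)

    def test_out_of_interval_singles_clamp(self, default_params):
        p = default_params
        # a dead single forces the floor, a saturated one forces the ceiling
        assert th.predict_double_ppi(p.lower - 0.1, 0.9, p) == pytest.approx(p.lower)
        assert th.predict_double_ppi(p.upper + 0.1, 0.9, p) == pytest.approx(p.upper)

    def test_conflicting_extremes(self, default_params):
        p = default_params
        with pytest.raises(ValueError):
            th.predict_double_ppi(p.lower - 0.1, p.upper + 0.1, p)
        out = th.predict_double_ppi(
            np.array([p.lower - 0.1]), np.array([p.upper + 0.1]), p, errors="nan"
        )
        assert np.isnan(out[0])


def _self_consistent_data(params, n_singles=200, n_doubles=4000, seed=0):
    rng = np.random.default_rng(seed)
    ddg = np.where(
        rng.random(n_singles) < 0.25,
        rng.normal(5, 1, n_singles),
        rng.normal(0, 0.35, n_singles),
    )
    s = th.ppi_from_ddg(ddg, params)
    i = rng.integers(0, n_singles, n_doubles)
    j = rng.integers(0, n_singles, n_doubles)
    obs = th.predict_double_ppi(s[i], s[j], params, errors="nan")
    return s[i], s[j], obs


class TestGridFit:
    def test_recovers_generating_grid_point_exactly(self):
        true = th.ThermoParams(1.30, 1.25, 0.700)
        s1, s2, obs = _self_consistent_data(true)
        grid = th.GridSpec((1.2, 1.4), 0.05, (1.15, 1.35), 0.05, (0.6, 0.8), 0.05)
        fit = th.fit_params_grid(s1, s2, obs, grid)
        # (a_total, b_total) are identified as an unordered pair
        assert sorted(fit.params.astuple()[:2]) == pytest.approx([1.25, 1.30])
        assert fit.params.bg == pytest.approx(0.700)
        assert fit.variance_explained == pytest.approx(1.0, abs=1e-12)

    def test_noise_recovery_within_three_fine_steps(self):
        true = th.ThermoParams(1.30, 1.25, 0.700)
        s1, s2, obs = _self_consistent_data(true, n_doubles=30_000, seed=2)
        rng = np.random.default_rng(3)
        noisy = obs * (1.0 + rng.normal(0, 0.02, obs.size))
        coarse = th.GridSpec((1.1, 1.6), 0.05, (1.1, 1.6), 0.05, (0.3, 1.0), 0.05)
        fit = th.fit_params_refine(s1, s2, noisy, coarse, fine_steps=(0.01, 0.01, 0.01))
        fa, fb = sorted(fit.params.astuple()[:2])
        assert abs(fa - 1.25) <= 3 * 0.01 + 1e-9
        assert abs(fb - 1.30) <= 3 * 0.01 + 1e-9
        assert abs(fit.params.bg - 0.700) <= 3 * 0.01 + 1e-9

    def test_objective_invariant_to_row_order(self, default_params):
        s1, s2, obs = _self_consistent_data(default_params, n_doubles=500)
        grid = th.GridSpec((1.3, 1.3), 0.1, (1.25, 1.25), 0.1, (0.6, 0.8), 0.1)
        f1 = th.fit_params_grid(s1, s2, obs, grid)
        perm = np.random.default_rng(1).permutation(obs.size)
        f2 = th.fit_params_grid(s1[perm], s2[perm], obs[perm], grid)
        assert f1.variance_explained == pytest.approx(f2.variance_explained, rel=1e-12)
        assert f1.params == f2.params

    def test_errors_without_valid_doubles(self, default_params):
        with pytest.raises(ValueError):
            th.fit_params_grid(
                np.array([np.nan]), np.array([1.0]), np.array([1.0]),
                th.GridSpec((1.2, 1.3), 0.1, (1.2, 1.3), 0.1, (0.5, 0.7), 0.1),
            )

    def test_default_grid_matches_protocol(self):
        g = th.DEFAULT_GRID
        assert g.a_values()[0] == pytest.approx(1.1)
        assert g.a_values()[-1] == pytest.approx(2.0)
        assert g.a_step == 0.01
        assert g.bg_values()[0] == pytest.approx(0.3)
        assert g.bg_values()[-1] == pytest.approx(1.2)
        assert g.bg_step == 0.001
        cv = th.CV_GRID
        assert cv.a_range == (1.1, 1.6) and cv.bg_range == (0.3, 1.0)
        assert cv.bg_step == 0.01


def _tables_from_arrays(params, n_each=40, seed=0):
    """Small noiseless singles/doubles tables keyed like real score tables."""
    rng = np.random.default_rng(seed)
    singles = {}
    for prot in "AB":
        for pos in range(1, n_each + 1):
            ddg = rng.normal(0, 0.6)
            key = f"{prot}{pos}L>M"
            singles[key] = th.ppi_from_ddg(ddg, params)
    s = pd.DataFrame(
        {f"ppi_r{r}": pd.Series(singles) for r in (1, 2, 3)}
    )
    a_keys = [k for k in s.index if k.startswith("A")]
    b_keys = [k for k in s.index if k.startswith("B")]
    rows = {}
    for ka in a_keys:
        for kb in b_keys:
            pred = th.predict_double_ppi(
                s.loc[ka, "ppi_r1"], s.loc[kb, "ppi_r1"], params
            )
            rows[f"{ka}:{kb}"] = pred
    d = pd.DataFrame({f"ppi_r{r}": pd.Series(rows) for r in (1, 2, 3)})
    return s, d


class TestMonteCarloCV:
    def test_noiseless_recovery_and_reproducibility(self, default_params):
        singles, doubles = _tables_from_arrays(default_params)
        grid = th.GridSpec((1.25, 1.35), 0.05, (1.2, 1.3), 0.05, (0.65, 0.75), 0.05)
        cv1 = th.monte_carlo_cv(singles, doubles, grid, n_repeats=5, rng=7)
        cv2 = th.monte_carlo_cv(singles, doubles, grid, n_repeats=5, rng=7)
        pd.testing.assert_frame_equal(cv1, cv2)
        fitted = np.sort(cv1[["a_total", "b_total"]].to_numpy(), axis=1)
        assert np.allclose(fitted[:, 0], 1.25) and np.allclose(fitted[:, 1], 1.30)
        assert np.allclose(cv1["bg"], 0.700)
        assert np.allclose(cv1["test_ve"], 1.0)
        summ = th.cv_summary(cv1)
        assert summ["test_ve"] == pytest.approx(1.0)


class TestResiduals:
    def test_zero_on_self_consistent_data(self, default_params):
        singles, doubles = _tables_from_arrays(default_params)
        gi, excluded = th.residual_interaction_scores(doubles, singles, default_params)
        assert excluded.empty
        assert np.abs(gi[["gi_r1", "gi_r2", "gi_r3"]].to_numpy()).max() < 1e-10

    def test_injected_offset_recovered(self, default_params):
        singles, doubles = _tables_from_arrays(default_params)
        target = doubles.index[5]
        doubles.loc[target] = doubles.loc[target] + 0.2
        gi, _ = th.residual_interaction_scores(doubles, singles, default_params)
        assert gi.loc[target, "gi_mean"] == pytest.approx(0.2, abs=1e-10)
        others = gi.drop(index=target)["gi_mean"].abs().max()
        assert others < 1e-10

    def test_missing_single_excluded_with_reason(self, default_params):
        singles, doubles = _tables_from_arrays(default_params, n_each=5)
        singles = singles.drop(index="A1L>M")
        gi, excluded = th.residual_interaction_scores(doubles, singles, default_params)
        assert (excluded["reason"] == "missing single").all()
        assert len(excluded) == 5
        assert len(gi) == len(doubles) - 5


class TestVarianceMetrics:
    def test_variance_explained_limits(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(size=100)
        assert th.variance_explained(obs, obs) == 1.0
        assert th.variance_explained(obs, np.full(100, obs.mean())) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            th.variance_explained(np.ones(5), np.ones(5))

    def test_variance_explained_matches_algebra(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(size=500)
        pred = obs + rng.normal(0, 0.5, 500)
        expected = 1 - np.sum((obs - pred) ** 2) / (np.var(obs) * obs.size)
        assert th.variance_explained(obs, pred) == pytest.approx(expected, rel=1e-12)

    def test_nonrandom_variance_fraction(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=500)
        identical = pd.DataFrame({f"ppi_r{r}": base for r in (1, 2, 3)})
        assert th.nonrandom_variance_fraction(identical) == pytest.approx(1.0)
        noise = pd.DataFrame(
            {f"ppi_r{r}": rng.normal(size=20_000) for r in (1, 2, 3)}
        )
        assert abs(th.nonrandom_variance_fraction(noise)) < 0.01
        two = pd.DataFrame({"ppi_r1": base, "ppi_r2": base + rng.normal(0, 1, 500)})
        r = np.corrcoef(two["ppi_r1"], two["ppi_r2"])[0, 1]
        assert th.nonrandom_variance_fraction(two) == pytest.approx(r * r)
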