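"""Weighted Bayesian line-difference model and guaranteed values."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from litvar.config import ChainConfig, LINE_DIFF_CHAIN
from litvar.diagnostics import mc_standard_error
from litvar.exceptions import ModelError, ValidationError
from litvar.linediff import (
    fit_weighted_linegen_model,
    gls_closed_form,
    guaranteed_value,
    line_contrasts,
)

SHORT = ChainConfig(iterations=12_000, burn_in=2_000, thin=5, seed=9)


def ve_frame(values, lines, gens, n_parities):
    return pd.DataFrame(
        {
            "doe": [f"d{i}" for i in range(len(values))],
            "line": lines,
            "generation": gens,
            "n_parities": n_parities,
            "ve": np.asarray(values, dtype=float),
            "vr": np.asarray(values, dtype=float),
            "sde": np.sqrt(np.asarray(values, dtype=float)),
        }
    )


class TestDefaults:
    def test_chain_defaults(self):
        assert (LINE_DIFF_CHAIN.iterations, LINE_DIFF_CHAIN.burn_in, LINE_DIFF_CHAIN.thin) == (
            60_000, 10_000, 10,
        )


class TestGLSClosedForm:
    def test_identity_design_returns_data(self):
        y = np.array([3.0, 1.0, 4.0])
        mean, cov = gls_closed_form(y, np.eye(3), np.ones(3), 2.0)
        assert np.allclose(mean, y)
        assert np.allclose(cov, 2.0 * np.eye(3))

    def test_toy_two_cell_hand_solution(self):
        # cells (records 0,1) and (2,3); weights c = Var(e_i)/sigma2
        y = np.array([1.0, 2.0, 5.0, 7.0])
        x = np.array([[1, 0], [1, 0], [0, 1], [0, 1.0]])
        c = np.array([1.0, 0.5, 1.0, 0.25])
        mean, cov = gls_closed_form(y, x, c, 1.0)
        # weighted means: (1*1 + 2*2)/3 and (1*5 + 4*7)/5
        assert np.allclose(mean, [5 / 3, 33 / 5])
        assert np.allclose(np.diag(cov), [1 / 3, 1 / 5])

    def test_rank_deficiency_detected(self):
        x = np.ones((4, 2))
        with pytest.raises(ModelError):
            gls_closed_form(np.zeros(4), x, np.ones(4), 1.0)


class TestGibbsSampler:
    def test_single_cell_posterior_mean_is_weighted_mean(self, rng):
        vals = rng.gamma(2.0, 2.0, 200)
        npar = rng.integers(2, 10, 200)
        df = ve_frame(vals, ["High"] * 200, [1] * 200, npar)
        post = fit_weighted_linegen_model(df, SHORT)
        from litvar.variance import ve_record_weights

        w = 1.0 / ve_record_weights(df)
        target = float((w * df["ve"]).sum() / w.sum())
        b = post.b_samples[:, 0]
        assert b.mean() == pytest.approx(target, abs=3 * mc_standard_error(b))

    def test_identical_cells_give_zero_difference(self, rng):
        vals = np.concatenate([rng.gamma(2, 2, 100)] * 2)
        df = ve_frame(vals, ["High"] * 100 + ["Low"] * 100, [1] * 200, 5)
        post = fit_weighted_linegen_model(df, SHORT)
        d = post.difference_samples(1)
        assert abs(d.mean()) < 4 * mc_standard_error(d)

    def test_posterior_matches_gls_closed_form(self, rng):
        """Cell-mean posterior equals the weighted LS solution (oracle equivalence)."""
        n = 300
        gens = rng.integers(1, 4, n)
        lines = np.where(rng.random(n) < 0.5, "High", "Low")
        vals = rng.gamma(2, 2, n) + 0.5 * gens
        npar = rng.integers(2, 10, n)
        df = ve_frame(vals, lines, gens, npar)
        post = fit_weighted_linegen_model(df, SHORT)
        from litvar.variance import ve_record_weights

        cells = post.cells
        x = np.zeros((n, len(cells)))
        for i, (l, g) in enumerate(zip(lines, gens)):
            x[i, cells.index((l, int(g)))] = 1.0
        mean, _ = gls_closed_form(df["ve"], x, ve_record_weights(df), 1.0)
        for j in range(len(cells)):
            b = post.b_samples[:, j]
            assert b.mean() == pytest.approx(mean[j], abs=3 * mc_standard_error(b))

    def test_empty_cell_rejected(self):
        df = ve_frame([1.0, 2.0], ["High", "High"], [1, 2], 4)
        post = fit_weighted_linegen_model(df, SHORT)
        with pytest.raises(ModelError):
            post.difference_samples(1)


class TestContrasts:
    def test_planted_difference_recovered(self, rng):
        delta = 2.0
        hi = rng.normal(5 + delta, 1.5, 150)
        lo = rng.normal(5, 1.5, 150)
        df = ve_frame(
            np.concatenate([hi, lo]),
            ["High"] * 150 + ["Low"] * 150,
            [10] * 300,
            rng.integers(4, 8, 300),
        )
        post = fit_weighted_linegen_model(df, SHORT)
        out = line_contrasts(post)
        row = out[out["generation"] == 10].iloc[0]
        # the posterior is centered on the realized (weighted) sample
        # difference, which scatters around the planted value with the
        # cell means' own sampling error
        from litvar.variance import ve_record_weights

        w = 1.0 / ve_record_weights(df)
        mask_hi = (df["line"] == "High").to_numpy()
        realized = (
            np.average(df["ve"][mask_hi], weights=w[mask_hi])
            - np.average(df["ve"][~mask_hi], weights=w[~mask_hi])
        )
        assert row["mean_diff"] == pytest.approx(realized, abs=0.05)
        assert row["ci_low"] < realized < row["ci_high"]
        se_realized = 1.5 * np.sqrt(2 / 150)
        assert row["mean_diff"] == pytest.approx(delta, abs=4 * se_realized)
        assert "guaranteed_80" in out.columns

    def test_homogeneous_weights_change_little(self, calibrated_experiment):
        """Robustness mirror: equal-variance refit gives nearly the same response."""
        ve = calibrated_experiment.ve_records
        post_w = fit_weighted_linegen_model(ve, SHORT)
        flat = ve.assign(n_parities=5)  # constant weights
        post_f = fit_weighted_linegen_model(flat, ChainConfig(12_000, 2_000, 5, seed=10))
        d_w = post_w.difference_samples(10).mean()
        d_f = post_f.difference_samples(10).mean()
        assert d_w == pytest.approx(d_f, abs=0.25)


class TestGuaranteedValue:
    def test_median_at_half(self, rng):
        x = rng.normal(3, 1, 50_001)
        assert guaranteed_value(x, 0.5) == pytest.approx(np.median(x))

    def test_standard_normal_eighty_percent(self, rng):
        x = rng.standard_normal(400_000)
        expected = scipy.stats.norm.ppf(0.2)
        assert guaranteed_value(x, 0.8) == pytest.approx(expected, abs=0.01)

    def test_monotone_decreasing_in_probability(self, rng):
        x = rng.gamma(3, 1, 10_000)
        ps = [0.1, 0.3, 0.5, 0.7, 0.9]
        ks = [guaranteed_value(x, p) for p in ps]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_empty_and_bad_probability(self):
        with pytest.raises(ValidationError):
            guaranteed_value([], 0.8)
        with pytest.raises(ValidationError):
            guaranteed_value([1.0], 1.5)
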