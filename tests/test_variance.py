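"""Intra-doe variance estimator, record weights and pre-correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litvar.exceptions import ModelError, ValidationError
from litvar.variance import (
    build_ve_records,
    fit_precorrection,
    intra_doe_variance,
    precorrect,
    record_weight,
)


class TestIntraDoeVariance:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([5, 7], 2 / 3),
            ([8, 8, 8, 8], 0.0),
            ([6, 8, 10, 12], 4.0),
        ],
    )
    def test_divisor_n_plus_one(self, values, expected):
        assert intra_doe_variance(values) == pytest.approx(expected)

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            n = rng.integers(2, 10)
            x = rng.normal(8, 3, n)
            brute = sum((xi - x.mean()) ** 2 for xi in x) / (n + 1)
            assert intra_doe_variance(x) == pytest.approx(brute)

    def test_relation_to_unbiased_variance(self, rng):
        x = rng.normal(0, 2, 7)
        n = len(x)
        assert intra_doe_variance(x) * (n + 1) / (n - 1) == pytest.approx(
            np.var(x, ddof=1)
        )

    @given(
        x=st.lists(st.floats(-50, 50), min_size=2, max_size=9),
        a=st.floats(-5, 5),
        b=st.floats(-20, 20),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_affine_scaling(self, x, a, b):
        """V(a x + b) = a^2 V(x): quadratic in scale, translation invariant."""
        x = np.asarray(x)
        v = intra_doe_variance(x)
        va = intra_doe_variance(a * x + b)
        assert va == pytest.approx(a**2 * v, abs=1e-6 * max(1.0, abs(a**2 * v)))

    def test_single_parity_rejected(self):
        with pytest.raises(ValidationError):
            intra_doe_variance([4.0])


class TestRecordWeight:
    @pytest.mark.parametrize("n, expected", [(2, 2 / 9), (3, 0.25), (9, 0.16)])
    def test_formula(self, n, expected):
        assert record_weight(n) == pytest.approx(expected)

    def test_maximum_at_three_parities(self):
        weights = {n: record_weight(n) for n in range(2, 51)}
        assert max(weights, key=weights.get) == 3

    def test_rejects_below_two(self):
        with pytest.raises(ValidationError):
            record_weight(1)


class TestPrecorrection:
    def test_constant_records_give_zero_effects(self):
        df = pd.DataFrame(
            {
                "doe": ["a", "a", "b", "b"],
                "parity": [1, 2, 1, 2],
                "year_season": ["s1", "s2", "s1", "s2"],
                "lactation_class": ["first", "later_lactating", "later_lactating", "first"],
                "litter_size": [9, 9, 9, 9],
            }
        )
        eff = fit_precorrection(df)
        assert all(v == pytest.approx(0) for v in eff.year_season.values())
        assert all(v == pytest.approx(0) for v in eff.parity_lactation.values())

    def test_two_season_toy_least_squares(self):
        df = pd.DataFrame(
            {
                "doe": ["a", "b", "c", "d"],
                "parity": [1] * 4,
                "year_season": ["A", "A", "B", "B"],
                "lactation_class": ["first"] * 4,
                "litter_size": [10, 10, 8, 8],
            }
        )
        eff = fit_precorrection(df)
        assert eff.year_season["B"] - eff.year_season["A"] == pytest.approx(-2.0)
        corrected = precorrect(df, eff)
        assert corrected == pytest.approx([10, 10, 10, 10])

    def test_three_lactation_levels_estimated(self, toy_litters):
        eff = fit_precorrection(toy_litters)
        assert len(eff.parity_lactation) == 3

    def test_confounded_design_rejected(self):
        df = pd.DataFrame(
            {
                "doe": ["a", "b"],
                "parity": [1, 1],
                "year_season": ["A", "B"],
                "lactation_class": ["first", "later_lactating"],
                "litter_size": [9, 7],
            }
        )
        with pytest.raises(ModelError, match="rank"):
            fit_precorrection(df)

    def test_unseen_level_rejected(self, toy_litters):
        eff = fit_precorrection(toy_litters)
        other = toy_litters.assign(year_season="s99")
        with pytest.raises(ValidationError):
            precorrect(other, eff)


class TestBuildVeRecords:
    def test_matches_independent_recomputation(self, toy_litters):
        eff = fit_precorrection(toy_litters)
        ve = build_ve_records(toy_litters, eff).set_index("doe")
        corrected = toy_litters.assign(_c=precorrect(toy_litters, eff))
        for doe in ("d1", "d2"):
            grp = corrected[corrected["doe"] == doe]
            x = grp["_c"].to_numpy()
            expected = np.sum((x - x.mean()) ** 2) / (len(x) + 1)
            assert ve.loc[doe, "ve"] == pytest.approx(expected)
            raw = grp["litter_size"].to_numpy(dtype=float)
            vr = np.sum((raw - raw.mean()) ** 2) / (len(raw) + 1)
            assert ve.loc[doe, "vr"] == pytest.approx(vr)
            assert ve.loc[doe, "sde"] == pytest.approx(np.sqrt(ve.loc[doe, "ve"]))

    def test_single_parity_doe_excluded(self, toy_litters):
        eff = fit_precorrection(toy_litters)
        ve = build_ve_records(toy_litters, eff)
        assert "d3" not in set(ve["doe"])
        assert ve.attrs["n_excluded"] == 1

    def test_zero_effects_make_ve_equal_vr(self, toy_litters):
        eff = fit_precorrection(toy_litters)
        zero = type(eff)(
            year_season={k: 0.0 for k in eff.year_season},
            parity_lactation={k: 0.0 for k in eff.parity_lactation},
            reference=eff.reference,
        )
        ve = build_ve_records(toy_litters, zero)
        assert np.allclose(ve["ve"], ve["vr"])

    def test_global_shift_leaves_ve_unchanged(self, toy_litters):
        eff = fit_precorrection(toy_litters)
        ve0 = build_ve_records(toy_litters, eff)
        shifted = toy_litters.assign(litter_size=toy_litters["litter_size"] + 5)
        ve1 = build_ve_records(shifted, fit_precorrection(shifted))
        assert np.allclose(ve0["ve"], ve1["ve"])
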