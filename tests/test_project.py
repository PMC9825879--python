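"""Shift formula, ensemble congruence and plasticity classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlpshift import model, project


class TestDeltaPsi:
    @pytest.mark.parametrize(
        "measured,predicted,expected",
        [(-2.0, -2.0, 0.0), (-2.0, -2.5, 25.0), (-2.0, -1.5, -25.0)],
    )
    def test_worked_examples(self, measured, predicted, expected):
        assert project.delta_psi_tlp(measured, predicted) == pytest.approx(
            expected
        )

    def test_sign_convention_more_negative_is_positive(self):
        # a shift toward more negative Psi_tlp yields a positive percentage
        assert project.delta_psi_tlp(-2.0, -3.0) > 0

    @given(
        st.floats(-5.0, -0.1), st.floats(-5.0, -0.1)
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, m, p):
        left = project.delta_psi_tlp(m, p)
        right = project.delta_psi_tlp(m, 2 * m - p)
        assert left == pytest.approx(-right, abs=1e-9)

    def test_nonnegative_measured_rejected(self):
        with pytest.raises(ValueError):
            project.delta_psi_tlp(0.0, -1.0)


def _preds(values, cell="c1"):
    return pd.DataFrame(
        {
            "cell_id": cell,
            "model": [f"m{i}" for i in range(len(values))],
            "psi_tlp_mpa": values,
        }
    )


class TestEnsembleCongruence:
    def test_identical_predictions_zero_cv(self):
        out = project.ensemble_and_congruence(_preds([-2.0, -2.0, -2.0]))
        assert out.loc[0, "ensemble_psi_tlp_mpa"] == pytest.approx(-2.0)
        assert out.loc[0, "congruence_cv_pct"] == pytest.approx(0.0)

    def test_hand_computed_cv(self):
        out = project.ensemble_and_congruence(_preds([-1.0, -2.0, -3.0]))
        assert out.loc[0, "ensemble_psi_tlp_mpa"] == pytest.approx(-2.0)
        assert out.loc[0, "congruence_cv_pct"] == pytest.approx(50.0)

    def test_two_model_cv(self):
        out = project.ensemble_and_congruence(_preds([-2.0, -2.2]))
        assert out.loc[0, "ensemble_psi_tlp_mpa"] == pytest.approx(-2.1)
        assert out.loc[0, "congruence_cv_pct"] == pytest.approx(
            6.734, abs=1e-3
        )

    def test_model_relabeling_invariance(self):
        a = project.ensemble_and_congruence(_preds([-1.0, -2.5, -3.0]))
        df = _preds([-3.0, -1.0, -2.5])  # same values, different labels
        b = project.ensemble_and_congruence(df)
        pd.testing.assert_frame_equal(a, b)

    def test_single_model_warns_and_leaves_cv_missing(self):
        with pytest.warns(UserWarning, match="single-model"):
            out = project.ensemble_and_congruence(_preds([-2.0]))
        assert out.loc[0, "ensemble_psi_tlp_mpa"] == pytest.approx(-2.0)
        assert np.isnan(out.loc[0, "congruence_cv_pct"])


def interval_oracle(psi, predicted, delta):
    """Exhaustive closed-interval membership check."""
    lo, hi = psi - delta, psi + delta
    if predicted < lo:
        return "above"  # envelope lies above the prediction
    if predicted > hi:
        return "below"
    return "within"


class TestPlasticityRisk:
    def test_median_prediction_within(self):
        row = project.plasticity_risk([-2.0], -2.0, 0.44)
        assert row["pct_within"] == 100.0
        assert row["pct_threatened"] == 0.0

    def test_prediction_below_envelope_is_threat(self):
        row = project.plasticity_risk([-2.0], -2.5, 0.44)
        assert row["pct_envelope_above"] == 100.0
        assert row["pct_threatened"] == 100.0

    def test_four_species_example(self):
        row = project.plasticity_risk(
            [-1.0, -2.0, -3.0, -2.1], -2.0, 0.22
        )
        assert row["pct_within"] == pytest.approx(50.0)
        assert row["pct_threatened"] == pytest.approx(50.0)

    def test_bound_counts_as_within(self):
        row = project.plasticity_risk([-2.0], -2.44, 0.44)
        assert row["pct_within"] == 100.0

    def test_percentages_sum_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            psi = -rng.uniform(0.5, 4.0, rng.integers(1, 9))
            row = project.plasticity_risk(
                psi, -rng.uniform(0.5, 4.0), rng.uniform(0.05, 1.0)
            )
            total = (
                row["pct_envelope_below"]
                + row["pct_within"]
                + row["pct_envelope_above"]
            )
            assert total == 100.0

    def test_within_nondecreasing_in_delta(self):
        rng = np.random.default_rng(1)
        psi = -rng.uniform(0.5, 4.0, 20)
        pred = -2.0
        within = [
            project.plasticity_risk(psi, pred, d)["pct_within"]
            for d in (0.1, 0.22, 0.44, 1.0)
        ]
        assert within == sorted(within)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_interval_oracle(self, seed):
        rng = np.random.default_rng(seed)
        psi = float(-rng.uniform(0.5, 4.0))
        pred = float(-rng.uniform(0.5, 4.0))
        delta = float(rng.uniform(0.05, 1.0))
        row = project.plasticity_risk([psi], pred, delta)
        verdict = interval_oracle(psi, pred, delta)
        assert row[f"pct_{'within' if verdict == 'within' else 'envelope_' + verdict}"] == 100.0

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            project.plasticity_risk([], -2.0, 0.44)

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            project.plasticity_risk([-2.0], -2.0, 0.0)


def _constant_suite(n_models=1):
    """Fits trained on a constant target: predictions equal the measured
    value everywhere, so the identity-future suite must report zero shift."""
    rng = np.random.default_rng(5)
    n = 30
    cells = [f"c{i:02d}" for i in range(n)]
    X = pd.DataFrame(
        {
            "b1": rng.normal(size=n),
            "b2": rng.normal(size=n),
        }
    )
    X.insert(0, "cell_id", cells)
    cent = rng.uniform(0, 5, size=(n, 2))
    y = np.full(n, -2.0)
    cfg = model.ModelConfig(
        ntree=20, outer_reps=1, inner_folds=2, inner_evals=2, seed=5
    )
    fits = {}
    for m in range(n_models):
        for group in ("angiosperm", "gymnosperm"):
            fits[(group, f"m{m}")] = model.tune_final_model(
                X[["b1", "b2"]], y, cent, cfg, group=group,
                climate_model=f"m{m}",
            )
    measured = {
        g: pd.DataFrame(
            {"cell_id": cells, "group": g, "psi_tlp_mpa": y,
             "n_species": 1, "coverage": 1.0, "flag": "measured"}
        )
        for g in ("angiosperm", "gymnosperm")
    }
    future = {
        ("rcp85", f"m{m}"): X.copy() for m in range(n_models)
    }
    occurrences = pd.DataFrame(
        {"sp1": 1, "sp2": 1},
        index=pd.Index(cells, name="cell_id"),
    )
    traits_df = pd.DataFrame(
        {
            "species_id": ["sp1", "sp2"],
            "group": ["angiosperm", "gymnosperm"],
            "growth_form": ["herbaceous", "woody"],
            "psi_tlp_mpa": [-2.0, -2.0],
        }
    )
    return fits, future, measured, occurrences, traits_df


class TestProjectionSuite:
    def test_identity_future_zero_shift_all_within(self):
        fits, future, measured, occ, tr = _constant_suite()
        with pytest.warns(UserWarning, match="single-model"):
            res = project.run_projection_suite(
                fits, future, measured, occ, tr, "rcp85"
            )
        assert np.allclose(res.projections["delta_psi_tlp_pct"], 0.0)
        assert (res.plasticity["pct_within"] == 100.0).all()
        assert (res.regional["mean_threatened_pct"] == 0.0).all()

    def test_delta_nesting_between_plasticity_levels(self):
        fits, future, measured, occ, tr = _constant_suite(n_models=2)
        res = project.run_projection_suite(
            fits, future, measured, occ, tr, "rcp85", deltas=(0.44, 0.22)
        )
        wide = res.plasticity.pivot_table(
            index=["cell_id", "group"], columns="delta_mpa",
            values="pct_threatened",
        )
        assert (wide[0.22] >= wide[0.44]).all()

    def test_missing_fit_combination_rejected(self):
        fits, future, measured, occ, tr = _constant_suite(n_models=2)
        del fits[("gymnosperm", "m1")]
        with pytest.raises(ValueError, match="gymnosperm"):
            project.run_projection_suite(
                fits, future, measured, occ, tr, "rcp85"
            )

    def test_unknown_high_emission_scenario_rejected(self):
        fits, future, measured, occ, tr = _constant_suite()
        with pytest.raises(ValueError, match="rcp99"):
            project.run_projection_suite(
                fits, future, measured, occ, tr, "rcp99"
            )


def test_warming_shifts_lowlands_more_than_highlands():
    """Truth coupled to temperature extremes on both flanks: heat lowers
    Psi_tlp, and so does frost-drought exposure (long consecutive-frost
    runs). Warming then deepens lowland Psi_tlp while collapsing frost
    runs raises it in the mountains, so the relative shift must be larger
    (more positive) in lowland than in highland cells."""
    from tlpshift import climate, synthgen

    reg = synthgen.generate_region(6, 8, 2, seed=9)
    tm = synthgen.TruthModel(
        trait_intercept=-1.0,
        trait_coefficients={"bio1_95_c": -0.04, "cfd_ann_days": -0.01},
        noise_sd=0.02,
    )
    w = climate.overlap_weights(reg.cells, reg.climate_cells)
    tabs = {}
    for scen, shift in (
        ("historical", (0.0, 1.0)),
        ("rcp85", (4.0, 0.8)),
    ):
        cube = synthgen.generate_daily_climate(
            reg, 20, shift, tm, seed=9, scenario_id=scen
        )
        t = climate.period_tables(cube, {"full": (0, 19)})
        tabs[scen] = climate.extract_survey_values(
            t.drop(columns=["period"]), w
        ).set_index("cell_id")

    predictors = list(synthgen.PREDICTORS)
    X = tabs["historical"][predictors]
    y = synthgen.generate_trait_response(X, tm, seed=9)
    cent = reg.cells.set_index("cell_id").loc[X.index, ["lon", "lat"]]
    cfg = model.ModelConfig(
        ntree=100, outer_reps=1, inner_folds=3, inner_evals=6, seed=9
    )
    fit = model.tune_final_model(X, y, cent.to_numpy(), cfg)
    pred = fit.predict(tabs["rcp85"][predictors])
    delta = project.delta_psi_tlp(y.to_numpy(), pred)

    elev = reg.cells.set_index("cell_id").loc[X.index, "elevation_m"]
    med = elev.median()
    lowland = delta[(elev < med).to_numpy()].mean()
    highland = delta[(elev >= med).to_numpy()].mean()
    assert lowland > 0  # shift toward more negative Psi_tlp
    assert lowland > highland
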