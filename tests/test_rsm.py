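"""Quadratic response-surface fitting and its diagnostic statistics."""

import numpy as np
import pytest

from formudoe import (
    DesignMatrix,
    DesignSpec,
    FactorDef,
    ResponseSurface,
    build_ccd,
    quadratic_matrix,
    quadratic_row,
    quadratic_terms,
)
from formudoe.errors import DegenerateResponseError, SingularDesignError
from formudoe.simulate import simulate_design_responses


@pytest.mark.parametrize(
    "x,expected",
    [
        ((0, 0, 0), [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]),
        ((1, 1, 1), [1] * 10),
        ((1, 2, 3), [1, 1, 2, 3, 2, 3, 6, 1, 4, 9]),
    ],
)
def test_quadratic_row_ordering(x, expected):
    assert np.allclose(quadratic_row(x), expected)


def test_term_labels_align_with_columns():
    terms = quadratic_terms(["a", "b", "c"])
    assert terms == [
        "Intercept", "a", "b", "c", "a*b", "a*c", "b*c", "a^2", "b^2", "c^2",
    ]
    assert len(terms) == quadratic_matrix([[1.0, 2.0, 3.0]]).shape[1]


def _unit_factors(k=3):
    return [FactorDef(f"x{i}", 0.0, 1.0) for i in range(k)]


TRUE_BETA = {
    "Intercept": 50.0, "x0": 4.0, "x1": -3.0, "x2": 1.5,
    "x0*x1": 2.0, "x0*x2": -1.0, "x1*x2": 0.5,
    "x0^2": -2.5, "x1^2": 1.2, "x2^2": -0.7,
}


def test_noiseless_fit_recovers_generating_coefficients():
    dm = build_ccd(DesignSpec(_unit_factors(), n_center=6))
    dm = simulate_design_responses(dm, TRUE_BETA, noise_sd=0.0)
    res = ResponseSurface(dm, "y").fit()
    for term, value in TRUE_BETA.items():
        assert res.params[term] == pytest.approx(value, abs=1e-8)
    assert res.r2 == pytest.approx(1.0, abs=1e-12)
    assert res.press == pytest.approx(0.0, abs=1e-12)
    assert res.pred_r2 == pytest.approx(1.0, abs=1e-10)
    assert res.adequate_precision == np.inf
    assert res.term_significance().isna().all()


def test_coefficient_recovery_improves_as_noise_vanishes():
    dm = build_ccd(DesignSpec(_unit_factors(), n_center=6))
    beta = np.array(list(TRUE_BETA.values()))
    rmses = []
    for sd in (1.0, 0.1, 0.01):
        sim = simulate_design_responses(dm, TRUE_BETA, noise_sd=sd, seed=11)
        res = ResponseSurface(sim, "y").fit()
        rmses.append(float(np.sqrt(np.mean((res.params.values - beta) ** 2))))
    assert rmses[0] > rmses[1] > rmses[2]


def _random_design(rng, n=16, k=3):
    coded = rng.uniform(-1.5, 1.5, size=(n, k))
    y = rng.normal(size=n)
    return DesignMatrix(_unit_factors(k), coded).with_responses(y=y)


def _brute_force_press(dm):
    """Leave-one-out refits, the independent oracle for the hat-matrix PRESS."""
    X = quadratic_matrix(dm.coded)
    y = dm.response("y")
    press = 0.0
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        press += (y[i] - X[i] @ beta) ** 2
    return press


def test_press_shortcut_equals_leave_one_out_refits():
    rng = np.random.default_rng(42)
    for _ in range(10):
        dm = _random_design(rng)
        res = ResponseSurface(dm, "y").fit()
        oracle = _brute_force_press(dm)
        assert res.press == pytest.approx(oracle, rel=1e-8)


def test_fit_is_invariant_to_coded_vs_actual_units(study_design):
    for name in ("size_nm", "ee_pct", "dl_pct"):
        coded = ResponseSurface(study_design, name, scale="coded").fit()
        actual = ResponseSurface(study_design, name, scale="actual").fit()
        assert abs(coded.r2 - actual.r2) < 1e-10
        assert abs(coded.adj_r2 - actual.adj_r2) < 1e-10
        assert abs(coded.pred_r2 - actual.pred_r2) < 1e-10
        assert abs(coded.f_pvalue - actual.f_pvalue) < 1e-10
        assert np.allclose(coded.fittedvalues, actual.fittedvalues, atol=1e-8)
        # ...but the coefficient vectors genuinely differ
        assert not np.allclose(coded.params.values, actual.params.values)


def test_r2_orderings_hold_on_real_data(fitted_models):
    for res in fitted_models.values():
        assert res.adj_r2 <= res.r2
        assert res.pred_r2 <= res.r2
        assert 0.0 <= res.r2 <= 1.0


def test_adequate_precision_definition_and_scaling(fitted_models):
    res = fitted_models["size_nm"]
    signal = res.fittedvalues.max() - res.fittedvalues.min()
    expected = signal / np.sqrt(res.p * res.mse_resid / res.n)
    assert res.adequate_precision == pytest.approx(expected, rel=1e-12)
    # doubling the MSE at fixed predictions divides the statistic by sqrt(2)
    halved = signal / np.sqrt(res.p * (2 * res.mse_resid) / res.n)
    assert halved == pytest.approx(expected / np.sqrt(2), rel=1e-12)


def test_strong_effect_is_detected_as_significant():
    dm = build_ccd(DesignSpec(_unit_factors(), n_center=6))
    dm = simulate_design_responses(
        dm, {"Intercept": 5.0, "x0": 10.0}, noise_sd=0.1, seed=3
    )
    res = ResponseSurface(dm, "y").fit()
    assert res.term_significance()["x0"] < 1e-3
    # genuinely zero coefficients should look like noise
    assert abs(res.params["x1*x2"]) < 0.5


def test_reduced_term_list_fits_fewer_parameters(study_design):
    terms = ["Intercept", "finasteride_mM", "total_lipid_mM", "cholesterol_pct"]
    res = ResponseSurface(study_design, "size_nm", terms=terms).fit()
    assert res.p == 4
    assert list(res.params.index) == terms


def test_rank_deficient_design_raises():
    coded = np.zeros((12, 3))  # all center points: only the intercept is seen
    dm = DesignMatrix(_unit_factors(), coded).with_responses(y=np.arange(12.0))
    with pytest.raises(SingularDesignError):
        ResponseSurface(dm, "y").fit()


def test_constant_response_raises(study_design):
    dm = study_design.with_responses(flat=np.full(study_design.n_runs, 7.0))
    with pytest.raises(DegenerateResponseError):
        ResponseSurface(dm, "flat").fit()


def test_json_report_round_trips_through_stored_surface(tmp_path, fitted_models):
    from formudoe import StoredSurface

    res = fitted_models["ee_pct"]
    path = tmp_path / "ee.json"
    res.to_json(path)
    stored = StoredSurface.from_json(path)
    pts = np.array([[0.0, 0.0, 0.0], [1.0, -1.0, 1.0], [0.3, 0.2, -0.7]])
    assert np.allclose(stored.predict(pts), res.predict(pts), atol=1e-10)
    assert stored.response_name == "ee_pct"


def test_summary_and_equation_render(fitted_models):
    res = fitted_models["size_nm"]
    text = res.summary()
    assert "R^2" in text and "adequate precision" in text
    assert res.equation().startswith("size_nm = ")
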