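"""Entrapment, loading, permeation and Draize irritation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from formudoe import (
    DraizeRecord,
    PermeationSeries,
    classify_pii,
    cumulative_permeation,
    draize_pii,
    drug_loading,
    entrapment_efficiency,
    transfollicular_cumulation,
)
from formudoe.errors import AlignmentError
from formudoe.simulate import simulate_permeation_sampling


@pytest.mark.parametrize(
    "total,free,expected",
    [(10.0, 0.0, 100.0), (10.0, 10.0, 0.0), (10.0, 2.0, 80.0)],
)
def test_entrapment_efficiency_examples(total, free, expected):
    assert entrapment_efficiency(total, free) == pytest.approx(expected)


@pytest.mark.parametrize(
    "total,free,lipid,expected",
    [(5.0, 5.0, 20.0, 0.0), (25.0, 5.0, 20.0, 50.0), (6.0, 1.0, 20.0, 20.0)],
)
def test_drug_loading_examples(total, free, lipid, expected):
    assert drug_loading(total, free, lipid) == pytest.approx(expected)


@settings(max_examples=100, derandomize=True)
@given(
    total=st.floats(0.1, 1e3),
    frac=st.floats(0, 1),
    lipid=st.floats(0.1, 1e3),
)
def test_metric_ranges(total, frac, lipid):
    free = total * frac
    assert 0.0 <= entrapment_efficiency(total, free) <= 100.0 + 1e-12
    assert 0.0 <= drug_loading(total, free, lipid) < 100.0


def test_invalid_assay_inputs():
    with pytest.raises(ValueError):
        entrapment_efficiency(10.0, 11.0)
    with pytest.raises(ValueError):
        entrapment_efficiency(0.0, 0.0)
    with pytest.raises(ValueError):
        drug_loading(10.0, 2.0, 0.0)


class TestPermeation:
    def test_single_timepoint_is_concentration_times_volume_per_area(self):
        series = PermeationSeries([2.0], [1.0], receptor_volume=12.0,
                                  sample_volume=0.5, diffusion_area=3.5)
        assert cumulative_permeation(series)[0] == pytest.approx(12.0 / 3.5)

    def test_all_zero_concentrations(self):
        series = PermeationSeries([1, 2, 4], np.zeros(3), receptor_volume=12.0)
        assert np.all(cumulative_permeation(series) == 0.0)

    def test_correction_recovers_constant_flux_truth(self):
        times = np.array([0.5, 1, 2, 4, 8, 12, 24])
        t, observed, truth = simulate_permeation_sampling(
            times, transepidermal_flux=0.8, receptor_volume=12.0,
            sample_volume=0.5, diffusion_area=3.5)
        series = PermeationSeries(t, observed, 12.0, 0.5, 3.5)
        assert np.allclose(cumulative_permeation(series), truth, atol=1e-6)

    def test_invariant_to_splitting_a_sampling_interval(self):
        coarse = np.array([1.0, 4.0, 8.0])
        fine = np.array([1.0, 2.0, 4.0, 8.0])
        kw = dict(transepidermal_flux=1.1, receptor_volume=12.0,
                  sample_volume=0.5, diffusion_area=3.5)
        _, obs_c, _ = simulate_permeation_sampling(coarse, **kw)
        _, obs_f, _ = simulate_permeation_sampling(fine, **kw)
        q_coarse = cumulative_permeation(PermeationSeries(coarse, obs_c, 12.0))
        q_fine = cumulative_permeation(PermeationSeries(fine, obs_f, 12.0))
        assert q_fine[[0, 2, 3]] == pytest.approx(q_coarse, abs=1e-9)

    def test_sample_volume_must_fit_in_receptor(self):
        with pytest.raises(ValueError):
            PermeationSeries([1.0], [1.0], receptor_volume=0.4,
                             sample_volume=0.5)


class TestTransfollicular:
    def test_scalar_examples(self):
        assert transfollicular_cumulation(7.0, 7.0) == 0.0
        assert transfollicular_cumulation(10.0, 4.0) == 6.0

    def test_difference_plus_blocked_reconstructs_full(self):
        rng = np.random.default_rng(5)
        full = rng.uniform(1, 10, 6)
        blocked = full * rng.uniform(0, 1, 6)
        trans = transfollicular_cumulation(full, blocked)
        assert np.allclose(trans + blocked, full)

    def test_two_route_simulation_recovers_follicular_component(self):
        times = np.array([1, 2, 4, 8, 24], dtype=float)
        kw = dict(receptor_volume=12.0, sample_volume=0.5, diffusion_area=3.5)
        _, obs_full, _ = simulate_permeation_sampling(
            times, transepidermal_flux=0.5, follicular_flux=0.3, **kw)
        _, obs_blocked, _ = simulate_permeation_sampling(
            times, transepidermal_flux=0.5, follicular_flux=0.0, **kw)
        q_full = cumulative_permeation(PermeationSeries(times, obs_full, 12.0))
        q_blocked = cumulative_permeation(
            PermeationSeries(times, obs_blocked, 12.0))
        trans = transfollicular_cumulation(q_full, q_blocked, times, times)
        assert np.allclose(trans, 0.3 * times, atol=1e-6)

    def test_mismatched_grids_raise(self):
        with pytest.raises(AlignmentError):
            transfollicular_cumulation([1.0, 2.0], [0.5, 1.0],
                                       [1.0, 2.0], [1.0, 3.0])
        with pytest.raises(AlignmentError):
            transfollicular_cumulation([1.0, 2.0], [0.5])


class TestDraize:
    def test_surfactant_positive_control_is_slight_irritation(self):
        rec = DraizeRecord("SLS", [(1, 1.5, 0), (24, 1.5, 0),
                                   (48, 1.25, 0), (72, 1.0, 0)])
        pii, label = draize_pii(rec)
        # 5.25 / 8 = 0.65625; 2-dp report
        assert pii == pytest.approx(0.66, abs=0.01)
        assert label == "Slight irritation"

    def test_all_zero_scores_mean_no_irritation(self):
        rec = DraizeRecord("blank", [(t, 0, 0) for t in (1, 24, 48, 72)])
        assert draize_pii(rec) == (0.0, "No irritation")

    def test_maximal_scores(self):
        rec = DraizeRecord("max", [(t, 4, 4) for t in (1, 24, 48, 72)])
        pii, label = draize_pii(rec)
        assert pii == 4.0
        assert label == "Moderate irritation"

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(
        st.tuples(st.floats(0, 4), st.floats(0, 4)), min_size=1, max_size=6,
    ))
    def test_pii_equals_plain_mean_of_all_scores(self, pairs):
        obs = [(float(i), ery, ede) for i, (ery, ede) in enumerate(pairs)]
        pii, _ = draize_pii(DraizeRecord("g", obs))
        oracle = np.mean([s for _, e, d in obs for s in (e, d)])
        assert pii == pytest.approx(round(float(oracle), 2), abs=1e-12)

    @pytest.mark.parametrize(
        "pii,label",
        [
            (0.0, "No irritation"), (0.4, "No irritation"),
            (0.5, "Slight irritation"), (1.9, "Slight irritation"),
            (2.0, "Moderate irritation"), (4.9, "Moderate irritation"),
            (5.0, "Severe irritation"), (8.0, "Severe irritation"),
        ],
    )
    def test_classification_bands(self, pii, label):
        assert classify_pii(pii) == label

    def test_score_validation(self):
        with pytest.raises(ValueError):
            DraizeRecord("bad", [(1, 5.0, 0)])
        with pytest.raises(ValueError):
            DraizeRecord("bad", [(1, 1, 0), (1, 1, 0)])
        with pytest.raises(ValueError):
            DraizeRecord("bad", [])
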