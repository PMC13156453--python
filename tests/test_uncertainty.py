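"""Monte-Carlo error propagation, mode sweeps and the safety budget."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sarbound import (EmptyErrorRegionError, ExcitationMode, MeasuredB1Set,
                      MixingTruth, decompose_circular, estimate_eemm,
                      generate_measured, probe_validation_report,
                      required_mode_count, safety_budget, sample_perturbations,
                      sweep_modes)
from sarbound.metrics import PerChannelErrors


@pytest.fixture(scope="module")
def measured(fieldset):
    truth = MixingTruth.random(8, seed=42)
    return generate_measured(fieldset, truth)


@pytest.fixture(scope="module")
def error_space(fieldset, measured, probe_qset, cp_mode):
    return estimate_eemm(fieldset, measured, probe_qset, cp_mode, n=5000, seed=3)


class TestSamplePerturbations:
    def test_box_constraint_holds_for_all_draws(self, cp_mode):
        eps = np.array([0.1, 0.05, 0.2, 0.0, 0.15, 0.08, 0.12, 0.3])
        _, lam = sample_perturbations(cp_mode, eps, n=10_000, seed=0)
        assert np.all(np.abs(lam.real) <= eps[None, :])
        assert np.all(np.abs(lam.imag) <= eps[None, :])

    def test_zero_bounds_give_unperturbed_modes(self, cp_mode):
        W, lam = sample_perturbations(cp_mode, np.zeros(8), n=100, seed=1)
        assert np.all(lam == 0)
        assert np.all(W == cp_mode.weights[None, :])

    def test_mean_perturbation_is_centered(self, cp_mode):
        # CLT: uniform(-b, b) has sd b/sqrt(3); |mean| <= 5 sd/sqrt(n)
        n = 100_000
        b = 0.2
        _, lam = sample_perturbations(cp_mode, np.full(8, b), n=n, seed=2)
        tol = 5 * b / np.sqrt(3 * n)
        assert np.all(np.abs(lam.real.mean(axis=0)) <= tol)
        assert np.all(np.abs(lam.imag.mean(axis=0)) <= tol)

    def test_reproducible_given_seed(self, cp_mode):
        W1, _ = sample_perturbations(cp_mode, np.full(8, 0.1), n=50, seed=9)
        W2, _ = sample_perturbations(cp_mode, np.full(8, 0.1), n=50, seed=9)
        assert np.array_equal(W1, W2)

    def test_negative_bounds_rejected(self, cp_mode):
        with pytest.raises(ValueError):
            sample_perturbations(cp_mode, np.array([0.1] * 7 + [-0.1]), n=10)

    def test_off_channels_use_median_scale(self):
        mode = ExcitationMode(weights=np.array([2.0, 0.0, 2.0, 2.0]))
        W, lam = sample_perturbations(mode, np.full(4, 0.1), n=200, seed=4)
        # channel 1 is off: perturbed by lambda * median(|w|) = 2*lambda
        assert np.allclose(W[:, 1], lam[:, 1] * 2.0)


class TestEstimateEemm:
    def test_selection_definition(self, error_space):
        assert np.array_equal(error_space.selection,
                              error_space.nrmse_i <= error_space.nrmse_0)

    def test_rel_dev_definition(self, error_space):
        assert np.allclose(error_space.rel_dev,
                           (error_space.psar_i - error_space.psar_0) / error_space.psar_0)

    def test_identical_measurement_is_degenerate_fixed_point(
            self, fieldset, probe_qset, cp_mode):
        bplus = decompose_circular(fieldset).b_plus
        meas = MeasuredB1Set(b_plus_meas=bplus.copy(), eval_mask=fieldset.phantom.mask)
        with pytest.warns(UserWarning, match="NRMSE0 = 0"):
            es = estimate_eemm(fieldset, meas, probe_qset, cp_mode, n=500, seed=0)
        assert es.nrmse_0 == 0.0
        assert es.e_emm == 0.0
        assert np.all(es.bounds == 0)
        assert np.all(es.rel_dev == 0)

    def test_empty_error_region_raises(self, fieldset, probe_qset):
        # per-channel errors with alternating sign cancel almost exactly in
        # the zero-phase mode map: NRMSE0 is tiny while the per-channel
        # bounds are large, so no finite sample of box draws reaches
        # NRMSEi <= NRMSE0 and the inconsistency must be reported
        rng = np.random.default_rng(8)
        bplus = decompose_circular(fieldset).b_plus
        shape = bplus.shape[1:]
        g = rng.normal(size=shape) + 1j * rng.normal(size=shape)
        g *= 0.05 * np.median(np.abs(bplus)) / np.median(np.abs(g))
        h = 1e-4 * g * rng.normal(size=shape)
        signs = (-1.0) ** np.arange(8)
        meas_maps = bplus + signs[:, None, None, None] * g[None] + h[None]
        meas = MeasuredB1Set(b_plus_meas=meas_maps, eval_mask=fieldset.phantom.mask)
        zero_phase = ExcitationMode(weights=np.ones(8, complex), label="zero-phase")
        with pytest.raises(EmptyErrorRegionError):
            estimate_eemm(fieldset, meas, probe_qset, zero_phase, n=200, seed=0)

    def test_deterministic_under_seed(self, fieldset, measured, probe_qset, cp_mode):
        es1 = estimate_eemm(fieldset, measured, probe_qset, cp_mode, n=2000, seed=7)
        es2 = estimate_eemm(fieldset, measured, probe_qset, cp_mode, n=2000, seed=7)
        assert es1.e_emm == es2.e_emm
        assert np.array_equal(es1.nrmse_i, es2.nrmse_i)
        assert np.array_equal(es1.psar_i, es2.psar_i)

    def test_percentile_monotonicity(self, error_space):
        e100 = error_space.percentile_eemm(100.0)
        e999 = error_space.percentile_eemm(99.9)
        e50 = error_space.percentile_eemm(50.0)
        assert e100 >= e999 >= e50

    def test_threshold_monotonicity(self, error_space):
        # shrinking the NRMSE threshold can only shrink the region and eEMM
        tighter = error_space.with_threshold(0.5 * error_space.nrmse_0)
        looser = error_space.with_threshold(2.0 * error_space.nrmse_0)
        assert tighter.e_emm <= error_space.e_emm <= looser.e_emm

    def test_gram_nrmse_matches_direct_synthesis(self, fieldset, measured, cp_mode,
                                                 probe_qset):
        # the O(Nc^2) Gram shortcut must equal voxelwise map synthesis
        from sarbound.metrics import nrmse, synthesize_mode
        es = estimate_eemm(fieldset, measured, probe_qset, cp_mode, n=64, seed=5)
        bplus = decompose_circular(fieldset).b_plus
        em = measured.eval_mask & fieldset.phantom.mask
        sim_map = synthesize_mode(bplus, cp_mode)
        W = cp_mode.weights[None, :] + es.lambdas  # CP has unit magnitudes
        for i in (0, 17, 63):
            pert_map = synthesize_mode(bplus, ExcitationMode(weights=W[i]))
            direct = nrmse(pert_map, sim_map, em)
            assert es.nrmse_i[i] == pytest.approx(direct, rel=1e-10)

    def test_pruning_conservative_speedup(self, fieldset, measured, qset, cp_mode):
        es = estimate_eemm(fieldset, measured, qset, cp_mode, n=1000, seed=3,
                           prune_quantile=0.95)
        assert es.metadata["pruned"]
        assert es.metadata["n_locations"] < qset.n_locations
        assert "pruning_check_rel_err" in es.metadata


class TestSweep:
    def test_single_mode_equals_overall(self, fieldset, measured, probe_qset, cp_mode):
        res = sweep_modes(fieldset, measured, probe_qset, [cp_mode], n=1000, seed=0)
        assert res.overall_eemm == res.error_spaces[0].e_emm

    def test_duplicated_modes_idempotent(self, fieldset, measured, probe_qset, cp_mode):
        one = sweep_modes(fieldset, measured, probe_qset, [cp_mode], n=1000, seed=0)
        two = sweep_modes(fieldset, measured, probe_qset, [cp_mode, cp_mode],
                          n=1000, seed=0)
        assert two.overall_eemm == one.overall_eemm

    def test_overall_is_max_of_individual_runs(self, fieldset, measured, probe_qset,
                                               canonical_modes):
        modes = canonical_modes[:4]
        res = sweep_modes(fieldset, measured, probe_qset, modes, n=1000, seed=0)
        singles = [estimate_eemm(fieldset, measured, probe_qset, m, n=1000, seed=0).e_emm
                   for m in modes]
        assert res.overall_eemm == max(singles)
        assert res.table().shape[0] == 4

    def test_empty_mode_list_rejected(self, fieldset, measured, probe_qset):
        with pytest.raises(ValueError, match="empty"):
            sweep_modes(fieldset, measured, probe_qset, [])


class TestRequiredModeCount:
    def test_zero_sigma_needs_no_modes(self):
        assert required_mode_count(mu=50.0, sigma=0.0) == 0

    def test_quadratic_in_sigma(self):
        assert required_mode_count(mu=1.0, sigma=1.0, z=1.0, e=1.0) == 1
        assert required_mode_count(mu=1.0, sigma=2.0, z=1.0, e=1.0) == 4

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            required_mode_count(mu=0.0, sigma=1.0)
        with pytest.raises(ValueError):
            required_mode_count(mu=1.0, sigma=1.0, e=0.0)


class TestSafetyBudget:
    def test_zero_uncertainty_gives_unit_factor(self):
        assert safety_budget(0.0, 0.0, 0.0).sf == 1.0

    def test_closed_form_power_and_subject_terms(self):
        # ePM = 15%, eISV = 50%: eSAR = sqrt(0.0225 + 0.25) ~ 0.52202
        b = safety_budget(0.15, 0.50, 0.0)
        assert b.e_sar == pytest.approx(np.sqrt(0.0225 + 0.25), abs=1e-12)
        assert b.sf == pytest.approx(1.52202, abs=5e-6)

    def test_sum_of_squares_identity(self):
        b = safety_budget(0.12, 0.4, 0.31)
        assert b.e_sar ** 2 == pytest.approx(b.e_pm ** 2 + b.e_isv ** 2 + b.e_emm ** 2,
                                             abs=1e-12)
        assert b.sf == 1.0 + b.e_sar

    @given(st.tuples(*[st.floats(0, 2) for _ in range(3)]),
           st.integers(0, 2), st.floats(0.001, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_each_component(self, triple, idx, bump):
        base = safety_budget(*triple)
        bumped = list(triple)
        bumped[idx] += bump
        assert safety_budget(*bumped).sf >= base.sf

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            safety_budget(-0.1, 0.5, 0.4)


class TestProbeValidation:
    def test_exact_model_never_underestimates(self, probe_qset, canonical_modes):
        from sarbound.sar import sar_at_locations
        modes = canonical_modes[:2]
        measured = {m.label: sar_at_locations(probe_qset, m) for m in modes}
        rep = probe_validation_report(probe_qset, modes, e_emm=0.1, measured_sar=measured)
        assert rep.n_underestimations == 0
        assert len(rep.table) == 2 * probe_qset.n_locations

    def test_moderate_bias_covered_by_margin(self, probe_qset, cp_mode):
        from sarbound.sar import sar_at_locations
        sim = sar_at_locations(probe_qset, cp_mode)
        rep = probe_validation_report(probe_qset, [cp_mode], e_emm=0.43,
                                      measured_sar={cp_mode.label: 1.2 * sim})
        assert rep.n_underestimations == 0  # 1.43 >= 1.2 everywhere

    def test_gross_bias_flags_every_probe(self, probe_qset, cp_mode):
        from sarbound.sar import sar_at_locations
        sim = sar_at_locations(probe_qset, cp_mode)
        rep = probe_validation_report(probe_qset, [cp_mode], e_emm=0.43,
                                      measured_sar={cp_mode.label: 2.0 * sim})
        assert rep.n_underestimations == probe_qset.n_locations

    def test_label_mismatch_rejected(self, probe_qset, cp_mode):
        with pytest.raises(KeyError):
            probe_validation_report(probe_qset, [cp_mode], e_emm=0.1,
                                    measured_sar={"other": np.ones(8)})
        with pytest.raises(ValueError, match="probes"):
            probe_validation_report(probe_qset, [cp_mode], e_emm=0.1,
                                    measured_sar={cp_mode.label: np.ones(3)})

    def test_unlabeled_set_rejected(self, qset, cp_mode):
        with pytest.raises(ValueError, match="labels"):
            probe_validation_report(qset, [cp_mode], e_emm=0.1, measured_sar={})
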