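"""Knockout, calibrated knockdown/overexpression, sensitivity sweeps, and
fold-change bookkeeping."""
import numpy as np
import pytest

import genecircuits as gc
from genecircuits.exceptions import CalibrationError
from genecircuits.model import Condition, GeneCircuitParams
from genecircuits.perturbation import (classify_quadrant, fold_change,
                                       knockdown_calibrated, knockout,
                                       overexpression_calibrated,
                                       sensitivity_sweep)

GRID = np.linspace(0, 168, 15)


def toy_activator_target():
    """Gene 'act' activates 'tgt'; no other couplings."""
    return GeneCircuitParams(
        ("act", "tgt"), [[0.0, 0.0], [3.0, 0.0]],
        b=[0.0, 0.0], h=[0.5, -1.0], R=[0.1, 0.1], lam=[0.1, 0.1])


class TestKnockout:
    def test_knocked_out_gene_stays_at_zero(self):
        p = toy_activator_target()
        ko, x0 = knockout(p, [0.5, 0.5], "act")
        for cond in (Condition.ERYTHROCYTE, Condition.NEUTROPHIL):
            traj = gc.simulate(ko, x0, cond, GRID)
            assert np.allclose(traj.gene("act"), 0.0, atol=1e-9)

    def test_decoupled_regulator_knockout_leaves_others_unchanged(self):
        # 'tgt' has no outgoing edges and no self term
        p = toy_activator_target()
        wt = gc.simulate(p, [0.5, 0.5], Condition.ERYTHROCYTE, GRID,
                         rel_accuracy=1e-9)
        ko, x0 = knockout(p, [0.5, 0.5], "tgt")
        mut = gc.simulate(ko, x0, Condition.ERYTHROCYTE, GRID,
                          rel_accuracy=1e-9)
        assert np.allclose(mut.gene("act"), wt.gene("act"), atol=1e-6)

    def test_activator_knockout_drops_target_to_basal(self):
        p = toy_activator_target()
        ko, x0 = knockout(p, [0.5, 0.2], "act")
        eq = gc.solve_equilibrium(ko, x0, Condition.PROGENITOR)
        basal = p.R[1] * gc.regulation_expression(p.h[1]) / p.lam[1]
        assert eq[1] == pytest.approx(basal, rel=1e-3)
        # and below the wildtype equilibrium
        wt_eq = gc.solve_equilibrium(p, [0.5, 0.2], Condition.PROGENITOR)
        assert eq[1] < wt_eq[1]

    def test_knockout_is_idempotent(self):
        p = toy_activator_target()
        once = knockout(p, [0.5, 0.5], "act")
        twice = knockout(once[0], once[1], "act")
        assert np.array_equal(once[0].R, twice[0].R)
        assert np.array_equal(once[1], twice[1])

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            knockout(toy_activator_target(), [0.5, 0.5], "nope")


class TestKnockdown:
    def test_identity_fold_change(self):
        p = toy_activator_target()
        spec, fc = knockdown_calibrated(p, "act", 1.0, [0.5, 0.5])
        assert spec.R_target == pytest.approx(p.R[0])
        assert fc.ratios == pytest.approx(np.ones(2), rel=1e-3)

    def test_decoupled_gene_fold_change_is_rate_ratio(self):
        """For a gene with no incoming self-dependence via T, the
        equilibrium scales linearly in R, so a 0.5 fold change halves R."""
        p = toy_activator_target()
        spec, fc = knockdown_calibrated(p, "act", 0.5, [0.5, 0.5])
        assert spec.R_target == pytest.approx(p.R[0] / 2, rel=1e-3)
        assert fc.ratios[0] == pytest.approx(0.5, rel=1e-3)

    def test_calibration_closure(self, truth4_and_data4):
        """Re-simulating with the calibrated rate reproduces the requested
        fold change."""
        params, dataset = truth4_and_data4
        gene = params.gene_names[0]
        spec, fc = knockdown_calibrated(params, gene, 0.6, dataset.x0)
        trial = params.copy()
        trial.R[params.index(gene)] = spec.R_target
        base = gc.solve_equilibrium(params, dataset.x0, Condition.PROGENITOR,
                                    deriv_tol=np.inf)
        pert = gc.solve_equilibrium(trial, dataset.x0, Condition.PROGENITOR,
                                    deriv_tol=np.inf)
        i = params.index(gene)
        assert pert[i] / base[i] == pytest.approx(0.6, rel=1e-3)
        assert gene in fc.non_predictive

    def test_target_marked_non_predictive(self):
        p = toy_activator_target()
        _, fc = knockdown_calibrated(p, "act", 0.7, [0.5, 0.5])
        frame = fc.to_frame()
        assert not frame.loc[frame.gene == "act", "predictive"].item()
        assert frame.loc[frame.gene == "tgt", "predictive"].item()

    def test_invalid_fold_change_rejected(self):
        with pytest.raises(CalibrationError):
            knockdown_calibrated(toy_activator_target(), "act", 1.5,
                                 [0.5, 0.5])


class TestOverexpression:
    def silent_driver(self):
        """Driver 'g' is never expressed (R=0) but activates 'a' with
        T = 1, so the baseline input of 'a' is exactly 0 and a bias beta
        shifts it to beta."""
        return GeneCircuitParams(
            ("g", "a"), [[0.0, 0.0], [1.0, 0.0]],
            b=[0.0, 0.0], h=[0.0, 0.0], R=[0.0, 0.1], lam=[0.1, 0.1])

    def test_zero_beta_identity(self):
        p = toy_activator_target()
        spec, fc = overexpression_calibrated(p, "act", "tgt", 1.0,
                                             [0.5, 0.5])
        assert spec.beta == 0.0
        assert fc.ratios == pytest.approx(np.ones(2), rel=1e-3)

    def test_closed_form_sigmoid_ratio(self):
        """With baseline input 0 the fold change of the target is
        S(beta)/S(0) = 2 S(beta); beta = 1 gives 1.70711."""
        p = self.silent_driver()
        expected = 2 * gc.regulation_expression(1.0)  # 1.7071067...
        spec, fc = overexpression_calibrated(p, "g", "a", expected,
                                             [0.0, 0.05])
        assert spec.beta == pytest.approx(1.0, rel=1e-3)
        assert fc.ratios[1] == pytest.approx(expected, rel=1e-3)

    def test_repression_sign_propagation(self):
        p = GeneCircuitParams(
            ("g", "a", "o"), np.array([[0.0, 0, 0], [-2.0, 0, 0],
                                       [0.0, 0, 0]]),
            b=[0, 0, 0], h=[0.5, 0.5, 0.5], R=[0.1, 0.1, 0.1],
            lam=[0.1, 0.1, 0.1])
        eq = gc.solve_equilibrium(p, [0.5, 0.5, 0.5], Condition.PROGENITOR,
                                  deriv_tol=np.inf)
        biased = gc.solve_equilibrium(p, [0.5, 0.5, 0.5],
                                      Condition.PROGENITOR,
                                      bias=p.T[:, 0] * 2.0,
                                      deriv_tol=np.inf)
        assert biased[1] < eq[1]          # repressed target falls
        assert biased[2] == pytest.approx(eq[2], rel=1e-3)  # untouched

    def test_overexpressed_and_reference_non_predictive(self):
        p = self.silent_driver()
        _, fc = overexpression_calibrated(p, "g", "a", 1.5, [0.0, 0.05])
        assert "g" in fc.non_predictive and "a" in fc.non_predictive

    def test_unreachable_fold_change_reports_range(self):
        # reference gene not regulated by the overexpressed gene
        p = GeneCircuitParams(
            ("g", "a"), np.zeros((2, 2)), b=[0, 0], h=[0.0, 0.0],
            R=[0.1, 0.1], lam=[0.1, 0.1])
        with pytest.raises(CalibrationError, match="achievable range"):
            overexpression_calibrated(p, "g", "a", 2.0, [0.5, 0.5])

    def test_same_gene_rejected(self):
        with pytest.raises(CalibrationError):
            overexpression_calibrated(toy_activator_target(), "act", "act",
                                      2.0, [0.5, 0.5])


class TestSensitivity:
    def test_sweep_size_for_full_design(self, tmp_path):
        spec = gc.SynthesisSpec(seed=0, noise_cv=0.0)
        params, dataset = gc.make_synthetic_dataset(spec)
        table = sensitivity_sweep(params, dataset)
        assert len(table) == 120  # 12 genes x 10 levels

    def test_zero_level_is_control(self, truth4_and_data4):
        params, dataset = truth4_and_data4
        from genecircuits.inference import (count_datapoints, residual_ss,
                                            rms_score)
        table = sensitivity_sweep(params, dataset, levels=(0.0,))
        control = rms_score(residual_ss(params, dataset),
                            count_datapoints(dataset))
        assert np.allclose(table["rms"], control)

    def test_decoupled_perturbation_is_gene_local(self, decoupled_params):
        """In a decoupled circuit, perturbing one gene's start changes only
        that gene's trajectory."""
        p = decoupled_params
        ds = gc.simulate_dataset(p, x0=[0.3, 0.2, 0.4],
                                 times=np.linspace(0, 50, 6), noise_cv=0.0)
        base = gc.simulate(p, ds.x0, Condition.ERYTHROCYTE, ds.times).values
        x0 = ds.x0.copy()
        x0[1] *= 1.5
        pert = gc.simulate(p, x0, Condition.ERYTHROCYTE, ds.times).values
        assert np.allclose(pert[[0, 2]], base[[0, 2]], atol=1e-8)
        assert not np.allclose(pert[1], base[1])


class TestFoldChange:
    def test_identity_and_doubling(self):
        base = np.array([0.5, 1.0])
        assert fold_change(base, base, ("a", "b")).ratios \
            == pytest.approx([1.0, 1.0])
        assert fold_change(2 * base, base, ("a", "b")).ratios \
            == pytest.approx([2.0, 2.0])

    def test_zero_baseline_flagged_not_raised(self):
        fc = fold_change([0.5, 0.5], [1.0, 0.0], ("a", "b"))
        assert fc.undefined == ("b",)
        assert np.isnan(fc.ratios[1])

    @pytest.mark.parametrize("pred,obs,expected", [
        (1.5, 2.0, "agreement"),
        (0.5, 0.8, "agreement"),
        (1.5, 0.8, "disagreement"),
        (0.4, 1.2, "disagreement"),
        (1.0, 2.0, "boundary"),
    ])
    def test_quadrant_classification(self, pred, obs, expected):
        assert classify_quadrant(pred, obs) == expected
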