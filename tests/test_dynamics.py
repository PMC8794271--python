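"""Regulatory-input decomposition, half-max ordering, ensemble edge
classification, representative selection, and dynamic-GRN export."""
import numpy as np
import pytest

import genecircuits as gc
from genecircuits.dynamics import (classify_edges, decompose,
                                   export_dynamic_grn, half_max_ordering,
                                   half_max_time, select_representative)
from genecircuits.inference import Ensemble, FitResult
from genecircuits.model import Condition, GeneCircuitParams


def random_circuit(seed, n=4):
    rng = np.random.default_rng(seed)
    return GeneCircuitParams(
        tuple(f"g{i}" for i in range(n)), rng.normal(0, 0.5, (n, n)),
        rng.normal(0, 0.5, n), rng.normal(0, 0.5, n),
        rng.uniform(0.02, 0.2, n), rng.uniform(0.02, 0.2, n))


class TestDecompose:
    def test_exact_additivity(self):
        p = random_circuit(1)
        traj = gc.simulate(p, [0.2, 0.4, 0.1, 0.3], Condition.ERYTHROCYTE,
                           np.linspace(0, 100, 12))
        for i, (gene, d) in enumerate(decompose(p, traj).items()):
            reconstructed = d.contributions.sum(axis=0) + d.external \
                + d.threshold + d.bias
            assert np.allclose(reconstructed, d.total, atol=1e-12)
            # and the total is the regulatory input evaluated on the states
            for ti in range(traj.times.size):
                u = gc.total_regulatory_input(p, traj.values[:, ti],
                                              traj.condition)
                assert d.total[ti] == pytest.approx(u[i], abs=1e-12)

    def test_zero_expression_regulator_contributes_nothing(self):
        p = GeneCircuitParams(("off", "tgt"), [[0.0, 0.0], [5.0, 0.0]],
                              [0, 0], [0.0, 0.0], [0.0, 0.1], [0.1, 0.1])
        traj = gc.simulate(p, [0.0, 0.3], Condition.PROGENITOR,
                           np.linspace(0, 50, 6))
        d = decompose(p, traj)["tgt"]
        assert np.allclose(d.contributions[0], 0.0, atol=1e-9)

    def test_decoupled_driver_matches_closed_form(self):
        """Driver relaxes along the 1-gene closed form; the contribution
        to its target is T times that curve."""
        lam_d, R_d, x0_d, T_ad = 0.1, 0.08, 0.1, 2.5
        p = GeneCircuitParams(
            ("drv", "a"), [[0.0, 0.0], [T_ad, 0.0]], [0, 0], [0.0, -0.5],
            [R_d, 0.1], [lam_d, 0.1])
        t = np.linspace(0, 80, 9)
        traj = gc.simulate(p, [x0_d, 0.2], Condition.PROGENITOR, t)
        xstar = R_d * 0.5 / lam_d
        exact = xstar + (x0_d - xstar) * np.exp(-lam_d * t)
        d = decompose(p, traj)["a"]
        assert np.allclose(d.contributions[0], T_ad * exact, atol=2e-2)

    def test_activator_repressor_partition(self):
        p = random_circuit(2)
        traj = gc.simulate(p, np.full(4, 0.2), Condition.NEUTROPHIL,
                           np.linspace(0, 50, 6))
        d = decompose(p, traj)["g0"]
        acts, reps = set(d.activators()), set(d.repressors())
        assert acts.isdisjoint(reps)
        for j, g in enumerate(d.gene_names):
            if p.T[0, j] > 0:
                assert g in acts
            elif p.T[0, j] < 0:
                assert g in reps


class TestHalfMaxTime:
    def test_linear_interpolated_crossing(self):
        t = np.linspace(0, 10, 11)
        u = np.linspace(-1, 1, 11)
        assert half_max_time(u, t) == pytest.approx(5.0)

    def test_no_crossing_returns_none(self):
        assert half_max_time(np.ones(5), np.arange(5)) is None

    def test_exact_zero_sample_reports_that_time(self):
        u = np.array([-1.0, 0.0, 1.0])
        assert half_max_time(u, [0.0, 3.0, 6.0]) == 3.0

    def test_ordering_early_activator_before_late_activator(self):
        """A target driven by a fast-rising activator reaches half-max
        input before one driven by a slow riser."""
        # drivers rise to the same ceiling with fast / slow kinetics
        p = GeneCircuitParams(
            ("fast", "slow", "ta", "tb"),
            [[0, 0, 0, 0], [0, 0, 0, 0],
             [3.0, 0, 0, 0], [0, 3.0, 0, 0]],
            b=[0, 0, 0, 0], h=[0.0, 0.0, -1.0, -1.0],
            R=[0.5, 0.02, 0.1, 0.1], lam=[0.5, 0.02, 0.1, 0.1])
        traj = gc.simulate(p, [0, 0, 0, 0], Condition.PROGENITOR,
                           np.linspace(0, 168, 85))
        decs = decompose(p, traj)
        assert decs["ta"].half_max_time < decs["tb"].half_max_time
        order = half_max_ordering(decs)
        ranked = list(order["gene"])
        assert ranked.index("ta") < ranked.index("tb")


class TestClassifyEdges:
    def jittered_ensemble(self, truth, sd, n_models, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n_models):
            p = truth.copy()
            p.T = truth.T + rng.normal(0, sd, truth.T.shape)
            p.b = truth.b + rng.normal(0, sd, truth.b.shape)
            out.append(p)
        return out

    def test_label_rules(self):
        truth = random_circuit(0, n=2)
        # construct the per-edge ensemble distributions explicitly
        base = [truth.copy() for _ in range(4)]
        for k, v in enumerate([2.0, 2.0, 2.0, 2.0]):
            base[k].T[0, 0] = v                      # all +2 -> activation
        for k, v in enumerate([-3.0, -1.0, 1.0, 3.0]):
            base[k].T[0, 1] = v                      # IQR spans 0
        for k, v in enumerate([-5.0, -4.0, -3.0, -2.0]):
            base[k].T[1, 0] = v                      # all negative
        edges = classify_edges(base)

        def label(tgt, reg):
            row = edges[(edges.target == tgt) & (edges.regulator == reg)]
            return row["label"].item()

        assert label("g0", "g0") == "activation"
        assert label("g0", "g1") == "unconstrained"
        assert label("g1", "g0") == "repression"

    def test_external_signal_rows_present(self):
        models = [random_circuit(s) for s in range(5)]
        edges = classify_edges(models)
        ext = edges[edges.regulator == "Ext. Sig."]
        assert len(ext) == 4  # one per target gene

    def test_order_invariance(self):
        models = [random_circuit(s) for s in range(6)]
        a = classify_edges(models)
        b = classify_edges(models[::-1])
        assert a["label"].tolist() == b["label"].tolist()

    def test_small_ensemble_rejected(self):
        with pytest.raises(ValueError):
            classify_edges([random_circuit(0)] * 3)

    def test_sign_recovery_on_jittered_ensembles(self):
        """Every interconnection whose |truth| exceeds 3x the jitter sd is
        labeled with the true sign."""
        truth = random_circuit(7)
        sd = 0.05
        edges = classify_edges(self.jittered_ensemble(truth, sd, 25))
        for i, tgt in enumerate(truth.gene_names):
            for j, reg in enumerate(truth.gene_names):
                if abs(truth.T[i, j]) > 3 * sd:
                    row = edges[(edges.target == tgt)
                                & (edges.regulator == reg)]
                    expected = "activation" if truth.T[i, j] > 0 \
                        else "repression"
                    assert row["label"].item() == expected


class TestSelectRepresentative:
    def as_fits(self, models, rms=None):
        rms = rms or [0.01] * len(models)
        return Ensemble([FitResult(m, r, r, 0.0, r, k, 0, True)
                         for k, (m, r) in enumerate(zip(models, rms))])

    def test_identical_models_score_fully(self):
        m = random_circuit(1)
        idx = select_representative([m.copy() for _ in range(5)])
        assert idx in range(5)

    def test_dissenting_model_not_selected(self):
        base = random_circuit(2)
        dissent = base.copy()
        dissent.T[0, 0] = -base.T[0, 0]  # flips one consensus sign
        idx = select_representative([base.copy(), dissent, base.copy()])
        assert idx != 1

    def test_tied_parameters_excluded_and_rms_breaks_ties(self):
        a = random_circuit(3)
        b = a.copy()
        b.T[0, 1] = -a.T[0, 1]  # exact 50/50 split on one parameter
        ens = self.as_fits([a, b], rms=[0.02, 0.01])
        assert select_representative(ens) == 1  # lower RMS wins the tie


class TestExportDynamicGrn:
    def decomps(self, p, cond=Condition.ERYTHROCYTE):
        traj = gc.simulate(p, np.full(p.n_genes, 0.2), cond,
                           np.linspace(0, 100, 11))
        return decompose(p, traj)

    def test_normalization_of_activation_weights(self):
        # static circuit: two activating edges with strengths 2 and 4
        p = GeneCircuitParams(
            ("a", "b", "c"),
            [[0, 2.0, 4.0], [0, 0, 0], [0, 0, 0]],
            b=[0, 0, 0], h=[0, 0.0, 0.0], R=[0.0, 0.0, 0.0],
            lam=[0.1, 0.1, 0.1])
        # R=0 so states decay identically from equal starts: x_b = x_c
        traj = gc.simulate(p, [0.2, 0.4, 0.4], Condition.PROGENITOR,
                           np.linspace(0, 10, 3))
        edges = export_dynamic_grn(decompose(p, traj), [0.0])

        def w(reg):
            return edges[(edges.regulator == reg)
                         & (edges.target == "a")]["weight"].item()

        assert w("c") == pytest.approx(1.0)
        assert w("b") == pytest.approx(0.5)

    def test_all_zero_contributions_zero_weights(self):
        p = GeneCircuitParams(("a", "b"), np.zeros((2, 2)), [0, 0],
                              [0.0, 0.0], [0.1, 0.1], [0.1, 0.1])
        edges = export_dynamic_grn(self.decomps(p), [0.0, 50.0])
        assert np.allclose(edges["weight"], 0.0)

    def test_snapshot_graph(self):
        p = random_circuit(4)
        edges = export_dynamic_grn(self.decomps(p), [0.0, 100.0])
        from genecircuits.dynamics import grn_snapshot_graph
        g = grn_snapshot_graph(edges, 100.0)
        assert g.number_of_edges() > 0
        for _, _, data in g.edges(data=True):
            assert data["sign"] in (-1, 1)
            assert 0 < data["weight"] <= 1
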