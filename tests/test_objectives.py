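"""Loss terms against naive, loop-based oracles and closed-form cases."""

import math

import numpy as np
import pytest

from cdrdesign import Model, ModelConfig
from cdrdesign.egnn import ForwardTrace
from cdrdesign.objectives import (
    CE_CDR_LAYERS,
    LABEL_SMOOTHING,
    LossBreakdown,
    STRUCTURE_WEIGHT,
    TAU_REPULSION,
    UndefinedLossError,
    VIOLATION_SKIP_LAYERS,
    ce_cdr_loss,
    ce_noncdr_loss,
    neighbor_loss,
    repulsion_loss,
    rmsd_loss,
    total_loss,
    _smoothed_ce,
)


# ---------------------------------------------------------------- oracles


def oracle_rmsd(per_layer_coords, truth, mask):
    vals = []
    for coords in per_layer_coords:
        acc, n = 0.0, 0
        for i in range(len(mask)):
            if mask[i] == 1:
                for a in range(3):
                    acc += (coords[i][a] - truth[i][a]) ** 2
                n += 1
        vals.append(math.sqrt(acc / n))
    return sum(vals) / len(vals)


def oracle_repulsion(per_layer_coords, mask, tau):
    vals = []
    for coords in per_layer_coords[VIOLATION_SKIP_LAYERS:]:
        acc, cnt = 0.0, 0
        for i in range(len(mask)):
            if mask[i] != 1:
                continue
            for j in range(len(mask)):
                if mask[j] == 1:
                    continue
                d = math.dist(coords[i], coords[j])
                acc += max(tau - d, 0.0)
                cnt += 1
        vals.append(acc / cnt)
    return sum(vals) / len(vals)


def oracle_neighbor(per_layer_coords, truth, mask):
    cdr = [i for i in range(len(mask)) if mask[i] == 1]
    path = list(range(cdr[0] - 1, cdr[-1] + 2))
    vals = []
    for coords in per_layer_coords[VIOLATION_SKIP_LAYERS:]:
        acc = 0.0
        for a, b in zip(path[:-1], path[1:]):
            acc += abs(math.dist(coords[a], coords[b]) - math.dist(truth[a], truth[b]))
        vals.append(acc / (len(cdr) + 1))
    return sum(vals) / len(vals)


def oracle_smoothed_ce(logits, targets, smoothing):
    total = 0.0
    for row, t in zip(logits, targets):
        m = max(row)
        logz = m + math.log(sum(math.exp(v - m) for v in row))
        logp = [v - logz for v in row]
        q = [smoothing / len(row)] * len(row)
        q[t] += 1.0 - smoothing
        total += -sum(qi * lp for qi, lp in zip(q, logp))
    return total / len(targets)


def random_fixture(rng, L=9, n_layers=6):
    mask = np.zeros(L, dtype=int)
    mask[3:6] = 1  # contiguous CDR with anchors at 2 and 6
    truth = rng.normal(size=(L, 3)) * 4
    layers = [truth + rng.normal(size=(L, 3)) for _ in range(n_layers)]
    return ForwardTrace(layers, [None] * n_layers, None), truth, mask


# ------------------------------------------------------------- structural


class TestRmsdLoss:
    def test_perfect_prediction_gives_zero(self):
        truth = np.arange(12.0).reshape(4, 3)
        trace = ForwardTrace([truth.copy()] * 5, [None] * 5, None)
        mask = np.array([0, 1, 1, 0])
        assert float(rmsd_loss(trace, truth, mask).data) == 0.0

    def test_three_four_five_offset(self):
        truth = np.zeros((3, 3))
        pred = truth.copy()
        pred[1] = [3.0, 4.0, 0.0]
        trace = ForwardTrace([pred], [None], None)
        assert float(rmsd_loss(trace, truth, np.array([0, 1, 0])).data) == 5.0

    def test_matches_loop_oracle_on_random_traces(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            trace, truth, mask = random_fixture(rng, n_layers=3)
            got = float(rmsd_loss(trace, truth, mask).data)
            want = oracle_rmsd([c for c in trace.per_layer_coords], truth, mask)
            assert got == pytest.approx(want, abs=1e-9)

    def test_empty_mask_is_undefined(self):
        trace = ForwardTrace([np.zeros((3, 3))], [None], None)
        with pytest.raises(UndefinedLossError):
            rmsd_loss(trace, np.zeros((3, 3)), np.zeros(3, dtype=int))


class TestRepulsionLoss:
    def _two_node_trace(self, d):
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        return ForwardTrace([coords.copy() for _ in range(6)], [None] * 6, None)

    def test_zero_beyond_threshold(self):
        trace = self._two_node_trace(5.0)
        assert float(repulsion_loss(trace, np.array([1, 0])).data) == 0.0

    def test_hinge_value_inside_threshold(self):
        trace = self._two_node_trace(3.2)
        got = float(repulsion_loss(trace, np.array([1, 0])).data)
        assert got == pytest.approx(max(TAU_REPULSION - 3.2, 0.0), abs=1e-12)
        assert got == pytest.approx(1.0, abs=1e-9)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            trace, truth, mask = random_fixture(rng)
            got = float(repulsion_loss(trace, mask).data)
            want = oracle_repulsion(trace.per_layer_coords, mask, TAU_REPULSION)
            assert got == pytest.approx(want, abs=1e-9)

    def test_hinge_is_non_increasing_in_distance(self):
        vals = [
            float(repulsion_loss(self._two_node_trace(d), np.array([1, 0])).data)
            for d in np.linspace(0.5, 6.0, 20)
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestNeighborLoss:
    def test_perfect_prediction_gives_zero(self):
        rng = np.random.default_rng(2)
        truth = rng.normal(size=(7, 3))
        trace = ForwardTrace([truth.copy()] * 6, [None] * 6, None)
        mask = np.array([0, 0, 1, 1, 1, 0, 0])
        assert float(neighbor_loss(trace, truth, mask).data) == 0.0

    def test_single_residue_both_edges_changed(self):
        # one CDR residue on a line; moving it stretches both flanking
        # edges by 0.5 Å → (0.5 + 0.5) / 2 = 0.5
        truth = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        pred = truth.copy()
        # y-offset making each edge length 1.5
        pred[1, 1] = math.sqrt(1.5**2 - 1.0)
        trace = ForwardTrace([pred] * 6, [None] * 6, None)
        got = float(neighbor_loss(trace, truth, np.array([0, 1, 0])).data)
        assert got == pytest.approx(0.5, abs=1e-12)

    def test_matches_edge_by_edge_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            trace, truth, mask = random_fixture(rng)
            got = float(neighbor_loss(trace, truth, mask).data)
            want = oracle_neighbor(trace.per_layer_coords, truth, mask)
            assert got == pytest.approx(want, abs=1e-9)


# --------------------------------------------------------------- sequence


def head_model():
    return Model(ModelConfig(n_layers=5, hidden_dim=6, aa_embed_dim=4), seed=4)


class TestCrossEntropy:
    def test_uniform_logits_give_ln20(self):
        from cdrdesign._autodiff import tensor

        logits = np.zeros((5, 20))
        targets = np.arange(5)
        got = float(_smoothed_ce(tensor(logits), targets, LABEL_SMOOTHING).data)
        assert got == pytest.approx(math.log(20.0), abs=1e-12)

    def test_perfect_smoothed_prediction_attains_entropy_floor(self):
        s = LABEL_SMOOTHING
        q = np.full(20, s / 20)
        q[7] += 1 - s
        logits = np.log(np.tile(q, (4, 1)))
        targets = np.full(4, 7)
        from cdrdesign._autodiff import tensor

        got = float(_smoothed_ce(tensor(logits), targets, s).data)
        floor = -(q * np.log(q)).sum()
        assert got == pytest.approx(floor, abs=1e-12)

    def test_random_logits_match_per_residue_oracle(self):
        from cdrdesign._autodiff import tensor

        rng = np.random.default_rng(5)
        for _ in range(10):
            logits = rng.normal(size=(6, 20)) * 3
            targets = rng.integers(0, 20, size=6)
            got = float(_smoothed_ce(tensor(logits), targets, LABEL_SMOOTHING).data)
            want = oracle_smoothed_ce(logits.tolist(), targets.tolist(),
                                      LABEL_SMOOTHING)
            assert got == pytest.approx(want, abs=1e-9)

    def test_cdr_ce_uses_only_last_four_layers(self):
        model = head_model()
        rng = np.random.default_rng(6)
        n_layers = model.config.n_layers
        feats = [rng.normal(size=(5, model.config.hidden_dim)) for _ in range(n_layers)]
        tokens = rng.integers(0, 20, size=5)
        mask = np.array([0, 1, 1, 0, 0])
        trace_a = ForwardTrace([None] * n_layers, feats, None)
        zeroed = [np.zeros_like(f) for f in feats[: n_layers - CE_CDR_LAYERS]]
        trace_b = ForwardTrace(
            [None] * n_layers, zeroed + feats[n_layers - CE_CDR_LAYERS:], None)
        a = float(ce_cdr_loss(trace_a, tokens, mask, model).data)
        b = float(ce_cdr_loss(trace_b, tokens, mask, model).data)
        assert a == pytest.approx(b, abs=1e-12)

    def test_noncdr_ce_averages_all_layers(self):
        model = head_model()
        rng = np.random.default_rng(7)
        n_layers = model.config.n_layers
        feats = [rng.normal(size=(5, model.config.hidden_dim)) for _ in range(n_layers)]
        tokens = rng.integers(0, 20, size=5)
        mask = np.array([0, 1, 1, 0, 0])
        trace = ForwardTrace([None] * n_layers, feats, None)
        got = float(ce_noncdr_loss(trace, tokens, mask, model).data)
        non = np.flatnonzero(mask == 0)
        per_layer = [
            oracle_smoothed_ce(
                model.head(f[non]).data.tolist(), tokens[non].tolist(),
                LABEL_SMOOTHING)
            for f in feats
        ]
        assert got == pytest.approx(sum(per_layer) / n_layers, abs=1e-9)


# ------------------------------------------------------------ composition


class TestTotals:
    def test_structure_sum_and_weighted_total_are_exact(self):
        parts = LossBreakdown(
            l_rmsd=0.3, l_repulsion=0.5, l_neighbor=0.2,
            l_ce_cdr=1.25, l_ce_noncdr=0.75)
        assert parts.l_structure == 0.3 + 0.5 + 0.2
        assert parts.l_ce_total == 2.0
        assert total_loss(parts) == STRUCTURE_WEIGHT * 1.0 + 2.0 == 12.0

    def test_all_zero_parts_give_zero(self):
        parts = LossBreakdown(0.0, 0.0, 0.0, 0.0, 0.0)
        assert total_loss(parts) == 0.0

    def test_random_parts_match_formula(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            vals = rng.uniform(0, 3, size=5)
            parts = LossBreakdown(*vals)
            want = 10.0 * vals[:3].sum() + vals[3:].sum()
            assert total_loss(parts) == pytest.approx(want, rel=1e-15)


class TestRigidInvariance:
    def test_structural_losses_invariant_under_joint_rigid_motion(self):
        rng = np.random.default_rng(9)
        trace, truth, mask = random_fixture(rng)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        t = rng.normal(size=3) * 7
        moved = ForwardTrace(
            [c @ Q.T + t for c in trace.per_layer_coords], trace.per_layer_feats, None)
        truth_m = truth @ Q.T + t
        for fn, args_a, args_b in [
            (rmsd_loss, (trace, truth, mask), (moved, truth_m, mask)),
            (repulsion_loss, (trace, mask), (moved, mask)),
            (neighbor_loss, (trace, truth, mask), (moved, truth_m, mask)),
        ]:
            assert float(fn(*args_a).data) == pytest.approx(
                float(fn(*args_b).data), abs=1e-6)
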