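"""Propagation scoring: iteration, closed form, ranking and thresholds."""

import numpy as np
import pytest

import lncnet as ln
from _helpers import net_from_edges, random_network

W_TOY = np.array([[0.5, 0.5], [0.5, 0.5]])


def toy_weights():
    return ln.ProjectionWeights(("g1", "g2"), W_TOY.copy())


class TestPropagate:
    def test_worked_example_two_genes(self):
        """Equal-sharing W with Y=(1,0) and alpha=0.618 gives (0.691, 0.309):
        the hand-solved fixed point (1 - alpha/2, alpha/2)."""
        sv = ln.propagate(toy_weights(), np.array([1.0, 0.0]))
        np.testing.assert_allclose(sv.F, [0.691, 0.309], atol=5e-4)
        assert sv.converged

    def test_alpha_zero_returns_initial_information(self):
        cfg = ln.PropagationConfig(alpha=0.0)
        sv = ln.propagate(toy_weights(), np.array([1.0, 0.0]), cfg)
        np.testing.assert_array_equal(sv.F, [1.0, 0.0])
        assert sv.iterations_used == 1

    def test_zero_initial_information_is_fixed_point(self):
        sv = ln.propagate(toy_weights(), np.zeros(2))
        assert not sv.F.any() and sv.iterations_used == 1

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        net = random_network(rng)
        weights = ln.resource_allocation_weights(net)
        Y = (rng.random(net.n_genes) < 0.3).astype(float)
        cfg = ln.PropagationConfig(tol=1e-12, deviation="max_abs")
        base = ln.propagate(weights, Y, cfg).F
        scaled = ln.propagate(weights, 3.5 * Y, cfg).F
        np.testing.assert_allclose(scaled, 3.5 * base, atol=1e-9)

    def test_scores_nonnegative(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            net = random_network(rng)
            weights = ln.resource_allocation_weights(net)
            Y = (rng.random(net.n_genes) < 0.4).astype(float)
            assert np.all(ln.propagate(weights, Y).F >= -1e-15)

    def test_deviation_sequence_nonincreasing_after_second_iteration(self, small_fixture):
        net, _ = small_fixture
        weights = ln.resource_allocation_weights(net)
        for disease in net.disease_ids[:5]:
            sv = ln.score_disease(net, disease, weights=weights)
            devs = sv.deviations
            assert all(b <= a * (1 + 1e-9) for a, b in zip(devs[1:], devs[2:]))

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError):
            ln.propagate(toy_weights(), np.array([np.nan, 0.0]))
        bad = ln.ProjectionWeights(("g1", "g2"), np.array([[np.inf, 0], [0, 0.5]]))
        with pytest.raises(ValueError):
            ln.propagate(bad, np.array([1.0, 0.0]))

    def test_max_iter_safeguard_reports_nonconvergence(self):
        cfg = ln.PropagationConfig(tol=1e-30, max_iter=5)
        slow = ln.ProjectionWeights(("g1", "g2"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        sv = ln.propagate(slow, np.array([1.0, 0.0]), cfg)
        assert not sv.converged and sv.iterations_used == 5

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_alpha_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            ln.PropagationConfig(alpha=bad)


class TestClosedForm:
    def test_worked_example(self):
        F = ln.propagate_closed_form(toy_weights(), np.array([1.0, 0.0]), 0.618)
        np.testing.assert_allclose(F, [0.691, 0.309], atol=1e-12)

    def test_identity_weights_cancel(self):
        W = ln.ProjectionWeights(("a", "b", "c"), np.eye(3))
        Y = np.array([0.2, 0.0, 1.0])
        np.testing.assert_allclose(ln.propagate_closed_form(W, Y, 0.618), Y, atol=1e-12)

    def test_agreement_with_iterative(self):
        """The iteration stopped on the max-abs statistic lands within
        tol * alpha / (1 - alpha) of the direct linear solve."""
        rng = np.random.default_rng(23)
        for _ in range(25):
            net = random_network(rng)
            weights = ln.resource_allocation_weights(net)
            Y = (rng.random(net.n_genes) < 0.4).astype(float)
            alpha = float(rng.uniform(0.05, 0.85))
            tol = 1e-8
            cfg = ln.PropagationConfig(alpha=alpha, tol=tol, deviation="max_abs")
            F_iter = ln.propagate(weights, Y, cfg).F
            F_closed = ln.propagate_closed_form(weights, Y, alpha)
            assert np.max(np.abs(F_iter - F_closed)) <= 10 * tol


class TestInitialInformation:
    def test_indicator_of_association(self):
        net = net_from_edges({("g1", "d1"), ("g2", "d2"), ("g3", "d2")})
        sv = ln.initial_information(net, "d1")
        np.testing.assert_array_equal(sv.Y, [1.0, 0.0, 0.0])

    def test_all_genes_associated(self):
        net = net_from_edges({("g1", "d1"), ("g2", "d1")})
        np.testing.assert_array_equal(ln.initial_information(net, "d1").Y, [1, 1])

    def test_degree_zero_disease_warns(self):
        net = net_from_edges({("g1", "d1")}, isolated_diseases=["d9"])
        with pytest.warns(UserWarning, match="no associated genes"):
            sv = ln.initial_information(net, "d9")
        assert not sv.Y.any()

    def test_unknown_disease_raises(self):
        with pytest.raises(KeyError):
            ln.initial_information(net_from_edges({("g1", "d1")}), "nope")


class TestRanking:
    def make_scores(self, net, disease, scores):
        sv = ln.initial_information(net, disease)
        sv.F = np.asarray(scores, dtype=float)
        return sv

    def test_only_unassociated_genes_ranked(self):
        net = net_from_edges({("g1", "d1"), ("g2", "d2"), ("g3", "d2")})
        sv = self.make_scores(net, "d1", [0.9, 0.4, 0.2])
        ranked = ln.rank_candidates(sv, net)
        assert ranked == [("g2", 0.4, 1), ("g3", 0.2, 2)]

    def test_ties_break_by_ascending_gene_id(self):
        net = net_from_edges({("g1", "d1"), ("g2", "d2"), ("g3", "d2")})
        sv = self.make_scores(net, "d1", [0.9, 0.3, 0.3])
        assert [g for g, _, _ in ln.rank_candidates(sv, net)] == ["g2", "g3"]

    def test_all_genes_associated_gives_empty_list(self):
        net = net_from_edges({("g1", "d1"), ("g2", "d1")})
        sv = self.make_scores(net, "d1", [0.5, 0.5])
        assert ln.rank_candidates(sv, net) == []


class TestPredictionThresholds:
    def ranked(self, n):
        return [(f"g{i:04d}", 1.0 - i / max(n, 1), i + 1) for i in range(n)]

    @pytest.mark.parametrize("n, fraction, expected", [(200, 0.01, 2), (50, 0.01, 1), (10, 1.0, 10)])
    def test_top_fraction_ceiling_with_floor_one(self, n, fraction, expected):
        assert len(ln.predict_top_fraction(self.ranked(n), fraction)) == expected

    def test_top_fraction_empty_and_errors(self):
        assert ln.predict_top_fraction([], 0.01) == []
        with pytest.raises(ValueError):
            ln.predict_top_fraction(self.ranked(5), 0.0)
        with pytest.raises(ValueError):
            ln.predict_top_fraction(self.ranked(5), 1.5)

    @pytest.mark.parametrize("n, k, expected", [(15, 10, 10), (4, 10, 4), (4, 0, 0)])
    def test_top_k(self, n, k, expected):
        assert len(ln.predict_top_k(self.ranked(n), k)) == expected

    def test_top_k_negative_rejected(self):
        with pytest.raises(ValueError):
            ln.predict_top_k(self.ranked(5), -1)
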