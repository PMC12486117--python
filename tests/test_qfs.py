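"""QAOA feature selection: QUBO construction, exact simulation, oracles."""

import numpy as np
import pytest
import scipy.linalg as sla

from quarg import qfs
from quarg.statevec import uniform_state


@pytest.fixture
def worked_qubo():
    """Two features, r = (1, 0.5), no redundancy, k = 1, alpha = 1, beta = 2."""
    scores = qfs.ScoreTable(relevance=[1.0, 0.5], redundancy=np.zeros((2, 2)))
    return qfs.build_qubo(scores, k=1, alpha=1.0, beta=2.0)


class TestScoreFeatures:
    def test_perfect_and_constant_features(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        X = np.column_stack([y.astype(float), np.full(6, 3.0), np.arange(6.0)])
        t = qfs.score_features(X, y)
        assert t.relevance[0] == pytest.approx(1.0)
        assert t.relevance[1] == 0.0
        assert np.all(t.redundancy[1] == 0.0)

    def test_noisy_duplicate_has_high_redundancy(self, strong_cohort):
        t = qfs.score_features(strong_cohort.pooled_features(), strong_cohort.labels)
        truth = strong_cohort.truth
        n_img = strong_cohort.X_img.shape[1]
        # each redundant column was built from an informative parent
        for col in truth["redundant_img"]:
            parents = truth["informative_img"]
            assert max(t.redundancy[col, p] for p in parents) > 0.8

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            qfs.score_features(np.zeros((4, 2)), [1, 1, 1, 1])


class TestQubo:
    def test_worked_example_costs(self, worked_qubo):
        # enumeration: 00 -> 2, 10 -> -1, 01 -> -0.5, 11 -> 0.5
        assert worked_qubo.all_costs() == pytest.approx([2.0, -1.0, -0.5, 0.5])

    def test_brute_force_on_worked_example(self, worked_qubo):
        best = qfs.brute_force_select(worked_qubo)
        assert best.indices == [0]
        assert best.cost == pytest.approx(-1.0)

    def test_separable_cost_selects_positive_relevance(self):
        scores = qfs.ScoreTable(relevance=[0.4, 0.0, 0.9], redundancy=np.zeros((3, 3)))
        q = qfs.build_qubo(scores, k=2, alpha=0.0, beta=0.0)
        assert qfs.brute_force_select(q).indices == [0, 2]

    def test_large_beta_enforces_cardinality(self, rng):
        scores = qfs.ScoreTable(
            relevance=rng.uniform(0, 1, 6), redundancy=np.zeros((6, 6))
        )
        q = qfs.build_qubo(scores, k=3, alpha=0.0, beta=100.0)
        costs = q.all_costs()
        ones = np.array([bin(z).count("1") for z in range(2**6)])
        # every bitstring within 1 cost unit of the optimum has exactly k ones
        near = costs <= costs.min() + 1.0
        assert np.all(ones[near] == 3)

    def test_constant_shift_preserves_argmin(self, worked_qubo):
        shifted = qfs.QuboProblem(
            n=2, h=worked_qubo.h, J=worked_qubo.J, c=worked_qubo.c + 7.5
        )
        a, b = qfs.brute_force_select(worked_qubo), qfs.brute_force_select(shifted)
        assert a.indices == b.indices
        assert b.cost == pytest.approx(a.cost + 7.5)

    def test_csv_export_roundtrip(self, worked_qubo, tmp_path):
        path = tmp_path / "qubo.csv"
        worked_qubo.to_csv(path)
        rows = [l.split(",") for l in path.read_text().strip().splitlines()[1:]]
        coeffs = {(int(i), int(j)): float(v) for i, j, v in rows}
        assert coeffs[(0, 0)] == pytest.approx(worked_qubo.h[0])
        assert coeffs[(0, 1)] == pytest.approx(worked_qubo.J[0, 1])


class TestQaoaState:
    def test_zero_angles_give_uniform_state(self, worked_qubo):
        state = qfs.qaoa_state(worked_qubo, [0.0, 0.0], [0.0, 0.0], 2)
        assert np.allclose(state, uniform_state(2), atol=1e-12)

    def test_norm_preserved_for_random_angles(self, worked_qubo, rng):
        for _ in range(10):
            g = rng.uniform(0, 2 * np.pi, 3)
            b = rng.uniform(0, 2 * np.pi, 3)
            state = qfs.qaoa_state(worked_qubo, g, b, 3)
            assert abs(np.linalg.norm(state) - 1.0) < 1e-9

    def test_matches_dense_matrix_product(self, worked_qubo):
        """p=1 evolution against exp(-i*b*H_M) exp(-i*g*H_C) built by hand."""
        g, b = 0.7, 0.3
        costs = worked_qubo.all_costs()
        X = np.array([[0.0, 1.0], [1.0, 0.0]])
        # qubit 0 is the LSB, so X on qubit 0 is kron(I, X)
        HM = np.kron(np.eye(2), X) + np.kron(X, np.eye(2))
        U = sla.expm(-1j * b * HM) @ np.diag(np.exp(-1j * g * costs))
        ref = U @ uniform_state(2)
        state = qfs.qaoa_state(worked_qubo, [g], [b], 1)
        assert np.max(np.abs(state - ref)) < 1e-8

    def test_dimension_mismatch_rejected(self, worked_qubo):
        with pytest.raises(ValueError):
            qfs.qaoa_state(worked_qubo, [0.1], [0.2, 0.3], 2)


class TestExpectation:
    def test_uniform_state_gives_mean_cost(self, worked_qubo):
        e = qfs.qaoa_expectation(worked_qubo, uniform_state(2))
        assert e == pytest.approx(worked_qubo.all_costs().mean())

    def test_basis_state_gives_exact_cost(self, worked_qubo):
        state = np.zeros(4, dtype=complex)
        state[1] = 1.0  # bitstring z = (1, 0)
        assert qfs.qaoa_expectation(worked_qubo, state) == pytest.approx(-1.0)

    def test_expectation_bounded_below_by_optimum(self, worked_qubo, rng):
        best = qfs.brute_force_select(worked_qubo).cost
        for _ in range(20):
            amps = rng.normal(size=4) + 1j * rng.normal(size=4)
            amps /= np.linalg.norm(amps)
            assert qfs.qaoa_expectation(worked_qubo, amps) >= best - 1e-12


class TestOptimizeQaoa:
    def test_never_worse_than_uniform_start(self, worked_qubo):
        cfg = qfs.QaoaConfig(p=1, restarts=2, seed=0)
        _, _, e = qfs.optimize_qaoa(worked_qubo, cfg)
        assert e <= qfs.qaoa_expectation(worked_qubo, uniform_state(2)) + 1e-9

    def test_nested_layers_do_not_hurt(self, worked_qubo):
        cfg1 = qfs.QaoaConfig(p=1, restarts=3, seed=1)
        g1, b1, e1 = qfs.optimize_qaoa(worked_qubo, cfg1)
        cfg2 = qfs.QaoaConfig(p=2, restarts=0, seed=1)
        pad = (np.concatenate([g1, [0.0]]), np.concatenate([b1, [0.0]]))
        _, _, e2 = qfs.optimize_qaoa(worked_qubo, cfg2, init=pad)
        assert e2 <= e1 + 1e-7

    def test_two_feature_qubo_reaches_near_optimum_at_p2(self, worked_qubo):
        cfg = qfs.QaoaConfig(p=2, restarts=8, seed=3)
        _, _, e = qfs.optimize_qaoa(worked_qubo, cfg)
        assert e == pytest.approx(-1.0, abs=0.05)

    def test_deterministic_given_seed(self, worked_qubo):
        cfg = qfs.QaoaConfig(p=2, restarts=2, seed=9)
        out1 = qfs.optimize_qaoa(worked_qubo, cfg)
        out2 = qfs.optimize_qaoa(worked_qubo, cfg)
        assert np.array_equal(out1[0], out2[0]) and out1[2] == out2[2]


class TestSubsetExtraction:
    def test_concentrated_state_returns_its_subset(self, worked_qubo):
        state = np.zeros(4, dtype=complex)
        state[2] = 1.0  # only feature 1 selected
        for mode in ("exact", "sampled"):
            cfg = qfs.QaoaConfig(p=1, mode=mode, seed=0)
            assert qfs.sample_subset(worked_qubo, state, cfg).indices == [1]

    def test_sampled_cost_never_beats_brute_force(self, rng):
        for trial in range(5):
            r = rng.uniform(0, 1, 6)
            rho = np.abs(np.corrcoef(rng.normal(size=(40, 6)), rowvar=False))
            np.fill_diagonal(rho, 0)
            q = qfs.build_qubo(qfs.ScoreTable(r, rho), k=3)
            cfg = qfs.QaoaConfig(p=2, restarts=2, mode="sampled", n_samples=64, seed=trial)
            g, b, _ = qfs.optimize_qaoa(q, cfg)
            sub = qfs.sample_subset(q, qfs.qaoa_state(q, g, b), cfg)
            assert sub.cost >= qfs.brute_force_select(q).cost - 1e-12

    def test_brute_force_refuses_large_problems(self):
        q = qfs.QuboProblem(n=21, h=np.zeros(21), J=np.zeros((21, 21)))
        with pytest.raises(ValueError, match="20"):
            qfs.brute_force_select(q)

    def test_subset_json_export(self, worked_qubo, tmp_path):
        sub = qfs.brute_force_select(worked_qubo)
        sub.to_json(tmp_path / "s.json", seed=5, config={"p": 3})
        import json

        payload = json.loads((tmp_path / "s.json").read_text())
        assert payload["indices"] == [0] and payload["provenance"] == "brute_force"
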