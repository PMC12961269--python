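"""EM kernel assembly, updates, ascent guarantees, and metrics."""

import numpy as np
import pytest
from scipy import sparse

import fluorem as fm

from conftest import random_dictionary


def _unique_string_setup():
    """Two proteins with disjoint single observable strings."""
    d = fm.build_dictionary(
        [("P1", "ACA"), ("P2", "AYA")],
        fm.LabelingScheme(channels=(frozenset("C"), frozenset("Y"))),
    )
    cond = fm.string_conditional(d, 0.0)
    efo = fm.expected_observable_strings(d, 0.0)
    return d, cond, efo


def _random_instance(rng, n_proteins=None, n_reads=None):
    """Random dictionary + posterior + eta table for property tests."""
    n_proteins = n_proteins or int(rng.integers(2, 10))
    d = random_dictionary(rng, n_proteins=n_proteins,
                          length=int(rng.integers(20, 60)))
    m = float(rng.uniform(0.0, 0.6))
    cond = fm.string_conditional(d, m)
    efo = fm.expected_observable_strings(d, m)
    p = fm.sample_abundances(d.n_proteins, rng)
    n_reads = n_reads or int(rng.integers(5, 1000))
    reads = fm.simulate_reads(p, d, m, n_reads, rng)
    n_b = int(rng.integers(1, d.n_observable + 1))
    if rng.random() < 0.5:
        post = fm.oracle_posterior(reads, float(rng.uniform(0, 1)),
                                   d.n_strings, n_b, null_index=d.null_index)
    else:
        post = fm.noisy_posterior(reads, d, float(rng.uniform(0.1, 3.0)), n_b)
    return d, cond, efo, p, post


class TestComputeEta:
    def test_point_mass_unique_strings(self):
        d, cond, efo = _unique_string_setup()
        f1 = d.strings_of(0)[0]
        reads = fm.ReadSet(true_string=np.array([f1]))
        post = fm.oracle_posterior(reads, 0.0, d.n_strings, 1,
                                   null_index=d.null_index)
        eta = fm.compute_eta(post, cond)
        np.testing.assert_allclose(eta.dense(), [[1.0, 0.0]])

    def test_remainder_baseline_arithmetic(self):
        # listed (f0: 0.8), r_k = 0.1; protein with conditional (f0:0.4, f1:0.6)
        # and f1 outside the retained set: eta = 0.1 + 0.8 * 0.4 = 0.42
        listed = sparse.csr_matrix(np.array([[0.8, 0.0, 0.0]]))
        post = fm.SparsePosterior(listed=listed, remainder=np.array([0.1]))
        cond = sparse.csr_matrix(np.array([[0.4, 0.6, 0.0]]))
        eta = fm.compute_eta(post, cond)
        np.testing.assert_allclose(eta.dense(), [[0.42]])

    def test_matches_dense_double_loop(self, rng):
        """With full retention, eta equals a brute-force dense Eq-by-Eq sum."""
        for _ in range(10):
            d, cond, efo, p, _ = _random_instance(rng)
            reads = fm.simulate_reads(p, d, 0.1, 50, rng)
            post = fm.oracle_posterior(reads, 0.3, d.n_strings,
                                       n_b=d.n_observable,
                                       null_index=d.null_index)
            eta = fm.compute_eta(post, fm.string_conditional(d, 0.1))
            conddense = fm.string_conditional(d, 0.1).toarray()
            dense_post = post.dense()
            brute = np.zeros((post.n_reads, d.n_proteins))
            for k in range(post.n_reads):
                for y in range(d.n_proteins):
                    for f in range(d.n_strings):
                        brute[k, y] += dense_post[k, f] * conddense[y, f]
            np.testing.assert_allclose(eta.dense(), brute, atol=1e-12)

    def test_index_mismatch_is_error(self):
        listed = sparse.csr_matrix(np.eye(2))
        post = fm.SparsePosterior(listed=listed, remainder=np.zeros(2))
        cond = sparse.csr_matrix(np.ones((1, 3)) / 3)
        with pytest.raises(ValueError, match="mismatch"):
            fm.compute_eta(post, cond)


class TestEmStep:
    def test_counts_reads_with_unique_strings(self):
        d, cond, efo = _unique_string_setup()
        f1, f2 = d.strings_of(0)[0], d.strings_of(1)[0]
        reads = fm.ReadSet(true_string=np.array([f1, f1, f1, f2]))
        post = fm.oracle_posterior(reads, 0.0, d.n_strings, 1,
                                   null_index=d.null_index)
        eta = fm.compute_eta(post, cond)
        q = fm.em_step(np.array([0.5, 0.5]), eta)
        np.testing.assert_allclose(q, [0.75, 0.25])

    def test_indistinguishable_proteins_are_fixed_points(self, rng):
        # two proteins producing the identical single string
        d = fm.build_dictionary(
            [("P1", "ACA"), ("P2", "ACA")],
            fm.LabelingScheme(channels=(frozenset("C"),)),
        )
        cond = fm.string_conditional(d, 0.0)
        f = d.strings_of(0)[0]
        reads = fm.ReadSet(true_string=np.full(10, f))
        post = fm.oracle_posterior(reads, 0.0, d.n_strings, 1,
                                   null_index=d.null_index)
        eta = fm.compute_eta(post, cond)
        for _ in range(5):
            q = rng.dirichlet(np.ones(2))
            np.testing.assert_allclose(fm.em_step(q, eta), q, atol=1e-12)

    def test_single_protein(self):
        eta = fm.EtaTable(delta=sparse.csr_matrix(np.ones((4, 1))),
                          remainder=np.zeros(4))
        np.testing.assert_allclose(fm.em_step(np.array([1.0]), eta), [1.0])

    def test_degenerate_read_is_error(self):
        eta = fm.EtaTable(delta=sparse.csr_matrix((2, 2)),
                          remainder=np.zeros(2))
        with pytest.raises(ValueError, match="read 0"):
            fm.em_step(np.array([0.5, 0.5]), eta)


class TestSurrogateLoglik:
    def test_unique_string_value(self):
        d, cond, efo = _unique_string_setup()
        f1, f2 = d.strings_of(0)[0], d.strings_of(1)[0]
        reads = fm.ReadSet(true_string=np.array([f1, f1, f1, f2]))
        post = fm.oracle_posterior(reads, 0.0, d.n_strings, 1,
                                   null_index=d.null_index)
        eta = fm.compute_eta(post, cond)
        val = fm.surrogate_loglik(np.array([0.75, 0.25]), eta)
        assert val == pytest.approx(3 * np.log(0.75) + np.log(0.25))

    def test_row_rescaling_shifts_by_constant(self, rng):
        d, cond, efo, p, post = _random_instance(rng, n_reads=30)
        eta = fm.compute_eta(post, cond)
        scaled = fm.EtaTable(delta=eta.delta.multiply(3.0).tocsr(),
                             remainder=eta.remainder * 3.0)
        q1 = rng.dirichlet(np.ones(d.n_proteins))
        q2 = rng.dirichlet(np.ones(d.n_proteins))
        d1 = fm.surrogate_loglik(q1, eta) - fm.surrogate_loglik(q2, eta)
        d2 = fm.surrogate_loglik(q1, scaled) - fm.surrogate_loglik(q2, scaled)
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_ascent_over_random_instances(self):
        """EM never decreases the surrogate log-likelihood (100 instances)."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            d, cond, efo, p, post = _random_instance(rng)
            eta = fm.compute_eta(post, cond)
            q = rng.dirichlet(np.ones(d.n_proteins))
            ll = fm.surrogate_loglik(q, eta)
            for _ in range(5):
                q = fm.em_step(q, eta)
                ll_new = fm.surrogate_loglik(q, eta)
                assert ll_new >= ll - 1e-8
                ll = ll_new


class TestRunEm:
    def test_zero_epochs_returns_init(self, toy_dictionary):
        p = fm.sample_abundances(5, 0)
        reads = fm.simulate_reads(p, toy_dictionary, 0.1, 100, 1)
        post = fm.oracle_posterior(reads, 0.0, toy_dictionary.n_strings, 1,
                                   null_index=toy_dictionary.null_index)
        cond = fm.string_conditional(toy_dictionary, 0.1)
        efo = fm.expected_observable_strings(toy_dictionary, 0.1)
        state, _ = fm.run_em(post, cond, efo, fm.EMConfig(max_epochs=0))
        np.testing.assert_allclose(state.q, np.full(5, 0.2))

    def test_uniform_posteriors_keep_uniform_init(self, toy_dictionary):
        n_obs = toy_dictionary.n_observable
        reads = fm.ReadSet(
            true_string=np.array(toy_dictionary.strings_of(0)[:3])
        )
        post = fm.oracle_posterior(reads, 1.0, toy_dictionary.n_strings,
                                   n_b=n_obs,
                                   null_index=toy_dictionary.null_index)
        cond = fm.string_conditional(toy_dictionary, 0.1)
        efo = fm.expected_observable_strings(toy_dictionary, 0.1)
        state, _ = fm.run_em(post, cond, efo, fm.EMConfig(max_epochs=5))
        np.testing.assert_allclose(state.q, np.full(5, 0.2), atol=1e-12)

    def test_perfect_oracle_recovers_abundances(self, toy_dictionary):
        """With e=0 and many reads, the estimate converges on the truth."""
        p_true = fm.sample_abundances(5, 12)
        reads = fm.simulate_reads(p_true, toy_dictionary, 0.1, 1_000_000, 13)
        post = fm.oracle_posterior(reads, 0.0, toy_dictionary.n_strings, 1,
                                   null_index=toy_dictionary.null_index)
        cond = fm.string_conditional(toy_dictionary, 0.1)
        efo = fm.expected_observable_strings(toy_dictionary, 0.1)
        state, p_hat = fm.run_em(post, cond, efo, p_true=p_true)
        assert fm.mae(p_hat, p_true) < 1e-3

    def test_sparse_matches_dense_trajectory(self, rng):
        """With N_b = |D_F|, the sparse update equals brute-force dense EM."""
        for _ in range(5):
            d, cond, efo, p, _ = _random_instance(rng)
            reads = fm.simulate_reads(p, d, 0.2, 200, rng)
            post = fm.oracle_posterior(reads, 0.4, d.n_strings,
                                       n_b=d.n_observable,
                                       null_index=d.null_index)
            assert np.allclose(post.remainder, 0.0)
            cond = fm.string_conditional(d, 0.2)
            eta_dense = post.dense() @ cond.toarray().T  # (reads, proteins)
            q_sparse = np.full(d.n_proteins, 1.0 / d.n_proteins)
            q_dense = q_sparse.copy()
            eta = fm.compute_eta(post, cond)
            for _ in range(10):
                q_sparse = fm.em_step(q_sparse, eta)
                gamma = eta_dense * q_dense
                gamma /= gamma.sum(axis=1, keepdims=True)
                q_dense = gamma.mean(axis=0)
                np.testing.assert_allclose(q_sparse, q_dense, atol=1e-10)

    def test_oracle_mae_early_stop_selects_best_epoch(self, toy_dictionary):
        p_true = fm.sample_abundances(5, 4)
        reads = fm.simulate_reads(p_true, toy_dictionary, 0.1, 2000, 5)
        post = fm.oracle_posterior(reads, 0.6, toy_dictionary.n_strings, 10,
                                   null_index=toy_dictionary.null_index)
        cond = fm.string_conditional(toy_dictionary, 0.1)
        efo = fm.expected_observable_strings(toy_dictionary, 0.1)
        state, p_hat = fm.run_em(
            post, cond, efo, fm.EMConfig(early_stop="oracle-mae"),
            p_true=p_true,
        )
        assert state.oracle_stopped
        assert state.selected_epoch == int(np.argmin(state.mae_trace))
        assert fm.mae(p_hat, p_true) == pytest.approx(min(state.mae_trace))

    def test_oracle_mae_stop_requires_truth(self, toy_dictionary):
        p = fm.sample_abundances(5, 4)
        reads = fm.simulate_reads(p, toy_dictionary, 0.1, 100, 5)
        post = fm.oracle_posterior(reads, 0.0, toy_dictionary.n_strings, 1,
                                   null_index=toy_dictionary.null_index)
        cond = fm.string_conditional(toy_dictionary, 0.1)
        efo = fm.expected_observable_strings(toy_dictionary, 0.1)
        with pytest.raises(ValueError, match="simulation-only"):
            fm.run_em(post, cond, efo, fm.EMConfig(early_stop="oracle-mae"))


class TestMae:
    def test_identical_vectors(self):
        assert fm.mae(np.array([0.3, 0.7]), np.array([0.3, 0.7])) == 0.0

    def test_worked_example(self):
        assert fm.mae(np.array([0.5, 0.5]), np.array([1.0, 0.0])) == 0.5

    def test_uniform_baseline(self):
        p = np.array([0.7, 0.1, 0.1, 0.1])
        expected = np.abs(p - 0.25).mean()
        assert fm.uniform_baseline_mae(p) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fm.mae(np.array([1.0]), np.array([0.5, 0.5]))


class TestEvaluateRun:
    def _states(self, traces):
        return [
            fm.EMState(q=np.array([1.0]), epoch=len(t) - 1,
                       surrogate_loglik_trace=[0.0] * len(t), mae_trace=t,
                       selected_epoch=len(t) - 1)
            for t in traces
        ]

    def test_single_dataset_has_zero_std(self):
        df = fm.evaluate_run(self._states([[0.4, 0.2, 0.1]]))
        np.testing.assert_allclose(df["mae_std"], 0.0)
        np.testing.assert_allclose(df["mae_mean"], [0.4, 0.2, 0.1])

    def test_identical_datasets_mean_equals_trace(self):
        df = fm.evaluate_run(self._states([[0.3, 0.1]] * 4))
        np.testing.assert_allclose(df["mae_mean"], [0.3, 0.1])
        np.testing.assert_allclose(df["mae_std"], 0.0)

    def test_baseline_ratio(self):
        df = fm.evaluate_run(self._states([[0.4, 0.02], [0.4, 0.04]]),
                             baseline_maes=[0.3, 0.3])
        assert df.attrs["baseline_ratio"] == pytest.approx(0.3 / 0.03)

    def test_missing_truth_is_error(self):
        state = fm.EMState(q=np.array([1.0]), epoch=0,
                           surrogate_loglik_trace=[0.0], mae_trace=None)
        with pytest.raises(ValueError, match="truth"):
            fm.evaluate_run([state])


class TestStudyProtocol:
    def test_small_study_end_to_end(self, toy_dictionary):
        cfg = fm.StudyConfig(n_reads=5000, n_datasets=3, e=0.1, m=0.1,
                             n_b=10, max_epochs=10, seed=5)
        res = fm.run_study(toy_dictionary, cfg)
        assert len(res.states) == 3
        assert res.summary.shape[0] == 11  # init + 10 epochs
        assert res.baseline_ratio > 1.0
        for p_hat in res.p_hats:
            assert abs(p_hat.sum() - 1) < 1e-9

    def test_study_is_reproducible(self, toy_dictionary):
        cfg = fm.StudyConfig(n_reads=2000, n_datasets=2, e=0.2, max_epochs=5,
                             seed=9)
        r1 = fm.run_study(toy_dictionary, cfg)
        r2 = fm.run_study(toy_dictionary, cfg)
        for a, b in zip(r1.p_hats, r2.p_hats):
            np.testing.assert_array_equal(a, b)

    def test_kernel_posterior_study(self, toy_dictionary):
        cfg = fm.StudyConfig(n_reads=3000, n_datasets=2, m=0.1,
                             posterior="kernel", kernel_decay=2.0,
                             n_b=10, max_epochs=10, seed=2)
        res = fm.run_study(toy_dictionary, cfg)
        assert res.baseline_ratio > 1.0
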