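import numpy as np
import pytest
from scipy.special import digamma, gammaln

from helpers_oracles import exact_log_evidence

from connfact.connectome import encode_counts
from connfact.lda import (
    FactorModel, bootstrap_profiles, brute_force_match, elbo, fit_lda,
    infer_expression, match_factors, predictive_log_likelihood, scan_k,
    threshold_profile,
)
from connfact.synthetic import generate_edge_profiles


def _toy_model(beta, alpha=None, eta=0.01):
    beta = np.asarray(beta, dtype=float)
    k = beta.shape[0]
    alpha = np.full(k, 1.0) if alpha is None else np.asarray(alpha, float)
    return FactorModel(beta=beta, lambda_=beta * 1e4 + eta, alpha=alpha,
                       eta=eta)


class TestFitLda:
    def test_separable_corpus_recovers_groups(self, separable_corpus):
        model, loadings = fit_lda(separable_corpus, 2, alpha=0.5,
                                  n_restarts=4, seed=0)
        masses = sorted([model.beta[0, :3].sum(), model.beta[1, :3].sum()])
        assert masses[0] <= 0.01 and masses[1] >= 0.99
        assert np.all(loadings.max(axis=1) > 0.9)

    def test_k1_degenerate(self, separable_corpus):
        model, loadings = fit_lda(separable_corpus, 1, alpha=1.0, eta=0.5,
                                  n_restarts=1, seed=0)
        np.testing.assert_allclose(loadings, 1.0)
        counts = separable_corpus.sum(axis=0)
        expected = (counts + 0.5) / (counts.sum() + 0.5 * counts.size)
        np.testing.assert_allclose(model.beta[0], expected, atol=1e-8)

    def test_row_stochastic_invariants(self, separable_corpus):
        model, loadings = fit_lda(separable_corpus, 3, n_restarts=2, seed=1)
        np.testing.assert_allclose(model.beta.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(model.beta > 0)
        np.testing.assert_allclose(loadings.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(loadings >= 0)

    def test_elbo_monotone_within_restart(self, separable_corpus):
        model, _ = fit_lda(separable_corpus, 2, n_restarts=1, seed=2)
        diffs = np.diff(model.fit_log)
        assert np.all(diffs > -1e-6 * np.abs(np.array(model.fit_log[:-1])))

    def test_best_restart_selected(self, separable_corpus):
        model, _ = fit_lda(separable_corpus, 2, n_restarts=5, seed=3)
        assert model.fit_log[-1] == pytest.approx(max(model.restart_elbos))

    def test_errors(self, separable_corpus):
        with pytest.raises(ValueError, match="empty corpus"):
            fit_lda(np.zeros((0, 4)), 2)
        with pytest.raises(ValueError, match="exceeds"):
            fit_lda(separable_corpus[:3], 5)
        with pytest.raises(ValueError, match="token"):
            fit_lda(np.zeros((3, 4)), 2)

    def test_nonconvergence_flagged(self, separable_corpus):
        with pytest.warns(RuntimeWarning, match="converge"):
            model, _ = fit_lda(separable_corpus, 2, n_restarts=1, max_iter=2,
                               seed=0)
        assert not model.converged

    def test_deterministic_under_seed(self, separable_corpus):
        a, la = fit_lda(separable_corpus, 2, n_restarts=2, seed=4)
        b, lb = fit_lda(separable_corpus, 2, n_restarts=2, seed=4)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(la, lb)

    def test_agreement_with_sklearn_bound(self, separable_corpus):
        """Final ELBO within 1% of scikit-learn's variational bound with
        matched hyperparameters (independent implementation)."""
        sklearn_lda = pytest.importorskip(
            "sklearn.decomposition").LatentDirichletAllocation
        alpha, eta = 0.5, 0.1
        model, _ = fit_lda(separable_corpus, 2, alpha=alpha, eta=eta,
                           n_restarts=5, max_iter=500, tol=1e-8, seed=0)
        ours = elbo(model, separable_corpus)
        sk = sklearn_lda(n_components=2, doc_topic_prior=alpha,
                         topic_word_prior=eta, learning_method="batch",
                         max_iter=500, random_state=0)
        sk.fit(separable_corpus)
        theirs = sk.score(separable_corpus)
        assert abs(ours - theirs) <= 0.01 * abs(theirs)


class TestElbo:
    def test_k1_closed_form(self):
        x = np.array([[3, 1, 0], [0, 2, 2]], dtype=float)
        eta = 0.5
        model, _ = fit_lda(x, 1, alpha=1.0, eta=eta, n_restarts=1, seed=0)
        counts = x.sum(axis=0)
        lam = eta + counts
        elog = digamma(lam) - digamma(lam.sum())
        expected = float(counts @ elog)
        expected += float(np.sum((eta - lam) * elog))
        expected += float(np.sum(gammaln(lam)) - gammaln(lam.sum()))
        expected -= float(3 * gammaln(eta) - gammaln(3 * eta))
        assert elbo(model, x) == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("corpus", [
        [[1, 1, 2], [2, 1, 1]],
        [[1, 2, 0], [2, 2, 0]],
        [[2, 0, 0], [2, 0, 1]],
    ])
    def test_lower_bounds_exact_evidence(self, corpus):
        x = np.array(corpus, dtype=float)
        alpha, eta = [0.7, 1.3], 0.5
        exact = exact_log_evidence(x, alpha, eta)
        model, _ = fit_lda(x, 2, alpha=alpha, eta=eta, n_restarts=8,
                           max_iter=300, tol=1e-10, seed=0)
        assert elbo(model, x) <= exact + 1e-9


class TestInferExpression:
    def test_pure_factor_document(self):
        beta = np.array([[0.30, 0.30, 0.30, 0.05, 0.03, 0.02],
                         [0.02, 0.03, 0.05, 0.30, 0.30, 0.30]])
        model = _toy_model(beta)
        rng = np.random.default_rng(0)
        doc = rng.multinomial(10_000, beta[0]).astype(float)
        expr = infer_expression(model, doc)
        assert expr[0] >= 0.95

    def test_training_documents_round_trip(self, separable_corpus):
        model, train = fit_lda(separable_corpus, 2, n_restarts=3, seed=0)
        rein = infer_expression(model, separable_corpus)
        assert np.max(np.abs(rein - train)) < 0.02

    def test_single_token_document(self):
        beta = np.array([[0.7, 0.2, 0.1], [0.1, 0.2, 0.7]])
        model = _toy_model(beta, alpha=[1.0, 1.0])
        doc = np.array([1.0, 0.0, 0.0])
        expr = infer_expression(model, doc)
        assert expr.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(expr >= 0)
        assert expr[0] > expr[1]  # follows beta[:, 0] under symmetric alpha

    def test_vocabulary_mismatch_rejected(self):
        model = _toy_model(np.array([[0.5, 0.5], [0.4, 0.6]]))
        with pytest.raises(ValueError, match="vocabulary"):
            infer_expression(model, np.array([1.0, 2.0, 3.0]))

    def test_deterministic(self):
        beta = np.array([[0.6, 0.3, 0.1], [0.1, 0.3, 0.6]])
        model = _toy_model(beta)
        doc = np.array([3.0, 2.0, 5.0])
        np.testing.assert_array_equal(infer_expression(model, doc),
                                      infer_expression(model, doc))


class TestMatchFactors:
    def test_recovers_row_permutation(self, rng):
        beta = rng.dirichlet(np.ones(30), size=4)
        perm = np.array([2, 0, 3, 1])
        recovered = match_factors(beta, beta[perm])
        # beta[i] sits at row argwhere(perm == i) of the permuted matrix
        np.testing.assert_array_equal(recovered, np.argsort(perm))

    def test_identical_rows_tie_break(self):
        beta = np.array([[0.2, 0.3, 0.5], [0.2, 0.3, 0.5]])
        np.testing.assert_array_equal(match_factors(beta, beta), [0, 1])

    def test_matches_brute_force_k4(self, rng):
        for _ in range(20):
            a = rng.dirichlet(np.ones(12), size=4)
            b = rng.dirichlet(np.ones(12), size=4)
            np.testing.assert_array_equal(match_factors(a, b),
                                          brute_force_match(a, b))


class TestThresholdProfile:
    def test_fraction_one_keeps_all_significant(self):
        w = np.array([1.0, -2.0, 0.0, 3.0])
        mask = threshold_profile(w, 1.0)
        np.testing.assert_array_equal(mask, [True, True, False, True])

    def test_magnitude_ranking(self):
        w = np.array([5.0, -4.0, 3.0, 1.0])
        mask = threshold_profile(w, 0.5)
        np.testing.assert_array_equal(mask, [True, True, False, False])

    def test_count_contract(self, rng):
        for n in [1, 2, 7, 10, 33]:
            w = rng.normal(size=n)
            w[np.abs(w) < 0.05] = 0.1  # keep all nonzero
            assert threshold_profile(w, 0.5).sum() == int(np.ceil(0.5 * n))

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            threshold_profile(np.ones(3), 0.0)


class TestBootstrapProfiles:
    @pytest.fixture(scope="class")
    def planted_corpus(self):
        profiles = generate_edge_profiles(2, 60, sparsity=0.3, seed=0)
        rng = np.random.default_rng(1)
        loadings = rng.dirichlet([1.0, 1.0], 60)
        dev = loadings @ profiles + rng.normal(0, 0.5, (60, 60))
        return np.array([encode_counts(d / 0.5, scale=10).counts
                         for d in dev], dtype=float), profiles

    def test_small_b_rejected(self, planted_corpus):
        with pytest.raises(ValueError, match="B"):
            bootstrap_profiles(planted_corpus[0], 2, B=5)

    def test_mask_matches_q(self, planted_corpus):
        docs, _ = planted_corpus
        ci = bootstrap_profiles(docs, 2, B=25, seed=0, max_iter=60,
                                alpha=1.0)
        np.testing.assert_array_equal(ci.mask, ci.q < 0.05)
        assert np.all(np.isfinite(ci.z[ci.boot_sd > 0]))

    def test_seed_reproducible(self, planted_corpus):
        docs, _ = planted_corpus
        a = bootstrap_profiles(docs, 2, B=20, seed=3, max_iter=40, alpha=1.0)
        b = bootstrap_profiles(docs, 2, B=20, seed=3, max_iter=40, alpha=1.0)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_strong_edges_detected(self, planted_corpus):
        docs, profiles = planted_corpus
        ci = bootstrap_profiles(docs, 2, B=30, seed=0, max_iter=60,
                                alpha=1.0)
        perm = match_factors(profiles, ci.signed_profile)
        strong = np.abs(profiles) > 1.0
        hits = ci.mask[perm][strong]
        assert hits.mean() > 0.5


class TestScanK:
    def test_singleton_range(self, separable_corpus):
        table = scan_k(separable_corpus, [2], n_folds=2, seed=0,
                       n_restarts=1, max_iter=50)
        assert len(table) == 1
        assert table.loc[0, "K"] == 2

    def test_deterministic(self, separable_corpus):
        a = scan_k(separable_corpus, [2, 3], n_folds=2, seed=1,
                   n_restarts=1, max_iter=50)
        b = scan_k(separable_corpus, [2, 3], n_folds=2, seed=1,
                   n_restarts=1, max_iter=50)
        np.testing.assert_array_equal(a["heldout_loglik"], b["heldout_loglik"])

    def test_recovers_planted_k(self):
        """K=4 data: held-out likelihood at K=4 beats K=2 in >= 90% of
        20 seeds (reduced corpus size for runtime)."""
        wins = 0
        for seed in range(20):
            profiles = generate_edge_profiles(4, 120, sparsity=0.2,
                                              seed=seed)
            rng = np.random.default_rng(seed + 100)
            loadings = rng.dirichlet([1.0] * 4, 80)
            dev = loadings @ profiles + rng.normal(0, 0.5, (80, 120))
            docs = np.array([encode_counts(d / 0.5, scale=10).counts
                             for d in dev], dtype=float)
            table = scan_k(docs, [2, 4], n_folds=3, seed=seed,
                           n_restarts=1, max_iter=60, alpha=1.0)
            wins += (table.set_index("K").loc[4, "heldout_loglik"]
                     >= table.set_index("K").loc[2, "heldout_loglik"])
        assert wins >= 18


class TestSerialization:
    def test_round_trip(self, tmp_path, separable_corpus):
        vocab = [f"w{i}" for i in range(6)]
        model, _ = fit_lda(separable_corpus, 2, n_restarts=1, seed=0,
                           vocabulary=vocab)
        model.save(tmp_path / "model")
        loaded = FactorModel.load(tmp_path / "model",
                                  expect_vocabulary=vocab)
        np.testing.assert_allclose(loaded.beta, model.beta)
        np.testing.assert_allclose(loaded.alpha, model.alpha)
        assert loaded.eta == model.eta

    def test_vocabulary_hash_checked(self, tmp_path, separable_corpus):
        model, _ = fit_lda(separable_corpus, 2, n_restarts=1, seed=0,
                           vocabulary=[f"w{i}" for i in range(6)])
        model.save(tmp_path / "model")
        with pytest.raises(ValueError, match="vocabulary"):
            FactorModel.load(tmp_path / "model",
                             expect_vocabulary=[f"x{i}" for i in range(6)])

    def test_signed_profile_definition(self):
        beta = np.array([[0.4, 0.1, 0.2, 0.3]])
        model = _toy_model(beta, alpha=[1.0])
        np.testing.assert_allclose(model.signed_profiles(),
                                   [[0.4 - 0.2, 0.1 - 0.3]])


def test_predictive_log_likelihood_matches_plugin(separable_corpus):
    model, _ = fit_lda(separable_corpus, 2, n_restarts=1, seed=0)
    theta = infer_expression(model, separable_corpus)
    manual = float(np.sum(separable_corpus *
                          np.log(theta @ model.beta + 1e-100)))
    assert predictive_log_likelihood(model, separable_corpus) == \
        pytest.approx(manual)
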