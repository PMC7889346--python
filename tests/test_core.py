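import numpy as np
import pytest

from advbpr.core import (
    FactorModel,
    Hyperparams,
    adversarial_delta,
    bpr_gradients,
    bpr_loss,
    predict_ranking,
    ranking_gradients,
    score,
    simgaus_gradient,
    simgaus_term,
    top_fraction,
    train,
)
from advbpr.data import TripleSet


def fd_gradient(fun, x, h=1e-6):
    """Central finite differences of a scalar function of a vector."""
    g = np.zeros_like(x)
    for q in range(x.size):
        e = np.zeros_like(x)
        e[q] = h
        g[q] = (fun(x + e) - fun(x - e)) / (2 * h)
    return g


def rel_err(a, b):
    return np.linalg.norm(a - b) / max(np.linalg.norm(b), 1e-12)


class TestScore:
    def test_orthogonal_and_aligned(self):
        model = FactorModel(F_D=np.array([[1.0, 0.0], [1.0, 1.0]]),
                            F_T=np.array([[0.0, 1.0], [1.0, 1.0]]))
        assert score(model, 0, 0) == 0.0
        assert score(model, 1, 1) == 2.0

    def test_matches_elementwise_sum(self, small_model, rng):
        i, j = 2, 7
        expected = sum(small_model.F_D[i][q] * small_model.F_T[j][q] for q in range(4))
        assert score(small_model, i, j) == pytest.approx(expected, rel=1e-12)

    def test_out_of_range(self, small_model):
        with pytest.raises(IndexError):
            score(small_model, 99, 0)


class TestBprLoss:
    def test_zero_gap_is_ln2(self):
        model = FactorModel(F_D=np.zeros((1, 3)), F_T=np.zeros((2, 3)))
        assert bpr_loss((0, 0, 1), model, 0.0) == pytest.approx(np.log(2.0), rel=1e-12)

    def test_softplus_tail(self):
        # score gap +20 -> loss is -ln(sigma(20)) ~ 2.06e-9, no overflow
        model = FactorModel(F_D=np.array([[20.0]]), F_T=np.array([[1.0], [0.0]]))
        assert bpr_loss((0, 0, 1), model, 0.0) == pytest.approx(
            np.log1p(np.exp(-20.0)), rel=1e-9
        )

    def test_regularized_unit_rows(self):
        model = FactorModel(F_D=np.array([[1.0, 0.0]]),
                            F_T=np.array([[0.0, 1.0], [0.0, -1.0]]))
        # gap = 0 - 0 ... choose rows so r_ij = r_ik: F_i=(1,0), F_j=(0,1), F_k=(0,-1)
        # r_ij = 0, r_ik = 0; all rows unit norm
        assert bpr_loss((0, 0, 1), model, 1.0) == pytest.approx(np.log(2.0) + 3.0)

    def test_extreme_gap_is_finite(self):
        model = FactorModel(F_D=np.array([[500.0]]), F_T=np.array([[1.0], [-1.0]]))
        assert np.isfinite(bpr_loss((0, 0, 1), model, 0.0))
        assert np.isfinite(bpr_loss((0, 1, 0), model, 0.0))

    def test_sigmoid_antisymmetry(self, small_model, rng):
        # sigma(g) + sigma(-g) = 1 <=> exp(-loss(j,k)) + exp(-loss(k,j)) = 1
        for _ in range(20):
            i, j, k = rng.integers(0, 6), rng.integers(0, 10), rng.integers(0, 10)
            if j == k:
                continue
            a = np.exp(-bpr_loss((i, j, k), small_model, 0.0))
            b = np.exp(-bpr_loss((i, k, j), small_model, 0.0))
            assert a + b == pytest.approx(1.0, abs=1e-12)


class TestBprGradients:
    def test_symmetric_targets_leave_only_regularizer(self):
        F_T = np.vstack([np.ones(3), np.ones(3)])
        model = FactorModel(F_D=np.array([[0.5, -1.0, 2.0]]), F_T=F_T)
        gi, _, _ = bpr_gradients((0, 0, 1), model, lambda_theta=0.2)
        np.testing.assert_allclose(gi, 2 * 0.2 * model.F_D[0], atol=1e-12)

    def test_matches_finite_differences(self, rng):
        for _ in range(10):
            model = FactorModel(F_D=rng.standard_normal((3, 4)),
                                F_T=rng.standard_normal((5, 4)))
            triple = (1, 0, 3)
            lam = 0.1
            gi, gj, gk = bpr_gradients(triple, model, lam)

            def loss_with(row, attr, idx):
                M = getattr(model, attr).copy()
                M[idx] = row
                m2 = FactorModel(
                    F_D=M if attr == "F_D" else model.F_D,
                    F_T=M if attr == "F_T" else model.F_T,
                )
                return bpr_loss(triple, m2, lam)

            assert rel_err(gi, fd_gradient(lambda r: loss_with(r, "F_D", 1), model.F_D[1].copy())) < 1e-5
            assert rel_err(gj, fd_gradient(lambda r: loss_with(r, "F_T", 0), model.F_T[0].copy())) < 1e-5
            assert rel_err(gk, fd_gradient(lambda r: loss_with(r, "F_T", 3), model.F_T[3].copy())) < 1e-5

    def test_swapping_targets_negates_sigmoid_term(self, small_model):
        lam = 0.0
        gi_fwd, _, _ = bpr_gradients((0, 1, 2), small_model, lam)
        gi_rev, _, _ = bpr_gradients((0, 2, 1), small_model, lam)
        fj, fk = small_model.F_T[1], small_model.F_T[2]
        g = float(small_model.F_D[0] @ (fj - fk))
        s_fwd = 1 / (1 + np.exp(g))
        s_rev = 1 / (1 + np.exp(-g))
        np.testing.assert_allclose(gi_fwd, -s_fwd * (fj - fk), atol=1e-12)
        np.testing.assert_allclose(gi_rev, s_rev * (fj - fk), atol=1e-12)


class TestAdversarialDelta:
    def test_direction_and_norm(self):
        model = FactorModel(F_D=np.array([[1.0, 2.0]]),
                            F_T=np.array([[3.0, 4.0], [0.0, 0.0]]))
        delta = adversarial_delta((0, 0, 1), model, epsilon=0.1)
        gi, gj, gk = ranking_gradients((0, 0, 1), model)
        np.testing.assert_allclose(
            delta.delta_di, 0.1 * gi / np.linalg.norm(gi), atol=1e-15
        )
        # gradient block (3,4) direction scaled to eps: sanity on the k block
        np.testing.assert_allclose(
            delta.delta_tk, 0.1 * gk / np.linalg.norm(gk), atol=1e-15
        )

    def test_epsilon_zero_gives_zero(self, small_model):
        d = adversarial_delta((0, 1, 2), small_model, epsilon=0.0)
        assert not d.delta_di.any() and not d.delta_tj.any() and not d.delta_tk.any()

    def test_unit_block_example(self):
        # gradient block proportional to (3,4) with eps=0.1 -> (0.06, 0.08)
        model = FactorModel(F_D=np.array([[0.0, 0.0]]),
                            F_T=np.array([[3.0, 4.0], [0.0, 0.0]]))
        # at zero drug factor, sigma term is 1/2: Gamma_i = -(1/2)(fj-fk) ~ -(1.5, 2)
        d = adversarial_delta((0, 0, 1), model, epsilon=0.1)
        np.testing.assert_allclose(np.abs(d.delta_di), [0.06, 0.08], atol=1e-12)

    def test_nonzero_blocks_have_norm_epsilon(self, small_model, rng):
        eps = 0.37
        for _ in range(25):
            i = int(rng.integers(0, 6))
            j, k = rng.choice(10, size=2, replace=False)
            d = adversarial_delta((i, int(j), int(k)), small_model, eps)
            for block in (d.delta_di, d.delta_tj, d.delta_tk):
                if block.any():
                    assert abs(np.linalg.norm(block) - eps) < 1e-12


class TestSimGaus:
    def test_identical_factors_all_one_similarity(self):
        F = np.tile([1.0, 2.0], (4, 1))
        S = np.ones((4, 4))
        assert simgaus_term(S, F, 0) == pytest.approx(0.0, abs=1e-15)
        np.testing.assert_allclose(simgaus_gradient(S, F, 0), 0.0, atol=1e-15)

    def test_gaussian_matches_half_similarity(self):
        # ||F_0 - F_1||^2 = ln 2  =>  e^{-d^2} = 0.5 exactly
        F = np.array([[0.0], [np.sqrt(np.log(2.0))]])
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert simgaus_term(S, F, 0) == pytest.approx(0.0, abs=1e-12)

    def test_dissimilar_term_vanishes_with_distance(self):
        S = np.array([[1.0, 0.0], [0.0, 1.0]])
        vals = [
            simgaus_term(S, np.array([[0.0], [d]]), 0) for d in (0.5, 1.0, 2.0, 4.0)
        ]
        assert vals == sorted(vals, reverse=True)
        assert vals[-1] == pytest.approx(0.0, abs=1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        for _ in range(10):
            F = rng.standard_normal((3, 2))
            S = rng.uniform(0, 1, (3, 3))
            S = (S + S.T) / 2
            np.fill_diagonal(S, 1.0)
            g = simgaus_gradient(S, F, 1)

            def term(row):
                F2 = F.copy()
                F2[1] = row
                return simgaus_term(S, F2, 1)

            assert rel_err(g, fd_gradient(term, F[1].copy())) < 1e-5

    def test_gradient_pushes_away_from_dissimilar_neighbor(self):
        F = np.array([[0.0, 0.0], [0.3, 0.0]])
        S = np.array([[1.0, 0.0], [0.0, 1.0]])
        g = simgaus_gradient(S, F, 0)
        # descent step -g moves F_0 further from F_1 (negative x direction)
        assert -g[0] < 0

    def test_misaligned_shapes_raise(self):
        with pytest.raises(ValueError):
            simgaus_term(np.ones((3, 3)), np.zeros((4, 2)), 0)


class TestTrain:
    def test_reduces_to_plain_bpr_bit_for_bit(self, small_triples):
        hp = Hyperparams(f=4, lambda_adv=0.0, lambda_sim=0.0, seed=7, n_epochs=15)
        res = train(small_triples, None, None, hp, n_drugs=6, n_targets=10)

        # independent plain-BPR reference with the same seeding convention
        rng = np.random.default_rng(hp.seed)
        FD = rng.normal(0.0, 0.01, size=(6, 4))
        FT = rng.normal(0.0, 0.01, size=(10, 4))
        tri = small_triples.triples
        for _ in range(hp.n_epochs):
            for row in rng.permutation(len(tri)):
                i, j, k = tri[row]
                fi, fj, fk = FD[i], FT[j], FT[k]
                g = float(fi @ (fj - fk))
                s = 1.0 / (1.0 + np.exp(g)) if g < 0 else np.exp(-g) / (1.0 + np.exp(-g))
                gi = -s * (fj - fk) + 2.0 * hp.lambda_theta * fi
                gj = -s * fi + 2.0 * hp.lambda_theta * fj
                gk = s * fi + 2.0 * hp.lambda_theta * fk
                FD[i] = fi - hp.learning_rate * gi
                FT[j] = fj - hp.learning_rate * gj
                FT[k] = fk - hp.learning_rate * gk
        np.testing.assert_array_equal(res.model.F_D, FD)
        np.testing.assert_array_equal(res.model.F_T, FT)

    def test_deterministic_given_seed(self, small_triples, rng):
        S_D = np.eye(6)
        S_T = np.eye(10)
        hp = Hyperparams(f=3, seed=5, n_epochs=3)
        a = train(small_triples, S_D, S_T, hp)
        b = train(small_triples, S_D, S_T, hp)
        np.testing.assert_array_equal(a.model.F_D, b.model.F_D)
        np.testing.assert_array_equal(a.loss_trace, b.loss_trace)

    def test_loss_trace_mostly_decreasing_at_default_rate(self):
        from advbpr.data import generate_triples, sample_negatives
        from advbpr.similarity import similarity_matrix
        from advbpr.synthetic import SyntheticConfig, generate

        cfg = SyntheticConfig(
            m_drugs=15, n_targets=10, n_nontargets=30, f_true=3, f_dim=40,
            interaction_rate=0.1, seed=0,
        )
        drugs, targets, im, _ = generate(cfg)
        ts = generate_triples(im.positive_pairs(), sample_negatives(im, seed=0))
        hp = Hyperparams(f=3, seed=0, n_epochs=30)  # default learning rate 0.03
        res = train(ts, similarity_matrix(drugs), similarity_matrix(targets), hp)
        diffs = np.diff(res.loss_trace)
        assert (diffs <= 1e-12).mean() >= 0.8

    def test_empty_triples_rejected(self, default_hp):
        with pytest.raises(ValueError):
            train(TripleSet(np.empty((0, 3))), None, None, default_hp,
                  n_drugs=2, n_targets=2)


class TestPredictRanking:
    def test_descending_by_score(self):
        model = FactorModel(F_D=np.array([[1.0]]), F_T=np.array([[0.9], [0.1]]))
        assert [t for t, _ in predict_ranking(model, 0, [0, 1])] == [0, 1]

    def test_tie_broken_by_index(self):
        model = FactorModel(F_D=np.array([[1.0]]), F_T=np.array([[0.5], [0.5], [0.5]]))
        assert [t for t, _ in predict_ranking(model, 0, [2, 0, 1])] == [0, 1, 2]

    def test_matches_sort_oracle(self, rng):
        model = FactorModel(F_D=rng.standard_normal((1, 3)),
                            F_T=rng.standard_normal((100, 3)))
        ranked = predict_ranking(model, 0, range(100))
        scores = model.F_D[0] @ model.F_T.T
        oracle = sorted(range(100), key=lambda t: (-scores[t], t))
        assert [t for t, _ in ranked] == oracle

    def test_exclusion_and_empty_error(self, small_model):
        ranked = predict_ranking(small_model, 0, [0, 1, 2], exclude={1})
        assert 1 not in [t for t, _ in ranked]
        with pytest.raises(ValueError):
            predict_ranking(small_model, 0, [1], exclude={1})


class TestTopFraction:
    def test_basic_counts(self):
        pairs = [(0, j, 1.0 - j * 0.001) for j in range(1000)]
        assert len(top_fraction(pairs, 0.01)) == 10
        assert len(top_fraction(pairs, 1.0)) == 1000

    def test_removal_happens_before_cut(self):
        pairs = [(0, j, 10.0 - j) for j in range(10)]
        known = {(0, 0), (0, 1)}  # the two top-scored pairs are known
        kept = top_fraction(pairs, 0.25, known_positives=known)
        # removal first: ceil(0.25 * 8) = 2 novel pairs, starting at rank 3
        assert [j for _, j, _ in kept] == [2, 3]
        # cut-then-removal would instead keep only pair 2: the orders differ
        cut_first = [p for p in pairs[:3] if (p[0], p[1]) not in known]
        assert [j for _, j, _ in cut_first] == [2]

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            top_fraction([(0, 0, 1.0)], 0.0)
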