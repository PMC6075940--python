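"""Learner mechanics: initialisation, forward pass, gradients, pruning, scoring."""

import numpy as np
import pytest

import giftedsim as gs
from giftedsim.network import binary_csr, pattern_loss, prepare_patterns
from conftest import make_params


@pytest.fixture(scope="module")
def small_patterns():
    cfg = gs.CorpusConfig(class_counts=(20, 3, 5, 2), n_novel=10)
    return gs.generate_corpus(5, cfg).pattern_arrays()


class TestInit:
    def test_dense_limit_all_connections_present(self):
        st = gs.init_network(make_params(sparseness=0.0), np.random.default_rng(0))
        assert st.M_ih.all() and st.M_ho.all()
        assert st.connection_count() == st.M_ih.size + st.M_ho.size

    def test_sparse_init_survival_fraction(self):
        st = gs.init_network(make_params(sparseness=0.7, hidden_units=50),
                             np.random.default_rng(1))
        frac = st.M_ih.mean()
        n = st.M_ih.size            # 557 x 50 Bernoulli(0.3) draws
        assert abs(frac - 0.3) < 4 * np.sqrt(0.3 * 0.7 / n)

    def test_direct_only_has_no_hidden_stores(self):
        st = gs.init_network(make_params(architecture="direct_only"),
                             np.random.default_rng(0))
        assert st.W_ih.size == 0 and st.W_ho.size == 0 and st.b_h.size == 0
        assert st.W_io.shape == (557, 62)

    def test_weights_within_init_range(self):
        st = gs.init_network(make_params(weight_variance=0.25), np.random.default_rng(2))
        assert np.abs(st.W_ih).max() <= 0.25 and np.abs(st.b_o).max() <= 0.25


class TestForward:
    def test_deterministic_without_noise(self, small_patterns):
        st = gs.init_network(make_params(), np.random.default_rng(0))
        x = small_patterns["X_train"][0]
        a1 = gs.forward(st, x)
        a2 = gs.forward(st, x)
        assert np.array_equal(a1, a2)
        assert ((a1 > 0) & (a1 < 1)).all()

    def test_zero_net_gives_half_activation(self):
        for temp in (0.0625, 1.0, 4.0):
            st = gs.init_network(make_params(architecture="direct_only",
                                             temperature=temp, weight_variance=0.005),
                                 np.random.default_rng(0))
            st.W_io[:] = 0.0
            st.b_o[:] = 0.0
            out = gs.forward(st, np.zeros(557))
            assert np.allclose(out, 0.5)

    def test_lower_temperature_steepens_response(self):
        def act(net, temp):
            return 1.0 / (1.0 + np.exp(-net / temp))
        for net in np.linspace(-5, 5, 41):
            for temp in (4.0, 2.0, 1.0, 0.5):
                assert abs(act(net, temp / 2) - 0.5) >= abs(act(net, temp) - 0.5) - 1e-12


class TestGradients:
    @pytest.mark.parametrize("algorithm", ["rmse", "cross_entropy"])
    @pytest.mark.parametrize("architecture", ["hidden_only", "direct_only", "both"])
    def test_backprop_matches_finite_differences(self, small_patterns, algorithm,
                                                 architecture):
        """Central finite differences of the objective recover the kernel's
        gradient to 1e-6 relative error (norm-wise) on a 5-hidden-unit net.

        With momentum and decay zero, a single update leaves
        dw = -eta_eff * grad, so the gradient is read off the weight
        change; the loss oracle is the independent numpy forward pass.
        """
        lr = 1e-3
        params = make_params(hidden_units=5, learning_rate=lr, momentum=0.0,
                             weight_decay=0.0, noise=0.0, temperature=0.7,
                             phonological_lr=0.8, semantic_lr=0.6,
                             learning_algorithm=algorithm, architecture=architecture)
        stores = ("W_ih", "W_ho", "W_io", "b_h", "b_o")
        st = gs.init_network(params, np.random.default_rng(3))
        probe = gs.init_network(params, np.random.default_rng(3))  # identical copy
        before = {n: getattr(st, n).copy() for n in stores}
        x = small_patterns["X_train"][4]
        t = small_patterns["T_train"][4]
        gs.train_epoch(st, x[None, :], t[None, :], order=np.array([0]))

        def loss_at(name, ij, delta):
            for n in stores:
                arr = getattr(probe, n)
                if arr.size:
                    arr[:] = before[n]
            getattr(probe, name)[ij] += delta
            return pattern_loss(probe, x, t)

        h = 1e-5
        rng = np.random.default_rng(0)
        checked = 0
        for name in stores:
            W0 = before[name]
            if W0.size == 0:
                continue
            if name in ("W_ih", "W_io"):
                eta = np.broadcast_to(st.lr_col[:, None], W0.shape)
            else:
                eta = np.full(W0.shape, lr)
            grad = (W0 - getattr(st, name)) / eta
            flat = rng.choice(W0.size, size=min(50, W0.size), replace=False)
            num = np.array([(loss_at(name, np.unravel_index(i, W0.shape), +h)
                             - loss_at(name, np.unravel_index(i, W0.shape), -h))
                            / (2 * h) for i in flat])
            ana = np.array([grad[np.unravel_index(i, W0.shape)] for i in flat])
            assert np.linalg.norm(num - ana) <= 1e-6 * max(np.linalg.norm(ana), 1e-8), name
            checked += 1
        assert checked >= 2

    def test_null_update_when_learning_rate_and_decay_zero(self, small_patterns):
        st = gs.init_network(make_params(learning_rate=0.0, weight_decay=0.0,
                                         momentum=0.5), np.random.default_rng(1))
        W0, b0 = st.W_ih.copy(), st.b_o.copy()
        gs.train_epoch(st, small_patterns["X_train"], small_patterns["T_train"])
        assert np.array_equal(st.W_ih, W0) and np.array_equal(st.b_o, b0)

    def test_semantic_lr_zero_freezes_semantic_bank(self, small_patterns):
        st = gs.init_network(make_params(semantic_lr=0.0), np.random.default_rng(2))
        sem0 = st.W_ih[57:].copy()
        phon0 = st.W_ih[:57].copy()
        for _ in range(3):
            gs.train_epoch(st, small_patterns["X_train"], small_patterns["T_train"])
        assert np.array_equal(st.W_ih[57:], sem0)
        assert not np.array_equal(st.W_ih[:57], phon0)

    def test_lazy_momentum_decay_matches_naive_sequential_updates(self, small_patterns):
        """The compiled kernel's lazy per-column momentum/decay bookkeeping is
        arithmetically equivalent to the naive per-pattern update."""
        X, T = small_patterns["X_train"], small_patterns["T_train"]
        p = make_params(hidden_units=9, momentum=0.55, weight_decay=5e-5,
                        learning_rate=0.2, phonological_lr=0.6, semantic_lr=0.9,
                        sparseness=0.2, learning_algorithm="rmse",
                        architecture="both", temperature=0.7)
        st = gs.init_network(p, np.random.default_rng(3))
        naive = {n: getattr(st, n).copy() for n in
                 ("W_ih", "V_ih", "M_ih", "W_ho", "V_ho", "M_ho",
                  "W_io", "V_io", "M_io", "b_h", "Vb_h", "b_o", "Vb_o")}
        orders = [np.random.default_rng(70 + k).permutation(len(X)) for k in range(6)]
        dc = 1.0 - p.weight_decay
        iT = 1.0 / p.temperature
        lr_col = st.lr_col.copy()
        for order in orders:
            for q in order:
                x, t = X[q], T[q]
                a_h = 1 / (1 + np.exp(-(x @ naive["W_ih"] + naive["b_h"]) * iT))
                net_o = naive["b_o"] + a_h @ naive["W_ho"] + x @ naive["W_io"]
                a_o = 1 / (1 + np.exp(-net_o * iT))
                d_o = (a_o - t) * a_o * (1 - a_o) * iT
                d_h = (naive["W_ho"] @ d_o) * a_h * (1 - a_h) * iT
                naive["V_ho"] = naive["M_ho"] * (p.momentum * naive["V_ho"]
                                                 - p.learning_rate * np.outer(a_h, d_o))
                naive["W_ho"] = (naive["W_ho"] + naive["V_ho"]) * dc
                naive["V_ih"] = naive["M_ih"] * (p.momentum * naive["V_ih"]
                                                 - np.outer(x * lr_col, d_h))
                naive["W_ih"] = (naive["W_ih"] + naive["V_ih"]) * dc
                naive["V_io"] = naive["M_io"] * (p.momentum * naive["V_io"]
                                                 - np.outer(x * lr_col, d_o))
                naive["W_io"] = (naive["W_io"] + naive["V_io"]) * dc
                naive["Vb_h"] = p.momentum * naive["Vb_h"] - p.learning_rate * d_h
                naive["b_h"] = (naive["b_h"] + naive["Vb_h"]) * dc
                naive["Vb_o"] = p.momentum * naive["Vb_o"] - p.learning_rate * d_o
                naive["b_o"] = (naive["b_o"] + naive["Vb_o"]) * dc
        for order in orders:
            gs.train_epoch(st, X, T, order=order)
        for n in ("W_ih", "W_ho", "W_io", "b_h", "b_o"):
            ref = naive[n]
            got = getattr(st, n)
            assert np.allclose(ref, got, rtol=1e-9, atol=1e-12), n


class TestPruning:
    def test_null_pruning_keeps_connection_count(self, small_patterns):
        st = gs.init_network(make_params(pruning_probability=0.0, pruning_onset=0),
                             np.random.default_rng(0))
        n0 = st.connection_count()
        for _ in range(3):
            gs.train_epoch(st, small_patterns["X_train"], small_patterns["T_train"])
            gs.apply_pruning(st)
        assert st.connection_count() == n0

    def test_forced_total_pruning(self):
        st = gs.init_network(make_params(pruning_onset=0, pruning_probability=1.0,
                                         pruning_threshold=1.5, weight_variance=0.5,
                                         learning_rate=0.0, weight_decay=0.0),
                             np.random.default_rng(0))
        gs.train_epoch(st, np.zeros((1, 557)), np.zeros((1, 62)))
        gs.apply_pruning(st)
        assert st.connection_count() == 0
        assert st.W_ih.sum() == 0 and st.W_ho.sum() == 0

    def test_noop_before_onset(self, small_patterns):
        st = gs.init_network(make_params(pruning_onset=1000, pruning_probability=1.0,
                                         pruning_threshold=1.5), np.random.default_rng(0))
        n0 = st.connection_count()
        gs.train_epoch(st, small_patterns["X_train"], small_patterns["T_train"])
        gs.apply_pruning(st)
        assert st.connection_count() == n0

    def test_connection_count_non_increasing_and_pruned_stay_zero(self, small_patterns):
        rng = np.random.default_rng(9)
        gs.seed_noise(9)
        for _ in range(12):
            ps = gs.decode(gs.sample_genome(rng))
            # force pruning to act within the short test horizon
            ps = gs.ParameterSet(**{**ps.as_dict(), "pruning_onset": 2})
            st = gs.init_network(ps, rng)
            counts = [st.connection_count()]
            for _ in range(6):
                try:
                    gs.train_epoch(st, small_patterns["X_train"], small_patterns["T_train"])
                except gs.DivergenceError:
                    break
                gs.apply_pruning(st)
                counts.append(st.connection_count())
                for W, M in ((st.W_ih, st.M_ih), (st.W_ho, st.M_ho), (st.W_io, st.M_io)):
                    if W.size:
                        assert (W[M == 0.0] == 0.0).all()
            assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestScoring:
    def test_exact_response_always_correct(self):
        t = np.zeros(62)
        assert gs.score_response(t, t, 0.005)

    def test_threshold_semantics(self):
        out = np.zeros(62)
        t = np.zeros(62)
        out[10] = 0.4
        assert not gs.score_response(out, t, 0.005)
        assert gs.score_response(out, t, 0.5)

    def test_matches_bruteforce_max_deviation(self):
        rng = np.random.default_rng(4)
        for _ in range(500):
            out = rng.random(62)
            t = rng.integers(0, 2, 62).astype(float)
            thr = rng.uniform(0.005, 0.5)
            assert gs.score_response(out, t, thr) == bool(np.abs(out - t).max() <= thr)


class TestEvaluate:
    def test_untrained_network_scores_near_zero_on_regulars(self, patterns):
        gs.seed_noise(123)
        vals = []
        for seed in range(20):
            ps = gs.decode(gs.sample_genome(np.random.default_rng(seed)))
            st = gs.init_network(ps, np.random.default_rng(seed), dtype=np.float32)
            vals.append(gs.evaluate(st, patterns).regular_pct)
        assert np.mean(vals) < 5.0

    def test_learnability_with_favourable_parameters(self, corpus, patterns):
        """A high-capacity, low-noise learner with the full corpus masters
        the regulars (> 90%) within a modest number of epochs."""
        st = gs.init_network(make_params(hidden_units=80, learning_rate=0.1),
                             np.random.default_rng(0), dtype=np.float32)
        gs.seed_noise(7)
        X, T = patterns["X_train"], patterns["T_train"]
        csr = binary_csr(X)
        for _ in range(40):
            gs.train_epoch(st, X, T, csr=csr)
        prof = gs.evaluate(st, patterns)
        assert prof.regular_pct > 90.0
        assert prof.novel_regularized_pct > 70.0

    def test_evaluation_covers_all_500_verbs(self, patterns):
        prep = prepare_patterns(patterns, np.float32)
        assert prep["X_all"].shape[0] == 910
        assert prep["class_counts"].tolist() == [410.0, 20.0, 68.0, 2.0]

    def test_divergence_detection_raises_with_parameters_attached(self, small_patterns):
        ps = make_params()
        st = gs.init_network(ps, np.random.default_rng(0))
        st.W_ih[3, 2] = np.inf     # poison one weight: detection must trip
        with pytest.raises(gs.DivergenceError) as exc:
            gs.train_epoch(st, small_patterns["X_train"], small_patterns["T_train"])
        assert exc.value.parameters is ps
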