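"""Noise schedule identities, forward/reverse processes, training loop and
dataset splitting."""

import numpy as np
import pytest

from rnarefine.egnn import DenoiserState, EgnnConfig, EquivariantDenoiser
from rnarefine.egnn_diffusion import (
    TrainingConfig,
    constrained_sample,
    diffusion_loss,
    forward_noise,
    make_schedule,
    reverse_step,
    split_dataset,
    train,
)
from rnarefine.errors import ConfigError, UndefinedLossError
from rnarefine.graph_encoding import EncodingConfig, encode_graph
from rnarefine.masking import masks_from_clash_report
from rnarefine.clash_detection import detect_clashes
from rnarefine.synthetic_fixtures import ideal_duplex, inject_clash, toy_corpus


class TestSchedule:
    def test_betas_strictly_inside_unit_interval(self):
        sch = make_schedule(T=100)
        assert np.all(sch.betas > 0) and np.all(sch.betas < 1)

    def test_alpha_bar_strictly_decreasing_and_extremes(self):
        sch = make_schedule(T=100)
        assert np.all(np.diff(sch.alpha_bars) < 0)
        assert sch.alpha_bar(1) > 0.999
        assert sch.alpha_bar(100) < 1e-3

    def test_self_consistency_to_1e10(self):
        sch = make_schedule(T=100)
        recomputed = np.cumprod(1.0 - sch.betas)
        np.testing.assert_allclose(sch.alpha_bars, recomputed, atol=1e-10, rtol=0)

    def test_bad_exponent_rejected(self):
        with pytest.raises(ConfigError):
            make_schedule(T=10, exponent=0)


class TestForwardNoise:
    def test_limits(self, rng):
        sch = make_schedule(T=100)
        x0 = rng.normal(size=(8, 3))
        eps = rng.normal(size=(8, 3))
        near_x0 = forward_noise(x0, 1, eps, sch)
        np.testing.assert_allclose(near_x0, x0, atol=0.1)
        near_eps = forward_noise(x0, 100, eps, sch)
        np.testing.assert_allclose(near_eps, eps, atol=0.1)

    def test_fragment_atoms_untouched(self, rng):
        sch = make_schedule(T=10)
        x0 = rng.normal(size=(6, 3))
        eps = rng.normal(size=(6, 3))
        mask = np.array([True, False, True, False, False, True])
        xt = forward_noise(x0, 5, eps, sch, linker_mask=mask)
        np.testing.assert_array_equal(xt[~mask], x0[~mask])

    def test_variance_preservation(self, rng):
        sch = make_schedule(T=100)
        n = 20000
        x0 = rng.standard_normal((n, 3))
        for t in (1, 25, 50, 75, 100):
            xt = forward_noise(x0, t, rng.standard_normal((n, 3)), sch)
            var = xt.var()
            sigma = np.sqrt(2.0 / (3 * n))  # var of sample variance of N(0,1)
            assert abs(var - 1.0) < 4 * sigma


class TestLoss:
    def test_perfect_prediction_is_zero(self, rng):
        eps = rng.normal(size=(5, 3))
        mask = np.ones(5, dtype=bool)
        assert diffusion_loss(eps, eps, mask) == 0.0

    def test_fragment_errors_do_not_count(self, rng):
        eps = rng.normal(size=(5, 3))
        eps_hat = eps.copy()
        mask = np.array([True, True, False, False, False])
        eps_hat[2:] += 100.0
        assert diffusion_loss(eps, eps_hat, mask) == 0.0

    def test_single_atom_unit_residual(self):
        eps = np.zeros((1, 3))
        eps_hat = np.array([[1.0, 0.0, 0.0]])
        assert diffusion_loss(eps, eps_hat, np.array([True])) == pytest.approx(1.0)

    def test_empty_linker_raises(self, rng):
        eps = rng.normal(size=(3, 3))
        with pytest.raises(UndefinedLossError):
            diffusion_loss(eps, eps, np.zeros(3, dtype=bool))


class TestReverseStep:
    def test_one_step_schedule_inverts_forward(self, rng):
        sch = make_schedule(T=2)
        x0 = rng.normal(size=(4, 3))
        eps = rng.normal(size=(4, 3))
        # exact inversion with oracle noise over the full chain
        x = forward_noise(x0, 2, eps, sch)
        for t in (2, 1):
            ab = sch.alpha_bar(t)
            oracle = (x - np.sqrt(ab) * x0) / np.sqrt(1 - ab)
            x = reverse_step(x, t, oracle, sch, rng=rng)
        np.testing.assert_allclose(x, x0, atol=1e-8)

    def test_chain_inversion_T5(self, rng):
        sch = make_schedule(T=5)
        x0 = rng.normal(size=(6, 3))
        x = forward_noise(x0, 5, rng.normal(size=(6, 3)), sch)
        for t in range(5, 0, -1):
            ab = sch.alpha_bar(t)
            oracle = (x - np.sqrt(ab) * x0) / np.sqrt(1 - ab)
            x = reverse_step(x, t, oracle, sch, rng=rng)
        np.testing.assert_allclose(x, x0, atol=1e-6)

    def test_fragment_bit_identical(self, rng):
        sch = make_schedule(T=10)
        xt = rng.normal(size=(5, 3))
        mask = np.array([True, False, True, False, True])
        out = reverse_step(xt, 4, rng.normal(size=(5, 3)), sch, rng=rng,
                           linker_mask=mask)
        assert np.array_equal(out[~mask], xt[~mask])

    def test_small_beta_limit(self):
        sch = make_schedule(T=100)
        t = 1  # earliest step has the smallest beta
        xt = np.ones((2, 3))
        out = reverse_step(xt, t, np.zeros((2, 3)), sch, z=np.zeros((2, 3)))
        np.testing.assert_allclose(out, xt / np.sqrt(sch.alpha(t)), rtol=1e-12)


def _tiny_state(graph, T=4, seed=0):
    cfg = EgnnConfig(n_blocks=1, hidden=8, gcls_per_block=1,
                     feature_dim=graph.config.feature_dim, edge_attr_dim=4)
    return DenoiserState(EquivariantDenoiser(cfg, rng=seed), make_schedule(T=T), {})


@pytest.fixture(scope="module")
def sample_setup():
    s, pairs, _ = ideal_duplex("GCAU")
    clashed = inject_clash(s, 1, rng=np.random.default_rng(0), pairs=pairs)
    report = detect_clashes(clashed, pairs=pairs)
    graph = encode_graph(clashed, pairs, EncodingConfig())
    mask = masks_from_clash_report(clashed, report)
    return graph, mask


class TestConstrainedSample:

    def test_fragment_pinned_exactly(self, sample_setup):
        graph, mask = sample_setup
        state = _tiny_state(graph)
        out = constrained_sample(graph, mask, state, n_samples=2,
                                 rng=np.random.default_rng(1))
        frag = ~mask.linker_node_mask(graph)
        for k in range(2):
            np.testing.assert_array_equal(out[k][frag], graph.coords[frag])

    def test_same_seed_bit_identical(self, sample_setup):
        graph, mask = sample_setup
        state = _tiny_state(graph)
        a = constrained_sample(graph, mask, state, n_samples=3,
                               rng=np.random.default_rng(7))
        b = constrained_sample(graph, mask, state, n_samples=3,
                               rng=np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_samples_differ_between_streams(self, sample_setup):
        graph, mask = sample_setup
        state = _tiny_state(graph)
        out = constrained_sample(graph, mask, state, n_samples=2,
                                 rng=np.random.default_rng(5))
        linker = mask.linker_node_mask(graph)
        assert not np.allclose(out[0][linker], out[1][linker])


class TestTrain:
    def test_loss_decreases_on_toy_fixtures(self):
        records = [(r.structure, r.pairs)
                   for r in toy_corpus(6, length_range=(6, 8), rng=0)]
        enc = EncodingConfig()
        cfg = EgnnConfig(n_blocks=1, hidden=16, gcls_per_block=1,
                         feature_dim=enc.feature_dim, edge_attr_dim=4)
        state = train(records, cfg, make_schedule(T=20), rng=1,
                      training=TrainingConfig(n_steps=200, lr=2e-3, log_every=0))
        h = state.meta["loss_history"]
        assert np.mean(h[-40:]) < 0.9 * np.mean(h[:40])

    def test_overlong_structure_rejected(self):
        records = [(r.structure, r.pairs)
                   for r in toy_corpus(2, length_range=(8, 10), rng=0)]
        enc = EncodingConfig()
        cfg = EgnnConfig(n_blocks=1, hidden=8,
                         feature_dim=enc.feature_dim, edge_attr_dim=4)
        with pytest.raises(ValueError):
            train(records, cfg, make_schedule(T=5), rng=0,
                  training=TrainingConfig(n_steps=1, max_length=5))


class TestSplitDataset:
    class Rec:
        def __init__(self, k, clash=False):
            self.k = k
            self.has_clashes = clash

    def test_ratio_sizes(self):
        records = [self.Rec(i) for i in range(1000)]
        tr, va, te = split_dataset(records, rng=0)
        assert (len(tr), len(va), len(te)) == (800, 150, 50)

    def test_partition(self):
        records = [self.Rec(i) for i in range(40)]
        tr, va, te = split_dataset(records, rng=1)
        ks = sorted(r.k for part in (tr, va, te) for r in part)
        assert ks == list(range(40))

    def test_clashed_records_never_in_train_or_val(self):
        records = [self.Rec(i, clash=(i % 10 == 0)) for i in range(100)]
        tr, va, te = split_dataset(records, rng=2)
        assert all(not r.has_clashes for r in tr + va)
        assert sum(r.has_clashes for r in te) == 10
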