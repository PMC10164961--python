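"""Network components: pooling, GCN layers, attention, forward, gradients."""

import numpy as np
import pytest

from ddimug.graphs import fit_pmi
from ddimug.model import (
    AspectBundle,
    DDIMuGModel,
    HashEncoderProvider,
    ModelConfig,
    attentive_pool,
    average_pool_nodes,
    encode_words,
    gather_aspects,
    gcn_forward,
    gcn_layer,
    get_encoder,
    prepare_instance,
    relu,
)
from ddimug.synthetic_data import GeneratorConfig, generate_corpus


@pytest.fixture(scope="module")
def prepared(tiny_config):
    """One prepared instance from a tiny synthetic corpus."""
    bundle = generate_corpus(GeneratorConfig(n_sentences=15, seed=4))
    table = fit_pmi(bundle.parses.values())
    encoder = get_encoder(tiny_config)
    inst = next(i for i in bundle.instances if i.label != "Negative")
    parsed = bundle.parses[inst.sentence.sentence_id]
    return prepare_instance(inst, parsed, table, encoder, tiny_config)


@pytest.fixture(scope="module")
def corpus_fixture(tiny_config):
    bundle = generate_corpus(GeneratorConfig(n_sentences=15, seed=4))
    table = fit_pmi(bundle.parses.values())
    return bundle, table, get_encoder(tiny_config)


class TestEncodeWords:
    def test_single_piece_token_row_equals_piece_vector(self, tiny_config):
        enc = HashEncoderProvider(dim=tiny_config.encoder_dim)
        from ddimug.linguistic import StubParserProvider
        tokens, _ = StubParserProvider().parse_text("abc")
        H = encode_words(tokens, enc, tiny_config)
        assert np.array_equal(H[0], enc.piece_vector("abc"))

    def test_multi_piece_token_row_is_piece_mean(self, tiny_config):
        enc = HashEncoderProvider(dim=tiny_config.encoder_dim, piece_len=4)
        from ddimug.linguistic import StubParserProvider
        tokens, _ = StubParserProvider().parse_text("abcdefgh")
        H = encode_words(tokens, enc, tiny_config)
        want = (enc.piece_vector("abcd") + enc.piece_vector("efgh")) / 2
        assert np.allclose(H[0], want)

    def test_truncated_token_gets_zero_row_and_warning(self):
        cfg = ModelConfig(encoder_dim=8, gcn_hidden=4, max_wordpieces=1, dropout=0.0)
        enc = HashEncoderProvider(dim=8)
        from ddimug.linguistic import StubParserProvider
        tokens, _ = StubParserProvider().parse_text("one two")
        with pytest.warns(UserWarning, match="truncated"):
            H = encode_words(tokens, enc, cfg)
        assert np.all(H[1] == 0.0) and np.any(H[0] != 0.0)

    def test_bit_for_bit_reproducible(self, tiny_config):
        from ddimug.linguistic import StubParserProvider
        tokens, _ = StubParserProvider().parse_text("aspirin increases warfarin")
        H1 = encode_words(tokens, HashEncoderProvider(tiny_config.encoder_dim), tiny_config)
        H2 = encode_words(tokens, HashEncoderProvider(tiny_config.encoder_dim), tiny_config)
        assert np.array_equal(H1, H2)


class TestGcnLayer:
    def test_identity_propagation(self):
        H = np.arange(6.0).reshape(3, 2)
        out = gcn_layer(H, np.eye(3), np.eye(2))
        assert np.array_equal(out, H)

    def test_two_node_hand_case(self):
        A = np.full((2, 2), 0.5)
        H = np.array([[1.0], [3.0]])
        W = np.eye(1)
        assert np.array_equal(gcn_layer(H, A, W), [[2.0], [2.0]])

    def test_relu_zeroes_negative_preactivations(self):
        H = np.array([[1.0], [1.0]])
        W = np.array([[-5.0]])
        out = gcn_layer(H, np.eye(2), W, sigma=relu)
        assert np.all(out == 0.0)

    def test_shape_mismatch_reports_shapes(self):
        with pytest.raises(ValueError, match="shape"):
            gcn_layer(np.ones((3, 2)), np.eye(2), np.eye(2))

    def test_linear_in_features_without_nonlinearity(self, rng):
        A = rng.random((4, 4))
        H1, H2 = rng.random((4, 3)), rng.random((4, 3))
        W = rng.random((3, 2))
        lhs = gcn_layer(2.0 * H1 + 3.0 * H2, A, W)
        rhs = 2.0 * gcn_layer(H1, A, W) + 3.0 * gcn_layer(H2, A, W)
        assert np.allclose(lhs, rhs)

    def test_no_input_mutation(self):
        H = np.ones((2, 2))
        before = H.copy()
        gcn_layer(H, np.eye(2), np.eye(2), sigma=relu)
        assert np.array_equal(H, before)


class TestGcnForward:
    def test_two_layer_hand_case(self):
        A = np.full((2, 2), 0.5)
        H0 = np.array([[1.0], [3.0]])
        W = np.eye(1)
        cache = gcn_forward(H0, A, W, W)
        # layer1: mean -> [2,2]; layer2: mean of [2,2] -> [2,2]
        assert np.allclose(cache["M2"], [[2.0], [2.0]])

    def test_output_shape_matches_hidden_dim(self, prepared, tiny_config):
        model = DDIMuGModel(tiny_config)
        cache = gcn_forward(
            prepared.H0, prepared.A_dep, model.params["W1_dep"], model.params["W2_dep"]
        )
        assert cache["M2"].shape == (prepared.H0.shape[0], tiny_config.gcn_hidden)


class TestPooling:
    def test_average_pool_single_node(self, rng):
        x = rng.random((1, 5))
        assert np.array_equal(average_pool_nodes(x), x[0])

    def test_average_pool_two_nodes(self, rng):
        x = rng.random((2, 5))
        assert np.allclose(average_pool_nodes(x), (x[0] + x[1]) / 2)

    def test_average_pool_of_centered_rows_is_zero(self, rng):
        x = rng.random((6, 4))
        centered = x - x.mean(axis=0)
        assert np.allclose(average_pool_nodes(centered), 0.0, atol=1e-12)

    def test_average_pool_empty_rejected(self):
        with pytest.raises(ValueError):
            average_pool_nodes(np.zeros((0, 3)))

    def test_attentive_pool_k1_is_identity(self, rng):
        col = rng.random((7, 1))
        z, alpha = attentive_pool(col, rng.random(7))
        assert np.allclose(z, col[:, 0])
        assert np.allclose(alpha, [1.0])

    def test_attentive_pool_identical_columns_split_evenly(self, rng):
        c = rng.random(5)
        z, alpha = attentive_pool(np.stack([c, c], axis=1), rng.random(5))
        assert np.allclose(alpha, [0.5, 0.5])
        assert np.allclose(z, c)

    def test_attentive_pool_hand_softmax_case(self):
        columns = np.array([[1.0, 0.0], [0.0, 1.0]])
        z, alpha = attentive_pool(columns, np.array([1.0, 0.0]))
        e = np.exp(np.tanh(1.0))
        a0 = e / (e + 1.0)
        assert alpha == pytest.approx([a0, 1 - a0], abs=1e-6)
        assert z == pytest.approx([a0, 1 - a0], abs=1e-6)

    def test_alpha_on_simplex_and_convex_combination(self, rng):
        columns = rng.normal(size=(6, 9))
        z, alpha = attentive_pool(columns, rng.normal(size=6))
        assert np.all(alpha >= 0) and alpha.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(z <= columns.max(axis=1) + 1e-12)
        assert np.all(z >= columns.min(axis=1) - 1e-12)

    def test_empty_columns_rejected(self):
        with pytest.raises(ValueError):
            attentive_pool(np.zeros((3, 0)), np.zeros(3))


class TestGatherAspects:
    def test_shapes_and_verb_count(self, corpus_fixture, tiny_config):
        bundle, table, encoder = corpus_fixture
        inst = next(i for i in bundle.instances if i.label != "Negative")
        parsed = bundle.parses[inst.sentence.sentence_id]
        H0 = encode_words(parsed.tokens, encoder, tiny_config)
        model = DDIMuGModel(tiny_config)
        dep = gcn_forward(H0, np.eye(len(parsed.tokens)),
                          model.params["W1_dep"], model.params["W2_dep"])["M2"]
        bundle_a = gather_aspects(H0, dep, dep, parsed, inst)
        assert isinstance(bundle_a, AspectBundle)
        assert bundle_a.drug1_pub.shape == (tiny_config.encoder_dim,)
        assert bundle_a.drug1_dep.shape == (tiny_config.gcn_hidden,)
        k = bundle_a.k
        assert bundle_a.verbs_dep.shape == (k, tiny_config.gcn_hidden)
        assert bundle_a.verbs_word.shape == (k, tiny_config.gcn_hidden)
        assert k == len(parsed.verb_indices)

    def test_single_token_drug_is_its_row(self, corpus_fixture, tiny_config):
        bundle, table, encoder = corpus_fixture
        inst = bundle.instances[0]
        parsed = bundle.parses[inst.sentence.sentence_id]
        H0 = encode_words(parsed.tokens, encoder, tiny_config)
        aspects = gather_aspects(H0, H0, H0, parsed, inst)
        lo, hi = parsed.mention_token_spans[inst.e1_id]
        if hi - lo == 1:
            assert np.array_equal(aspects.drug1_pub, H0[lo])


class TestForward:
    def test_probabilities_sum_to_one(self, prepared, tiny_config):
        model = DDIMuGModel(tiny_config)
        probs = model.forward(prepared)
        assert probs.shape == (tiny_config.num_classes,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zero_verb_instance_still_defined(self, corpus_fixture, tiny_config):
        bundle, table, encoder = corpus_fixture
        no_verb = None
        for inst in bundle.instances:
            if not bundle.parses[inst.sentence.sentence_id].verb_indices:
                no_verb = inst
                break
        assert no_verb is not None, "generator should produce verb-free negatives"
        prep = prepare_instance(
            no_verb, bundle.parses[no_verb.sentence.sentence_id], table,
            encoder, tiny_config,
        )
        model = DDIMuGModel(tiny_config)
        probs, cache = model.forward(prep, want_cache=True)
        assert np.all(cache["z_total"][2 * tiny_config.aspect_dim:] == 0.0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_deterministic_given_seed(self, prepared, tiny_config):
        p1 = DDIMuGModel(tiny_config).forward(prepared)
        p2 = DDIMuGModel(tiny_config).forward(prepared)
        assert np.array_equal(p1, p2)

    def test_verb_permutation_equivariance(self, prepared, tiny_config):
        model = DDIMuGModel(tiny_config)
        base = model.forward(prepared)
        import copy
        prep2 = copy.copy(prepared)
        prep2.verb_indices = list(reversed(prepared.verb_indices))
        assert np.allclose(model.forward(prep2), base)

    def test_ablation_switches_zero_their_aspects(self, corpus_fixture):
        bundle, table, encoder = corpus_fixture
        inst = bundle.instances[0]
        parsed = bundle.parses[inst.sentence.sentence_id]
        for kw, sl in [({"use_dep_graph": False}, 1), ({"use_word_graph": False}, 2)]:
            cfg = ModelConfig(encoder_dim=32, gcn_hidden=16, dropout=0.0, **kw)
            enc = get_encoder(cfg)
            prep = prepare_instance(inst, parsed, table, enc, cfg)
            model = DDIMuGModel(cfg)
            _, cache = model.forward(prep, want_cache=True)
            De, Dg = cfg.encoder_dim, cfg.gcn_hidden
            lo = De + (sl - 1) * Dg
            assert np.all(cache["c1"][lo:lo + Dg] == 0.0)


class TestGradients:
    def test_backprop_matches_finite_differences(self, prepared, tiny_config):
        """Analytic gradients agree with central differences to ~1e-6."""
        model = DDIMuGModel(tiny_config)
        loss, grads = model.loss_and_grads(prepared, train_mode=False)
        eps = 1e-6
        rng = np.random.default_rng(0)
        for name, param in model.params.items():
            idxs = rng.choice(param.size, size=min(6, param.size), replace=False)
            for flat_idx in idxs:
                idx = np.unravel_index(flat_idx, param.shape)
                orig = param[idx]
                param[idx] = orig + eps
                lp, _ = model.loss_and_grads(prepared, train_mode=False)
                param[idx] = orig - eps
                lm, _ = model.loss_and_grads(prepared, train_mode=False)
                param[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[name][idx]
                assert analytic == pytest.approx(numeric, abs=5e-5), name

    def test_ablated_graph_receives_no_gradient(self, corpus_fixture):
        bundle, table, _ = corpus_fixture
        cfg = ModelConfig(encoder_dim=32, gcn_hidden=16, dropout=0.0,
                          use_word_graph=False)
        enc = get_encoder(cfg)
        inst = bundle.instances[0]
        prep = prepare_instance(inst, bundle.parses[inst.sentence.sentence_id],
                                table, enc, cfg)
        model = DDIMuGModel(cfg)
        _, grads = model.loss_and_grads(prep, train_mode=False)
        assert np.all(grads["W1_word"] == 0.0)
        assert np.all(grads["W2_word"] == 0.0)


class TestPersistence:
    def test_save_load_round_trip(self, prepared, tiny_config, tmp_path):
        model = DDIMuGModel(tiny_config)
        before = model.forward(prepared)
        model.save(tmp_path / "ckpt")
        loaded = DDIMuGModel.load(tmp_path / "ckpt")
        assert loaded.config == tiny_config or (
            tuple(loaded.config.labels) == tuple(tiny_config.labels)
        )
        assert np.array_equal(loaded.forward(prepared), before)
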