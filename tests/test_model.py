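import numpy as np
import pytest

from fp2mol import nn
from fp2mol.model import GenerativeModel, ModelConfig, TrainingConfig
from fp2mol.molecules import ELEMENT_INDEX, standardize, struct_fingerprint
from fp2mol.tokenizer import onehot, token_true_hydrogens, tokenize


@pytest.fixture()
def small_model(tiny_vocab):
    cfg = ModelConfig(fp_len=16, latent_dim=6, enc_units=8, dec_layers=2,
                      dec_units=7, hcount_units=4, max_len=12, seed=1)
    return GenerativeModel(cfg, tiny_vocab)


def random_batch(model, B=3, seed=0):
    rng = np.random.default_rng(seed)
    xF = (rng.random((B, model.cfg.fp_len)) < 0.4).astype(float)
    xM = rng.integers(0, 3, (B, 10)).astype(float)
    return xF, xM


class TestEncoder:
    def test_infer_deterministic(self, small_model):
        xF, xM = random_batch(small_model)
        z1, s1 = small_model.encode(xF, xM)
        z2, s2 = small_model.encode(xF, xM)
        assert np.array_equal(z1, z2)
        assert np.array_equal(s1[0][0], s2[0][0])

    def test_latent_dimension(self, small_model):
        xF, xM = random_batch(small_model)
        z, states = small_model.encode(xF, xM)
        assert z.shape == (3, small_model.cfg.latent_dim)
        assert len(states) == small_model.cfg.dec_layers
        assert states[0][0].shape == (3, small_model.cfg.dec_units)

    def test_naive_mode_is_fingerprint_blind(self, tiny_vocab):
        cfg = ModelConfig(fp_len=16, latent_dim=6, enc_units=8, dec_layers=2,
                          dec_units=7, max_len=12, seed=1, naive_mode=True)
        model = GenerativeModel(cfg, tiny_vocab)
        _, xM = random_batch(model)
        rng = np.random.default_rng(1)
        z1, _ = model.encode(rng.random((3, 16)), xM)
        z2, _ = model.encode(rng.random((3, 16)), xM)
        assert np.array_equal(z1, z2)

    def test_shape_mismatch(self, small_model):
        with pytest.raises(ValueError):
            small_model.encode(np.zeros((1, 5)), np.zeros((1, 10)))


class TestCounter:
    def test_initial_state(self, small_model):
        xM = np.arange(10.0).reshape(1, 10)
        Y = np.array([[0, 2, 2]])  # start then pads
        V = small_model.counters(xM, onehot(Y, small_model.vocab.t),
                                 np.zeros((1, 3)))
        assert np.array_equal(V[0, 0], np.concatenate([xM[0], [0.0]]))

    def test_ethanol_budget_reaches_zero(self, small_model):
        # tokens C,C,O with true hydrogen counts 3,2,1 exhaust C2H6O
        vocab = small_model.vocab
        xM = standardize("CCO").formula.astype(float).reshape(1, 10)
        Y = np.array([[vocab.index["$"], vocab.index["C"], vocab.index["C"],
                       vocab.index["O"], vocab.index["*"]]])
        yH = np.array([[0.0, 3.0, 2.0, 1.0, 0.0]])
        V = small_model.counters(xM, onehot(Y, vocab.t), yH)
        assert np.allclose(V[0, -1], 0.0)

    def test_bracket_tokens_move_balance(self, small_model):
        vocab = small_model.vocab
        xM = np.zeros((1, 10))
        Y = np.array([[vocab.index["$"], vocab.index["("], vocab.index[")"]]])
        V = small_model.counters(xM, onehot(Y, vocab.t), np.zeros((1, 3)))
        assert V[0, 1, 10] == 1.0  # "(" raises the open balance
        assert V[0, 2, 10] == 0.0  # ")" closes it


class TestCounterConservation:
    def test_full_corpus_teacher_forced(self, corpus, vocab):
        """Teacher-forced counters with true hydrogen labels terminate at
        the zero vector for every accepted molecule."""
        cfg = ModelConfig(fp_len=8, latent_dim=4, enc_units=4, dec_layers=1,
                          dec_units=4, max_len=40, seed=0)
        model = GenerativeModel(cfg, vocab)
        for m in corpus:
            seq = tokenize(m.smiles_canonical, vocab, 40)
            labels = token_true_hydrogens(m.rdmol, m.smiles_canonical)
            yH = np.zeros((1, 40))
            yH[0, 1 : 1 + len(labels)] = labels
            V = model.counters(m.formula.astype(float).reshape(1, 10),
                               onehot(seq.reshape(1, -1), vocab.t), yH)
            stop_pos = int(np.argmax(seq == vocab.stop_idx))
            assert np.allclose(V[0, stop_pos], 0.0), m.smiles_canonical


class TestDecodeStep:
    def test_distribution_sums_to_one(self, small_model):
        xF, xM = random_batch(small_model)
        z, states, hc, v = small_model.init_decode(xF, xM)
        y = np.full(3, small_model.vocab.start_idx)
        probs, _ = small_model.decode_step(y, v, z, states)
        assert probs.shape == (3, small_model.vocab.t)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_deterministic(self, small_model):
        xF, xM = random_batch(small_model)
        z, states, hc, v = small_model.init_decode(xF, xM)
        y = np.full(3, small_model.vocab.start_idx)
        p1, _ = small_model.decode_step(y, v, z, states)
        p2, _ = small_model.decode_step(y, v, z, states)
        assert np.array_equal(p1, p2)

    def test_sensitive_to_latent_code(self, small_model):
        xF, xM = random_batch(small_model)
        z, states, hc, v = small_model.init_decode(xF, xM)
        y = np.full(3, small_model.vocab.start_idx)
        p1, _ = small_model.decode_step(y, v, z, states)
        p2, _ = small_model.decode_step(y, v, z + 1.0, states)
        assert not np.allclose(p1, p2)

    def test_hcount_totality(self, small_model):
        y = np.array([small_model.vocab.index["C"]])
        hc = small_model.phi_modules["hc_lstm"].zero_state(1)
        yh, _ = small_model.hcount_step(y, hc)
        assert np.isfinite(yh).all()


class TestGradientIsolation:
    def test_losses_touch_disjoint_parameters(self, small_model):
        """The decoder loss must not move phi; the hydrogen loss must not
        move theta (they are optimized concomitantly but separately)."""
        model = small_model
        vocab = model.vocab
        xF, xM = random_batch(model)
        Y = np.array([[0, 3, 4, 3, 1, 2, 2, 2]] * 3)
        h_tot = xM[:, ELEMENT_INDEX["H"]]
        theta_before = {k: v.copy() for k, v in
                        nn.collect_params(model.theta_modules).items()}
        phi_before = {k: v.copy() for k, v in
                      nn.collect_params(model.phi_modules).items()}

        # zero out the hydrogen loss gradient path by a zero-lr phi opt
        opt_theta = nn.Adam(lr=1e-2)
        opt_phi = nn.Adam(lr=0.0)
        model.train_step(xF, xM, Y, h_tot, opt_theta, opt_phi)
        phi_after = nn.collect_params(model.phi_modules)
        for k in phi_before:
            assert np.array_equal(phi_before[k], phi_after[k])
        theta_after = nn.collect_params(model.theta_modules)
        assert any(not np.array_equal(theta_before[k], theta_after[k])
                   for k in theta_before)

    def test_finite_difference_cross_grads_are_zero(self, small_model):
        """Perturbing phi must not change the decoder loss (the decoder
        consumes the hydrogen estimates as constants it never trains)."""
        model = small_model
        xF, xM = random_batch(model)
        Y = np.array([[0, 3, 4, 3, 1, 2, 2, 2]] * 3)
        h_tot = xM[:, ELEMENT_INDEX["H"]]

        def ce():
            out = model.teacher_forward(xF, xM, Y, training=False)
            return model.losses(out, Y, h_tot)[0]

        base = ce()
        w = model.phi_modules["hc_out"].params["W"]
        old = w[0, 0]
        w[0, 0] = old + 10.0  # large perturbation changes hcount output a lot
        ce_perturbed = ce()
        w[0, 0] = old
        # the counter changes, so CE may shift, but only through the counter
        # input, never through trained decoder weights; with labels-driven
        # counters the decoder loss must be exactly invariant
        cfg2 = ModelConfig(**{**vars(model.cfg), "counter_from_labels": True})
        model2 = GenerativeModel(cfg2, model.vocab)
        labels = np.zeros_like(Y, dtype=float)

        def ce2():
            out = model2.teacher_forward(xF, xM, Y, training=False,
                                         h_labels=labels)
            return model2.losses(out, Y, h_tot)[0]

        base2 = ce2()
        w2 = model2.phi_modules["hc_out"].params["W"]
        w2[0, 0] += 10.0
        assert ce2() == base2


class TestTraining:
    def test_loss_decreases_and_checkpoint_round_trips(self, corpus, vocab,
                                                       tmp_path):
        from fp2mol.evaluate import train_model
        from fp2mol.molecules import FingerprintConfig

        fp_cfg = FingerprintConfig(n_bits=32)
        cfg = ModelConfig(fp_len=32, latent_dim=8, enc_units=16, dec_layers=1,
                          dec_units=16, max_len=40, seed=2)
        tcfg = TrainingConfig(epochs=3, batch_size=16, seed=2)
        model, hist = train_model(corpus[:30], vocab, cfg, tcfg, fp_cfg)
        assert hist[2]["ce"] < hist[0]["ce"]

        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = GenerativeModel.load(path)
        xF = np.stack([struct_fingerprint(m, fp_cfg) for m in corpus[:4]]
                      ).astype(float)
        xM = np.stack([m.formula for m in corpus[:4]]).astype(float)
        z1, _ = model.encode(xF, xM)
        z2, _ = loaded.encode(xF, xM)
        assert np.allclose(z1, z2, atol=1e-12)
        assert loaded.vocab.tokens == vocab.tokens

    def test_score_additivity_against_teacher_forcing(self, corpus, vocab):
        """Stepwise decode log-probabilities must re-add to the
        teacher-forced sequence score."""
        cfg = ModelConfig(fp_len=16, latent_dim=6, enc_units=8, dec_layers=2,
                          dec_units=8, max_len=40, seed=3)
        model = GenerativeModel(cfg, vocab)
        m = corpus[0]
        seq = tokenize(m.smiles_canonical, vocab, 40)
        xF = np.random.default_rng(0).random((1, 16))
        xM = m.formula.astype(float).reshape(1, 10)
        ref = model.score_sequences(xF, xM, seq.reshape(1, -1))[0]

        z, states, hc, v = model.init_decode(xF, xM)
        total = 0.0
        cur = np.array([seq[0]])
        yh, hc = model.hcount_step(cur, hc)
        v = model.advance_counter(v, cur, yh)
        probs, states = model.decode_step(cur, v, z, states)
        for i in range(1, 40):
            total += np.log(probs[0, seq[i]])
            if seq[i] == vocab.stop_idx:
                break
            cur = np.array([seq[i]])
            yh, hc = model.hcount_step(cur, hc)
            v = model.advance_counter(v, cur, yh)
            probs, states = model.decode_step(cur, v, z, states)
        assert total == pytest.approx(ref, abs=1e-5)
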