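import itertools

import numpy as np
import pytest

from fp2mol.decoding import (beam_search, stochastic_decode,
                             validate_dereplicate, ScoredSequence)
from fp2mol.model import GenerativeModel, ModelConfig
from fp2mol.molecules import standardize
from fp2mol.tokenizer import TokenVocabulary


@pytest.fixture(scope="module")
def tiny_decoder():
    """Randomly initialized decoder over a 5-token vocabulary."""
    vocab = TokenVocabulary(tokens=("$", "*", "&", "C", "O"))
    cfg = ModelConfig(fp_len=6, latent_dim=4, enc_units=5, dec_layers=2,
                      dec_units=5, hcount_units=3, max_len=5, seed=12345)
    model = GenerativeModel(cfg, vocab)
    rng = np.random.default_rng(0)
    xF = rng.random(6)
    xM = np.array([3.0, 0, 0, 0, 0, 1, 0, 0, 0, 8])
    return model, xF, xM


def enumerate_exhaustive(model, xF, xM, l_max):
    """Independent oracle: enumerate every terminating sequence and score
    it by stepwise log-probability accumulation."""
    vocab = model.vocab
    body_tokens = [i for i in range(vocab.t)
                   if i not in (vocab.start_idx, vocab.pad_idx)]
    finished = []
    for length in range(0, l_max - 1):
        for body in itertools.product(
                [i for i in body_tokens if i != vocab.stop_idx],
                repeat=length):
            seq = (vocab.start_idx,) + body + (vocab.stop_idx,)
            if len(seq) > l_max:
                continue
            z, states, hc, v = model.init_decode(xF, xM)
            cur = np.array([seq[0]])
            yh, hc = model.hcount_step(cur, hc)
            v = model.advance_counter(v, cur, yh)
            probs, states = model.decode_step(cur, v, z, states)
            score = 0.0
            for tok in seq[1:]:
                score += np.log(probs[0, tok])
                if tok == vocab.stop_idx:
                    break
                cur = np.array([tok])
                yh, hc = model.hcount_step(cur, hc)
                v = model.advance_counter(v, cur, yh)
                probs, states = model.decode_step(cur, v, z, states)
            finished.append((seq, score))
    finished.sort(key=lambda x: (-x[1], x[0]))
    return finished


class TestBeamOracle:
    def test_exhaustive_equivalence(self, tiny_decoder):
        """With k at least the number of possible sequences, beam search
        returns exactly the exhaustive enumeration ranked by score."""
        model, xF, xM = tiny_decoder
        oracle = enumerate_exhaustive(model, xF, xM, l_max=5)
        out = beam_search(model, xF, xM, k=5 ** 4, l_max=5)
        fin = [r for r in out if r.finished]
        assert len(fin) == len(oracle)
        for r, (seq, score) in zip(fin, oracle):
            assert r.tokens == seq
            assert r.score == pytest.approx(score, abs=1e-9)

    @pytest.mark.parametrize("k", [1, 4, 16])
    def test_true_top_k(self, tiny_decoder, k):
        model, xF, xM = tiny_decoder
        oracle = enumerate_exhaustive(model, xF, xM, l_max=5)
        out = [r for r in beam_search(model, xF, xM, k=k, l_max=5)
               if r.finished]
        for r, (seq, score) in zip(out[:k], oracle[:k]):
            assert r.score == pytest.approx(score, abs=1e-9)

    def test_monotone_widening(self, tiny_decoder):
        """Widening the beam never worsens the best-k finished scores."""
        model, xF, xM = tiny_decoder
        s8 = [r.score for r in beam_search(model, xF, xM, k=8, l_max=5)
              if r.finished]
        s32 = [r.score for r in beam_search(model, xF, xM, k=32, l_max=5)
               if r.finished]
        for a, b in zip(s8, s32):
            assert b >= a - 1e-12

    def test_score_additivity_reevaluation(self, tiny_decoder):
        """Returned scores equal teacher-forced re-evaluation."""
        model, xF, xM = tiny_decoder
        out = [r for r in beam_search(model, xF, xM, k=8, l_max=5)
               if r.finished]
        for r in out:
            Y = np.full((1, model.cfg.max_len), model.vocab.pad_idx)
            Y[0, : len(r.tokens)] = r.tokens
            ref = model.score_sequences(xF.reshape(1, -1),
                                        xM.reshape(1, -1), Y)[0]
            assert r.score == pytest.approx(ref, abs=1e-5)

    def test_deterministic(self, tiny_decoder):
        model, xF, xM = tiny_decoder
        a = beam_search(model, xF, xM, k=16, l_max=5)
        b = beam_search(model, xF, xM, k=16, l_max=5)
        assert a == b

    def test_k1_is_greedy(self, tiny_decoder):
        """Beam width 1 follows the argmax chain."""
        model, xF, xM = tiny_decoder
        vocab = model.vocab
        z, states, hc, v = model.init_decode(xF, xM)
        cur = np.array([vocab.start_idx])
        yh, hc = model.hcount_step(cur, hc)
        v = model.advance_counter(v, cur, yh)
        probs, states = model.decode_step(cur, v, z, states)
        greedy = [vocab.start_idx]
        for _ in range(model.cfg.max_len - 1):
            p = probs[0].copy()
            p[[vocab.start_idx, vocab.pad_idx]] = -np.inf
            tok = int(np.argmax(p))
            greedy.append(tok)
            if tok == vocab.stop_idx:
                break
            cur = np.array([tok])
            yh, hc = model.hcount_step(cur, hc)
            v = model.advance_counter(v, cur, yh)
            probs, states = model.decode_step(cur, v, z, states)
        out = beam_search(model, xF, xM, k=1)
        assert list(out[0].tokens) == greedy


class TestStochastic:
    def test_seeded_reproducibility(self, tiny_decoder):
        model, xF, xM = tiny_decoder
        a = stochastic_decode(model, xF, xM, k=20, seed=5)
        b = stochastic_decode(model, xF, xM, k=20, seed=5)
        assert a == b

    def test_termination_or_truncation(self, tiny_decoder):
        model, xF, xM = tiny_decoder
        for r in stochastic_decode(model, xF, xM, k=50, seed=1):
            if r.finished:
                assert r.tokens[-1] == model.vocab.stop_idx
            assert len(r.tokens) <= model.cfg.max_len

    def test_binomial_split_under_near_uniform_model(self, tiny_decoder):
        """First sampled tokens follow the model's first-step distribution
        (binomial bounds at 99% for each token)."""
        model, xF, xM = tiny_decoder
        n = 4000
        out = stochastic_decode(model, xF, xM, k=n, seed=9, l_max=3)
        firsts = np.array([r.tokens[1] for r in out])
        vocab = model.vocab
        z, states, hc, v = model.init_decode(xF, xM)
        cur = np.array([vocab.start_idx])
        yh, hc = model.hcount_step(cur, hc)
        v = model.advance_counter(v, cur, yh)
        probs, _ = model.decode_step(cur, v, z, states)
        p = probs[0].copy()
        p[[vocab.start_idx, vocab.pad_idx]] = 0
        p /= p.sum()
        from scipy import stats as sps
        for tok in np.nonzero(p > 0)[0]:
            count = int((firsts == tok).sum())
            lo, hi = sps.binom.interval(0.99, n, p[tok])
            assert lo <= count <= hi


class TestValidateDereplicate:
    def _seqs(self, vocab, items):
        out = []
        for smiles, score in items:
            toks = ([vocab.start_idx]
                    + [vocab.index[t] for t in smiles]
                    + [vocab.stop_idx])
            out.append(ScoredSequence(tuple(toks), score, True))
        return out

    def test_duplicates_and_invalid(self, tiny_vocab):
        xM = standardize("CCO").formula
        seqs = self._seqs(tiny_vocab, [("CCO", -1.0), ("OCC", -2.0)])
        seqs.append(ScoredSequence(
            (0, tiny_vocab.index["("], 1), -0.5, True))  # unparseable "("
        cands = validate_dereplicate(seqs, xM, tiny_vocab)
        assert len(cands) == 1
        assert cands.candidates[0].smiles == "CCO"
        assert cands.candidates[0].rnn_score == -1.0  # max over spellings

    def test_formula_gate(self, tiny_vocab):
        xM = standardize("CCCO").formula  # C3H8O
        seqs = self._seqs(tiny_vocab, [("CCO", -1.0)])
        assert len(validate_dereplicate(seqs, xM, tiny_vocab,
                                        require_formula=True)) == 0
        soft = validate_dereplicate(seqs, xM, tiny_vocab)
        assert len(soft) == 1 and not soft.candidates[0].formula_ok

    def test_keeps_best_scoring_duplicate(self, tiny_vocab):
        xM = standardize("CCO").formula
        seqs = self._seqs(tiny_vocab, [("OCC", -0.2), ("CCO", -3.0)])
        cands = validate_dereplicate(seqs, xM, tiny_vocab)
        assert cands.candidates[0].rnn_score == -0.2

    def test_unfinished_dropped(self, tiny_vocab):
        seq = ScoredSequence((0, tiny_vocab.index["C"]), -0.1, False)
        assert len(validate_dereplicate([seq], standardize("C").formula,
                                        tiny_vocab)) == 0

    def test_sorted_by_score(self, tiny_vocab):
        xM = standardize("CCO").formula
        seqs = self._seqs(tiny_vocab, [("CCO", -2.0), ("CCN", -1.0),
                                       ("CCC", -3.0)])
        cands = validate_dereplicate(seqs, xM, tiny_vocab)
        scores = [c.rnn_score for c in cands]
        assert scores == sorted(scores, reverse=True)
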