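"""Candidate generation: beam search, stochastic sampling, dereplication.

Beam search keeps the k highest-scoring sequence prefixes per step, where
the score of a sequence is its cumulative token log-probability under the
decoder (the RNN score). Finished sequences (those that emitted the stop
token) compete for slots in the same top-k pool with frozen scores. Tie
breaking is stable by (score, then token index, then beam index) so the
search is bitwise reproducible.

Generated sequences are then validated (parsed), dereplicated by the
14-character connectivity hash (keeping the highest-scoring spelling), and
optionally filtered to the query formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import GenerativeModel
from .molecules import Molecule, ParseFailure, standardize
from .tokenizer import detokenize


@dataclass(frozen=True)
class ScoredSequence:
    """A decoded token sequence with its cumulative log-probability."""

    tokens: tuple[int, ...]  # includes the leading start token
    score: float
    finished: bool


@dataclass(frozen=True)
class ScoredCandidate:
    """A validated unique structure generated for one query."""

    smiles: str
    dedup_key: str
    rnn_score: float
    formula_ok: bool
    molecule: Molecule
    modplatt: float | None = None


@dataclass
class CandidateSet:
    """Unique valid structures for a query, sorted by RNN score."""

    candidates: list[ScoredCandidate] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def keys(self) -> list[str]:
        return [c.dedup_key for c in self.candidates]


def beam_search(model: GenerativeModel, x_F, x_M, k: int,
                l_max: int | None = None,
                feasibility_mask: bool = False,
                retire_finished: bool = False) -> list[ScoredSequence]:
    """Top-k sequence decoding for one query tuple.

    Returns finished sequences sorted by RNN score descending, followed by
    any sequences that hit ``l_max`` without terminating (flagged
    unfinished; they fail downstream validation). Deterministic given the
    model parameters and inputs.

    By default finished sequences keep competing in the shared top-k pool
    and no tokens are hard-masked (the model's learned termination is
    trusted). ``feasibility_mask=True`` additionally forbids tokens whose
    heavy-atom cost would drive an element budget negative;
    ``retire_finished=True`` moves finished sequences to a separate
    completed list, freeing their beam slots.
    """
    if k < 1:
        raise ValueError("beam width must be >= 1")
    vocab = model.vocab
    l_max = l_max or model.cfg.max_len
    t = vocab.t

    z, dec_states, hc_states, v0 = model.init_decode(x_F, x_M)
    start = np.array([vocab.start_idx])
    yh, hc_states = model.hcount_step(start, hc_states)
    v = model.advance_counter(v0, start, yh)
    probs, dec_states = model.decode_step(start, v, z, dec_states)

    tokens: list[tuple[int, ...]] = [(vocab.start_idx,)]
    scores = np.zeros(1)
    finished = np.array([False])
    next_logp = np.log(np.maximum(probs, 1e-300))

    blocked = np.array([vocab.start_idx, vocab.pad_idx])
    completed: list[ScoredSequence] = []
    heavy_cost = model.M[:-1, :t]  # element rows x token columns

    for _ in range(l_max - 1):
        if finished.all() or (retire_finished and len(completed) >= k):
            break
        K = len(tokens)
        cand = scores[:, None] + next_logp  # (K, t)
        cand[:, blocked] = -np.inf
        if feasibility_mask:
            # forbid tokens whose heavy-atom cost overdraws a budget
            need = heavy_cost[None, :, :] > 0
            over = v[:, :-1, None] - heavy_cost[None, :, :] < -1e-9
            cand[np.any(need & over, axis=1)] = -np.inf
        # a finished beam contributes itself as a single frozen candidate
        cand[finished] = -np.inf
        if not retire_finished:
            cand[finished, vocab.pad_idx] = scores[finished]

        flat = cand.ravel()
        parent = np.repeat(np.arange(K), t)
        token = np.tile(np.arange(t), K)
        valid = flat > -np.inf
        flat, parent, token = flat[valid], parent[valid], token[valid]
        order = np.lexsort((parent, token, -flat))
        if retire_finished:
            # finished candidates leave the beam; refill with alive ones
            keep, n_alive = [], 0
            for oi in order:
                if token[oi] == vocab.stop_idx:
                    if len(completed) < k:
                        completed.append(ScoredSequence(
                            tokens[parent[oi]] + (int(token[oi]),),
                            float(flat[oi]), True))
                    continue
                if n_alive < k:
                    keep.append(oi)
                    n_alive += 1
            order = np.array(keep, dtype=int)
            if len(order) == 0:
                finished = np.array([], dtype=bool)
                tokens, scores = [], np.zeros(0)
                break
        else:
            order = order[: min(k, len(flat))]
        parent, token, flat = parent[order], token[order], flat[order]

        new_tokens = []
        for p, tok, fin in zip(parent, token, finished[parent]):
            new_tokens.append(tokens[p] if fin else tokens[p] + (int(tok),))
        new_finished = finished[parent] | (token == vocab.stop_idx)

        dec_states = [(h[parent].copy(), c[parent].copy())
                      for h, c in dec_states]
        hc_states = [(h[parent].copy(), c[parent].copy())
                     for h, c in hc_states]
        v = v[parent].copy()
        next_logp = next_logp[parent].copy()
        scores = flat
        tokens = new_tokens
        finished = new_finished

        advance = ~finished
        if advance.any():
            idx = np.flatnonzero(advance)
            toks = token[idx]
            hc_sub = [(h[idx], c[idx]) for h, c in hc_states]
            yh, hc_sub = model.hcount_step(toks, hc_sub)
            v_sub = model.advance_counter(v[idx], toks, yh)
            dec_sub = [(h[idx], c[idx]) for h, c in dec_states]
            z_sub = np.broadcast_to(z, (len(idx), z.shape[1]))
            probs, dec_sub = model.decode_step(toks, v_sub, z_sub, dec_sub)
            v[idx] = v_sub
            next_logp[idx] = np.log(np.maximum(probs, 1e-300))
            for li in range(len(dec_states)):
                dec_states[li][0][idx] = dec_sub[li][0]
                dec_states[li][1][idx] = dec_sub[li][1]
            for li in range(len(hc_states)):
                hc_states[li][0][idx] = hc_sub[li][0]
                hc_states[li][1][idx] = hc_sub[li][1]

    results = [ScoredSequence(tuple(tok), float(s), bool(f))
               for tok, s, f in zip(tokens, scores, finished)]
    fin = sorted([r for r in results if r.finished] + completed,
                 key=lambda r: (-r.score, r.tokens))[:k]
    unfin = sorted([r for r in results if not r.finished],
                   key=lambda r: (-r.score, r.tokens))
    return fin + unfin


def stochastic_decode(model: GenerativeModel, x_F, x_M, k: int, seed: int,
                      l_max: int | None = None) -> list[ScoredSequence]:
    """Sample k independent sequences token-by-token from the decoder.

    Each sequence is terminated by the stop token or truncated at
    ``l_max``; the RNN score records the model log-probability of the
    sampled tokens. Reproducible under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    vocab = model.vocab
    l_max = l_max or model.cfg.max_len
    xf = np.broadcast_to(np.atleast_2d(np.asarray(x_F, dtype=np.float64)),
                         (k, model.cfg.fp_len))
    xm = np.broadcast_to(np.atleast_2d(np.asarray(x_M, dtype=np.float64)),
                         (k, len(np.atleast_2d(x_M)[0])))
    z, dec_states, hc_states, v = model.init_decode(xf, xm)
    cur = np.full(k, vocab.start_idx)
    yh, hc_states = model.hcount_step(cur, hc_states)
    v = model.advance_counter(v, cur, yh)
    probs, dec_states = model.decode_step(cur, v, z, dec_states)

    tokens = [[vocab.start_idx] for _ in range(k)]
    scores = np.zeros(k)
    finished = np.zeros(k, dtype=bool)

    for _ in range(l_max - 1):
        if finished.all():
            break
        p = probs.copy()
        p[:, [vocab.start_idx, vocab.pad_idx]] = 0.0
        p /= p.sum(axis=1, keepdims=True)
        cdf = np.cumsum(p, axis=1)
        u = rng.random(k)
        chosen = (u[:, None] > cdf).sum(axis=1)
        alive = ~finished
        for i in np.flatnonzero(alive):
            tokens[i].append(int(chosen[i]))
        scores[alive] += np.log(
            np.maximum(probs[alive, chosen[alive]], 1e-300))
        finished = finished | (alive & (chosen == vocab.stop_idx))

        adv = ~finished
        if adv.any():
            # advance all rows together (frozen rows are never read again,
            # but keeping the batch dense is simpler than gathering)
            yh, hc_states = model.hcount_step(chosen, hc_states)
            v = model.advance_counter(v, chosen, yh)
            probs, dec_states = model.decode_step(chosen, v, z, dec_states)

    return [ScoredSequence(tuple(tok), float(s), bool(f))
            for tok, s, f in zip(tokens, scores, finished)]


def validate_dereplicate(
    sequences: Sequence[ScoredSequence], x_M: np.ndarray,
    vocab, require_formula: bool = False,
) -> CandidateSet:
    """Parse, canonicalize and dereplicate decoded sequences.

    Unfinished or unparseable sequences are dropped. Each surviving
    structure is keyed by its connectivity hash; duplicates keep the
    highest RNN score. Formula agreement with the query is flagged and,
    with ``require_formula``, enforced. The result is sorted by RNN score
    descending.
    """
    x_M = np.asarray(x_M).ravel()
    best: dict[str, ScoredCandidate] = {}
    for seq in sequences:
        if not seq.finished:
            continue
        smiles = detokenize(np.array(seq.tokens), vocab)
        try:
            mol = standardize(smiles)
        except ParseFailure:
            continue
        formula_ok = bool(np.array_equal(mol.formula, x_M))
        if require_formula and not formula_ok:
            continue
        cand = ScoredCandidate(
            smiles=mol.smiles_canonical, dedup_key=mol.dedup_key,
            rnn_score=seq.score, formula_ok=formula_ok, molecule=mol)
        prev = best.get(cand.dedup_key)
        if prev is None or cand.rnn_score > prev.rnn_score:
            best[cand.dedup_key] = cand
    ordered = sorted(best.values(),
                     key=lambda c: (-c.rnn_score, c.dedup_key))
    return CandidateSet(ordered)


def write_candidates_tsv(path, cands: CandidateSet) -> None:
    """Candidate table: rank, smiles, dedup_key, rnn_score, formula_ok."""
    with open(path, "w") as fh:
        fh.write("rank\tsmiles\tdedup_key\trnn_score\tformula_ok\n")
        for rank, c in enumerate(cands, start=1):
            fh.write(f"{rank}\t{c.smiles}\t{c.dedup_key}\t"
                     f"{c.rnn_score:.6f}\t{int(c.formula_ok)}\n")
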