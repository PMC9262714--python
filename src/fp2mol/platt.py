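"""Modified Platt score: fingerprint match scoring and candidate re-ranking.

The score measures how well a candidate structure's binary fingerprint
y agrees with a probabilistic query fingerprint x, weighting each bit by
the predictor's per-bit sensitivity a and specificity b:

    sum over bits i of
        0.75 ln x_i     + 0.25 ln(1 - a_i)   if x_i >= 0.5 and y_i = 1
        0.75 ln(1 - x_i)                     if x_i >= 0.5 and y_i = 0
        0.75 ln x_i                          if x_i <  0.5 and y_i = 1
        0.75 ln(1 - x_i) + 0.25 ln(1 - b_i)  if x_i <  0.5 and y_i = 0

Logarithms are natural; x, (1-a) and (1-b) are clamped into
[eps, 1 - eps] (default eps 1e-3) before evaluation, which keeps every
term finite and the total non-positive. The score is additive over bits,
so concatenating fingerprints adds their scores.
"""

from __future__ import annotations

from dataclasses import replace
import numpy as np

from .decoding import CandidateSet
from .molecules import FingerprintConfig, struct_fingerprint
from .simulate import BitStats

DEFAULT_SMOOTHING = 1e-3


def modplatt(x_F: np.ndarray, y_F: np.ndarray, stats: BitStats,
             smoothing: float = DEFAULT_SMOOTHING,
             per_bit: bool = False):
    """Modified Platt score of candidate fingerprint(s) against a query.

    ``x_F``: probabilistic query fingerprint, length n. ``y_F``: binary
    candidate fingerprint, length n, or a (m, n) matrix scoring m
    candidates at once. Returns a float (or a length-m vector); with
    ``per_bit=True`` additionally returns the per-bit contributions.
    """
    x = np.asarray(x_F, dtype=np.float64).ravel()
    y = np.asarray(y_F, dtype=np.float64)
    single = y.ndim == 1
    y = np.atleast_2d(y)
    if x.shape[0] != y.shape[1] or x.shape[0] != stats.n:
        raise ValueError("fingerprint/statistics length mismatch")
    eps = smoothing
    x = np.clip(x, eps, 1.0 - eps)
    # (1-a), (1-b) only need the lower guard: a perfect statistic (a = 0
    # penalty term log 1 = 0) must stay exact
    one_m_a = np.clip(1.0 - stats.sensitivity, eps, 1.0)
    one_m_b = np.clip(1.0 - stats.specificity, eps, 1.0)

    hi = x >= 0.5  # boundary 0.5 belongs to the "high" branches
    pos = y >= 0.5
    log_x = np.log(x)
    log_1mx = np.log(1.0 - x)
    contrib = np.where(
        pos,
        0.75 * log_x + np.where(hi, 0.25 * np.log(one_m_a), 0.0),
        0.75 * log_1mx + np.where(hi, 0.0, 0.25 * np.log(one_m_b)),
    )
    total = contrib.sum(axis=1)
    if single:
        total = float(total[0])
        contrib = contrib[0]
    return (total, contrib) if per_bit else total


def rerank(cands: CandidateSet, x_F: np.ndarray, stats: BitStats,
           fp_config: FingerprintConfig | None = None,
           smoothing: float = DEFAULT_SMOOTHING) -> CandidateSet:
    """Re-rank a candidate set by modified Platt score (descending).

    Each candidate's structural fingerprint is computed with
    ``fp_config``, scored against the query, and the set is re-sorted by
    (modified Platt score, RNN score, dedup key). Both scores are retained;
    the set is unchanged as a set.
    """
    if len(cands) == 0:
        return CandidateSet([])
    fps = np.stack([struct_fingerprint(c.molecule, fp_config)
                    for c in cands])
    scores = modplatt(x_F, fps, stats, smoothing=smoothing)
    scored = [replace(c, modplatt=float(s)) for c, s in zip(cands, scores)]
    scored.sort(key=lambda c: (-c.modplatt, -c.rnn_score, c.dedup_key))
    return CandidateSet(scored)


def write_ranked_tsv(path, cands: CandidateSet,
                     truth_key: str | None = None) -> None:
    """Ranked table: rank, smiles, dedup_key, modplatt, rnn_score
    (+ is_correct when ground truth is supplied)."""
    with open(path, "w") as fh:
        cols = "rank\tsmiles\tdedup_key\tmodplatt\trnn_score"
        if truth_key is not None:
            cols += "\tis_correct"
        fh.write(cols + "\n")
        for rank, c in enumerate(cands, start=1):
            row = (f"{rank}\t{c.smiles}\t{c.dedup_key}\t"
                   f"{c.modplatt:.6f}\t{c.rnn_score:.6f}")
            if truth_key is not None:
                row += f"\t{int(c.dedup_key == truth_key)}"
            fh.write(row + "\n")
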