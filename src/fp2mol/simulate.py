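"""Fingerprint error simulation and per-bit prediction statistics.

Predicted (spectrum-derived) fingerprints are noisy estimates of the true
binary structural fingerprint. To train a decoder that tolerates this
noise, clean fingerprints are corrupted into simulated fingerprints
(sim-FP) by resampling, per bit, a predicted value from a pool of paired
(true, predicted) fingerprints conditioned on the true bit value, adding
uniform jitter, and clipping back to the value range observed for that bit
in the pool.

The same pool yields per-bit sensitivity/specificity estimates (from the
2x2 confusion table at threshold 0.5) used by the modified Platt score.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: prior used when a confusion-table denominator is empty
STAT_PRIOR = 0.5
ROUND_THRESHOLD = 0.5


@dataclass
class BitStats:
    """Per-bit sensitivity/specificity with the underlying counts."""

    sensitivity: np.ndarray
    specificity: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def n(self) -> int:
        return len(self.sensitivity)

    def write_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["bit", "TP", "FP", "TN", "FN", "a", "b"])
            for i in range(self.n):
                w.writerow(
                    [i, int(self.tp[i]), int(self.fp[i]), int(self.tn[i]),
                     int(self.fn[i]), f"{self.sensitivity[i]:.6g}",
                     f"{self.specificity[i]:.6g}"]
                )

    @classmethod
    def read_tsv(cls, path) -> "BitStats":
        rows = list(csv.DictReader(open(path), delimiter="\t"))
        get = lambda k, t: np.array([t(r[k]) for r in rows])
        return cls(
            sensitivity=get("a", float), specificity=get("b", float),
            tp=get("TP", int), fp=get("FP", int),
            tn=get("TN", int), fn=get("FN", int),
        )


@dataclass
class PredictionPool:
    """Paired (true binary fingerprint, predicted fingerprint) rows with a
    fold tag per row, emulating cross-validated fingerprint predictions."""

    true_fp: np.ndarray  # (rows, n) in {0,1}
    predicted_fp: np.ndarray  # (rows, n) in [0,1]
    fold: np.ndarray  # (rows,) int

    def __post_init__(self):
        self.true_fp = np.asarray(self.true_fp, dtype=np.float64)
        self.predicted_fp = np.asarray(self.predicted_fp, dtype=np.float64)
        self.fold = np.asarray(self.fold, dtype=np.int64)
        if self.true_fp.shape != self.predicted_fp.shape:
            raise ValueError("true/predicted shape mismatch")
        if len(self.fold) != len(self.true_fp):
            raise ValueError("fold tag length mismatch")

    @property
    def n_bits(self) -> int:
        return self.true_fp.shape[1]

    def exclude_fold(self, fold: int | None) -> "PredictionPool":
        if fold is None:
            return self
        keep = self.fold != fold
        return PredictionPool(self.true_fp[keep], self.predicted_fp[keep],
                              self.fold[keep])

    def write_tsv(self, path) -> None:
        n = self.n_bits
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["fold"] + [f"true{i}" for i in range(n)]
                       + [f"pred{i}" for i in range(n)])
            for f, t, p in zip(self.fold, self.true_fp, self.predicted_fp):
                w.writerow([int(f)] + [str(int(b)) for b in t]
                           + [f"{v:.6g}" for v in p])

    @classmethod
    def read_tsv(cls, path) -> "PredictionPool":
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            n = (len(header) - 1) // 2
            folds, trues, preds = [], [], []
            for row in reader:
                folds.append(int(row[0]))
                trues.append([float(x) for x in row[1 : 1 + n]])
                preds.append([float(x) for x in row[1 + n :]])
        return cls(np.array(trues), np.array(preds), np.array(folds))


def estimate_bitstats(
    pool: PredictionPool, exclude_fold: int | None = None,
    prior: float = STAT_PRIOR,
) -> BitStats:
    """Per-bit confusion counts and sensitivity a / specificity b.

    Predictions are thresholded at 0.5 against the true bits;
    a_i = TP/(TP+FN) and b_i = TN/(TN+FP), with ``prior`` substituted where
    a denominator is zero (bit never true / never false in the pool).
    """
    pool = pool.exclude_fold(exclude_fold)
    if len(pool.true_fp) == 0:
        raise ValueError("prediction pool is empty after fold exclusion")
    truth = pool.true_fp >= 0.5
    pred = pool.predicted_fp >= ROUND_THRESHOLD
    tp = (truth & pred).sum(axis=0)
    fn = (truth & ~pred).sum(axis=0)
    tn = (~truth & ~pred).sum(axis=0)
    fp = (~truth & pred).sum(axis=0)
    with np.errstate(invalid="ignore"):
        a = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), prior)
        b = np.where(tn + fp > 0, tn / np.maximum(tn + fp, 1), prior)
    return BitStats(sensitivity=a, specificity=b, tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class SimConfig:
    """Fingerprint simulation settings.

    ``noisefactor`` scales the uniform jitter added to each resampled bit
    value; ``rounding`` selects discrete ({0,1} at threshold 0.5, ties up)
    or probabilistic (values kept as-is) output.
    """

    noisefactor: float = 0.2
    rounding: str = "discrete"
    seed: int = 0

    def __post_init__(self):
        if self.noisefactor < 0:
            raise ValueError("noisefactor must be >= 0")
        if self.rounding not in ("discrete", "probabilistic"):
            raise ValueError(f"unknown rounding {self.rounding!r}")


def round_fingerprint(fp: np.ndarray, mode: str = "discrete") -> np.ndarray:
    """Threshold a fingerprint at 0.5 (discrete) or pass it through."""
    fp = np.asarray(fp, dtype=np.float64)
    if mode == "probabilistic":
        return fp
    if mode != "discrete":
        raise ValueError(f"unknown rounding {mode!r}")
    return (fp >= ROUND_THRESHOLD).astype(np.float64)


class FingerprintSimulator:
    """Per-bit conditional resampler from a prediction pool.

    For each bit the pool's predicted values are split by the true bit
    value; simulation draws one value from the matching side, jitters it by
    ``(uniform(0,1) - 0.5) * noisefactor`` and clips to the min/max
    predicted value observed for that bit in the pool. Bits with no pool
    row of the required truth value fall back to the clean bit value.
    """

    def __init__(self, pool: PredictionPool, exclude_fold: int | None = None):
        pool = pool.exclude_fold(exclude_fold)
        if len(pool.true_fp) == 0:
            raise ValueError("prediction pool is empty after fold exclusion")
        n = pool.n_bits
        truth = pool.true_fp >= 0.5
        # ragged per-bit value lists, padded into dense matrices for
        # vectorized row sampling
        self._counts = np.zeros((2, n), dtype=np.int64)
        maxrows = len(pool.true_fp)
        self._bank = np.zeros((2, maxrows, n), dtype=np.float64)
        for side in (0, 1):
            mask = truth == bool(side)
            for i in range(n):
                vals = pool.predicted_fp[mask[:, i], i]
                self._counts[side, i] = len(vals)
                self._bank[side, : len(vals), i] = vals
        self.lo = pool.predicted_fp.min(axis=0)
        self.hi = pool.predicted_fp.max(axis=0)
        self.n_bits = n
        self._fallback = self._counts == 0
        if self._fallback.any():
            logger.warning(
                "no pool rows for %d (truth, bit) cells; falling back to "
                "the clean bit value there", int(self._fallback.sum()),
            )

    def simulate(
        self, true_fp: np.ndarray, cfg: SimConfig,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Simulate predicted fingerprints for clean binary ones.

        ``true_fp`` may be a single fingerprint or a (batch, n) matrix.
        """
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        single = np.ndim(true_fp) == 1
        X = np.atleast_2d(np.asarray(true_fp, dtype=np.float64))
        B, n = X.shape
        if n != self.n_bits:
            raise ValueError("fingerprint length mismatch")
        side = (X >= 0.5).astype(np.int64)  # (B, n)
        counts = self._counts[side, np.arange(n)]  # (B, n)
        row = (rng.random((B, n)) * counts).astype(np.int64)
        row = np.minimum(row, np.maximum(counts - 1, 0))
        sim = self._bank[side, row, np.arange(n)]
        if cfg.noisefactor > 0:
            sim = sim + (rng.random((B, n)) - 0.5) * cfg.noisefactor
            sim = np.clip(sim, self.lo, self.hi)
        fb = self._fallback[side, np.arange(n)]
        sim = np.where(fb, X, sim)
        sim = round_fingerprint(sim, cfg.rounding)
        return sim[0] if single else sim


def simulate_fingerprint(
    true_fp: np.ndarray, pool: PredictionPool, cfg: SimConfig,
    exclude_fold: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One-shot convenience wrapper around :class:`FingerprintSimulator`."""
    sim = FingerprintSimulator(pool, exclude_fold=exclude_fold)
    return sim.simulate(true_fp, cfg, rng=rng)
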