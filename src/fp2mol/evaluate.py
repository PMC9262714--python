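"""Evaluation metrics and the structure-disjoint cross-validation harness.

Per query instance the suite records: the percentage of raw decoded
sequences that parse (% valid SMILES), the percentage that additionally
match the true molecular formula (% correct MF), whether the true
structure appears among the dereplicated candidates (retrieval) and at
which rank, the modified Platt score of the top-ranked candidate, and the
Tanimoto similarity of the best incorrect candidate to the truth (computed
after removing candidates that parse to the correct structure). Dataset
reports aggregate retrieval, the top-n retrieval curve and median/quartile
summaries, under either ranking mode (modified Platt or raw RNN score)
over the same candidate pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .decoding import (CandidateSet, ScoredSequence, beam_search,
                       validate_dereplicate)
from .model import GenerativeModel, ModelConfig, TrainingConfig
from .molecules import (FingerprintConfig, Molecule, ParseFailure,
                        standardize, struct_fingerprint, tanimoto)
from .platt import modplatt, rerank
from .simulate import (BitStats, FingerprintSimulator, PredictionPool,
                       SimConfig, estimate_bitstats)
from .tokenizer import OOVError, TokenVocabulary, TooLongError, detokenize, tokenize


class FoldLeakageError(RuntimeError):
    """A connectivity key appears in both a training and a test fold."""


@dataclass
class InstanceResult:
    """Evaluation outcome for one query."""

    query_id: str
    true_key: str
    n_raw: int
    pct_valid: float
    pct_correct_mf: float
    found: bool
    rank: int | None
    top_modplatt: float | None
    best_incorrect_tanimoto: float | None
    candidates: CandidateSet = field(repr=False, default_factory=CandidateSet)


@dataclass
class DatasetReport:
    """Aggregate over the instances of one dataset and ranking mode."""

    ranking_mode: str
    n_instances: int
    retrieval: float
    top_n: dict[int, float]
    quantiles: dict[str, tuple[float, float, float]]  # 25%, median, 75%

    def to_dict(self) -> dict:
        return {
            "ranking_mode": self.ranking_mode,
            "n_instances": self.n_instances,
            "retrieval": self.retrieval,
            "top_n": {str(k): v for k, v in self.top_n.items()},
            "quantiles": {k: list(v) for k, v in self.quantiles.items()},
        }


def instance_metrics(
    query_id: str,
    sequences: Sequence[ScoredSequence],
    ranked: CandidateSet,
    truth: Molecule,
    x_F: np.ndarray,
    stats: BitStats,
    fp_config: FingerprintConfig,
    vocab: TokenVocabulary,
) -> InstanceResult:
    """Per-instance metrics from raw sequences and a ranked candidate set.

    ``ranked`` must already be ordered under the active ranking mode (the
    modified Platt scores are computed here if the set does not carry
    them). % valid / % correct MF are fractions of the raw sequence count.
    """
    n_raw = len(sequences)
    n_valid = 0
    n_mf = 0
    for seq in sequences:
        if not seq.finished:
            continue
        try:
            mol = standardize(detokenize(np.array(seq.tokens), vocab))
        except ParseFailure:
            continue
        n_valid += 1
        if np.array_equal(mol.formula, truth.formula):
            n_mf += 1
    pct_valid = 100.0 * n_valid / n_raw if n_raw else 0.0
    pct_mf = 100.0 * n_mf / n_raw if n_raw else 0.0

    keys = ranked.keys()
    found = truth.dedup_key in keys
    rank = keys.index(truth.dedup_key) + 1 if found else None

    top_modplatt = None
    best_incorrect_tani = None
    if len(ranked):
        top = ranked.candidates[0]
        if top.modplatt is not None:
            top_modplatt = top.modplatt
        else:
            top_modplatt = float(modplatt(
                x_F, struct_fingerprint(top.molecule, fp_config), stats))
        truth_fp = struct_fingerprint(truth, fp_config)
        for c in ranked:
            if c.dedup_key == truth.dedup_key:
                continue
            best_incorrect_tani = tanimoto(
                struct_fingerprint(c.molecule, fp_config), truth_fp)
            break
    return InstanceResult(
        query_id=query_id, true_key=truth.dedup_key, n_raw=n_raw,
        pct_valid=pct_valid, pct_correct_mf=pct_mf, found=found, rank=rank,
        top_modplatt=top_modplatt, best_incorrect_tanimoto=best_incorrect_tani,
        candidates=ranked)


def dataset_report(
    instances: Sequence[InstanceResult], ranking_mode: str,
    n_grid: Sequence[int] = (1, 2, 5, 10, 32, 128),
) -> DatasetReport:
    """Aggregate instance results: retrieval, top-n curve, quantiles."""
    if not instances:
        raise ValueError("no instances to aggregate")
    n = len(instances)
    retrieval = sum(r.found for r in instances) / n
    top_n = {
        int(g): sum(1 for r in instances if r.rank is not None and r.rank <= g) / n
        for g in n_grid
    }
    quantiles = {}
    for name, values in (
        ("pct_valid", [r.pct_valid for r in instances]),
        ("pct_correct_mf", [r.pct_correct_mf for r in instances]),
        ("top_modplatt", [r.top_modplatt for r in instances
                          if r.top_modplatt is not None]),
        ("best_incorrect_tanimoto", [r.best_incorrect_tanimoto
                                     for r in instances
                                     if r.best_incorrect_tanimoto is not None]),
    ):
        if values:
            q25, q50, q75 = np.percentile(values, [25, 50, 75])
            quantiles[name] = (float(q25), float(q50), float(q75))
    return DatasetReport(ranking_mode=ranking_mode, n_instances=n,
                         retrieval=retrieval, top_n=top_n,
                         quantiles=quantiles)


def evaluate_queries(
    model: GenerativeModel,
    queries: Sequence[tuple[str, Molecule, np.ndarray]],
    stats: BitStats,
    fp_config: FingerprintConfig,
    k: int = 32,
    ranking: str = "modplatt",
    require_formula: bool = False,
) -> list[InstanceResult]:
    """Beam-decode, validate, (re)rank and score a list of queries.

    ``queries``: (id, true molecule, query fingerprint) triples. With
    ``ranking='rnn'`` the candidate order from decoding is kept; with
    ``'modplatt'`` candidates are re-ranked by fingerprint match. The
    candidate sets are identical as sets under both modes.
    """
    if ranking not in ("modplatt", "rnn"):
        raise ValueError(f"unknown ranking mode {ranking!r}")
    results = []
    for qid, truth, x_F in queries:
        seqs = beam_search(model, x_F, truth.formula, k=k)
        cands = validate_dereplicate(seqs, truth.formula, model.vocab,
                                     require_formula=require_formula)
        ranked = rerank(cands, x_F, stats, fp_config)
        if ranking == "rnn":
            by_key = {c.dedup_key: c for c in ranked}
            ranked = CandidateSet(
                [by_key[c.dedup_key] for c in cands])
        results.append(instance_metrics(
            qid, seqs, ranked, truth, x_F, stats, fp_config, model.vocab))
    return results


def closed_world_queries(
    mols: Sequence[Molecule], fp_config: FingerprintConfig,
) -> list[tuple[str, Molecule, np.ndarray]]:
    """Self-recovery queries: each molecule queried with its own clean
    structural fingerprint."""
    return [(m.dedup_key, m, struct_fingerprint(m, fp_config).astype(float))
            for m in mols]


def training_set_baseline(
    train_mols: Sequence[Molecule], x_F: np.ndarray, stats: BitStats,
    fp_config: FingerprintConfig, mode: str = "best",
    rng: np.random.Generator | None = None,
) -> tuple[Molecule, float]:
    """Baseline comparators: best or random training-set structure.

    'best' scans the training corpus for the molecule whose fingerprint
    maximizes the modified Platt score against the query; 'random' picks a
    uniform training molecule. Returns (molecule, its score).
    """
    if mode == "random":
        rng = rng or np.random.default_rng(0)
        mol = train_mols[int(rng.integers(len(train_mols)))]
        return mol, float(modplatt(
            x_F, struct_fingerprint(mol, fp_config), stats))
    if mode != "best":
        raise ValueError(f"unknown baseline mode {mode!r}")
    fps = np.stack([struct_fingerprint(m, fp_config) for m in train_mols])
    scores = modplatt(x_F, fps, stats)
    i = int(np.argmax(scores))
    return train_mols[i], float(scores[i])


def write_instances_tsv(path, instances: Sequence[InstanceResult]) -> None:
    """Per-instance metric table (one row per query)."""
    cols = ["query_id", "true_key", "n_raw", "pct_valid", "pct_correct_mf",
            "found", "rank", "top_modplatt", "best_incorrect_tanimoto"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in instances:
            fh.write("\t".join("" if v is None else str(v) for v in (
                r.query_id, r.true_key, r.n_raw, round(r.pct_valid, 4),
                round(r.pct_correct_mf, 4), int(r.found), r.rank,
                None if r.top_modplatt is None else round(r.top_modplatt, 4),
                None if r.best_incorrect_tanimoto is None
                else round(r.best_incorrect_tanimoto, 4))) + "\n")


# ---------------------------------------------------------------------------
# cross-validation


def tokenize_corpus(
    mols: Sequence[Molecule], vocab: TokenVocabulary, l: int,
) -> tuple[list[Molecule], np.ndarray]:
    """Tokenize molecules, dropping those with OOV tokens or over-length
    sequences; returns (kept molecules, index matrix)."""
    kept, rows = [], []
    for m in mols:
        try:
            rows.append(tokenize(m.smiles_canonical, vocab, l))
            kept.append(m)
        except (OOVError, TooLongError):
            continue
    if not kept:
        raise ValueError("no tokenizable molecules")
    return kept, np.stack(rows)


def train_model(
    mols: Sequence[Molecule],
    vocab: TokenVocabulary,
    model_cfg: ModelConfig,
    train_cfg: TrainingConfig,
    fp_config: FingerprintConfig,
    pool: PredictionPool | None = None,
    sim_cfg: SimConfig | None = None,
    exclude_fold: int | None = None,
    log: Callable | None = None,
) -> tuple[GenerativeModel, list[dict]]:
    """Fit a generative model on a molecule list.

    If a prediction pool is given, training fingerprints are corrupted
    on the fly into sim-FPs (with ``exclude_fold`` removed from the pool);
    otherwise the clean structural fingerprints are used.
    """
    kept, Y = tokenize_corpus(mols, vocab, model_cfg.max_len)
    x_F = np.stack([struct_fingerprint(m, fp_config) for m in kept]
                   ).astype(np.float64)
    x_M = np.stack([m.formula for m in kept]).astype(np.float64)
    model = GenerativeModel(model_cfg, vocab, fp_config)
    simulator = None
    if pool is not None:
        simulator = FingerprintSimulator(pool, exclude_fold=exclude_fold)
    history = model.fit(x_F, x_M, Y, train_cfg, simulator=simulator,
                        sim_config=sim_cfg or SimConfig(), log=log)
    return model, history


def crossval_run(
    mols: Sequence[Molecule],
    record_folds: Sequence[int],
    pool: PredictionPool,
    model_cfg: ModelConfig,
    train_cfg: TrainingConfig,
    fp_config: FingerprintConfig,
    sim_cfg: SimConfig | None = None,
    k: int = 32,
    folds: Sequence[int] | None = None,
    ranking_modes: Sequence[str] = ("modplatt", "rnn"),
    query_seed: int = 0,
) -> dict[int, dict[str, DatasetReport]]:
    """Structure-disjoint cross-validation.

    For every evaluated fold f, a model is trained on all records outside
    f with the fingerprint-simulation pool also excluding f, then queried
    with simulated fingerprints of the fold-f molecules. Any connectivity
    key shared between the training and test side raises
    :class:`FoldLeakageError` before training starts.
    """
    sim_cfg = sim_cfg or SimConfig()
    record_folds = np.asarray(record_folds)
    if len(record_folds) != len(mols):
        raise ValueError("one fold tag per record required")
    all_folds = sorted(set(int(f) for f in record_folds))
    out: dict[int, dict[str, DatasetReport]] = {}
    for f in (folds if folds is not None else all_folds):
        test = [m for m, mf in zip(mols, record_folds) if mf == f]
        train = [m for m, mf in zip(mols, record_folds) if mf != f]
        test_keys = {m.dedup_key for m in test}
        train_keys = {m.dedup_key for m in train}
        shared = test_keys & train_keys
        if shared:
            raise FoldLeakageError(
                f"fold {f}: {len(shared)} connectivity keys shared between "
                f"train and test (e.g. {sorted(shared)[0]})")
        vocab = TokenVocabulary.from_corpus(
            [m.smiles_canonical for m in train], min_count=0)
        model, _ = train_model(train, vocab, model_cfg, train_cfg,
                               fp_config, pool=pool, sim_cfg=sim_cfg,
                               exclude_fold=f)
        stats = estimate_bitstats(pool, exclude_fold=f)
        simulator = FingerprintSimulator(pool, exclude_fold=f)
        rng = np.random.default_rng(query_seed + f)
        queries = []
        for m in test:
            clean = struct_fingerprint(m, fp_config).astype(float)
            q = simulator.simulate(clean, sim_cfg, rng=rng)
            queries.append((m.dedup_key, m, q))
        out[f] = {}
        for mode in ranking_modes:
            inst = evaluate_queries(model, queries, stats, fp_config,
                                    k=k, ranking=mode)
            out[f][mode] = dataset_report(inst, mode)
    return out
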