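"""Self-contained synthetic inputs: molecules, fingerprints, noise pools.

The generator grows small organic molecules by seeded, valence-respecting
random graph growth (optionally starting from an aromatic ring template),
canonicalizes and filters them with the same rules as real input data, and
derives everything downstream needs: structural fingerprints, a paired
(true, predicted) fingerprint pool with calibrated per-bit noise, the
resulting bit statistics, and structure-disjoint fold tags. All outputs
are deterministic under the spec seed.

The corpus is guaranteed to exercise every tokenizer path (an aromatic
ring, a branch, a bracket atom such as ``[nH]``, and a two-letter element
written via its alias) by seeding it with a few fixed structures before
random growth. The chemistry is deliberately simple — small decorated
rings and branched chains — and is not representative of natural-product
space; it exists to exercise the pipeline, not to model metabolomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from .molecules import (FingerprintConfig, Molecule, filter_molecule,
                        split_folds, standardize, struct_fingerprint)
from .simulate import BitStats, PredictionPool, estimate_bitstats

logger = logging.getLogger(__name__)

#: default valences for single-bond growth
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1,
            "P": 3, "I": 1}

#: aromatic ring templates (aromatic ring, bracket token, heteroatoms)
_TEMPLATES = ("c1ccccc1", "c1cc[nH]c1", "c1ccoc1", "c1ccsc1", "c1ccncc1")

#: fixed starters guaranteeing tokenizer path coverage
_SEED_SMILES = ("c1cc[nH]c1", "CC(C)O", "CCCl", "CCBr", "Clc1ccccc1")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic fixture set.

    ``flip_prob`` is the per-bit probability that a pool prediction lands
    on the wrong side of 0.5, so the programmed per-bit sensitivity and
    specificity are both ``1 - flip_prob``; predicted values are drawn
    uniformly from [0.55, 0.95] (bit on) or [0.05, 0.45] (bit off), which
    is the calibration spread.
    """

    n_molecules: int = 500
    max_heavy_atoms: int = 9
    palette: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br")
    fp_len: int = 512
    flip_prob: float = 0.1
    pool_replicates: int = 4
    n_folds: int = 10
    seed: int = 0

    def fingerprint_config(self) -> FingerprintConfig:
        return FingerprintConfig(n_bits=self.fp_len)


def _free_valence(atom: Chem.Atom) -> int:
    return atom.GetTotalNumHs()


def _grow_molecule(rng: np.random.Generator, spec: FixtureSpec) -> str | None:
    """One attempt at growing a random molecule; returns SMILES or None."""
    palette = [e for e in spec.palette if e in _VALENCE]
    weights = np.array([6.0 if e == "C" else 1.0 for e in palette])
    weights /= weights.sum()

    pal = set(palette)
    templates = [t for t in _TEMPLATES
                 if {c.upper() for c in t if c.isalpha() and c != "H"} <= pal]
    if templates and rng.random() < 0.5:
        smiles = templates[int(rng.integers(len(templates)))]
        mol = Chem.RWMol(Chem.MolFromSmiles(smiles))
    else:
        sym = rng.choice(palette, p=weights)
        mol = Chem.RWMol()
        mol.AddAtom(Chem.Atom(sym))
    Chem.SanitizeMol(mol)

    target = int(rng.integers(4, spec.max_heavy_atoms + 1))
    guard = 0
    while mol.GetNumAtoms() < target and guard < 50:
        guard += 1
        anchors = [a.GetIdx() for a in mol.GetAtoms() if _free_valence(a) > 0]
        if not anchors:
            break
        ai = int(anchors[int(rng.integers(len(anchors)))])
        anchor = mol.GetAtomWithIdx(ai)
        # keep the chemistry sane: heteroatoms only accept carbon neighbors
        if anchor.GetSymbol() == "C":
            sym = str(rng.choice(palette, p=weights))
        else:
            sym = "C"
        order = Chem.BondType.SINGLE
        if (_VALENCE[sym] >= 2 and _free_valence(anchor) >= 2
                and not anchor.GetIsAromatic() and rng.random() < 0.15):
            order = Chem.BondType.DOUBLE
        trial = Chem.RWMol(mol)
        bi = trial.AddAtom(Chem.Atom(sym))
        trial.AddBond(ai, bi, order)
        try:
            Chem.SanitizeMol(trial)
        except Exception:
            continue
        mol = trial
    if mol.GetNumAtoms() < 3:
        return None
    # occasional extra (non-aromatic) ring closure
    if rng.random() < 0.15:
        idx = [a.GetIdx() for a in mol.GetAtoms()
               if _free_valence(a) > 0 and not a.GetIsAromatic()]
        if len(idx) >= 2:
            a, b = rng.choice(idx, size=2, replace=False)
            if not mol.GetBondBetweenAtoms(int(a), int(b)):
                trial = Chem.RWMol(mol)
                trial.AddBond(int(a), int(b), Chem.BondType.SINGLE)
                try:
                    Chem.SanitizeMol(trial)
                    mol = trial
                except Exception:
                    pass
    return Chem.MolToSmiles(mol)


def generate_corpus(spec: FixtureSpec) -> list[Molecule]:
    """Deterministic synthetic molecule corpus.

    Every returned molecule passes the full input filter; duplicates (by
    connectivity key) are removed. If the attempt budget runs out before
    ``n_molecules`` distinct structures are found, a partial corpus is
    returned with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    corpus: list[Molecule] = []
    seen: set[str] = set()

    def admit(smiles: str) -> None:
        try:
            mol = standardize(smiles)
        except Exception:
            return
        if mol.dedup_key in seen:
            return
        if not filter_molecule(mol, smiles).keep:
            return
        seen.add(mol.dedup_key)
        corpus.append(mol)

    allowed = set(spec.palette) | {"H"}
    for s in _SEED_SMILES:
        try:
            m = Chem.MolFromSmiles(s)
        except Exception:  # pragma: no cover
            continue
        if all(a.GetSymbol() in allowed for a in m.GetAtoms()):
            admit(s)
    budget = 60 * spec.n_molecules
    attempts = 0
    while len(corpus) < spec.n_molecules and attempts < budget:
        attempts += 1
        smiles = _grow_molecule(rng, spec)
        if smiles:
            admit(smiles)
    if len(corpus) < spec.n_molecules:
        logger.warning("corpus generation exhausted budget: %d/%d molecules",
                       len(corpus), spec.n_molecules)
    return corpus[: spec.n_molecules]


def generate_pool(
    corpus: Sequence[Molecule], spec: FixtureSpec,
    folds: dict[str, int] | None = None,
) -> tuple[PredictionPool, BitStats]:
    """Paired (true, predicted) fingerprint pool with calibrated noise.

    Each molecule contributes ``pool_replicates`` rows. Per bit, the
    predicted value sits on the true side of 0.5 with probability
    ``1 - flip_prob``, drawn uniformly within the calibration band, so
    :func:`~fp2mol.simulate.estimate_bitstats` recovers sensitivity and
    specificity ``1 - flip_prob`` up to binomial sampling error. Fold tags
    follow the supplied structure-disjoint fold assignment.
    """
    rng = np.random.default_rng(spec.seed + 1)
    fp_cfg = spec.fingerprint_config()
    trues, preds, tags = [], [], []
    for m in corpus:
        true = struct_fingerprint(m, fp_cfg).astype(np.float64)
        tag = folds[m.dedup_key] if folds is not None else 0
        for _ in range(spec.pool_replicates):
            flip = rng.random(spec.fp_len) < spec.flip_prob
            eff = np.where(flip, 1.0 - true, true)
            lo = np.where(eff >= 0.5, 0.55, 0.05)
            pred = lo + 0.40 * rng.random(spec.fp_len)
            trues.append(true)
            preds.append(pred)
            tags.append(tag)
    pool = PredictionPool(np.stack(trues), np.stack(preds), np.array(tags))
    return pool, estimate_bitstats(pool)


@dataclass
class FixtureSet:
    """Everything the pipeline needs, generated from one spec."""

    spec: FixtureSpec
    corpus: list[Molecule]
    folds: dict[str, int]
    pool: PredictionPool
    stats: BitStats

    @property
    def fp_config(self) -> FingerprintConfig:
        return self.spec.fingerprint_config()


def make_fixture(spec: FixtureSpec | None = None) -> FixtureSet:
    """Generate the full fixture bundle (corpus, folds, pool, stats)."""
    spec = spec or FixtureSpec()
    corpus = generate_corpus(spec)
    folds = split_folds(corpus, n_folds=spec.n_folds, seed=spec.seed)
    pool, stats = generate_pool(corpus, spec, folds)
    return FixtureSet(spec=spec, corpus=corpus, folds=folds, pool=pool,
                      stats=stats)
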