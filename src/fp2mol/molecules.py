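"""Molecule standardization, filtering, fingerprinting and fold splitting.

The package works on stereochemistry-free aromatic canonical SMILES. Every
molecule is identified by a 14-character connectivity hash (the first block
of its InChIKey, which ignores stereochemistry and charge); this key drives
dereplication of generated candidates and structure-disjoint fold splitting.

Molecular formulas are held as integer count vectors over the ten supported
elements in the fixed order C, F, I, Cl, N, O, P, Br, S, H.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

#: Fixed element order of the formula vector.
ELEMENTS: tuple[str, ...] = ("C", "F", "I", "Cl", "N", "O", "P", "Br", "S", "H")
ELEMENT_INDEX: dict[str, int] = {e: i for i, e in enumerate(ELEMENTS)}
N_ELEMENTS = len(ELEMENTS)

#: Elements a molecule may contain (the ten above; hydrogen is implicit).
ALLOWED_ELEMENTS = frozenset(ELEMENTS)

MAX_SMILES_LEN = 127
MAX_MOL_WEIGHT = 1000.0
MAX_RINGS = 7


class ParseFailure(ValueError):
    """A SMILES string could not be parsed into a molecular graph."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


@dataclass(frozen=True)
class Molecule:
    """A standardized molecule.

    ``smiles_canonical`` is the aromatic, stereo-free canonical SMILES;
    ``formula`` the length-10 element count vector; ``dedup_key`` the
    14-character connectivity hash; ``mol_weight`` the average molecular
    weight in Da.
    """

    smiles_canonical: str
    formula: np.ndarray
    dedup_key: str
    mol_weight: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "formula", np.asarray(self.formula, dtype=np.int64)
        )

    @property
    def rdmol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles_canonical)


def formula_vector(mol: Chem.Mol) -> np.ndarray:
    """Element count vector (incl. total hydrogens) for an RDKit molecule."""
    counts = np.zeros(N_ELEMENTS, dtype=np.int64)
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        idx = ELEMENT_INDEX.get(sym)
        if idx is not None:
            counts[idx] += 1
        counts[ELEMENT_INDEX["H"]] += atom.GetTotalNumHs()
    return counts


def dedup_key(mol: Chem.Mol) -> str:
    """14-character connectivity hash (first InChIKey block)."""
    return Chem.MolToInchiKey(mol)[:14]


def standardize(smiles_raw: str) -> Molecule:
    """Parse a SMILES, strip stereochemistry and canonicalize.

    Stereo descriptors are removed on the molecular graph (not textually),
    so any dialect of wedge/slash/``@`` annotation is handled. The returned
    canonical form is idempotent: re-standardizing it is a fixed point.

    Raises
    ------
    ParseFailure
        If the SMILES cannot be parsed.
    """
    if not smiles_raw:
        raise ParseFailure(smiles_raw)
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise ParseFailure(smiles_raw)
    Chem.RemoveStereochemistry(mol)
    smiles = Chem.MolToSmiles(mol)
    # reparse so that formula/key/weight describe exactly the canonical form
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - canonical output always reparses
        raise ParseFailure(smiles_raw)
    return Molecule(
        smiles_canonical=smiles,
        formula=formula_vector(mol),
        dedup_key=dedup_key(mol),
        mol_weight=Descriptors.MolWt(mol),
    )


def ring_closure_count(smiles: str) -> int:
    """Number of ring-closure digit pairs written in a SMILES string.

    Counts ring-bond closure labels (digits and ``%nn`` groups) outside of
    square brackets; each ring contributes an opening and a closing label.
    """
    n = 0
    depth = 0
    i = 0
    while i < len(smiles):
        ch = smiles[i]
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
        elif depth == 0:
            if ch == "%":
                n += 1
                i += 3
                continue
            if ch.isdigit():
                n += 1
        i += 1
    return n // 2


# primary rejection reason codes, checked in this order
REASON_TOO_LONG = "too-long"
REASON_DISCONNECTED = "disconnected"
REASON_OVERWEIGHT = "overweight"
REASON_CHARGED = "charged"
REASON_TOO_MANY_RINGS = "too-many-rings"
REASON_DISALLOWED_ELEMENT = "disallowed-element"
REASON_UNPARSEABLE = "unparseable"


@dataclass(frozen=True)
class FilterResult:
    keep: bool
    reason: str | None = None


def filter_molecule(mol: Molecule, smiles_raw: str | None = None) -> FilterResult:
    """Apply the training-set acceptance rules to a standardized molecule.

    A molecule is rejected if its input SMILES is longer than 127
    characters, it is disconnected (SMILES contains a dot), heavier than
    1,000 Da, carries a formal charge, writes more than seven rings in its
    SMILES, or contains elements outside C, H, N, O, P, S, Br, Cl, I, F.
    Exactly one (the first violated) reason is reported.
    """
    raw = smiles_raw if smiles_raw is not None else mol.smiles_canonical
    if len(raw) > MAX_SMILES_LEN:
        return FilterResult(False, REASON_TOO_LONG)
    if "." in raw or "." in mol.smiles_canonical:
        return FilterResult(False, REASON_DISCONNECTED)
    if mol.mol_weight > MAX_MOL_WEIGHT:
        return FilterResult(False, REASON_OVERWEIGHT)
    rd = mol.rdmol
    if any(a.GetFormalCharge() != 0 for a in rd.GetAtoms()):
        return FilterResult(False, REASON_CHARGED)
    if ring_closure_count(mol.smiles_canonical) > MAX_RINGS:
        return FilterResult(False, REASON_TOO_MANY_RINGS)
    for atom in rd.GetAtoms():
        if atom.GetSymbol() not in ALLOWED_ELEMENTS:
            return FilterResult(False, REASON_DISALLOWED_ELEMENT)
    return FilterResult(True, None)


def prepare(smiles_raw: str) -> tuple[Molecule | None, FilterResult]:
    """Standardize and filter in one step; parse failures become rejections."""
    try:
        mol = standardize(smiles_raw)
    except ParseFailure:
        return None, FilterResult(False, REASON_UNPARSEABLE)
    return mol, filter_molecule(mol, smiles_raw)


def parse_formula(formula: str) -> np.ndarray:
    """Parse a molecular formula string (e.g. ``C2H6O``) into the fixed
    10-element count vector."""
    import re

    counts = np.zeros(N_ELEMENTS, dtype=np.int64)
    pos = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        sym, num = m.group(1), m.group(2)
        if sym not in ELEMENT_INDEX:
            raise ValueError(f"unsupported element {sym!r} in {formula!r}")
        counts[ELEMENT_INDEX[sym]] += int(num) if num else 1
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def formula_to_string(counts: np.ndarray) -> str:
    """Hill-ordered formula string for a count vector."""
    counts = np.asarray(counts)
    parts = []
    order = ["C", "H"] + sorted(e for e in ELEMENTS if e not in ("C", "H"))
    for sym in order:
        n = int(counts[ELEMENT_INDEX[sym]])
        if n == 1:
            parts.append(sym)
        elif n > 1:
            parts.append(f"{sym}{n}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# structural fingerprints


@dataclass(frozen=True)
class FingerprintConfig:
    """Configuration of the deterministic structural fingerprint.

    The fingerprint function is pluggable: ``kind`` selects a registered
    implementation, ``n_bits`` its length. The default is an RDKit Morgan
    (circular, radius 2) bit vector.
    """

    n_bits: int = 512
    kind: str = "morgan"
    radius: int = 2

    def to_dict(self) -> dict:
        return {"n_bits": self.n_bits, "kind": self.kind, "radius": self.radius}

    @classmethod
    def from_dict(cls, d: dict) -> "FingerprintConfig":
        return cls(**d)


_FP_REGISTRY: dict[str, Callable[[Chem.Mol, "FingerprintConfig"], np.ndarray]] = {}


def register_fingerprint(kind: str):
    def deco(fn):
        _FP_REGISTRY[kind] = fn
        return fn

    return deco


@register_fingerprint("morgan")
def _morgan_fp(mol: Chem.Mol, cfg: FingerprintConfig) -> np.ndarray:
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=cfg.radius, fpSize=cfg.n_bits
    )
    return np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)


def struct_fingerprint(
    mol: Molecule | Chem.Mol, fp_config: FingerprintConfig | None = None
) -> np.ndarray:
    """Deterministic binary structural fingerprint of a molecule."""
    cfg = fp_config or FingerprintConfig()
    rd = mol.rdmol if isinstance(mol, Molecule) else mol
    fn = _FP_REGISTRY.get(cfg.kind)
    if fn is None:
        raise ValueError(f"unknown fingerprint kind {cfg.kind!r}")
    return fn(rd, cfg)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity of two binary fingerprints."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


# ---------------------------------------------------------------------------
# structure-disjoint folds


def split_folds(
    mols: Sequence[Molecule], n_folds: int = 10, seed: int = 0
) -> dict[str, int]:
    """Assign every distinct connectivity key to one of ``n_folds`` folds.

    All records sharing a ``dedup_key`` land in the same fold, making the
    folds structure-disjoint. Keys are shuffled deterministically under
    ``seed`` and dealt round-robin, so fold sizes differ by at most one.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    keys = sorted({m.dedup_key for m in mols})
    if len(keys) < n_folds:
        raise ValueError(
            f"need at least {n_folds} distinct structures, got {len(keys)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    return {keys[j]: int(i % n_folds) for i, j in enumerate(order)}


# ---------------------------------------------------------------------------
# file formats


def read_smiles_file(path) -> list[str]:
    """Read a .smi (one SMILES per line) or CSV/TSV with a 'smiles' column."""
    path = str(path)
    if path.endswith((".csv", ".tsv")):
        delim = "\t" if path.endswith(".tsv") else ","
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter=delim)
            if reader.fieldnames is None or "smiles" not in reader.fieldnames:
                raise ValueError(f"{path}: no 'smiles' column")
            return [row["smiles"] for row in reader]
    with open(path) as fh:
        return [line.split()[0] for line in fh if line.strip()]


def write_smiles_file(path, smiles: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for s in smiles:
            fh.write(s + "\n")


def write_fingerprint_table(path, mols: Sequence[Molecule], fps: np.ndarray) -> None:
    """TSV: dedup_key, smiles, then one column per fingerprint bit."""
    fps = np.asarray(fps)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["dedup_key", "smiles"] + [f"bit{i}" for i in range(fps.shape[1])])
        for m, fp in zip(mols, fps):
            w.writerow([m.dedup_key, m.smiles_canonical] + [str(int(b)) for b in fp])


def write_folds(path, folds: dict[str, int]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["dedup_key", "fold"])
        for k in sorted(folds):
            w.writerow([k, folds[k]])


def read_folds(path) -> dict[str, int]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return {row["dedup_key"]: int(row["fold"]) for row in reader}
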