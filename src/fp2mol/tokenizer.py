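"""SMILES tokenization and the token vocabulary.

A SMILES string is split into tokens that are either a single character
(``C``, ``c``, ``=``, ``3``, ``(`` ...), a two-letter element alias (``Br``
is written ``R`` and ``Cl`` is written ``L`` so every token is one scan
unit), a ``%nn`` ring-closure label, or a full square-bracket group such as
``[nH]``. Sequences are framed with a start token ``$``, a stop token ``*``
and padded with ``&`` to a fixed length.

The module also derives, for each token, the heavy-atom counts used by the
formula countdown, and the per-token true hydrogen labels obtained from the
molecular graph (used to verify counter conservation).
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .molecules import ELEMENT_INDEX, N_ELEMENTS

START, STOP, PAD = "$", "*", "&"
SPECIALS = (START, STOP, PAD)

_TWO_LETTER = (("Br", "R"), ("Cl", "L"))

#: single-character tokens that denote an atom
_ATOM_CHARS = frozenset("CNOSPFIRL" + "cnops")

_BRACKET_ELEMENT_RE = re.compile(r"\[(?:\d+)?([A-Z][a-z]?|[cnops])")
_BRACKET_H_RE = re.compile(r"\[(?:\d+)?(?:[A-Z][a-z]?|[cnops])@*H(\d*)")


class OOVError(ValueError):
    """A token of the SMILES is not in the vocabulary."""

    def __init__(self, token: str):
        super().__init__(f"out-of-vocabulary token: {token!r}")
        self.token = token


class TooLongError(ValueError):
    """A SMILES needs more than the fixed sequence length."""


def smiles_tokens(smiles: str) -> list[str]:
    """Split a SMILES into tokens (with Br/Cl already aliased to R/L)."""
    for full, alias in _TWO_LETTER:
        smiles = smiles.replace(full, alias)
    tokens: list[str] = []
    i = 0
    while i < len(smiles):
        ch = smiles[i]
        if ch == "[":
            j = smiles.index("]", i)
            tokens.append(smiles[i : j + 1])
            i = j + 1
        elif ch == "%":
            tokens.append(smiles[i : i + 3])
            i += 3
        else:
            tokens.append(ch)
            i += 1
    return tokens


def join_tokens(tokens: Iterable[str]) -> str:
    """Inverse of :func:`smiles_tokens` (restores Br/Cl spelling)."""
    s = "".join(tokens)
    for full, alias in _TWO_LETTER:
        s = s.replace(alias, full)
    return s


def is_atom_token(token: str) -> bool:
    return token.startswith("[") or token in _ATOM_CHARS


def token_element(token: str) -> str | None:
    """Element symbol of an atom token (``None`` for non-atom tokens)."""
    if token.startswith("["):
        m = _BRACKET_ELEMENT_RE.match(token)
        if not m:
            return None
        sym = m.group(1)
    elif token in _ATOM_CHARS:
        sym = token
    else:
        return None
    sym = {"R": "Br", "L": "Cl"}.get(sym, sym)
    if sym.islower():
        sym = sym.capitalize()
    return sym


def token_atom_counts(token: str) -> np.ndarray:
    """Heavy-element count vector contributed by one token.

    Hydrogens — including explicit ones inside bracket atoms — are not
    counted here; they are budgeted through the dedicated hydrogen channel
    of the countdown matrix.
    """
    counts = np.zeros(N_ELEMENTS, dtype=np.float64)
    sym = token_element(token)
    if sym is not None and sym in ELEMENT_INDEX and sym != "H":
        counts[ELEMENT_INDEX[sym]] += 1.0
    return counts


def token_true_hydrogens(mol: Chem.Mol, canonical_smiles: str) -> np.ndarray:
    """True hydrogen count per token of a canonical SMILES.

    Atom tokens receive the total hydrogen count (implicit + explicit) of
    the atom they spell, matched through the writer's atom output order;
    all other tokens receive 0.
    """
    mol = Chem.Mol(mol)
    out = Chem.MolToSmiles(mol)
    if out != canonical_smiles:
        raise ValueError("SMILES is not in canonical form")
    order = json.loads(mol.GetProp("_smilesAtomOutputOrder"))
    tokens = smiles_tokens(canonical_smiles)
    labels = np.zeros(len(tokens), dtype=np.float64)
    ai = 0
    for t, tok in enumerate(tokens):
        if is_atom_token(tok):
            atom = mol.GetAtomWithIdx(order[ai])
            labels[t] = atom.GetTotalNumHs()
            ai += 1
    if ai != mol.GetNumAtoms():
        raise ValueError("token/atom alignment failed")
    return labels


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered token set with the three specials always present.

    Token order: ``$``, ``*``, ``&`` first, then retained corpus tokens by
    descending frequency (ties lexical). Indices are stable across
    save/load.
    """

    tokens: tuple[str, ...]
    min_count: int = 0

    def __post_init__(self):
        if self.tokens[:3] != SPECIALS:
            raise ValueError("vocabulary must start with the special tokens")

    @property
    def t(self) -> int:
        return len(self.tokens)

    @property
    def index(self) -> dict[str, int]:
        return {tok: i for i, tok in enumerate(self.tokens)}

    start_idx = 0
    stop_idx = 1
    pad_idx = 2

    @classmethod
    def from_corpus(
        cls, corpus: Sequence[str], min_count: int = 100
    ) -> "TokenVocabulary":
        """Build the vocabulary of tokens occurring more than ``min_count``
        times in the corpus."""
        if not corpus:
            raise ValueError("empty corpus")
        freq: Counter[str] = Counter()
        for smiles in corpus:
            freq.update(smiles_tokens(smiles))
        kept = [
            tok
            for tok, n in sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
            if n > min_count and tok not in SPECIALS
        ]
        return cls(tokens=SPECIALS + tuple(kept), min_count=min_count)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"tokens": list(self.tokens), "min_count": self.min_count}, fh)

    @classmethod
    def load(cls, path) -> "TokenVocabulary":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tokens=tuple(d["tokens"]), min_count=d["min_count"])

    def to_dict(self) -> dict:
        return {"tokens": list(self.tokens), "min_count": self.min_count}

    @classmethod
    def from_dict(cls, d: dict) -> "TokenVocabulary":
        return cls(tokens=tuple(d["tokens"]), min_count=d["min_count"])


def tokenize(smiles: str, vocab: TokenVocabulary, l: int = 128) -> np.ndarray:
    """Encode a SMILES as a fixed-length index sequence ``$ s... * & ...``.

    Raises :class:`OOVError` for tokens outside the vocabulary and
    :class:`TooLongError` if the tokens plus start/stop exceed ``l``.
    """
    toks = smiles_tokens(smiles)
    index = vocab.index
    try:
        body = [index[t] for t in toks]
    except KeyError:
        for t in toks:
            if t not in index:
                raise OOVError(t) from None
        raise  # pragma: no cover
    if len(body) + 2 > l:
        raise TooLongError(f"{len(body)} tokens + start/stop > l={l}")
    seq = np.full(l, vocab.pad_idx, dtype=np.int64)
    seq[0] = vocab.start_idx
    seq[1 : 1 + len(body)] = body
    seq[1 + len(body)] = vocab.stop_idx
    return seq


def detokenize(seq: Sequence[int] | np.ndarray, vocab: TokenVocabulary) -> str:
    """Decode an index sequence back to a SMILES string.

    Start/stop/pad framing is stripped; decoding stops at the first stop
    token.
    """
    toks = []
    for idx in np.asarray(seq).ravel():
        idx = int(idx)
        if idx == vocab.stop_idx:
            break
        if idx in (vocab.start_idx, vocab.pad_idx):
            continue
        toks.append(vocab.tokens[idx])
    return join_tokens(toks)


def onehot(seq: np.ndarray, t: int) -> np.ndarray:
    """One-hot encode an index array along a trailing token axis."""
    seq = np.asarray(seq)
    out = np.zeros(seq.shape + (t,), dtype=np.float64)
    np.put_along_axis(out, seq[..., None], 1.0, axis=-1)
    return out


def counter_matrix(vocab: TokenVocabulary) -> np.ndarray:
    """Constant countdown matrix M of shape (11, t + 1).

    Rows: the ten element budgets then the open-bracket balance. Columns:
    one per vocabulary token plus a final hydrogen channel. Under the update
    ``v_i = v_{i-1} - M @ concat(y_i, y_i_H)`` an atom token decrements its
    element budget, the hydrogen channel decrements the hydrogen budget, and
    ``(`` / ``)`` raise / lower the bracket balance.
    """
    t = vocab.t
    M = np.zeros((N_ELEMENTS + 1, t + 1), dtype=np.float64)
    for j, tok in enumerate(vocab.tokens):
        M[:N_ELEMENTS, j] = token_atom_counts(tok)
        if tok == "(":
            M[N_ELEMENTS, j] = -1.0
        elif tok == ")":
            M[N_ELEMENTS, j] = 1.0
    M[ELEMENT_INDEX["H"], t] = 1.0
    return M
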