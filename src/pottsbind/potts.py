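"""Potts-model score over peptide sequences with tabulated energies.

The design landscape is a Potts model: each of the ``n`` peptide residues
carries a discrete state (its amino-acid identity), and the score of a
sequence is the sum of per-residue one-body energies plus pairwise two-body
energies scaled by a dimensionless weight ``lambda``::

    Score(s) = sum_i E[i, s_i] + lambda * sum_{i<j} E[i, s_i, j, s_j] + p

Lower scores mean higher predicted affinity of the peptide for the plastic
surface.  ``p`` is a constant offset carried through from the annealer
formulation; it shifts every score equally and cannot change the minimizer
(this is asserted by property tests).

Energies are in kcal/mol and come either from the :mod:`pottsbind.energies`
builder (physics-based) or from the :mod:`pottsbind.synthetic` generators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_LETTERS",
    "Alphabet",
    "AlphabetError",
    "ShapeError",
    "InfeasibleAssignment",
    "EnergyTables",
    "PottsModel",
    "SolveResult",
    "potts_score",
    "assignment_from_sequence",
    "sequence_from_assignment",
    "validate_sequence",
]

#: 19 natural amino acids (one-letter, alphabetical) -- proline is excluded
#: because its constrained backbone is incompatible with the fixed-backbone
#: assumption of the score.
DEFAULT_LETTERS = "ACDEFGHIKLMNQRSTVWY"


class AlphabetError(ValueError):
    """A letter not present in the design alphabet was encountered."""


class ShapeError(ValueError):
    """A sequence/assignment does not match the model dimensions."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered, immutable set of candidate amino-acid letters."""

    letters: str = DEFAULT_LETTERS

    def __post_init__(self) -> None:
        if len(set(self.letters)) != len(self.letters):
            raise AlphabetError("alphabet letters must be unique")

    def __len__(self) -> int:
        return len(self.letters)

    def __iter__(self):
        return iter(self.letters)

    def __contains__(self, letter: str) -> bool:
        return letter in self.letters

    def index(self, letter: str) -> int:
        try:
            return self.letters.index(letter)
        except ValueError:
            raise AlphabetError(f"letter {letter!r} not in alphabet {self.letters!r}") from None

    def encode(self, seq: str) -> np.ndarray:
        """Sequence string -> integer state vector."""
        return np.array([self.index(c) for c in seq], dtype=np.intp)

    def decode(self, states: Iterable[int]) -> str:
        return "".join(self.letters[int(s)] for s in states)


def validate_sequence(seq: str, alphabet: Alphabet, n: int | None = None) -> None:
    if n is not None and len(seq) != n:
        raise ShapeError(f"sequence length {len(seq)} != expected {n}")
    for c in seq:
        if c not in alphabet:
            raise AlphabetError(f"letter {c!r} not in alphabet {alphabet.letters!r}")


@dataclass
class EnergyTables:
    """One- and two-body energies (kcal/mol) for one fixed conformation.

    ``one_body[i, a]`` is the energy of amino acid ``a`` at residue ``i``
    interacting with the plastic and with itself; ``two_body[i, j, a, b]``
    (stored for ``i < j`` only) is the side-chain/side-chain interaction.
    The symmetric accessor :meth:`pair` handles either argument order.
    """

    n: int
    alphabet: Alphabet
    one_body: np.ndarray          # (n, A)
    two_body: np.ndarray          # (n, n, A, A), populated for i<j
    conformation_id: str = "unknown"

    def __post_init__(self) -> None:
        A = len(self.alphabet)
        self.one_body = np.asarray(self.one_body, dtype=float)
        self.two_body = np.asarray(self.two_body, dtype=float)
        if self.one_body.shape != (self.n, A):
            raise ShapeError(f"one_body shape {self.one_body.shape} != {(self.n, A)}")
        if self.two_body.shape != (self.n, self.n, A, A):
            raise ShapeError(f"two_body shape {self.two_body.shape} != {(self.n, self.n, A, A)}")
        if not np.isfinite(self.one_body).all() or not np.isfinite(self.two_body).all():
            raise ValueError("energy tables contain non-finite entries")

    def pair(self, i: int, j: int, a: int, b: int) -> float:
        """Two-body energy, symmetrized over residue order."""
        if i == j:
            raise ValueError("two-body energy undefined for i == j")
        if i < j:
            return float(self.two_body[i, j, a, b])
        return float(self.two_body[j, i, b, a])

    def symmetric_two_body(self) -> np.ndarray:
        """Full (n, n, A, A) array with T[i,j,a,b] == T[j,i,b,a]; zero diagonal."""
        return self.two_body + np.transpose(self.two_body, (1, 0, 3, 2))

    # -- serialization (tidy CSV + JSON sidecar) ---------------------------

    def to_csv(self, csv_path: str | Path, sidecar: dict | None = None) -> None:
        rows = []
        letters = self.alphabet.letters
        for i in range(self.n):
            for a, la in enumerate(letters):
                rows.append((i, "", la, "", self.one_body[i, a]))
        for i in range(self.n):
            for j in range(i + 1, self.n):
                for a, la in enumerate(letters):
                    for b, lb in enumerate(letters):
                        rows.append((i, j, la, lb, self.two_body[i, j, a, b]))
        df = pd.DataFrame(rows, columns=["i", "j", "alpha", "beta", "energy"])
        df.to_csv(csv_path, index=False, float_format="%.12g")
        meta = {
            "n": self.n,
            "alphabet": letters,
            "conformation_id": self.conformation_id,
        }
        if sidecar:
            meta.update(sidecar)
        Path(str(csv_path) + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, csv_path: str | Path) -> "EnergyTables":
        meta = json.loads(Path(str(csv_path) + ".json").read_text())
        alphabet = Alphabet(meta["alphabet"])
        n, A = meta["n"], len(alphabet)
        one = np.zeros((n, A))
        two = np.zeros((n, n, A, A))
        df = pd.read_csv(csv_path, keep_default_na=False)
        for row in df.itertuples(index=False):
            i = int(row.i)
            a = alphabet.index(row.alpha)
            if row.j == "" or (isinstance(row.j, float) and np.isnan(row.j)):
                one[i, a] = row.energy
            else:
                two[i, int(row.j), a, alphabet.index(row.beta)] = row.energy
        return cls(n=n, alphabet=alphabet, one_body=one, two_body=two,
                   conformation_id=meta.get("conformation_id", "unknown"))


@dataclass
class PottsModel:
    """Energy tables plus the stability weight ``lam`` and offset ``penalty``."""

    tables: EnergyTables
    lam: float = 0.01          # relative weight of intramolecular (two-body) terms
    penalty: float = 0.0       # constant offset p, kcal/mol

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")

    @property
    def n(self) -> int:
        return self.tables.n

    @property
    def alphabet(self) -> Alphabet:
        return self.tables.alphabet


@dataclass
class SolveResult:
    """A solver's answer: sequence, its score, and provenance."""

    sequence: str
    score: float
    method: str
    seed: int | None = None
    metadata: dict = field(default_factory=dict)


def potts_score(model: PottsModel, seq: str) -> float:
    """Score of ``seq`` under ``model`` (kcal/mol; lower = better binder)."""
    t = model.tables
    validate_sequence(seq, t.alphabet, t.n)
    s = t.alphabet.encode(seq)
    return score_states(model, s)


def score_states(model: PottsModel, states: np.ndarray) -> float:
    """Score from an integer state vector (no letter validation)."""
    t = model.tables
    idx = np.arange(t.n)
    one = float(t.one_body[idx, states].sum())
    two = 0.0
    for i in range(t.n):
        js = np.arange(i + 1, t.n)
        two += float(t.two_body[i, js, states[i], states[js]].sum())
    return one + model.lam * two + model.penalty


def assignment_from_sequence(seq: str, alphabet: Alphabet) -> np.ndarray:
    """One-hot binary matrix (n x |alphabet|) realizing the sequence."""
    validate_sequence(seq, alphabet)
    bits = np.zeros((len(seq), len(alphabet)), dtype=np.int8)
    for i, c in enumerate(seq):
        bits[i, alphabet.index(c)] = 1
    return bits


@dataclass
class InfeasibleAssignment:
    """Marker returned when a binary matrix violates the one-hot constraint."""

    bad_rows: list[int]

    def __bool__(self) -> bool:  # infeasible results are falsy
        return False


def sequence_from_assignment(bits: np.ndarray, alphabet: Alphabet) -> str | InfeasibleAssignment:
    """Decode a one-hot matrix; returns :class:`InfeasibleAssignment` if any
    row does not contain exactly one 1."""
    bits = np.asarray(bits)
    if bits.ndim != 2 or bits.shape[1] != len(alphabet):
        raise ShapeError(f"expected (n, {len(alphabet)}) matrix, got {bits.shape}")
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("assignment entries must be binary")
    row_sums = bits.sum(axis=1)
    bad = [int(i) for i in np.nonzero(row_sums != 1)[0]]
    if bad:
        return InfeasibleAssignment(bad_rows=bad)
    return alphabet.decode(np.argmax(bits, axis=1))
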