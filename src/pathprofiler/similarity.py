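"""Bioactivity and structural similarity measures.

Two similarities drive MOA inference here, and they are deliberately
independent of each other:

* **Pearson's correlation coefficient (Rp)** between two compounds' activity
  profiles across the assay panel — the bioactivity similarity,

      Rp = Σ(x_i − x̄)(y_i − ȳ) / (√Σ(x_i − x̄)² · √Σ(y_i − ȳ)²),

  summed over the N panel readouts.
* **Tanimoto coefficient** |A∩B| / |A∪B| between hashed linear atom-bond-path
  bit fingerprints — the structural similarity.

The fingerprint is an open re-implementation of the classic hashed-path
(Daylight-style) scheme: all simple atom paths of 1..max_path_length atoms
are enumerated, each path is written as a canonical element/bond-order
string, and a stable hash of that string sets one bit.  Precomputed
fingerprints from any toolkit can be supplied instead wherever a
:class:`Fingerprint` is accepted.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ActivityMatrix, ValidationError


class ConstantProfileError(ValueError):
    """Pearson correlation is undefined for a constant activity profile."""


def pearson_rp(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson's correlation coefficient between two activity profiles.

    Raises :class:`ConstantProfileError` when either profile is constant
    (zero denominator) rather than returning NaN, so that a degenerate
    profile can never silently corrupt a similarity ranking.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValidationError(
            f"profiles must be 1-D and equal length, got {x.shape} and {y.shape}"
        )
    if x.size < 2:
        raise ValidationError("profiles need at least 2 readouts")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc * xc)) * np.sqrt(np.sum(yc * yc))
    if denom == 0.0:
        raise ConstantProfileError(
            "constant activity profile: correlation undefined"
        )
    return float(np.sum(xc * yc) / denom)


def pairwise_rp(query: np.ndarray, db: ActivityMatrix) -> pd.Series:
    """Rp between a query profile and every compound in the database.

    Returns a Series indexed by compound_id.  Constant database rows have no
    defined correlation; they are reported as NaN and must be excluded from
    any ranking (``rank_neighbors`` does this).  A constant *query* is an
    error.
    """
    q = np.asarray(query, dtype=float)
    if q.ndim != 1 or q.size != db.n_assays:
        raise ValidationError(
            f"query length {q.size} does not match panel width {db.n_assays}"
        )
    qc = q - q.mean()
    qn = np.sqrt(np.sum(qc * qc))
    if qn == 0.0:
        raise ConstantProfileError("constant query profile")
    X = db.values.to_numpy(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(Xc * Xc, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rp = (Xc @ qc) / (norms * qn)
    rp[norms == 0.0] = np.nan
    return pd.Series(rp, index=db.values.index, name="rp")


# ---------------------------------------------------------------------------
# Structural fingerprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fingerprint:
    """Hashed-path structural bit fingerprint.

    ``bits`` is the set of set-bit positions in ``[0, n_bits)``; ``n_bits``
    must be a power of two (2048 by default, matching common hashed-path
    folding sizes).
    """

    bits: frozenset[int]
    n_bits: int = 2048
    provenance: str = "supplied"

    def __post_init__(self) -> None:
        if self.n_bits <= 0 or (self.n_bits & (self.n_bits - 1)) != 0:
            raise ValidationError(f"n_bits must be a power of two, got {self.n_bits}")
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise ValidationError("fingerprint bit outside [0, n_bits)")
        object.__setattr__(self, "bits", frozenset(int(b) for b in self.bits))

    @property
    def n_set(self) -> int:
        return len(self.bits)


_BOND_LABEL = {1.0: "-", 2.0: "=", 3.0: "#", 1.5: ":"}


def _atom_label(atom) -> str:
    """Element symbol, lower-cased for aromatic atoms (SMILES convention)."""
    sym = atom.GetSymbol()
    return sym.lower() if atom.GetIsAromatic() else sym


def hash_path(path_string: str, n_bits: int) -> int:
    """Stable bit position for a canonical path string.

    Uses blake2b (8-byte digest) folded modulo n_bits; independent of Python's
    per-process hash randomization.
    """
    digest = hashlib.blake2b(path_string.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "big") % n_bits


def enumerate_path_strings(mol, max_path_length: int) -> set[str]:
    """Canonical label strings of all simple paths of 1..max_path_length atoms.

    A path string interleaves atom labels with bond-order symbols
    (``- = # :``); each path is represented by the lexicographically smaller
    of its two traversal directions, which makes the result independent of
    atom numbering.
    """
    n = mol.GetNumAtoms()
    labels = [_atom_label(a) for a in mol.GetAtoms()]
    adj: list[list[tuple[int, str]]] = [[] for _ in range(n)]
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        lab = _BOND_LABEL[bond.GetBondTypeAsDouble()]
        adj[i].append((j, lab))
        adj[j].append((i, lab))

    paths: set[str] = set()

    def dfs(current: int, visited: list[int], atom_seq: list[str],
            bond_seq: list[str]) -> None:
        forward = "".join(
            s for pair in zip(atom_seq, bond_seq + [""]) for s in pair
        )
        backward = "".join(
            s for pair in zip(atom_seq[::-1], bond_seq[::-1] + [""]) for s in pair
        )
        paths.add(min(forward, backward))
        if len(atom_seq) == max_path_length:
            return
        for nbr, blab in adj[current]:
            if nbr in visited:
                continue
            visited.append(nbr)
            dfs(nbr, visited, atom_seq + [labels[nbr]], bond_seq + [blab])
            visited.pop()

    for start in range(n):
        dfs(start, [start], [labels[start]], [])
    return paths


def path_fingerprint(smiles: str, max_path_length: int = 7,
                     n_bits: int = 2048) -> Fingerprint:
    """Hashed linear atom-bond-path fingerprint of a SMILES structure.

    Hydrogens are implicit (heavy-atom paths only); bond labels distinguish
    single/double/triple/aromatic; stereochemistry is ignored.
    """
    from rdkit import Chem

    if max_path_length < 1:
        raise ValidationError("max_path_length must be >= 1")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable SMILES: {smiles!r}")
    paths = enumerate_path_strings(mol, max_path_length)
    bits = frozenset(hash_path(p, n_bits) for p in paths)
    return Fingerprint(bits=bits, n_bits=n_bits, provenance="computed_from_smiles")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B|; two empty fingerprints give 0."""
    if a.n_bits != b.n_bits:
        raise ValidationError(
            f"fingerprint size mismatch: {a.n_bits} vs {b.n_bits}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union
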