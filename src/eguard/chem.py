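"""Molecule handling: parsing, canonicalization, fingerprints, scaffolds, similarity.

All downstream modules operate on :class:`Molecule` objects, which carry the
RDKit canonical SMILES as identity.  Invalid SMILES are rejected (returned as
``None``) and counted, never imputed: generative stubs are allowed to emit
junk and the pipeline simply drops it.

Fingerprint conventions: the classifier uses Morgan fingerprints of radius 3
("Morgan 3"), diversity and scaffold-similarity metrics use radius 2
("Morgan2"); both are binary, 2048 bits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.Scaffolds import MurckoScaffold
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

DEFAULT_NBITS = 2048

#: running count of rejected SMILES (diagnostic only; never consulted by logic)
_rejection_count = 0


@dataclass(frozen=True)
class Molecule:
    """A parsed compound, identified by its canonical SMILES.

    ``mw`` is the average molecular weight in Da.
    """

    smiles: str
    mw: float

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # pragma: no cover - canonical SMILES always reparse
            raise ValueError(f"canonical SMILES failed to reparse: {self.smiles!r}")
        return mol


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary Morgan fingerprint."""

    bits: np.ndarray  # uint8 0/1 vector of length nbits
    radius: int
    nbits: int = DEFAULT_NBITS

    def __post_init__(self) -> None:
        if len(self.bits) != self.nbits:
            raise ValueError(f"bit vector length {len(self.bits)} != nbits {self.nbits}")

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def rejection_count() -> int:
    """Number of SMILES rejected by :func:`parse_and_canonicalize` so far."""
    return _rejection_count


def parse_and_canonicalize(smiles: str) -> Molecule | None:
    """Parse a SMILES string into a canonical :class:`Molecule`.

    Returns ``None`` for chemically invalid input (the rejection marker);
    rejections are counted and logged at DEBUG level.  Never raises on bad
    chemistry — only on an empty/non-string argument, which is a caller bug.
    """
    global _rejection_count
    if not smiles or not isinstance(smiles, str):
        raise ValueError("smiles must be a non-empty string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        _rejection_count += 1
        logger.debug("rejected invalid SMILES: %r", smiles)
        return None
    return Molecule(smiles=Chem.MolToSmiles(mol), mw=Descriptors.MolWt(mol))


_FP_GENERATORS: dict[tuple[int, int], object] = {}


def _fp_generator(radius: int, nbits: int):
    key = (radius, nbits)
    if key not in _FP_GENERATORS:
        _FP_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=nbits
        )
    return _FP_GENERATORS[key]


def morgan_fingerprint(
    mol: Molecule, radius: int = 3, nbits: int = DEFAULT_NBITS
) -> Fingerprint:
    """Binary Morgan fingerprint of ``mol``.

    Deterministic: any SMILES form of the same molecule yields the same bits,
    because hashing operates on the molecular graph.
    """
    gen = _fp_generator(radius, nbits)
    arr = np.zeros(nbits, dtype=np.uint8)
    bv = gen.GetFingerprint(mol.to_rdkit())
    arr[list(bv.GetOnBits())] = 1
    return Fingerprint(bits=arr, radius=radius, nbits=nbits)


def fingerprint_matrix(
    mols: list[Molecule], radius: int = 3, nbits: int = DEFAULT_NBITS
) -> np.ndarray:
    """Stack fingerprints into an (n_mols, nbits) uint8 matrix."""
    out = np.zeros((len(mols), nbits), dtype=np.uint8)
    gen = _fp_generator(radius, nbits)
    for i, m in enumerate(mols):
        bv = gen.GetFingerprint(m.to_rdkit())
        out[i, list(bv.GetOnBits())] = 1
    return out


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a AND b| / |a OR b|.

    Two empty fingerprints are defined as identical (1.0) so that duplicated
    trivial molecules do not inflate diversity estimates.
    """
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint length mismatch: {a.nbits} vs {b.nbits}")
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        return 1.0
    return inter / union


def tanimoto_matrix(fps_a: np.ndarray, fps_b: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto between rows of two 0/1 matrices; 0/0 pairs -> 1."""
    a = fps_a.astype(np.float64)
    b = fps_b.astype(np.float64)
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    return sim


#: sentinel canonical SMILES for the empty (acyclic) scaffold
EMPTY_SCAFFOLD = Molecule(smiles="", mw=0.0)


def murcko_scaffold(mol: Molecule) -> Molecule:
    """Bemis–Murcko framework: ring systems plus connecting linkers.

    Acyclic molecules have no framework; the :data:`EMPTY_SCAFFOLD` marker is
    returned for them.
    """
    core = MurckoScaffold.GetScaffoldForMol(mol.to_rdkit())
    if core is None or core.GetNumAtoms() == 0:
        return EMPTY_SCAFFOLD
    return Molecule(smiles=Chem.MolToSmiles(core), mw=Descriptors.MolWt(core))
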