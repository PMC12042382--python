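"""Pluggable expert-preference scoring.

A learned medicinal-chemist preference model is an optional external
adapter; the default is a deterministic heuristic proxy built from QED
drug-likeness with penalties for flexibility and heavy halogenation.
Raw scores carry an orientation flag (whether larger means preferred) and
are min-max normalized within the current candidate pool before being
combined with predictor-side acquisition scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from rdkit.Chem import Descriptors, QED

from .chem import Molecule


@runtime_checkable
class ExpertScorerProtocol(Protocol):
    #: True if larger raw score means more preferred
    higher_is_better: bool

    def score(self, mols: list[Molecule]) -> np.ndarray: ...


class HeuristicExpertScorer:
    """Drug-likeness-oriented proxy preference.

    score = QED - 0.05 * max(0, n_rotatable_bonds - 8)
                - 0.10 * max(0, n_halogens - 3)

    Larger is preferred.  Deterministic and finite for any valid molecule.
    """

    higher_is_better = True

    ROTB_SOFT_MAX = 8
    HALOGEN_SOFT_MAX = 3

    def score(self, mols: list[Molecule]) -> np.ndarray:
        out = np.empty(len(mols))
        for i, mol in enumerate(mols):
            rd = mol.to_rdkit()
            qed = QED.qed(rd)
            rotb = Descriptors.NumRotatableBonds(rd)
            halogens = sum(
                1 for a in rd.GetAtoms() if a.GetAtomicNum() in (9, 17, 35, 53)
            )
            out[i] = (
                qed
                - 0.05 * max(0, rotb - self.ROTB_SOFT_MAX)
                - 0.10 * max(0, halogens - self.HALOGEN_SOFT_MAX)
            )
        return out


@dataclass
class CallableExpertScorer:
    """Adapter for an external preference model exposed as a callable."""

    fn: object
    higher_is_better: bool = True

    def score(self, mols: list[Molecule]) -> np.ndarray:
        return np.asarray([float(self.fn(m)) for m in mols], dtype=float)


def normalize_preferences(raw, higher_is_better: bool = True) -> np.ndarray:
    """Min-max rescale raw preference scores to A_human in [0, 1].

    Orientation is flipped if needed so 1 is always the most preferred.
    A degenerate pool (all scores equal) maps to 0.5 everywhere.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("preference scores must be finite")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.full(len(raw), 0.5)
    scaled = (raw - lo) / (hi - lo)
    return scaled if higher_is_better else 1.0 - scaled
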