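"""Centered kernel alignment with a random-forest kernel (CKA_rf).

The forest kernel between two probe molecules is the fraction of trees in
which they fall into the same leaf — an average of per-tree partition
indicator kernels, hence symmetric, unit-diagonal and positive
semidefinite.  CKA on two such kernels (biased HSIC estimator, plain
Frobenius form) quantifies how similarly two forests partition the same
probe set: 1 means identical partition geometry, 0 none.  It is used to
track how far students drift from the initial teacher across
self-distillation iterations and how consistent students are across
independent runs.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from .chem import Molecule
from .qsir import QSIRModel, leaf_assignments


def rf_kernel(leaves: np.ndarray) -> np.ndarray:
    """K[i, j] = fraction of trees where probes i and j share a leaf.

    ``leaves`` is the (n_molecules, n_trees) leaf-assignment matrix.
    """
    leaves = np.asarray(leaves)
    if leaves.ndim != 2 or leaves.shape[1] == 0:
        raise ValueError("need a (n, T) leaf matrix with at least one tree")
    n, T = leaves.shape
    K = np.zeros((n, n))
    for t in range(T):
        col = leaves[:, t]
        K += (col[:, None] == col[None, :]).astype(float)
    return K / T


def center_kernel(K: np.ndarray) -> np.ndarray:
    """Double centering HKH with H = I - (1/n) 11^T; row/col sums vanish."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("kernel must be square")
    n = K.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    return H @ K @ H


def cka(K1: np.ndarray, K2: np.ndarray) -> float:
    """Centered kernel alignment between two kernels on the same probe set.

    <K1c, K2c>_F / (||K1c||_F * ||K2c||_F), clipped to [0, 1] for PSD
    inputs.  NaN if either centered kernel is identically zero (a constant
    kernel carries no alignment information).
    """
    K1 = np.asarray(K1, dtype=float)
    K2 = np.asarray(K2, dtype=float)
    if K1.shape != K2.shape:
        raise ValueError("kernels must share shape (same probe set)")
    K1c = center_kernel(K1)
    K2c = center_kernel(K2)
    n1 = np.linalg.norm(K1c)
    n2 = np.linalg.norm(K2c)
    if n1 == 0 or n2 == 0:
        return math.nan
    val = float(np.sum(K1c * K2c) / (n1 * n2))
    return min(1.0, max(0.0, val))


def model_kernel(model: QSIRModel, probe: list[Molecule]) -> np.ndarray:
    """Forest kernel of a fitted model over a probe molecule set."""
    return rf_kernel(leaf_assignments(model, probe))


def cka_between_models(
    a: QSIRModel, b: QSIRModel, probe: list[Molecule]
) -> float:
    return cka(model_kernel(a, probe), model_kernel(b, probe))


def student_similarity_report(
    teacher: QSIRModel,
    students_per_run: list[list[QSIRModel]],
    probe: list[Molecule],
) -> dict[str, list[float]]:
    """Teacher-student and inter-student CKA_rf series across iterations.

    ``students_per_run[r][t]`` is run r's student after iteration t.  For
    each iteration the report carries the mean CKA between the initial
    teacher and each run's student, and the mean over all pairwise
    student-student combinations across runs.
    """
    if not students_per_run or not students_per_run[0]:
        raise ValueError("need at least one run with at least one student")
    n_iter = len(students_per_run[0])
    if any(len(run) != n_iter for run in students_per_run):
        raise ValueError("all runs must have the same number of iterations")
    K_teacher = model_kernel(teacher, probe)
    teacher_student: list[float] = []
    inter_student: list[float] = []
    for t in range(n_iter):
        kernels = [model_kernel(run[t], probe) for run in students_per_run]
        teacher_student.append(
            float(np.mean([cka(K_teacher, K) for K in kernels]))
        )
        if len(kernels) >= 2:
            pairs = [cka(ka, kb) for ka, kb in combinations(kernels, 2)]
            inter_student.append(float(np.mean(pairs)))
        else:
            inter_student.append(math.nan)
    return {"teacher_student": teacher_student, "inter_student": inter_student}
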