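"""Rigid-body superposition over alignment-derived equivalences.

Two layers:

* :func:`kabsch` — closed-form least-squares superposition of two matched
  Cα point sets (proper rotations only; mirror solutions are rejected by
  sign-correcting the smallest singular direction).
* :func:`multiple_superpose` — iterative consensus fitting of all
  superfamily members onto a common frame, in the style of MNYFIT: start
  from a reference member's core coordinates, repeatedly superpose every
  member onto the consensus and recompute the consensus as the
  coordinate-wise mean, until the consensus stops moving.

Equivalences come exclusively from alignment columns: the ensemble is
fitted over the *core* columns (ungapped in every member), while pairwise
statistics later use pairwise-ungapped columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateGeometryError,
    NoCoreColumnsError,
    TooFewPointsError,
)
from .structure_io import GAP, DomainStructure, MultipleAlignment


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R @ x + t`` (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3, translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) coordinate array (returns a new array)."""
        return np.asarray(coords, dtype=float) @ self.rotation.T \
            + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def _kabsch_raw(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal (R, t) minimizing sum ||R y + t - x||^2, reflection-free."""
    mx = X.mean(axis=0)
    my = Y.mean(axis=0)
    H = (Y - my).T @ (X - mx)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = mx - R @ my
    return R, t


def kabsch(X: np.ndarray, Y: np.ndarray, *,
           allow_degenerate: bool = False) -> tuple[RigidTransform, float]:
    """Least-squares superposition of Y onto X.

    Returns the proper rotation/translation minimizing
    ``sum_i ||R y_i + t - x_i||^2`` and the resulting RMSD in Å.

    Parameters
    ----------
    X, Y : (n, 3) arrays, n >= 3
        Matched coordinate sets (row i of Y corresponds to row i of X).
    allow_degenerate : bool
        When False (default), point sets of rank < 2 (all points collinear
        or coincident) raise :class:`DegenerateGeometryError`; the optimal
        rotation is then not unique.  Internal callers that only need *an*
        optimal transform (e.g. TM-score seeding on short, nearly straight
        fragments) pass True.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must be matched (n, 3) arrays")
    n = X.shape[0]
    if n < 3:
        raise TooFewPointsError(f"kabsch needs >= 3 points, got {n}")
    if not allow_degenerate:
        for P, name in ((X, "X"), (Y, "Y")):
            s = np.linalg.svd(P - P.mean(axis=0), compute_uv=False)
            if s[1] <= 1e-8 * max(1.0, s[0]):
                raise DegenerateGeometryError(
                    f"{name} has rank < 2 (collinear points)")
    R, t = _kabsch_raw(X, Y)
    diff = Y @ R.T + t - X
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return RigidTransform(R, t), rmsd


def core_columns(aln: MultipleAlignment) -> np.ndarray:
    """Columns ungapped in *every* member, in alignment order."""
    stack = np.stack([aln.rows[m] for m in aln.member_ids])
    cols = np.flatnonzero(np.all(stack != GAP, axis=0))
    if cols.size == 0:
        raise NoCoreColumnsError(
            "alignment has no common core: every column is gapped in at "
            "least one member")
    return cols


def pair_columns(aln: MultipleAlignment, a: str, b: str,
                 min_count: int = 0) -> np.ndarray:
    """Columns ungapped in both members *a* and *b* (superset of the core).

    Deviation statistics need at least 3 matched positions to superpose,
    so those callers pass ``min_count=3``; below the minimum a
    :class:`TooFewPointsError` is raised.
    """
    mask = (aln.rows[a] != GAP) & (aln.rows[b] != GAP)
    cols = np.flatnonzero(mask)
    if cols.size < min_count:
        raise TooFewPointsError(
            f"members {a!r}/{b!r} share only {cols.size} aligned positions")
    return cols


def _core_coords(struct: DomainStructure, row: np.ndarray,
                 cols: np.ndarray) -> np.ndarray:
    return struct.coords[row[cols]]


@dataclass(frozen=True)
class SuperposedEnsemble:
    """Result of iterative multiple superposition.

    ``transforms[m]`` maps member *m*'s input coordinates into the common
    consensus frame; ``consensus`` holds one mean Cα position per core
    column.  ``converged`` is False when ``max_iter`` was exhausted before
    the consensus stopped moving.
    """

    transforms: Mapping[str, RigidTransform]
    consensus: np.ndarray
    core_cols: np.ndarray
    iterations_run: int
    converged: bool

    def superposed_coords(self, struct: DomainStructure) -> np.ndarray:
        """Member's full Cα trace in the consensus frame."""
        return self.transforms[struct.member_id].apply(struct.coords)


def multiple_superpose(aln: MultipleAlignment,
                       structures: Sequence[DomainStructure],
                       tol: float = 0.01,
                       max_iter: int = 100) -> SuperposedEnsemble:
    """Fit all members into one frame by iterative consensus superposition.

    The consensus is initialized from the reference member — the member
    with the most non-gap alignment positions, ties broken by lexicographic
    member id.  Each iteration superposes every member onto the consensus
    over the core columns (Kabsch) and recomputes the consensus as the
    coordinate-wise mean of the superposed members; iteration stops when no
    consensus point moved more than *tol* Å, or after *max_iter* rounds
    (``converged=False``).  Input structures are never modified.
    """
    if len(structures) < 2:
        raise ValueError("multiple superposition needs >= 2 members")
    by_id = {s.member_id: s for s in structures}
    cols = core_columns(aln)
    if cols.size < 3:
        raise TooFewPointsError(
            f"only {cols.size} core columns; >= 3 required")

    ref = min(by_id, key=lambda m: (-aln.residue_count(m), m))
    consensus = _core_coords(by_id[ref], aln.rows[ref], cols).copy()

    transforms: dict[str, RigidTransform] = {}
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        superposed = []
        for m in aln.member_ids:
            Y = _core_coords(by_id[m], aln.rows[m], cols)
            tr, _ = kabsch(consensus, Y, allow_degenerate=True)
            transforms[m] = tr
            superposed.append(tr.apply(Y))
        new_consensus = np.mean(superposed, axis=0)
        shift = float(np.max(np.linalg.norm(new_consensus - consensus,
                                            axis=1)))
        consensus = new_consensus
        if shift < tol:
            converged = True
            break
    return SuperposedEnsemble(transforms=transforms, consensus=consensus,
                              core_cols=cols, iterations_run=iterations,
                              converged=converged)
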