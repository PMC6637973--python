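"""Symmetry expansion: asymmetric unit → complete capsid.

Most icosahedral capsids are deposited in the PDB as an asymmetric unit plus
the REMARK 350 BIOMT operators that rebuild the biological assembly.
:func:`expand` applies such a list of proper rigid motions to every atom,
producing the full shell; :func:`icosahedral_operators` supplies the 60
rotations of the icosahedral group I for structures (or synthetic fixtures)
that carry no deposited operators.

Operator source priority is explicit, never guessed: deposited BIOMT
operators are authoritative when present; the built-in group must be
requested by the caller.
"""

from __future__ import annotations

from dataclasses import replace
from functools import lru_cache

import numpy as np

from .structure_io import CapsidError, CapsidStructure, SymmetryTransform

__all__ = ["MirrorOperatorError", "expand", "icosahedral_operators"]


class MirrorOperatorError(CapsidError):
    """A transform with determinant −1 (improper rotation) was supplied."""


def expand(struct: CapsidStructure, transforms: list[SymmetryTransform]) -> CapsidStructure:
    """Apply each transform to every atom: ``x' = R x + t``.

    Output is transform-major (all atoms of operator 1, then operator 2, …)
    with each copy's operator serial recorded per atom as provenance.
    Charges (and masses) are replicated unchanged, so the expanded total
    charge is exactly T × the unit's total.

    Raises
    ------
    MirrorOperatorError
        if any transform is an improper rotation (det ≈ −1).
    CapsidError
        if the transform list is empty; pass ``[SymmetryTransform.identity()]``
        explicitly for a no-op expansion.
    """
    if not transforms:
        raise CapsidError(
            "empty transform list; pass [SymmetryTransform.identity()] for a "
            "no-op expansion"
        )
    for t in transforms:
        det = np.linalg.det(t.rotation)
        if det < 0:
            raise MirrorOperatorError(
                f"transform serial {t.serial} has det {det:.6f}: mirror "
                "operators are not physical capsid symmetries"
            )
        if not t.is_proper():
            raise CapsidError(
                f"transform serial {t.serial} is not orthogonal within 1e-6"
            )

    n = len(struct)
    blocks = [struct.positions @ t.rotation.T + t.translation for t in transforms]
    T = len(transforms)
    out = replace(struct)
    out.positions = np.vstack(blocks)
    out.names = list(struct.names) * T
    out.residue_names = list(struct.residue_names) * T
    out.chain_ids = list(struct.chain_ids) * T
    out.residue_seqs = np.tile(struct.residue_seqs, T)
    out.charges = np.tile(struct.charges, T)
    out.masses = None if struct.masses is None else np.tile(struct.masses, T)
    out.transform_serials = np.repeat([t.serial for t in transforms], n)
    out.transforms = []
    out.source_ids = dict(struct.source_ids, expanded_by=T)
    return out


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


@lru_cache(maxsize=1)
def _icosahedral_matrices() -> tuple:
    """The 60 proper rotations of I, generated by closure.

    Orientation: icosahedron vertices at cyclic permutations of (0, ±1, ±φ),
    which puts 2-fold axes along the coordinate axes.  Generators are the
    5-fold rotation about the vertex axis (0, 1, φ) and the 2-fold rotation
    about z; closure under multiplication yields exactly 60 matrices.
    """
    phi = (1 + np.sqrt(5)) / 2
    g5 = _rotation(np.array([0.0, 1.0, phi]), 2 * np.pi / 5)
    g2 = np.diag([-1.0, -1.0, 1.0])

    def key(M):
        return tuple(np.round(M, 9).ravel())

    group = {key(np.eye(3)): np.eye(3)}
    frontier = [np.eye(3)]
    while frontier:
        nxt = []
        for M in frontier:
            for g in (g5, g2):
                P = g @ M
                k = key(P)
                if k not in group:
                    group[k] = P
                    nxt.append(P)
        frontier = nxt
    assert len(group) == 60, f"closure produced {len(group)} elements"
    # canonical deterministic order: identity first, then lexicographic
    mats = sorted(group.values(), key=key)
    mats.sort(key=lambda M: (not np.allclose(M, np.eye(3)), key(M)))
    return tuple(mats)


def icosahedral_operators() -> list[SymmetryTransform]:
    """Return the 60 proper rotations of the icosahedral group I.

    All operators have zero translation and determinant +1; the set contains
    the identity (serial 1) and is closed under composition.
    """
    return [
        SymmetryTransform(M.copy(), np.zeros(3), serial=i + 1)
        for i, M in enumerate(_icosahedral_matrices())
    ]
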