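"""Synthetic capsid-like structures with known geometry and charges.

Every physics operation in this package is testable without downloading a
real structure: these generators place atoms on spherical shells (or in an
icosahedral fundamental-domain wedge) with exactly known radii and charges,
and write the result as a valid PDB + PSF pair that the package's own
readers parse back bit-for-bit.

Placement uses a Fibonacci sphere — deterministic and near-uniform — rather
than random sampling, so shell radii and charge assignments are reproducible
by construction; optional radial jitter (seeded) adds controlled realism.
Fixtures model geometry and charge only, not protein chemistry: PSFs carry
an empty bonds section.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from .structure_io import CapsidStructure, SymmetryTransform, write_pdb
from .symmetry import expand, icosahedral_operators

__all__ = ["FixtureSpec", "make_shell_fixture", "make_asymmetric_unit", "write_fixture"]

_GOLDEN = (1 + math.sqrt(5)) / 2


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic shell structure.

    charge_scheme: ``uniform`` (all +1 e), ``alternating`` (+1/−1 e by
    index) or ``random`` (uniform in [−1, 1] e from ``seed``).  If
    ``net_charge`` is given, charges are shifted uniformly to hit it
    exactly.  ``jitter`` is the std-dev (Å) of seeded radial noise.
    """

    n_atoms: int
    shell_radii: tuple = (100.0,)
    charge_scheme: str = "random"
    seed: int = 0
    net_charge: float | None = None
    jitter: float = 0.0

    def __post_init__(self):
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be ≥ 1")
        if any(r <= 0 for r in self.shell_radii):
            raise ValueError("shell radii must be positive")
        if self.jitter < 0:
            raise ValueError("jitter must be ≥ 0")
        if self.charge_scheme not in ("uniform", "alternating", "random"):
            raise ValueError(f"unknown charge scheme {self.charge_scheme!r}")


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the sphere (golden-angle lattice)."""
    i = np.arange(n, dtype=float)
    z = 1 - (2 * i + 1) / n
    theta = 2 * math.pi * i / _GOLDEN
    rho = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _charges_for(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_atoms
    if spec.charge_scheme == "uniform":
        q = np.ones(n)
    elif spec.charge_scheme == "alternating":
        q = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    else:
        # draw on the PSF charge grid (6 decimals) so written fixtures
        # round-trip their charges exactly
        q = rng.integers(-1_000_000, 1_000_001, size=n) / 1e6
    if spec.net_charge is not None:
        q = q + (spec.net_charge - q.sum()) / n
    return q


def make_shell_fixture(spec: FixtureSpec) -> CapsidStructure:
    """Place atoms on the spec's shells with the spec's charge scheme.

    Atoms are split as evenly as possible across shells (shell k takes atom
    indices ≡ k mod n_shells), each shell filled by its own Fibonacci
    lattice so |r_i| equals the shell radius exactly when jitter is 0.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_atoms
    radii = np.asarray(spec.shell_radii, dtype=float)
    shell_of = np.arange(n) % len(radii)
    positions = np.empty((n, 3))
    for k, r in enumerate(radii):
        idx = np.flatnonzero(shell_of == k)
        positions[idx] = r * fibonacci_sphere(len(idx))
    if spec.jitter > 0:
        scale = 1.0 + rng.normal(0.0, spec.jitter, size=n) / np.linalg.norm(
            positions, axis=1
        )
        positions = positions * scale[:, None]
    charges = _charges_for(spec, rng)
    return CapsidStructure(
        positions=positions,
        names=["CA"] * n,
        residue_names=["GLY"] * n,
        chain_ids=["A"] * n,
        residue_seqs=np.arange(1, n + 1),
        charges=charges,
        masses=np.full(n, 12.011),
        source_ids={"fixture": f"shells={tuple(radii)} seed={spec.seed}"},
    )


def make_asymmetric_unit(
    n_atoms: int, seed: int, radius: float = 100.0
) -> tuple[CapsidStructure, list[SymmetryTransform]]:
    """An asymmetric unit in a fundamental-domain wedge, plus the 60 operators.

    Atoms are scattered (seeded) in a narrow cone about a generic direction —
    one avoiding all symmetry axes — at radii near ``radius``, so the
    60-fold expansion produces non-overlapping copies whose centroid sits at
    the origin by group averaging.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be ≥ 1")
    rng = np.random.default_rng(seed)
    # generic direction well inside a fundamental wedge of I
    axis = np.array([0.23, 0.41, 0.88])
    axis /= np.linalg.norm(axis)
    u = np.cross(axis, [0.0, 0.0, 1.0])
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    # cone half-angle ~5°: well within the ~37° wedge aperture
    ang = rng.uniform(0.0, math.radians(5.0), size=n_atoms)
    azi = rng.uniform(0.0, 2 * math.pi, size=n_atoms)
    dirs = (
        np.cos(ang)[:, None] * axis
        + (np.sin(ang) * np.cos(azi))[:, None] * u
        + (np.sin(ang) * np.sin(azi))[:, None] * v
    )
    r = rng.uniform(0.95 * radius, 1.05 * radius, size=n_atoms)
    positions = dirs * r[:, None]
    charges = rng.uniform(-1.0, 1.0, size=n_atoms)
    unit = CapsidStructure(
        positions=positions,
        names=["CA"] * n_atoms,
        residue_names=["GLY"] * n_atoms,
        chain_ids=["A"] * n_atoms,
        residue_seqs=np.arange(1, n_atoms + 1),
        charges=charges,
        masses=np.full(n_atoms, 12.011),
        source_ids={"fixture": f"asymmetric-unit seed={seed}"},
    )
    return unit, icosahedral_operators()


# ---------------------------------------------------------------------------
# PSF writing (fixture-grade: atoms + empty bonds section)

_PSF_ATOM_FORMATS = {
    # serial seg resid resname name type charge mass imove
    "xplor": "{serial:8d} {seg:<4s} {resid:<4s} {resname:<4s} {name:<4s} {type:<4s} {charge:10.6f} {mass:13.4f} {imove:11d}\n",
    "charmm": "{serial:8d} {seg:<4s} {resid:<4s} {resname:<4s} {name:<4s} {type:<4s} {charge:10.6f} {mass:13.4f} {imove:11d}\n",
    "ext": "{serial:10d} {seg:<8s} {resid:<8s} {resname:<8s} {name:<8s} {type:<6s} {charge:12.6f} {mass:14.4f} {imove:12d}\n",
}


def write_psf(struct: CapsidStructure, path, dialect: str = "xplor") -> None:
    """Write a minimal PSF carrying the structure's atoms and charges.

    ``dialect`` selects X-PLOR (alphabetic atom types), CHARMM (numeric
    types) or EXT (wide fields); all carry identical logical content.
    """
    if dialect not in _PSF_ATOM_FORMATS:
        raise ValueError(f"unknown PSF dialect {dialect!r}")
    if not struct.has_charges:
        raise ValueError("cannot write a PSF for a structure with unset charges")
    fmt = _PSF_ATOM_FORMATS[dialect]
    masses = (
        struct.masses if struct.masses is not None else np.full(len(struct), 12.011)
    )
    tmp = f"{path}.tmp{os.getpid()}"
    try:
        with open(tmp, "w") as fh:
            fh.write("PSF EXT\n" if dialect == "ext" else "PSF\n")
            fh.write("\n")
            fh.write(f"{1:8d} !NTITLE\n")
            fh.write(" REMARKS synthetic fixture written by capsidcharge\n")
            fh.write("\n")
            fh.write(f"{len(struct):8d} !NATOM\n")
            for i in range(len(struct)):
                atype = "22" if dialect == "charmm" else struct.names[i][:4]
                fh.write(
                    fmt.format(
                        serial=i + 1,
                        seg=struct.chain_ids[i][:8] or "A",
                        resid=str(int(struct.residue_seqs[i])),
                        resname=struct.residue_names[i][:8],
                        name=struct.names[i][:8],
                        type=atype,
                        charge=struct.charges[i],
                        mass=masses[i],
                        imove=0,
                    )
                )
            fh.write("\n")
            fh.write(f"{0:8d} !NBOND: bonds\n")
            fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_fixture(
    struct: CapsidStructure, basename, dialect: str = "xplor"
) -> tuple[str, str]:
    """Write a matched PDB + PSF pair; returns the two paths.

    Ordering is consistent by construction, so ``read_pdb`` + ``read_psf`` +
    ``pair_structure`` on the outputs reproduces the structure (positions to
    the 1e-3 Å PDB precision, charges to the PSF's 6 decimals).
    """
    pdb_path = f"{basename}.pdb"
    psf_path = f"{basename}.psf"
    write_pdb(struct, pdb_path)
    write_psf(struct, psf_path, dialect=dialect)
    return pdb_path, psf_path
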