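"""Reading and writing capsid structures: PDB coordinates, PSF charges.

A capsid structure is assembled from two files: a PDB carrying atomic
coordinates (and, optionally, REMARK 350 BIOMT symmetry operators for the
biological assembly) and a PSF carrying per-atom partial charges in
elementary charge units.  Pairing is strictly positional: atom ``k`` of the
filtered PDB receives the charge of PSF entry ``k``, and any count mismatch
is a hard error — silent repair would corrupt charge totals.

Conventions
-----------
* Lengths in Å, charges in e; coordinates are kept in the deposited frame
  (right-handed, no re-orientation on read).
* Alternate locations: only altloc ``' '`` or ``'A'`` is kept, so each site
  contributes exactly one atom.
* HETATM records (waters, ligands) are excluded by default; capsids are
  protein shells.  Pass ``include_hetatm=True`` to keep them.
* Hydrogens are never stripped: PSF charge sets are only balanced with
  hydrogens present.
* On write, atom serials are renumbered 1..N; serials above 99999 use the
  hybrid-36 widened encoding so full capsids (>100k atoms) remain writable.
"""

from __future__ import annotations

import math
import re
import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Atom",
    "CapsidStructure",
    "SymmetryTransform",
    "PsfAtom",
    "CapsidError",
    "ParseError",
    "SymmetryParseError",
    "PairingError",
    "FormatOverflowError",
    "read_pdb",
    "read_psf",
    "pair_structure",
    "write_pdb",
    "write_fasta",
]


class CapsidError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(CapsidError):
    """A file could not be parsed; the message names the offending line/row."""


class SymmetryParseError(ParseError):
    """REMARK 350 BIOMT rows do not form complete 1,2,3 triples."""


class PairingError(CapsidError):
    """PDB atom count and PSF entry count disagree."""


class FormatOverflowError(CapsidError):
    """A value cannot be represented in its fixed-width PDB column."""


@dataclass(frozen=True)
class SymmetryTransform:
    """A proper rigid motion ``x' = R x + t`` (BIOMT convention, t in Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    serial: int = 0

    ORTHO_TOL = 1e-6

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def is_proper(self, tol: float = ORTHO_TOL) -> bool:
        R = self.rotation
        return (
            np.max(np.abs(R.T @ R - np.eye(3))) <= tol
            and abs(np.linalg.det(R) - 1.0) <= tol
        )

    @classmethod
    def identity(cls, serial: int = 1) -> "SymmetryTransform":
        return cls(np.eye(3), np.zeros(3), serial)


@dataclass(frozen=True)
class Atom:
    """One point particle: position in Å, partial charge in e.

    ``charge`` is ``nan`` until the structure is paired with a PSF.
    """

    index: int
    name: str
    residue_name: str
    chain_or_segment: str
    position: np.ndarray
    charge: float = math.nan
    vdw_hint: float | None = None


@dataclass
class CapsidStructure:
    """An ordered atom collection stored as parallel arrays.

    Arrays are column-wise for efficiency on full capsids (10^5–10^6 atoms);
    the :meth:`atoms` accessor materialises :class:`Atom` records on demand.
    Charges use ``nan`` as the "unset" sentinel until PSF pairing.
    """

    positions: np.ndarray                     # (N, 3) float, Å
    names: list[str]
    residue_names: list[str]
    chain_ids: list[str]
    residue_seqs: np.ndarray                  # (N,) int
    charges: np.ndarray                       # (N,) float, e; nan = unset
    masses: np.ndarray | None = None          # (N,) float, amu, if from PSF
    transform_serials: np.ndarray | None = None  # provenance of symmetry copy
    transforms: list[SymmetryTransform] = field(default_factory=list)
    source_ids: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.charges = np.asarray(self.charges, dtype=float)
        self.residue_seqs = np.asarray(self.residue_seqs, dtype=int)
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be an (N, 3) array")
        for name, seq in (("names", self.names), ("residue_names", self.residue_names),
                          ("chain_ids", self.chain_ids)):
            if len(seq) != n:
                raise ValueError(f"{name} length {len(seq)} != atom count {n}")
        if len(self.charges) != n or len(self.residue_seqs) != n:
            raise ValueError("charges/residue_seqs length != atom count")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("atom positions must be finite")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def has_charges(self) -> bool:
        return len(self) > 0 and not np.any(np.isnan(self.charges))

    @property
    def total_charge(self) -> float:
        if not self.has_charges:
            raise CapsidError("structure has unset charges; pair with a PSF first")
        return float(np.sum(self.charges))

    def atoms(self):
        """Yield :class:`Atom` views in file order (1-based indices)."""
        for i in range(len(self)):
            yield Atom(
                index=i + 1,
                name=self.names[i],
                residue_name=self.residue_names[i],
                chain_or_segment=self.chain_ids[i],
                position=self.positions[i].copy(),
                charge=float(self.charges[i]),
            )

    def with_positions(self, positions: np.ndarray) -> "CapsidStructure":
        out = replace(self)
        out.positions = np.asarray(positions, dtype=float)
        return out


@dataclass(frozen=True)
class PsfAtom:
    """One !NATOM entry: label, segment, residue info, charge (e), mass (amu)."""

    name: str
    segment: str
    residue_name: str
    residue_id: str
    charge: float
    mass: float


# ---------------------------------------------------------------------------
# PDB reading

_COORD_SLICES = {"x": slice(30, 38), "y": slice(38, 46), "z": slice(46, 54)}


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"line {lineno}: malformed {what} field {text.strip()!r}"
        ) from None


def read_pdb(path, include_hetatm: bool = False) -> CapsidStructure:
    """Read ATOM (and optionally HETATM) records and BIOMT operators.

    Coordinates come from the fixed PDB columns (x 31–38, y 39–46, z 47–54,
    in Å).  Altloc ``' '``/``'A'`` atoms are kept, others dropped.  Charges
    are initialised to the unset sentinel.  REMARK 350 BIOMT rows, if
    present, become :class:`SymmetryTransform` objects; incomplete 1,2,3
    triples raise :class:`SymmetryParseError`.
    """
    positions, names, resnames, chains, resseqs = [], [], [], [], []
    biomt_rows: dict[int, dict[int, tuple]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "ATOM  " or (include_hetatm and rec == "HETATM"):
                altloc = line[16] if len(line) > 16 else " "
                if altloc not in (" ", "A"):
                    continue
                xyz = [
                    _parse_float(line[sl], ax, lineno)
                    for ax, sl in _COORD_SLICES.items()
                ]
                positions.append(xyz)
                names.append(line[12:16].strip())
                resnames.append(line[17:21].strip())
                chains.append(line[21].strip() or "A")
                try:
                    resseqs.append(int(line[22:26]))
                except ValueError:
                    resseqs.append(len(resseqs) + 1)
            elif rec == "REMARK" and line[7:10] == "350" and "BIOMT" in line:
                m = re.match(
                    r"REMARK 350\s+BIOMT([123])\s+(\S+)\s+(\S+)\s+(\S+)\s+(\S+)\s+(\S+)",
                    line,
                )
                if not m:
                    raise SymmetryParseError(f"line {lineno}: malformed BIOMT row")
                row = int(m.group(1))
                try:
                    serial = int(m.group(2))
                    vals = tuple(float(v) for v in m.groups()[2:])
                except ValueError:
                    raise SymmetryParseError(
                        f"line {lineno}: non-numeric BIOMT field"
                    ) from None
                biomt_rows.setdefault(serial, {})[row] = vals

    if not positions:
        raise ParseError(f"{path}: no ATOM records found")

    transforms = []
    for serial in sorted(biomt_rows):
        rows = biomt_rows[serial]
        if set(rows) != {1, 2, 3}:
            raise SymmetryParseError(
                f"BIOMT serial {serial}: rows {sorted(rows)} do not form a 1,2,3 triple"
            )
        R = np.array([rows[r][:3] for r in (1, 2, 3)])
        t = np.array([rows[r][3] for r in (1, 2, 3)])
        transforms.append(SymmetryTransform(R, t, serial))

    n = len(positions)
    return CapsidStructure(
        positions=np.array(positions),
        names=names,
        residue_names=resnames,
        chain_ids=chains,
        residue_seqs=np.array(resseqs),
        charges=np.full(n, np.nan),
        transforms=transforms,
        source_ids={"pdb": str(path)},
    )


# ---------------------------------------------------------------------------
# PSF reading

def read_psf(path) -> list[PsfAtom]:
    """Read the !NATOM section of a PSF file.

    Accepts X-PLOR (alphabetic type field), CHARMM (numeric type field) and
    EXT wide-format dialects; atom lines are tokenised by whitespace, which
    all three dialects permit.  Returns exactly NATOM entries in file order.
    """
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("PSF"):
            raise ParseError(f"{path}: missing PSF signature line")
        natom = None
        for line in fh:
            if "!NATOM" in line:
                try:
                    natom = int(line.split("!")[0].strip())
                except ValueError:
                    raise ParseError(f"{path}: unreadable NATOM header") from None
                break
        if natom is None:
            raise ParseError(f"{path}: no !NATOM section")

        entries: list[PsfAtom] = []
        for line in fh:
            if not line.strip():
                break
            fields = line.split()
            if len(fields) < 8:
                raise ParseError(
                    f"atom row {len(entries) + 1}: expected ≥8 fields, got {len(fields)}"
                )
            try:
                charge = float(fields[6])
                mass = float(fields[7])
            except ValueError:
                raise ParseError(
                    f"atom row {len(entries) + 1}: non-numeric charge/mass field"
                ) from None
            entries.append(
                PsfAtom(
                    name=fields[4],
                    segment=fields[1],
                    residue_name=fields[3],
                    residue_id=fields[2],
                    charge=charge,
                    mass=mass,
                )
            )
            if len(entries) == natom:
                break

    if len(entries) != natom:
        raise ParseError(
            f"{path}: NATOM header declares {natom} atoms but section has "
            f"{len(entries)} rows (truncated file?)"
        )
    return entries


def pair_structure(pdb_struct: CapsidStructure, psf_entries: list[PsfAtom]) -> CapsidStructure:
    """Assign PSF charges to PDB atoms by file position.

    Pairing is positional and total: atom ``k`` gets entry ``k``'s charge and
    mass, with no re-ordering and no drops.  A count mismatch raises
    :class:`PairingError` naming both counts.
    """
    n_pdb, n_psf = len(pdb_struct), len(psf_entries)
    if n_pdb != n_psf:
        raise PairingError(
            f"cannot pair: PDB has {n_pdb} atoms vs PSF {n_psf} entries"
        )
    out = replace(pdb_struct)
    out.charges = np.array([e.charge for e in psf_entries])
    out.masses = np.array([e.mass for e in psf_entries])
    out.source_ids = dict(pdb_struct.source_ids)
    return out


# ---------------------------------------------------------------------------
# PDB writing

_H36_DIGITS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def hybrid36_encode(value: int, width: int) -> str:
    """Encode an integer in the hybrid-36 counting used for wide PDB fields.

    Values that fit the decimal field are written as decimal; larger values
    continue in base 36, first with upper-case then lower-case alphabets, as
    the cctbx convention defines.
    """
    if value < 0:
        raise FormatOverflowError(f"negative value {value} in width-{width} field")
    if value < 10 ** width:
        return str(value).rjust(width)
    # upper-case block starts at A000..; encodes 10^width .. 10^width + 26*36^(width-1) - 1
    upper_span = 26 * 36 ** (width - 1)
    rest = value - 10 ** width
    if rest < upper_span:
        return _to_base36(rest + 10 * 36 ** (width - 1), width)
    rest -= upper_span
    if rest < upper_span:
        return _to_base36(rest + 10 * 36 ** (width - 1), width).lower()
    raise FormatOverflowError(f"value {value} exceeds hybrid-36 width {width}")


def _to_base36(value: int, width: int) -> str:
    out = []
    for _ in range(width):
        value, rem = divmod(value, 36)
        out.append(_H36_DIGITS[rem])
    return "".join(reversed(out))


def write_pdb(struct: CapsidStructure, path) -> None:
    """Write fixed-column ATOM records, renumbering serials 1..N.

    Coordinates of magnitude ≥ 10000 Å cannot fit the 8.3 field and raise
    :class:`FormatOverflowError`.  Output is written atomically (temp file +
    rename) so a failed write never leaves a partial PDB behind.
    """
    if np.any(np.abs(struct.positions) >= 10000.0):
        bad = int(np.argmax(np.max(np.abs(struct.positions), axis=1)))
        raise FormatOverflowError(
            f"atom {bad + 1}: coordinate magnitude ≥ 10000 Å does not fit the "
            "8.3 PDB column"
        )
    tmp = f"{path}.tmp{os.getpid()}"
    try:
        with open(tmp, "w") as fh:
            for t in struct.transforms:
                for row in (1, 2, 3):
                    r = t.rotation[row - 1]
                    fh.write(
                        f"REMARK 350   BIOMT{row} {t.serial:3d}"
                        f"{r[0]:10.6f}{r[1]:10.6f}{r[2]:10.6f}"
                        f"     {t.translation[row - 1]:10.5f}\n"
                    )
            for i in range(len(struct)):
                serial = hybrid36_encode(i + 1, 5)
                name = struct.names[i][:4]
                # short names are conventionally offset one column right
                name_field = f" {name:<3s}" if len(name) < 4 else name
                resseq = hybrid36_encode(int(struct.residue_seqs[i]), 4)
                x, y, z = struct.positions[i]
                element = next((c for c in name if c.isalpha()), "X")
                fh.write(
                    f"ATOM  {serial} {name_field} {struct.residue_names[i]:<4s}"
                    f"{struct.chain_ids[i][:1]}{resseq}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {element:>2s}\n"
                )
            fh.write("END\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_fasta(struct: CapsidStructure, path) -> None:
    """Export one FASTA record per chain, residues in author order."""
    from Bio.SeqUtils import seq1

    chains: dict[str, list[str]] = {}
    seen: set[tuple[str, int]] = set()
    for i in range(len(struct)):
        key = (struct.chain_ids[i], int(struct.residue_seqs[i]))
        if key in seen:
            continue
        seen.add(key)
        chains.setdefault(struct.chain_ids[i], []).append(struct.residue_names[i])
    with open(path, "w") as fh:
        for chain, resnames in chains.items():
            seq = "".join(seq1(rn, undef_code="X") or "X" for rn in resnames)
            fh.write(f">chain_{chain}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")
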