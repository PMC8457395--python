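"""Structure and shift-table I/O.

Canonical in-memory model for molecules, conformers and chemical-shift
records, plus readers/writers for the standard interchange formats:
SDF/MOL (V2000) with 3D coordinates, SMILES lists, simple XYZ, and CSV
shift tables.

Conventions enforced at the boundary and never converted implicitly:
atom indices are 0-based and contiguous; coordinates are in angstroms;
shifts in ppm; conformer energies in kcal/mol.  Hydrogens are always made
explicit on read because the models predict per-proton shifts.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors

SUPPORTED_ELEMENTS = ("H", "C", "N", "O", "F", "P", "S", "Cl")
NUCLEI = ("H1", "C13")
#: element probed by each nucleus
NUCLEUS_ELEMENT = {"H1": "H", "C13": "C"}
PROVENANCES = ("computed", "experimental", "predicted")

SHIFT_TABLE_HEADER = ["molecule_id", "atom_index", "nucleus", "shift_ppm", "provenance"]


class RecordError(ValueError):
    """A single record in a multi-record file could not be parsed."""


@dataclass
class Molecule:
    """Topology and identity of one molecule (no coordinates)."""

    id: str
    elements: list[str]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    formal_charges: list[int] | None = None
    #: one flag per stereocenter: True if its configuration is specified
    stereo_defined: list[bool] = field(default_factory=list)
    mol_weight: float = 0.0

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def total_charge(self) -> int:
        return int(sum(self.formal_charges)) if self.formal_charges else 0

    def validate(self) -> None:
        if self.formal_charges is not None and len(self.formal_charges) != self.n_atoms:
            raise ValueError(f"{self.id}: charge list length mismatch")
        unsupported = sorted({e for e in self.elements if e not in SUPPORTED_ELEMENTS})
        if unsupported:
            warnings.warn(
                f"molecule {self.id} contains elements outside the supported set: "
                f"{unsupported}",
                stacklevel=2,
            )


@dataclass
class Conformer:
    """One 3D geometry of a molecule; coordinates in angstroms."""

    molecule_id: str
    coords: np.ndarray  # (N, 3), float64
    rel_energy: float | None = None  # kcal/mol above the ensemble minimum
    source: str = "user"  # mmff | dft | user

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"{self.molecule_id}: coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.molecule_id}: non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def validate(self, mol: Molecule) -> None:
        if self.n_atoms != mol.n_atoms:
            raise ValueError(
                f"{self.molecule_id}: conformer has {self.n_atoms} atoms, "
                f"molecule has {mol.n_atoms}"
            )
        d = np.linalg.norm(self.coords[:, None] - self.coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-6:
            raise ValueError(f"{self.molecule_id}: two atoms at identical coordinates")


@dataclass(frozen=True)
class ShiftRecord:
    """One per-atom chemical shift, δ in ppm."""

    molecule_id: str
    atom_index: int
    nucleus: str  # H1 | C13
    shift: float
    provenance: str  # computed | experimental | predicted

    def __post_init__(self):
        if self.nucleus not in NUCLEI:
            raise ValueError(f"unknown nucleus {self.nucleus!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if not np.isfinite(self.shift):
            raise ValueError("shift must be finite")

    @property
    def key(self) -> tuple:
        return (self.molecule_id, self.atom_index, self.nucleus, self.provenance)


# ---------------------------------------------------------------------------
# rdkit interop


def from_rdkit(rdmol: Chem.Mol, mol_id: str) -> tuple[Molecule, list[Conformer]]:
    """Convert an rdkit Mol (hydrogens explicit) to the internal model."""
    elements = [a.GetSymbol() for a in rdmol.GetAtoms()]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), float(b.GetBondTypeAsDouble()))
        for b in rdmol.GetBonds()
    ]
    charges = [a.GetFormalCharge() for a in rdmol.GetAtoms()]
    centers = Chem.FindMolChiralCenters(
        rdmol, includeUnassigned=True, useLegacyImplementation=False
    )
    stereo = [label != "?" for _idx, label in centers]
    mol = Molecule(
        id=mol_id,
        elements=elements,
        bonds=bonds,
        formal_charges=charges,
        stereo_defined=stereo,
        mol_weight=float(Descriptors.MolWt(rdmol)),
    )
    mol.validate()
    confs = [
        Conformer(mol_id, np.array(c.GetPositions(), dtype=np.float64))
        for c in rdmol.GetConformers()
    ]
    return mol, confs


def to_rdkit(mol: Molecule, conf: Conformer | None = None) -> Chem.Mol:
    """Rebuild an editable rdkit Mol from topology (and optional geometry)."""
    rw = Chem.RWMol()
    for i, sym in enumerate(mol.elements):
        atom = Chem.Atom(sym)
        if mol.formal_charges is not None:
            atom.SetFormalCharge(int(mol.formal_charges[i]))
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    order_map = {
        1.0: Chem.BondType.SINGLE,
        1.5: Chem.BondType.AROMATIC,
        2.0: Chem.BondType.DOUBLE,
        3.0: Chem.BondType.TRIPLE,
    }
    for i, j, order in mol.bonds:
        rw.AddBond(int(i), int(j), order_map.get(float(order), Chem.BondType.SINGLE))
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    if conf is not None:
        conf.validate(mol)
        rdconf = Chem.Conformer(mol.n_atoms)
        for i, xyz in enumerate(conf.coords):
            rdconf.SetAtomPosition(i, tuple(float(v) for v in xyz))
        out.AddConformer(rdconf, assignId=True)
    return out


# ---------------------------------------------------------------------------
# structure readers


def read_structures(
    path: str | Path, fmt: str
) -> list[tuple[Molecule, list[Conformer]]]:
    """Read molecules (and any 3D conformers) from ``path``.

    Parameters
    ----------
    path : str or Path
    fmt : {"sdf", "smiles", "xyz"}
        ``sdf`` entries carry coordinates; ``smiles`` entries carry none
        (conformer generation is the ensemble module's job); ``xyz`` carries
        coordinates but no bonds.

    Unparseable records are skipped with a warning naming the record; the
    rest of the file is still read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "sdf":
        return _read_sdf(path)
    if fmt == "smiles":
        return _read_smiles(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown format {fmt!r}")


def _read_sdf(path: Path) -> list[tuple[Molecule, list[Conformer]]]:
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    out = []
    for i, rdmol in enumerate(supplier):
        if rdmol is None:
            warnings.warn(f"{path}: SDF record {i} unparseable, skipped", stacklevel=2)
            continue
        rdmol = Chem.AddHs(rdmol, addCoords=True)
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
        mol_id = name.strip() or f"{path.stem}_{i}"
        out.append(from_rdkit(rdmol, mol_id))
    return out


def _read_smiles(path: Path) -> list[tuple[Molecule, list[Conformer]]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"{path.stem}_{lineno}"
            rdmol = Chem.MolFromSmiles(smiles)
            if rdmol is None:
                warnings.warn(
                    f"{path}:{lineno}: unparseable SMILES {smiles!r}, skipped",
                    stacklevel=2,
                )
                continue
            rdmol = Chem.AddHs(rdmol)
            out.append(from_rdkit(rdmol, mol_id))
    return out


def _read_xyz(path: Path) -> list[tuple[Molecule, list[Conformer]]]:
    out = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    block = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
            comment = lines[pos + 1].strip() if pos + 1 < len(lines) else ""
            rows = lines[pos + 2 : pos + 2 + n]
            if len(rows) < n:
                raise RecordError("truncated XYZ block")
            elements, coords = [], []
            for row in rows:
                tok = row.split()
                elements.append(tok[0])
                coords.append([float(v) for v in tok[1:4]])
        except (ValueError, IndexError, RecordError) as exc:
            warnings.warn(f"{path}: XYZ block at line {pos + 1}: {exc}", stacklevel=2)
            pos += 1
            continue
        mol_id = comment.split()[0] if comment else f"{path.stem}_{block}"
        mol = Molecule(id=mol_id, elements=elements)
        mol.validate()
        out.append((mol, [Conformer(mol_id, np.array(coords))]))
        pos += 2 + n
        block += 1
    return out


# ---------------------------------------------------------------------------
# shift tables


def parse_shift_table(path: str | Path) -> list[ShiftRecord]:
    """Read a CSV shift table with the canonical five-column header."""
    path = Path(path)
    records: list[ShiftRecord] = []
    seen: dict[tuple, int] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected header") from None
        if [h.strip() for h in header] != SHIFT_TABLE_HEADER:
            raise ValueError(
                f"{path}: bad header {header!r}, expected {SHIFT_TABLE_HEADER}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 5:
                raise RecordError(f"{path}:{lineno}: expected 5 columns, got {len(row)}")
            mol_id, idx_s, nucleus, shift_s, prov = (c.strip() for c in row)
            try:
                idx = int(idx_s)
                shift = float(shift_s)
            except ValueError as exc:
                raise RecordError(f"{path}:{lineno}: {exc}") from None
            try:
                rec = ShiftRecord(mol_id, idx, nucleus, shift, prov)
            except ValueError as exc:
                raise RecordError(f"{path}:{lineno}: {exc}") from None
            if rec.key in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate record for key {rec.key} "
                    f"(first seen at line {seen[rec.key]})"
                )
            seen[rec.key] = lineno
            records.append(rec)
    return records


def write_shift_table(records: list[ShiftRecord], path: str | Path) -> None:
    """Write any shift records as CSV (round-trips through the parser)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SHIFT_TABLE_HEADER)
        for r in records:
            writer.writerow(
                [r.molecule_id, r.atom_index, r.nucleus, f"{r.shift:.6f}", r.provenance]
            )


def write_predictions(
    records: list[ShiftRecord],
    path: str | Path,
    fmt: str = "csv",
    structures: list[tuple[Molecule, Conformer]] | None = None,
) -> None:
    """Write predicted shifts as CSV or as SDF property blocks.

    All records must carry provenance ``predicted``.  For ``sdf_annotated``
    the corresponding structures must be supplied; shifts are embedded as
    ``<SHIFT_H1>`` / ``<SHIFT_C13>`` properties with one "index value" pair
    per line (0-based indices).
    """
    bad = [r for r in records if r.provenance != "predicted"]
    if bad:
        raise ValueError(f"{len(bad)} records are not provenance=predicted")
    if fmt == "csv":
        write_shift_table(records, path)
        return
    if fmt != "sdf_annotated":
        raise ValueError(f"unknown format {fmt!r}")
    if structures is None:
        raise ValueError("sdf_annotated output requires structures=")
    by_mol: dict[str, list[ShiftRecord]] = {}
    for r in records:
        by_mol.setdefault(r.molecule_id, []).append(r)
    writer = Chem.SDWriter(str(path))
    try:
        for mol, conf in structures:
            rdmol = to_rdkit(mol, conf)
            rdmol.SetProp("_Name", mol.id)
            for nucleus in NUCLEI:
                recs = [r for r in by_mol.get(mol.id, []) if r.nucleus == nucleus]
                if recs:
                    prop = "\n".join(
                        f"{r.atom_index} {r.shift:.6f}"
                        for r in sorted(recs, key=lambda r: r.atom_index)
                    )
                    rdmol.SetProp(f"SHIFT_{nucleus}", prop)
            writer.write(rdmol)
    finally:
        writer.close()
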