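"""All-atom protein structures from PDB/PQR files and per-residue geometry.

The parser is deliberately strict about the one invariant the downstream
graph builders rely on — every residue view carries exactly one Cα — and
permissive about everything else that varies across real files (altlocs,
insertion codes, blank element columns, heteroatoms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "DihedralAngle",
    "DihedralSet",
    "StructureError",
    "parse_structure",
    "write_pdb",
    "backbone_dihedrals",
    "com_distance",
    "dihedral_angle",
    "AMINO_ACIDS",
    "AA_INDEX",
    "THREE_TO_ONE",
]


class StructureError(ValueError):
    """Raised when a file violates a structural invariant (e.g. missing Cα)."""


AMINO_ACIDS = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
#: index used for the generic residue produced by permissive parsing
UNKNOWN_AA_INDEX = 20

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

# histidine protonation-state aliases map back to HIS
_RESNAME_ALIASES = {"HSD": "HIS", "HSE": "HIS", "HSP": "HIS", "HID": "HIS", "HIE": "HIS", "HIP": "HIS"}
_WATER_NAMES = {"HOH", "WAT", "TIP3", "TIP", "SOL"}

ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
_OTHER_MASSES = {
    "P": 30.974, "FE": 55.845, "ZN": 65.38, "MG": 24.305, "CA": 40.078,
    "MN": 54.938, "NA": 22.990, "CL": 35.45, "K": 39.098, "SE": 78.971,
}
_DEFAULT_MASS = 12.011

#: van der Waals radii (Å) used when the file provides none
ELEMENT_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
_DEFAULT_VDW = 1.80

# side-chain dihedral atom names per residue type (chi1..chi3)
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "NE")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "CE")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [],
    "GLY": [],
}

#: maximum Cα–Cα distance (Å) treated as a peptide-bonded neighbour
CHAIN_BREAK_CA_DIST = 4.5


@dataclass
class Atom:
    serial: int
    name: str
    element: str  # one of C,H,N,O,S,other
    residue_index: int  # 0-based ordinal within the structure's residue list
    residue_type: str
    chain_id: str
    position: np.ndarray  # (3,) Å
    partial_charge: float | None = None
    vdw_radius: float | None = None
    mass: float = _DEFAULT_MASS
    res_seq: int = 0  # author residue number as in the file
    insertion_code: str = ""


@dataclass
class Residue:
    index: int
    residue_type: str
    chain_id: str
    res_seq: int
    insertion_code: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def identity(self) -> str:
        return f"{self.chain_id}:{self.res_seq}{self.insertion_code}:{self.residue_type}"

    @property
    def ca(self) -> Atom:
        for a in self.atoms:
            if a.name == "CA":
                return a
        raise StructureError(f"residue {self.identity} has no CA atom")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def aa_index(self) -> int:
        return AA_INDEX.get(self.residue_type, UNKNOWN_AA_INDEX)


@dataclass
class ProteinStructure:
    atoms: list[Atom]
    residues: list[Residue]
    het_atoms: list[Atom] = field(default_factory=list)
    source_format: str = "PDB"

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=np.float64)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=np.float64)

    def ca_coordinates(self) -> np.ndarray:
        return np.array([r.ca.position for r in self.residues], dtype=np.float64)

    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.residue_type, "X") for r in self.residues)

    def center_of_mass(self) -> np.ndarray:
        m = self.masses()
        return (self.coordinates() * m[:, None]).sum(axis=0) / m.sum()

    def transformed(self, rotation: np.ndarray | None = None, translation: np.ndarray | None = None) -> "ProteinStructure":
        """Return a copy with a rigid (or improper) transform applied."""
        import copy

        out = copy.deepcopy(self)
        for a in out.atoms + out.het_atoms:
            p = a.position
            if rotation is not None:
                p = rotation @ p
            if translation is not None:
                p = p + translation
            a.position = p
        return out


def _element_from_fields(element_field: str, atom_name: str) -> tuple[str, str]:
    """Return (raw element symbol, CHNOS-or-other class)."""
    raw = element_field.strip().upper()
    if not raw:
        for ch in atom_name.strip():
            if not ch.isdigit():
                raw = ch.upper()
                break
    cls = raw[:1] if raw[:1] in ELEMENT_MASSES else "other"
    # two-letter symbols that start with a CHNOS letter but are not CHNOS
    if len(raw) == 2 and raw in _OTHER_MASSES:
        cls = "other"
    return raw, cls


def _mass_for(raw_element: str, cls: str) -> float:
    if cls in ELEMENT_MASSES:
        return ELEMENT_MASSES[cls]
    if raw_element in _OTHER_MASSES:
        return _OTHER_MASSES[raw_element]
    return _DEFAULT_MASS


def _parse_pdb_line(line: str) -> Atom | None:
    altloc = line[16] if len(line) > 16 else " "
    if altloc not in (" ", "A"):
        return None
    name = line[12:16].strip()
    res_name = line[17:20].strip()
    chain = line[21] if len(line) > 21 else " "
    res_seq = int(line[22:26])
    icode = (line[26] if len(line) > 26 else " ").strip()
    x = float(line[30:38])
    y = float(line[38:46])
    z = float(line[46:54])
    element_field = line[76:78] if len(line) >= 78 else ""
    raw, cls = _element_from_fields(element_field, name)
    return Atom(
        serial=int(line[6:11]),
        name=name,
        element=cls,
        residue_index=-1,
        residue_type=res_name,
        chain_id=chain.strip() or "A",
        position=np.array([x, y, z], dtype=np.float64),
        mass=_mass_for(raw, cls),
        res_seq=res_seq,
        insertion_code=icode,
    )


def _parse_pqr_line(line: str) -> Atom | None:
    tok = line.split()
    # ATOM serial name resName [chain] resSeq x y z charge radius
    if len(tok) == 11:
        _, serial, name, res_name, chain, res_seq, x, y, z, q, r = tok
    elif len(tok) == 10:
        _, serial, name, res_name, res_seq, x, y, z, q, r = tok
        chain = "A"
    else:
        raise StructureError(f"unparseable PQR line: {line.rstrip()}")
    raw, cls = _element_from_fields("", name)
    return Atom(
        serial=int(serial),
        name=name,
        element=cls,
        residue_index=-1,
        residue_type=res_name,
        chain_id=chain,
        position=np.array([float(x), float(y), float(z)], dtype=np.float64),
        partial_charge=float(q),
        vdw_radius=float(r),
        mass=_mass_for(raw, cls),
        res_seq=int(res_seq),
        insertion_code="",
    )


def parse_structure(path: str | Path, format: str = "auto", permissive: bool = False) -> ProteinStructure:
    """Parse a PDB or PQR file into a :class:`ProteinStructure`.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"PDB"``, ``"PQR"`` or ``"auto"`` (by extension, default PDB).
    permissive:
        Map unknown residue types to a generic residue instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.upper()
    if fmt == "AUTO":
        fmt = "PQR" if path.suffix.lower() == ".pqr" else "PDB"
    if fmt not in ("PDB", "PQR"):
        raise ValueError(f"unknown format {format!r}")

    atoms: list[Atom] = []
    het_atoms: list[Atom] = []
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise StructureError(f"unreadable file {path}: {exc}") from exc

    for line in lines:
        rec = line.split(None, 1)[0] if fmt == "PQR" and line.strip() else line[:6].strip()
        if rec == "ENDMDL":  # first model only
            break
        if rec not in ("ATOM", "HETATM"):
            continue
        try:
            atom = _parse_pdb_line(line) if fmt == "PDB" else _parse_pqr_line(line)
        except (ValueError, IndexError) as exc:
            raise StructureError(f"unparseable {fmt} line: {line.rstrip()}") from exc
        if atom is None:
            continue
        atom.residue_type = _RESNAME_ALIASES.get(atom.residue_type, atom.residue_type)
        is_protein = atom.residue_type in AA_INDEX
        if rec == "HETATM" and not is_protein:
            het_atoms.append(atom)
            continue
        if atom.residue_type in _WATER_NAMES:
            het_atoms.append(atom)
            continue
        if not is_protein:
            if permissive:
                atom.residue_type = "UNK"
            else:
                raise StructureError(
                    f"unknown residue type {atom.residue_type!r} "
                    f"({atom.chain_id}:{atom.res_seq}); pass permissive=True to map it to a generic residue"
                )
        atoms.append(atom)

    residues = _group_residues(atoms)
    for res in residues:
        n_ca = sum(1 for a in res.atoms if a.name == "CA")
        if n_ca != 1:
            raise StructureError(f"residue {res.identity} has {n_ca} CA atoms (expected exactly 1)")
    return ProteinStructure(atoms=atoms, residues=residues, het_atoms=het_atoms, source_format=fmt)


def _group_residues(atoms: list[Atom]) -> list[Residue]:
    residues: list[Residue] = []
    key = None
    for atom in atoms:
        k = (atom.chain_id, atom.res_seq, atom.insertion_code)
        if k != key:
            residues.append(
                Residue(
                    index=len(residues),
                    residue_type=atom.residue_type,
                    chain_id=atom.chain_id,
                    res_seq=atom.res_seq,
                    insertion_code=atom.insertion_code,
                )
            )
            key = k
        atom.residue_index = len(residues) - 1
        residues[-1].atoms.append(atom)
    return residues


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write fixed-column PDB; coordinates at %.3f so round-trips are bit-stable."""
    lines = []
    for a in structure.atoms:
        elem = a.element if a.element != "other" else ""
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {a.serial:5d} {name:<4.4s} {a.residue_type:<3s} {a.chain_id[:1]}"
            f"{a.res_seq:4d}{a.insertion_code[:1] or ' '}   "
            f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {elem:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed four-point dihedral in (-π, π]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = -float(m1 @ n2)
    angle = np.arctan2(y, x)
    return float(angle) if angle != -np.pi else np.pi


@dataclass
class DihedralAngle:
    angle: float
    exists: bool

    @classmethod
    def absent(cls) -> "DihedralAngle":
        return cls(angle=0.0, exists=False)


@dataclass
class DihedralSet:
    phi: DihedralAngle
    psi: DihedralAngle
    chi1: DihedralAngle
    chi2: DihedralAngle
    chi3: DihedralAngle

    def feature_vector(self) -> np.ndarray:
        """15-vector: (sin, cos, mask) per angle, zeros where the mask is 0."""
        out = np.zeros(15, dtype=np.float64)
        for j, ang in enumerate((self.phi, self.psi, self.chi1, self.chi2, self.chi3)):
            if ang.exists:
                out[3 * j] = np.sin(ang.angle)
                out[3 * j + 1] = np.cos(ang.angle)
                out[3 * j + 2] = 1.0
        return out


def _connected(s: ProteinStructure, i: int, j: int) -> bool:
    """Peptide continuity between consecutive residue ordinals i < j."""
    a, b = s.residues[i], s.residues[j]
    if a.chain_id != b.chain_id:
        return False
    if b.insertion_code == "" and a.insertion_code == "" and b.res_seq - a.res_seq > 1:
        return False  # numbering gap
    try:
        d = float(np.linalg.norm(a.ca.position - b.ca.position))
    except StructureError:
        return False
    return d <= CHAIN_BREAK_CA_DIST


def _four_point(atoms: list[Atom | None]) -> DihedralAngle:
    if any(a is None for a in atoms):
        return DihedralAngle.absent()
    return DihedralAngle(dihedral_angle(*(a.position for a in atoms)), True)


def backbone_dihedrals(s: ProteinStructure, i: int) -> DihedralSet:
    """φ, ψ and χ1–χ3 of residue ``i`` with existence masks.

    φ is absent at a chain start (or after a chain break), ψ at a chain end;
    χ angles are absent when the residue type defines none or the defining
    atoms are missing from the file.
    """
    if not 0 <= i < len(s.residues):
        raise IndexError(f"residue index {i} out of range")
    res = s.residues[i]

    phi = DihedralAngle.absent()
    if i > 0 and _connected(s, i - 1, i):
        atoms = [s.residues[i - 1].atom("C"), res.atom("N"), res.atom("CA"), res.atom("C")]
        phi = _four_point(atoms)
        if not phi.exists:
            logger.warning("missing backbone atom for phi of %s", res.identity)

    psi = DihedralAngle.absent()
    if i < len(s.residues) - 1 and _connected(s, i, i + 1):
        atoms = [res.atom("N"), res.atom("CA"), res.atom("C"), s.residues[i + 1].atom("N")]
        psi = _four_point(atoms)
        if not psi.exists:
            logger.warning("missing backbone atom for psi of %s", res.identity)

    chis = []
    defs = CHI_ATOMS.get(res.residue_type, [])
    for k in range(3):
        if k < len(defs):
            chis.append(_four_point([res.atom(n) for n in defs[k]]))
        else:
            chis.append(DihedralAngle.absent())
    return DihedralSet(phi=phi, psi=psi, chi1=chis[0], chi2=chis[1], chi3=chis[2])


def com_distance(s: ProteinStructure, i: int) -> float:
    """Distance (Å) from residue ``i``'s Cα to the protein center of mass."""
    if not 0 <= i < len(s.residues):
        raise IndexError(f"residue index {i} out of range")
    return float(np.linalg.norm(s.residues[i].ca.position - s.center_of_mass()))
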