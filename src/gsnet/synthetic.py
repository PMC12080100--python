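"""Synthetic all-atom protein chains with analytically computable targets.

Structures are built from ideal internal coordinates (NeRF chain extension),
so every geometric feature downstream — dihedrals, Cα distances, radius of
gyration — is exactly known. The six stand-in global targets use documented
closed-form proxies (Stokes–Einstein-like hydrodynamics, Born-like
solvation) whose only purpose is to give the networks learnable,
correctly-scaled regression targets; they are not claims about any
reference software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure import (
    AMINO_ACIDS,
    CHI_ATOMS,
    ELEMENT_MASSES,
    ELEMENT_VDW,
    THREE_TO_ONE,
    Atom,
    ProteinStructure,
    Residue,
    write_pdb,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SynthSpec",
    "TargetRecord",
    "TARGET_NAMES",
    "generate_structure",
    "assign_charges",
    "synth_targets",
    "generate_dataset",
    "write_dataset",
    "ca_virtual_bond_length",
    "SIMPLE_CHARGES",
]

TARGET_NAMES = ["dG_sol", "Rg", "Rh", "Dt", "Dr", "V"]
TARGET_UNITS = {"dG_sol": "kJ/mol", "Rg": "Å", "Rh": "Å", "Dt": "nm²/µs", "Dr": "µs⁻¹", "V": "nm³"}

# proxy constants (documented package choices)
RH_OVER_RG = 1.29                 # compact-globule-like ratio
KAPPA_T = 245.0                   # nm³/µs: Dt = KAPPA_T / Rh[nm]  (kT/6πη, water 298 K)
KAPPA_R = 183.8                   # nm³/µs: Dr = KAPPA_R / Rh[nm]³ (kT/8πη)
KAPPA_BORN = 686.0                # kJ·Å/mol: dG_sol = -KAPPA_BORN · Σq² / Rh[Å]

# ideal backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_B_C_O, _A_CA_C_O = 1.231, 120.8
_B_CA_CB, _A_N_CA_CB = 1.530, 110.5
_B_CB_G, _A_CA_CB_G = 1.520, 114.0
_OMEGA = 180.0

_COIL_BASINS = [(-57.0, -47.0), (-139.0, 135.0), (-78.0, 149.0), (60.0, 45.0)]


@dataclass
class SynthSpec:
    """Recipe for one synthetic chain; the seed fully determines the output."""

    n_residues: int
    conformation: str = "helix"  # helix | extended | coil
    jitter_sd: float = 0.0  # Å
    seed: int = 0
    include_hydrogens: bool = True
    sequence: str | None = None  # 3-letter codes joined? no: 1-letter string

    def __post_init__(self):
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.conformation not in ("helix", "extended", "coil"):
            raise ValueError(f"unknown conformation {self.conformation!r}")


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given three predecessors: |cd|=bond, ∠bcd=angle, ∠abcd=torsion."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    ab /= np.linalg.norm(ab)
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(theta), bond * np.sin(theta) * np.cos(chi), bond * np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


_ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def _phi_psi(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.conformation == "helix":
        return np.tile([-57.0, -47.0], (spec.n_residues, 1))
    if spec.conformation == "extended":
        return np.tile([180.0, 180.0], (spec.n_residues, 1))
    idx = rng.integers(0, len(_COIL_BASINS), size=spec.n_residues)
    return np.array([_COIL_BASINS[i] for i in idx], dtype=np.float64)


def generate_structure(spec: SynthSpec) -> ProteinStructure:
    """Build an all-atom chain from ideal internal coordinates.

    Backbone N/CA/C/O per residue; Cβ and the first χ1-defining atom are
    added where the residue type has them, so the dihedral-mask code paths
    (φ at termini, χ on Gly/Ala) are all exercised. Hydrogens (amide H and
    Hα) are optional.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.sequence is not None:
        seq3 = [_ONE_TO_THREE[c] for c in spec.sequence.upper()]
        if len(seq3) != spec.n_residues:
            raise ValueError("sequence length must equal n_residues")
    else:
        seq3 = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=spec.n_residues)]

    phi_psi = _phi_psi(spec, rng)

    # backbone trace
    n_pos = [np.array([0.0, 0.0, 0.0])]
    ca_pos = [np.array([_B_N_CA, 0.0, 0.0])]
    theta = np.deg2rad(_A_N_CA_C)
    c_pos = [ca_pos[0] + _B_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])]
    for i in range(1, spec.n_residues):
        psi_prev = phi_psi[i - 1, 1]
        n_next = _nerf(n_pos[-1], ca_pos[-1], c_pos[-1], _B_C_N, _A_CA_C_N, psi_prev)
        ca_next = _nerf(ca_pos[-1], c_pos[-1], n_next, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_next = _nerf(c_pos[-1], n_next, ca_next, _B_CA_C, _A_N_CA_C, phi_psi[i, 0])
        n_pos.append(n_next)
        ca_pos.append(ca_next)
        c_pos.append(c_next)

    atoms: list[Atom] = []
    serial = 1

    def add(name: str, element: str, pos: np.ndarray, res_i: int):
        nonlocal serial
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                residue_index=res_i,
                residue_type=seq3[res_i],
                chain_id="A",
                position=np.asarray(pos, dtype=np.float64),
                mass=ELEMENT_MASSES[element],
                vdw_radius=ELEMENT_VDW[element],
                res_seq=res_i + 1,
            )
        )
        serial += 1

    for i in range(spec.n_residues):
        add("N", "N", n_pos[i], i)
        add("CA", "C", ca_pos[i], i)
        add("C", "C", c_pos[i], i)
        # carbonyl O anti-periplanar to the next amide N
        o = _nerf(n_pos[i], ca_pos[i], c_pos[i], _B_C_O, _A_CA_C_O, phi_psi[i, 1] + 180.0)
        add("O", "O", o, i)
        chis = CHI_ATOMS.get(seq3[i], [])
        if seq3[i] != "GLY":
            cb = _nerf(c_pos[i], n_pos[i], ca_pos[i], _B_CA_CB, _A_N_CA_CB, -122.0)
            add("CB", "C", cb, i)
            if chis:
                gname = chis[0][3]
                gelem = gname[0]  # CG→C, OG→O, SG→S
                g = _nerf(n_pos[i], ca_pos[i], cb, _B_CB_G, _A_CA_CB_G, -60.0)
                add(gname, gelem, g, i)
        if spec.include_hydrogens:
            if seq3[i] != "PRO":
                h = _nerf(c_pos[i], ca_pos[i], n_pos[i], 1.01, 118.0, 180.0)
                add("H", "H", h, i)
            ha = _nerf(c_pos[i], n_pos[i], ca_pos[i], 1.09, 109.0, 118.0)
            add("HA", "H", ha, i)

    if spec.jitter_sd > 0:
        noise = rng.normal(0.0, spec.jitter_sd, size=(len(atoms), 3))
        for a, dx in zip(atoms, noise):
            a.position = a.position + dx

    residues = []
    for i, rt in enumerate(seq3):
        residues.append(Residue(index=i, residue_type=rt, chain_id="A", res_seq=i + 1, insertion_code=""))
    for a in atoms:
        residues[a.residue_index].atoms.append(a)
    return ProteinStructure(atoms=atoms, residues=residues, source_format="synthetic")


def ca_virtual_bond_length() -> float:
    """Consecutive Cα–Cα distance implied by the ideal backbone geometry."""
    s = generate_structure(SynthSpec(n_residues=2, conformation="extended", jitter_sd=0.0, seed=0))
    ca = s.ca_coordinates()
    return float(np.linalg.norm(ca[1] - ca[0]))


# Simplified per-atom partial charges, CHARMM-like backbone values plus
# nominal side-chain stub charges. A stand-in set bundled for testing the
# charge-dependent code paths; "*" rows apply to every residue type.
SIMPLE_CHARGES: dict[str, dict[str, float]] = {
    "*": {"N": -0.47, "H": 0.31, "CA": 0.07, "HA": 0.09, "C": 0.51, "O": -0.51, "CB": -0.18},
    "ASP": {"CG": -0.76},
    "GLU": {"CG": -0.49},
    "LYS": {"CG": 0.33},
    "ARG": {"CG": 0.33},
    "HIS": {"CG": 0.22},
    "SER": {"OG": -0.66},
    "THR": {"OG1": -0.66},
    "CYS": {"SG": -0.23},
    "TYR": {"CG": 0.00},
    "PRO": {"CG": -0.18},
    "ASN": {"CG": 0.55},
    "GLN": {"CG": -0.18},
    "ILE": {"CG1": -0.18},
    "LEU": {"CG": -0.18},
    "VAL": {"CG1": -0.18},
    "MET": {"CG": -0.14},
    "PHE": {"CG": 0.00},
    "TRP": {"CG": -0.03},
}


def assign_charges(s: ProteinStructure, table: dict[str, dict[str, float]] | None = None) -> ProteinStructure:
    """Set every atom's partial charge from a (residue_type, atom_name) table.

    Atoms absent from the table get charge 0 with a warning. Returns ``s``
    (charges are set in place).
    """
    table = SIMPLE_CHARGES if table is None else table
    wildcard = table.get("*", {})
    for a in s.atoms:
        specific = table.get(a.residue_type, {})
        if a.name in specific:
            a.partial_charge = specific[a.name]
        elif a.name in wildcard:
            a.partial_charge = wildcard[a.name]
        else:
            logger.warning("no charge for %s/%s; assigning 0", a.residue_type, a.name)
            a.partial_charge = 0.0
    return s


@dataclass
class TargetRecord:
    """The six global targets with per-target availability mask."""

    dG_sol: float
    Rg: float
    Rh: float
    Dt: float
    Dr: float
    V: float
    mask: np.ndarray = field(default_factory=lambda: np.ones(6, dtype=bool))

    def values(self) -> np.ndarray:
        return np.array([self.dG_sol, self.Rg, self.Rh, self.Dt, self.Dr, self.V], dtype=np.float64)


def synth_targets(s: ProteinStructure) -> TargetRecord:
    """Closed-form proxy targets for a synthetic structure.

    Rg is exact (mass-weighted); Rh = 1.29·Rg; Dt and Dr follow
    Stokes–Einstein(-Debye) scalings in water at 298 K; V sums atomic vdW
    sphere volumes; ΔG_sol is a Born-like −κ·Σq²/Rh. Missing charges mask
    out ΔG_sol (they never fail the record).
    """
    from .reference import radius_of_gyration

    rg = radius_of_gyration(s)
    rh = RH_OVER_RG * rg
    rh_nm = rh / 10.0
    dt = KAPPA_T / rh_nm if rh_nm > 0 else 0.0
    dr = KAPPA_R / rh_nm**3 if rh_nm > 0 else 0.0
    radii = np.array([a.vdw_radius if a.vdw_radius is not None else ELEMENT_VDW.get(a.element, 1.8) for a in s.atoms])
    vol = float((4.0 / 3.0) * np.pi * (radii**3).sum()) / 1000.0  # Å³ → nm³
    mask = np.ones(6, dtype=bool)
    charges = [a.partial_charge for a in s.atoms]
    if any(q is None for q in charges):
        mask[0] = False
        dg = 0.0
    else:
        dg = -KAPPA_BORN * float(np.sum(np.square(charges))) / rh if rh > 0 else 0.0
    return TargetRecord(dG_sol=dg, Rg=rg, Rh=rh, Dt=dt, Dr=dr, V=vol, mask=mask)


def generate_dataset(
    n_structures: int,
    seed: int,
    n_residue_range: tuple[int, int] = (16, 48),
    conformations: tuple[str, ...] = ("helix", "extended", "coil"),
    jitter_sd: float = 0.3,
    include_hydrogens: bool = True,
    with_charges: bool = True,
    dg_missing_fraction: float = 0.2,
) -> list[tuple[ProteinStructure, TargetRecord]]:
    """Generate a labelled dataset of synthetic structures.

    A ``dg_missing_fraction`` of records has ΔG_sol masked out, mirroring
    datasets where the solvation target covers only a subset of structures.
    """
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_structures):
        spec = SynthSpec(
            n_residues=int(rng.integers(n_residue_range[0], n_residue_range[1] + 1)),
            conformation=conformations[int(rng.integers(0, len(conformations)))],
            jitter_sd=jitter_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            include_hydrogens=include_hydrogens,
        )
        s = generate_structure(spec)
        if with_charges:
            assign_charges(s)
        rec = synth_targets(s)
        if rec.mask[0] and rng.random() < dg_missing_fraction:
            rec.mask = rec.mask.copy()
            rec.mask[0] = False
        out.append((s, rec))
    return out


def write_dataset(dataset: list[tuple[ProteinStructure, TargetRecord]], outdir: str | Path) -> pd.DataFrame:
    """Write one PDB per structure and a targets table (CSV) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, (s, rec) in enumerate(dataset):
        sid = f"synth{k:05d}"
        write_pdb(s, outdir / f"{sid}.pdb")
        row = {"id": sid}
        row.update(dict(zip(TARGET_NAMES, rec.values())))
        row.update({f"mask_{n}": bool(m) for n, m in zip(TARGET_NAMES, rec.mask)})
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "targets.csv", index=False)
    return df
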