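"""Reference calculators: radius of gyration, Shrake–Rupley SASA, null-model pKa.

These supply ground-truth labels and baselines that can be computed honestly
from coordinates alone. SASA uses a deterministic golden-spiral point set,
so results are bit-reproducible at fixed ``n_points``.
"""

from __future__ import annotations

import numpy as np

from .structure import ELEMENT_VDW, ProteinStructure, _DEFAULT_VDW

__all__ = [
    "radius_of_gyration",
    "sasa",
    "sphere_points",
    "NullPkaTable",
    "DEFAULT_NULL_PKA",
    "null_pka",
    "ionizable_residues",
]


def radius_of_gyration(s: ProteinStructure) -> float:
    """Mass-weighted radius of gyration in Å."""
    pos = s.coordinates()
    m = s.masses()
    com = (pos * m[:, None]).sum(axis=0) / m.sum()
    d2 = ((pos - com) ** 2).sum(axis=1)
    return float(np.sqrt((m * d2).sum() / m.sum()))


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere (golden spiral; no RNG)."""
    k = np.arange(n, dtype=np.float64) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack([np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)


def sasa(s: ProteinStructure, probe: float = 1.4, n_points: int = 960) -> dict:
    """Shrake–Rupley solvent-accessible surface area.

    Returns ``{"molecular": nm², "per_residue": array of nm²}``; per-residue
    values sum to the molecular value exactly because each atom's area is
    attributed to its residue. Radii come from the file (PQR) when present,
    else from the bundled element table.
    """
    if n_points < 12:
        raise ValueError("n_points must be >= 12")
    atoms = s.atoms
    pos = s.coordinates()
    radii = np.array(
        [a.vdw_radius if a.vdw_radius is not None else ELEMENT_VDW.get(a.element, _DEFAULT_VDW) for a in atoms]
    )
    ext = radii + probe
    unit = sphere_points(n_points)
    n_atoms = len(atoms)
    per_atom = np.zeros(n_atoms)

    # neighbour lists via cell-free cutoff: pairwise distances in blocks
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    for i in range(n_atoms):
        cutoff2 = (ext[i] + ext) ** 2
        nbr = np.where((d2[i] < cutoff2) & (np.arange(n_atoms) != i))[0]
        pts = pos[i] + ext[i] * unit
        if nbr.size:
            dist2 = ((pts[:, None, :] - pos[nbr][None, :, :]) ** 2).sum(axis=2)
            buried = (dist2 < (ext[nbr] ** 2)[None, :]).any(axis=1)
            n_acc = int((~buried).sum())
        else:
            n_acc = n_points
        per_atom[i] = 4.0 * np.pi * ext[i] ** 2 * n_acc / n_points

    per_residue = np.zeros(s.n_residues)
    for a, area in zip(atoms, per_atom):
        per_residue[a.residue_index] += area
    per_residue /= 100.0  # Å² → nm²
    return {"molecular": float(per_residue.sum()), "per_residue": per_residue, "per_atom": per_atom / 100.0}


class NullPkaTable(dict):
    """residue_type → reference (model-compound) pKa."""

    REQUIRED = {"ASP", "GLU", "HIS", "LYS", "TYR", "CYS"}

    def __init__(self, values: dict[str, float]):
        missing = self.REQUIRED - set(values)
        if missing:
            raise ValueError(f"null pKa table missing required residue types: {sorted(missing)}")
        super().__init__(values)


#: bundled defaults on the common experimental reference scale (a package
#: choice; override by passing your own table)
DEFAULT_NULL_PKA = NullPkaTable(
    {"ASP": 3.65, "GLU": 4.25, "HIS": 6.54, "LYS": 10.40, "TYR": 9.84, "CYS": 8.55}
)


def null_pka(residue_type: str, table: NullPkaTable | None = None) -> float:
    """The null model: every residue gets its reference pKa (shift ≡ 0)."""
    table = DEFAULT_NULL_PKA if table is None else table
    rt = residue_type.upper()
    if rt not in table:
        raise KeyError(f"{residue_type!r} is not ionizable; valid types: {sorted(table)}")
    return float(table[rt])


def ionizable_residues(s: ProteinStructure, table: NullPkaTable | None = None) -> list[int]:
    """Indices of residues whose type appears in the null-pKa table."""
    table = DEFAULT_NULL_PKA if table is None else table
    return [r.index for r in s.residues if r.residue_type in table]
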