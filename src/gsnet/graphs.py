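"""Graph construction: the global residue graph and the local atom graph.

Both graphs carry E(3)-invariant features only — scalar distances expanded
on a Gaussian basis ("smearing"), dihedral sin/cos/mask triplets, distances
to the center of mass, discrete type indices and charges. Coordinates are
kept on the graph solely for radius-pooled readouts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import ProteinStructure, backbone_dihedrals, com_distance

__all__ = [
    "SmearingSpec",
    "smear",
    "ResidueGraph",
    "AtomGraph",
    "build_residue_graph",
    "build_atom_graph",
    "residue_smearing_spec",
    "atom_smearing_spec",
    "save_graph",
    "load_graph",
]

ATOM_TYPES = ["C", "H", "N", "O", "S"]
ATOM_TYPE_INDEX = {t: i for i, t in enumerate(ATOM_TYPES)}

RESIDUE_EDGE_CUTOFF = 15.0  # Å, Cα–Cα
ATOM_SELECTION_RADIUS = 10.0  # Å around the center Cα
ATOM_EDGE_CUTOFF = 5.0  # Å, atom–atom
MAX_EDGES_PER_NODE = 150


@dataclass(frozen=True)
class SmearingSpec:
    """Linearly spaced Gaussian basis over [d_min, d_max]; σ equals the spacing."""

    K: int
    d_min: float
    d_max: float

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if not self.d_max > self.d_min:
            raise ValueError("d_max must exceed d_min")

    @property
    def sigma(self) -> float:
        return (self.d_max - self.d_min) / (self.K - 1)

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(self.d_min, self.d_max, self.K)


def residue_smearing_spec() -> SmearingSpec:
    return SmearingSpec(K=300, d_min=0.0, d_max=15.0)


def atom_smearing_spec() -> SmearingSpec:
    return SmearingSpec(K=300, d_min=0.0, d_max=5.0)


def smear(d, spec: SmearingSpec) -> np.ndarray:
    """Expand distance(s) ``d`` on the Gaussian basis: exp(−(d−μ_k)²/2σ²).

    Accepts a scalar (returns shape ``(K,)``) or a 1-D array (``(n, K)``).
    No normalization across components.
    """
    d = np.asarray(d, dtype=np.float64)
    scalar = d.ndim == 0
    diff = d.reshape(-1, 1) - spec.centers[None, :]
    out = np.exp(-(diff**2) / (2.0 * spec.sigma**2))
    return out[0] if scalar else out


@dataclass
class ResidueGraph:
    aa_index: np.ndarray  # (n,)
    dihedral_feats: np.ndarray  # (n, 15)
    com_dist: np.ndarray  # (n,)
    coords: np.ndarray  # (n, 3) Cα coordinates, Å
    edge_index: np.ndarray  # (2, E) directed, both orientations
    edge_dist: np.ndarray  # (E,)
    edge_feats: np.ndarray  # (E, K) float32
    spec: SmearingSpec = field(default_factory=residue_smearing_spec)

    @property
    def n_nodes(self) -> int:
        return len(self.aa_index)


@dataclass
class AtomGraph:
    center_residue: int
    aa_index: np.ndarray  # (n,)
    atom_type_index: np.ndarray  # (n,) over C,H,N,O,S
    charge: np.ndarray  # (n,)
    coords: np.ndarray  # (n, 3)
    ca_node: int
    residue_node_set: np.ndarray  # node indices of the center residue's atoms
    edge_index: np.ndarray
    edge_dist: np.ndarray
    edge_feats: np.ndarray
    spec: SmearingSpec = field(default_factory=atom_smearing_spec)

    @property
    def n_nodes(self) -> int:
        return len(self.aa_index)


def _radius_edges(coords: np.ndarray, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """All directed pairs (i≠j) with ``|p_i − p_j| ≤ cutoff`` (inclusive)."""
    delta = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((delta**2).sum(axis=2))
    src, dst = np.where((dist <= cutoff) & ~np.eye(len(coords), dtype=bool))
    return np.stack([src, dst]), dist[src, dst]


def build_residue_graph(s: ProteinStructure, spec: SmearingSpec | None = None) -> ResidueGraph:
    """Residue-level graph: one node per residue, edges between Cα pairs ≤ 15 Å."""
    if s.n_residues < 1:
        raise ValueError("structure has no residues")
    spec = residue_smearing_spec() if spec is None else spec
    coords = s.ca_coordinates()
    aa_index = np.array([r.aa_index for r in s.residues], dtype=np.intp)
    dihedral_feats = np.array([backbone_dihedrals(s, i).feature_vector() for i in range(s.n_residues)])
    com = s.center_of_mass()
    com_dist = np.linalg.norm(coords - com, axis=1)
    edge_index, edge_dist = _radius_edges(coords, RESIDUE_EDGE_CUTOFF)
    edge_feats = smear(edge_dist, spec).astype(np.float32)
    return ResidueGraph(
        aa_index=aa_index,
        dihedral_feats=dihedral_feats,
        com_dist=com_dist,
        coords=coords,
        edge_index=edge_index,
        edge_dist=edge_dist,
        edge_feats=edge_feats,
        spec=spec,
    )


def build_atom_graph(
    s: ProteinStructure,
    i: int,
    selection_radius: float = ATOM_SELECTION_RADIUS,
    edge_cutoff: float = ATOM_EDGE_CUTOFF,
    max_edges: int = MAX_EDGES_PER_NODE,
    spec: SmearingSpec | None = None,
) -> AtomGraph:
    """Local atom graph around residue ``i``'s Cα.

    Nodes are every C/H/N/O/S atom within ``selection_radius`` of the center
    Cα (the Cα itself always included); edges connect atom pairs within
    ``edge_cutoff``, capped at the ``max_edges`` nearest per receiving node
    (ties broken by atom serial, ascending).
    """
    if not 0 <= i < s.n_residues:
        raise IndexError(f"residue index {i} out of range")
    spec = atom_smearing_spec() if spec is None else spec
    ca = s.residues[i].ca

    selected = []
    for a in s.atoms:
        if a.element not in ATOM_TYPE_INDEX:
            continue
        if np.linalg.norm(a.position - ca.position) <= selection_radius:
            selected.append(a)
    missing = [a for a in selected if a.partial_charge is None]
    if missing:
        raise ValueError(
            f"{len(missing)} selected atoms lack partial charges; "
            "parse a PQR file or run assign_charges() first"
        )

    coords = np.array([a.position for a in selected])
    serials = np.array([a.serial for a in selected])
    from .structure import AA_INDEX, UNKNOWN_AA_INDEX

    aa_index = np.array([AA_INDEX.get(a.residue_type, UNKNOWN_AA_INDEX) for a in selected], dtype=np.intp)
    atom_type = np.array([ATOM_TYPE_INDEX[a.element] for a in selected], dtype=np.intp)
    charge = np.array([a.partial_charge for a in selected], dtype=np.float64)
    ca_node = next(k for k, a in enumerate(selected) if a is ca)
    residue_nodes = np.array([k for k, a in enumerate(selected) if a.residue_index == i], dtype=np.intp)

    edge_index, edge_dist = _radius_edges(coords, edge_cutoff)
    # cap incoming edges per receiver: keep max_edges nearest, ties by serial
    if edge_index.shape[1]:
        src, dst = edge_index
        order = np.lexsort((serials[src], edge_dist, dst))  # by dst, then dist, then serial
        src, dst, edge_dist = src[order], dst[order], edge_dist[order]
        rank = np.zeros(len(dst), dtype=np.intp)
        counts: dict[int, int] = {}
        for k, d_ in enumerate(dst):
            rank[k] = counts.get(d_, 0)
            counts[d_] = rank[k] + 1
        keep = rank < max_edges
        edge_index = np.stack([src[keep], dst[keep]])
        edge_dist = edge_dist[keep]
    edge_feats = smear(edge_dist, spec).astype(np.float32)
    return AtomGraph(
        center_residue=i,
        aa_index=aa_index,
        atom_type_index=atom_type,
        charge=charge,
        coords=coords,
        ca_node=ca_node,
        residue_node_set=residue_nodes,
        edge_index=edge_index,
        edge_dist=edge_dist,
        edge_feats=edge_feats,
        spec=spec,
    )


def save_graph(graph: ResidueGraph | AtomGraph, path: str | Path) -> None:
    """Serialize a graph to an .npz container with a JSON metadata entry."""
    meta = {
        "kind": type(graph).__name__,
        "spec": {"K": graph.spec.K, "d_min": graph.spec.d_min, "d_max": graph.spec.d_max},
    }
    arrays = {k: v for k, v in graph.__dict__.items() if isinstance(v, np.ndarray)}
    scalars = {k: v for k, v in graph.__dict__.items() if isinstance(v, (int, np.integer))}
    meta["scalars"] = {k: int(v) for k, v in scalars.items()}
    np.savez(path, _meta=json.dumps(meta), **arrays)


def load_graph(path: str | Path) -> ResidueGraph | AtomGraph:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["_meta"]))
        spec = SmearingSpec(**meta["spec"])
        kwargs = {k: data[k] for k in data.files if k != "_meta"}
        kwargs.update(meta["scalars"])
        cls = {"ResidueGraph": ResidueGraph, "AtomGraph": AtomGraph}[meta["kind"]]
        return cls(spec=spec, **kwargs)
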