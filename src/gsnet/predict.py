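"""End-to-end prediction pipelines: global properties with denormalization,
per-residue SASA, and per-residue pKa with null-model reconstruction and
conformational-ensemble averaging."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphs import build_atom_graph, build_residue_graph
from .model import GNNModel
from .reference import DEFAULT_NULL_PKA, NullPkaTable, ionizable_residues, null_pka
from .structure import ProteinStructure
from .synthetic import TARGET_NAMES, TARGET_UNITS
from .training import NormStats

__all__ = ["PredictionReport", "predict_global", "predict_per_residue", "predict_rsasa", "predict_pka"]


@dataclass
class PredictionReport:
    structure_id: str
    values: dict[str, float]
    units: dict[str, str]
    per_residue: pd.DataFrame | None = None
    checkpoint_id: str = ""
    norm_stats_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"target": list(self.values), "value": list(self.values.values()),
             "unit": [self.units.get(k, "") for k in self.values]}
        )


def predict_global(
    structure: ProteinStructure,
    model: GNNModel,
    stats: NormStats,
    structure_id: str = "",
    target_names: list[str] | None = None,
) -> PredictionReport:
    """Featurize → forward → invert normalization → report with units."""
    if model.config.head_spec not in ("global6", "global1"):
        raise ValueError("predict_global requires a global6 or global1 head")
    if stats is None:
        raise ValueError("normalization stats required to report physical units")
    graph = build_residue_graph(structure)
    z = model.predict(graph)
    y = stats.invert(z)
    names = target_names or (TARGET_NAMES if len(y) == 6 else ["value"])
    units = {n: TARGET_UNITS.get(n, "") for n in names}
    return PredictionReport(structure_id=structure_id, values=dict(zip(names, map(float, y))), units=units)


def predict_per_residue(model: GNNModel, graph, indices: list[int]) -> np.ndarray:
    """Per-residue head outputs sharing one embedding pass over the graph."""
    was = model.training
    model.eval()
    H = model.embed(graph)
    out = np.array([model.head(model.readout(H, graph, i).reshape(1, -1)).data.item() for i in indices])
    model.train(was)
    return out


def predict_rsasa(
    structure: ProteinStructure, model: GNNModel, stats: NormStats | None = None, structure_id: str = ""
) -> PredictionReport:
    """Residue-level SASA (nm²) for every residue."""
    if model.config.head_spec != "residue1":
        raise ValueError("predict_rsasa requires a residue1 head")
    graph = build_residue_graph(structure)
    z = predict_per_residue(model, graph, list(range(structure.n_residues)))
    y = stats.invert(z) if stats is not None else z
    df = pd.DataFrame(
        {"residue": [r.identity for r in structure.residues], "rsasa_nm2": y}
    )
    return PredictionReport(structure_id=structure_id, values={}, units={"rsasa": "nm²"}, per_residue=df)


def predict_pka(
    structures: ProteinStructure | list[ProteinStructure],
    model: GNNModel,
    residues: list[int] | None = None,
    stats: NormStats | None = None,
    table: NullPkaTable | None = None,
    absolute: bool = False,
    structure_id: str = "",
) -> pd.DataFrame:
    """Per-residue pKa from the shift head; ``structures`` may be a
    conformational ensemble, in which case per-residue predictions are
    arithmetically averaged across members.

    The head is trained in shift space by default: pKa = null + shift.
    With ``absolute=True`` the head output is taken as pKa directly and the
    shift column is derived.
    """
    table = DEFAULT_NULL_PKA if table is None else table
    ensemble = structures if isinstance(structures, list) else [structures]
    first = ensemble[0]
    if residues is None:
        residues = ionizable_residues(first, table)
    else:
        bad = [i for i in residues if first.residues[i].residue_type not in table]
        if bad:
            types = {first.residues[i].residue_type for i in bad}
            raise KeyError(f"non-ionizable residues requested ({sorted(types)}); valid types: {sorted(table)}")

    per_member = []
    for s in ensemble:
        if model.config.head_spec == "pka_gsnet":
            graph = build_residue_graph(s)
            raw = predict_per_residue(model, graph, residues)
        elif model.config.head_spec == "pka_alcnet":
            raw = np.array([model.predict(build_atom_graph(s, i)).item() for i in residues])
        else:
            raise ValueError("predict_pka requires a pKa head")
        if stats is not None:
            raw = stats.invert(raw)
        per_member.append(raw)
    mean_raw = np.mean(per_member, axis=0)

    null = np.array([null_pka(first.residues[i].residue_type, table) for i in residues])
    if absolute:
        pka = mean_raw
        shift = pka - null
    else:
        shift = mean_raw
        pka = null + shift
    return pd.DataFrame(
        {
            "structure_id": structure_id,
            "residue": [first.residues[i].identity for i in residues],
            "residue_index": residues,
            "null_pka": null,
            "shift": shift,
            "pka": pka,
            "n_ensemble": len(ensemble),
        }
    )
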