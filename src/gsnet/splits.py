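"""Leakage-aware splitting of residue-level pKa data.

Two pKa measurements are "the same data point in disguise" when their parent
sequences are homologous (identity > 0.5), the residues occupy the same
alignment column, and the residue types match. The splitter clusters
sequences greedily at the identity threshold, aligns members to their
cluster representative to index alignment columns, and removes similar
pairs within the validation set, between validation and train, and between
an independent test source and train ∪ validation. A verification pass
re-checks the predicate exhaustively and reports every pair it found.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

logger = logging.getLogger(__name__)

__all__ = [
    "PkaRecord",
    "ClusterAssignment",
    "pairwise_identity",
    "cluster_sequences",
    "is_similar",
    "split_dataset",
    "SplitResult",
    "load_pka_table",
    "records_to_frame",
]

IONIZABLE = {"ASP", "GLU", "HIS", "LYS", "TYR", "CYS"}


@dataclass(frozen=True)
class PkaRecord:
    """One ionizable-residue measurement tied to a parent sequence."""

    structure_id: str
    chain: str
    residue_number: int  # author numbering, here 1-based position in sequence
    residue_type: str
    pka: float
    sequence: str

    @property
    def label(self) -> str:
        return f"{self.structure_id}_{self.chain}:{self.residue_number}:{self.residue_type}"

    @property
    def seq_position(self) -> int:
        """0-based position of the residue in the parent sequence."""
        pos = self.residue_number - 1
        if not 0 <= pos < len(self.sequence):
            raise ValueError(f"residue number {self.residue_number} outside sequence for {self.label}")
        return pos


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity: matches / alignment length
    (gap columns included in the denominator)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _make_aligner().align(a, b)[0]
    return aln.counts().identities / aln.length


def _column_map(rep: str, member: str) -> list[int | None]:
    """Map each member position to its column (= representative position)."""
    aln = _make_aligner().align(rep, member)[0]
    mapping: list[int | None] = [None] * len(member)
    for (r0, r1), (m0, m1) in zip(*aln.aligned):
        for k in range(r1 - r0):
            mapping[m0 + k] = r0 + k
    return mapping


@dataclass
class ClusterAssignment:
    """Cluster id and alignment-column map per distinct sequence."""

    cluster_of: dict[str, int]
    representatives: list[str]
    column_map: dict[str, list[int | None]]
    threshold: float = 0.5

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def cluster_sequences(seqs: list[str], threshold: float = 0.5) -> ClusterAssignment:
    """Greedy longest-first clustering at the identity threshold.

    Each sequence joins the first existing cluster whose representative it
    matches at identity > ``threshold``, else founds a new cluster. Column
    maps are pairwise alignments to the representative (the representative
    maps to itself).
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    distinct = list(dict.fromkeys(seqs))
    order = sorted(range(len(distinct)), key=lambda i: (-len(distinct[i]), i))
    cluster_of: dict[str, int] = {}
    reps: list[str] = []
    column_map: dict[str, list[int | None]] = {}
    for i in order:
        seq = distinct[i]
        for cid, rep in enumerate(reps):
            if pairwise_identity(seq, rep) > threshold:
                cluster_of[seq] = cid
                column_map[seq] = _column_map(rep, seq)
                break
        else:
            cluster_of[seq] = len(reps)
            column_map[seq] = list(range(len(seq)))
            reps.append(seq)
    return ClusterAssignment(cluster_of=cluster_of, representatives=reps, column_map=column_map, threshold=threshold)


def is_similar(x: PkaRecord, y: PkaRecord, clusters: ClusterAssignment) -> bool:
    """The three-condition predicate: same cluster ∧ same alignment column
    ∧ same residue type. Symmetric; unmappable residues are dissimilar."""
    if x.sequence not in clusters.cluster_of or y.sequence not in clusters.cluster_of:
        raise ValueError("both records' sequences must be clustered first")
    if clusters.cluster_of[x.sequence] != clusters.cluster_of[y.sequence]:
        return False
    if x.residue_type != y.residue_type:
        return False
    cx = clusters.column_map[x.sequence][x.seq_position]
    cy = clusters.column_map[y.sequence][y.seq_position]
    if cx is None or cy is None:
        logger.warning("residue of %s or %s falls in an unaligned region; treated as dissimilar", x.label, y.label)
        return False
    return cx == cy


@dataclass
class SplitResult:
    train: list[PkaRecord]
    validation: list[PkaRecord]
    test: list[PkaRecord]
    clusters: ClusterAssignment
    report: dict = field(default_factory=dict)


def _dedup(records: list[PkaRecord], clusters: ClusterAssignment) -> tuple[list[PkaRecord], list[tuple[str, str]]]:
    kept: list[PkaRecord] = []
    removed: list[tuple[str, str]] = []
    for r in records:
        hit = next((k for k in kept if is_similar(r, k, clusters)), None)
        if hit is None:
            kept.append(r)
        else:
            removed.append((r.label, hit.label))
    return kept, removed


def _cross_pairs(a: list[PkaRecord], b: list[PkaRecord], clusters: ClusterAssignment) -> list[tuple[str, str]]:
    return [(x.label, y.label) for x in a for y in b if is_similar(x, y, clusters)]


def split_dataset(
    records: list[PkaRecord],
    ratio: float = 0.9,
    seed: int = 0,
    test_source: list[PkaRecord] | None = None,
    threshold: float = 0.5,
) -> SplitResult:
    """Random 9:1 train/validation split with similarity filtering.

    Training keeps internally similar points; validation is deduplicated
    internally and purged of anything similar to a training point; the test
    set (from the disjoint ``test_source``) is deduplicated and purged of
    anything similar to train ∪ validation. The report lists every removed
    pair and the final exhaustive train×test similarity count (always 0).
    """
    test_source = test_source or []
    seqs = [r.sequence for r in records] + [r.sequence for r in test_source]
    clusters = cluster_sequences(seqs, threshold=threshold)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = int(round(ratio * len(records)))
    train = [records[i] for i in order[:n_train]]
    val0 = [records[i] for i in order[n_train:]]

    val1, removed_internal = _dedup(val0, clusters)
    leaked_val = _cross_pairs(val1, train, clusters)
    leaked_labels = {x for x, _ in leaked_val}
    validation = [r for r in val1 if r.label not in leaked_labels]
    if val0 and not validation:
        bad = sorted({clusters.cluster_of[r.sequence] for r in val0})
        raise ValueError(f"no leakage-free validation split possible; offending clusters: {bad}")

    test1, removed_test_internal = _dedup(test_source, clusters)
    pool = train + validation
    leaked_test = _cross_pairs(test1, pool, clusters)
    leaked_test_labels = {x for x, _ in leaked_test}
    test = [r for r in test1 if r.label not in leaked_test_labels]

    verification = _cross_pairs(train, test, clusters)
    assert not verification, "similarity filter failed to remove a train×test pair"
    report = {
        "n_train": len(train),
        "n_validation": len(validation),
        "n_test": len(test),
        "removed_validation_internal": removed_internal,
        "removed_validation_vs_train": leaked_val,
        "removed_test_internal": removed_test_internal,
        "removed_test_vs_train_val": leaked_test,
        "train_test_similar_pairs_after": len(verification),
    }
    return SplitResult(train=train, validation=validation, test=test, clusters=clusters, report=report)


def load_pka_table(path) -> list[PkaRecord]:
    """Read a delimited table (pdb_id, chain, resnum, restype, pka, sequence)."""
    df = pd.read_csv(path)
    cols = ["pdb_id", "chain", "resnum", "restype", "pka", "sequence"]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"pKa table missing columns: {sorted(missing)}")
    return [
        PkaRecord(
            structure_id=str(r.pdb_id),
            chain=str(r.chain),
            residue_number=int(r.resnum),
            residue_type=str(r.restype).upper(),
            pka=float(r.pka),
            sequence=str(r.sequence).upper(),
        )
        for r in df.itertuples()
    ]


def records_to_frame(records: list[PkaRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pdb_id": [r.structure_id for r in records],
            "chain": [r.chain for r in records],
            "resnum": [r.residue_number for r in records],
            "restype": [r.residue_type for r in records],
            "pka": [r.pka for r in records],
            "sequence": [r.sequence for r in records],
        }
    )
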