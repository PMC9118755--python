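"""Readers and writers for the flat files the pipeline touches.

Every tabular file is TSV (tab-delimited, UTF-8, ``.`` decimal); sequences
are FASTA.  The three domain containers defined here — the binary
lncRNA x disease association matrix, the lncRNA sequence set, and the
disease-ontology DAG — carry the canonical entity orderings that every
downstream module (similarity views, embeddings, pair features) reuses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AssociationMatrix",
    "SequenceSet",
    "OntologyDAG",
    "read_associations",
    "read_fasta",
    "read_ontology",
    "read_matrix",
    "write_matrix",
]

_NUCLEOTIDES = frozenset("ACGT")


@dataclass
class AssociationMatrix:
    """Binary adjacency matrix LD between lncRNAs (rows) and diseases (columns).

    LD[i, j] = 1 iff lncRNA i is known to be associated with disease j.  The
    row/column orders are the canonical entity orders used by every other
    module in one run.
    """

    values: np.ndarray
    lncrna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        L, T = self.values.shape
        if len(self.lncrna_ids) != L or len(self.disease_ids) != T:
            raise ValueError("axis label counts do not match matrix shape")
        for axis, ids in (("lncrna", self.lncrna_ids), ("disease", self.disease_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {axis} ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def lncrna_index(self, lncrna_id: str) -> int:
        return self.lncrna_ids.index(lncrna_id)

    def disease_index(self, disease_id: str) -> int:
        return self.disease_ids.index(disease_id)

    def masked(self, zero_cells: np.ndarray) -> "AssociationMatrix":
        """Copy with the given boolean (L, T) cell mask forced to 0."""
        values = self.values.copy()
        values[np.asarray(zero_cells, dtype=bool)] = 0
        return AssociationMatrix(values, list(self.lncrna_ids), list(self.disease_ids))


@dataclass
class SequenceSet:
    """Nucleotide sequences keyed by lncRNA id, normalized to upper-case ACGT."""

    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for {name!r}")
            extra = set(seq) - _NUCLEOTIDES
            if extra:
                raise ValueError(
                    f"sequence {name!r} has characters outside ACGT after "
                    f"normalization: {sorted(extra)}"
                )

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class OntologyDAG:
    """Disease-term hierarchy as a child -> parent edge set, acyclic by contract."""

    edges: set[tuple[str, str]]
    terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        graph.add_edges_from(self.edges)  # edge direction: child -> parent
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"ontology edges contain a cycle: {cycle}")
        self.terms = set(graph.nodes)
        self._graph = graph

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    def ancestor_closure(self, term: str) -> set[str]:
        """The term together with all its ancestors (D(d) in Wang's method)."""
        if term not in self._graph:
            return set()
        return {term} | nx.descendants(self._graph, term)

    def children_in(self, term: str, closure: set[str]) -> list[str]:
        """Direct children of ``term`` that lie inside an ancestor closure."""
        return [c for c in self._graph.predecessors(term) if c in closure]


def _read_tsv_pairs(path, what: str) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns in "
                    f"{what} file, got {len(fields)}"
                )
            pairs.append((fields[0].strip(), fields[1].strip()))
    return pairs


def read_associations(
    path,
    lncrna_universe: Sequence[str] | None = None,
    disease_universe: Sequence[str] | None = None,
) -> AssociationMatrix:
    """Read a two-column (lncrna_id, disease_id) TSV into an AssociationMatrix.

    Duplicate lines collapse to a single 1.  Axis order follows the supplied
    universes when given, else first appearance in the file.  An optional
    header line named ``lncrna_id<TAB>disease_id`` is skipped.
    """
    pairs = _read_tsv_pairs(path, "association")
    if pairs and [p.lower() for p in pairs[0]] == ["lncrna_id", "disease_id"]:
        pairs = pairs[1:]
    if not pairs:
        raise ValueError(f"association file {path} lists no pairs")

    def build_index(universe, seen, axis):
        if universe is not None:
            order = list(universe)
            unknown = [x for x in seen if x not in set(order)]
            if unknown:
                raise ValueError(
                    f"{axis} id {unknown[0]!r} in {path} is absent from the "
                    f"supplied {axis} universe"
                )
        else:
            order = list(dict.fromkeys(seen))
        return order, {name: i for i, name in enumerate(order)}

    lnc_seen = [l for l, _ in pairs]
    dis_seen = [d for _, d in pairs]
    lnc_order, lnc_idx = build_index(lncrna_universe, lnc_seen, "lncrna")
    dis_order, dis_idx = build_index(disease_universe, dis_seen, "disease")

    values = np.zeros((len(lnc_order), len(dis_order)), dtype=np.int8)
    for l, d in pairs:
        values[lnc_idx[l], dis_idx[d]] = 1
    return AssociationMatrix(values, lnc_order, dis_order)


def write_associations(path, ld: AssociationMatrix) -> None:
    """Write the 1-cells of an AssociationMatrix as a two-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("lncrna_id\tdisease_id\n")
        rows, cols = np.nonzero(ld.values)
        for i, j in zip(rows, cols):
            fh.write(f"{ld.lncrna_ids[i]}\t{ld.disease_ids[j]}\n")


def read_fasta(path) -> SequenceSet:
    """Read a multi-record FASTA; upper-case, U -> T; duplicate ids are fatal."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {rec.id!r}")
        records[rec.id] = seq
    return SequenceSet(records)


def write_fasta(path, seqs: SequenceSet, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in seqs.records:
            fh.write(f">{name}\n")
            seq = seqs[name]
            for start in range(0, len(seq), width):
                fh.write(seq[start : start + width] + "\n")


def read_ontology(path) -> OntologyDAG:
    """Read a (child, parent) edge-list TSV; cycles are rejected on load."""
    pairs = _read_tsv_pairs(path, "ontology edge")
    if pairs and [p.lower() for p in pairs[0]] == ["child", "parent"]:
        pairs = pairs[1:]
    return OntologyDAG(edges=set(pairs))


def write_ontology(path, dag: OntologyDAG) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("child\tparent\n")
        for child, parent in sorted(dag.edges):
            fh.write(f"{child}\t{parent}\n")


def write_matrix(path, values: np.ndarray, row_ids: Sequence[str], col_ids: Sequence[str]) -> None:
    """Write a labeled dense matrix as TSV, 12 significant digits."""
    frame = pd.DataFrame(np.asarray(values), index=list(row_ids), columns=list(col_ids))
    # 17 significant digits: float64 round-trips bit-exactly
    frame.to_csv(path, sep="\t", float_format="%.17g", index_label="id")


def read_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a labeled dense matrix TSV written by :func:`write_matrix`."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # pandas raises several flavours on ragged input
        raise ValueError(f"cannot parse matrix file {path}: {exc}") from exc
    if frame.columns.size and all(_is_number(c) for c in frame.columns):
        raise ValueError(f"matrix file {path} is missing a header row of column labels")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"matrix file {path} contains non-numeric cells")
    return values.astype(float), [str(i) for i in frame.index], [str(c) for c in frame.columns]


def _is_number(token: str) -> bool:
    try:
        float(token)
    except (TypeError, ValueError):
        return False
    return True
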