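"""Bipartite peptide-protein graphs and protein-inference ambiguity.

Peptide-to-protein mappings form a bipartite graph: peptide vertices, protein
vertices, an edge where a peptide maps to a protein. Its incidence matrix I
(peptides along rows, proteins along columns) yields the protein adjacency
matrix A = I^T I, whose off-diagonal entry (i, j) counts peptides shared by
proteins i and j and whose diagonal holds per-protein peptide counts.
Connected components (CCs) of A partition the proteins: a single-protein CC —
a protein with only specific peptides — is an unambiguous identification,
while a multi-protein CC bundles proteins entangled by shared peptides.

For large datasets the multi-protein CCs can be computed on a pruned matrix
from which proteins sharing no peptide (and their peptides) were removed;
single-protein CCs are recoverable from the original matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cs_cc

from .msio import _open_text

SINGLE_PROTEIN = "SINGLE_PROTEIN"
MULTI_PROTEIN = "MULTI_PROTEIN"


@dataclass
class IncidenceMatrix:
    """0/1 peptide x protein membership matrix.

    Row/column order is first-appearance order of the input pairs, so every
    derived artifact is reproducible byte-for-byte.
    """

    peptides: list
    proteins: list
    matrix: sp.csr_matrix

    @classmethod
    def from_pairs(cls, pairs) -> "IncidenceMatrix":
        """Build from (peptide, protein accession) pairs, deduplicated."""
        pairs = list(pairs)
        if not pairs:
            raise ValueError("no peptide-protein pairs")
        pep_idx: dict = {}
        prot_idx: dict = {}
        rows, cols = [], []
        seen = set()
        for pep, prot in pairs:
            if (pep, prot) in seen:
                continue
            seen.add((pep, prot))
            rows.append(pep_idx.setdefault(pep, len(pep_idx)))
            cols.append(prot_idx.setdefault(prot, len(prot_idx)))
        m = sp.csr_matrix(
            (np.ones(len(rows), dtype=np.int64), (rows, cols)),
            shape=(len(pep_idx), len(prot_idx)),
        )
        return cls(list(pep_idx), list(prot_idx), m)

    def pairs(self):
        coo = self.matrix.tocoo()
        return [(self.peptides[i], self.proteins[j]) for i, j in zip(coo.row, coo.col)]

    def peptide_degree(self) -> np.ndarray:
        """Number of proteins each peptide maps to."""
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def specific_peptides(self) -> set:
        """Peptides mapping to exactly one protein."""
        deg = self.peptide_degree()
        return {p for p, d in zip(self.peptides, deg) if d == 1}

    def proteins_of(self, peptide: str) -> set:
        i = self.peptides.index(peptide)
        return {self.proteins[j] for j in self.matrix[i].indices}

    def peptides_of(self, protein: str) -> set:
        j = self.proteins.index(protein)
        col = self.matrix.getcol(j).tocoo()
        return {self.peptides[i] for i in col.row}

    def subset(self, keep_peptides=None, keep_proteins=None) -> "IncidenceMatrix":
        """Restrict to given peptides/proteins (deterministic row-major order)."""
        kp = set(self.peptides if keep_peptides is None else keep_peptides)
        kq = set(self.proteins if keep_proteins is None else keep_proteins)
        kept = [
            (pep, prot)
            for pep, prot in self.pairs()
            if pep in kp and prot in kq
        ]
        if not kept:
            return IncidenceMatrix([], [], sp.csr_matrix((0, 0), dtype=np.int64))
        return IncidenceMatrix.from_pairs(kept)


@dataclass
class AdjacencyMatrix:
    """Protein x protein shared-peptide counts, A = I^T I."""

    proteins: list
    matrix: sp.csr_matrix


@dataclass(frozen=True)
class ConnectedComponent:
    """A maximal set of proteins linked by shared peptides, with their peptides."""

    proteins: tuple
    peptides: tuple
    kind: str

    @property
    def n_proteins(self):
        return len(self.proteins)


@dataclass(frozen=True)
class ProteinGroup:
    """Proteins identified by exactly the same peptide set."""

    proteins: tuple
    peptides: tuple
    kind: str  # "SINGLE" or "MULTI"


@dataclass
class AmbiguityMetrics:
    n_cc: int
    n_single_protein_cc: int
    n_multi_protein_cc: int
    pct_single_protein_cc: float
    pct_specific_peptides: float
    protein_to_gene_ratios: list

    def as_dict(self):
        return {
            "n_cc": self.n_cc,
            "n_single_protein_cc": self.n_single_protein_cc,
            "n_multi_protein_cc": self.n_multi_protein_cc,
            "pct_single_protein_cc": self.pct_single_protein_cc,
            "pct_specific_peptides": self.pct_specific_peptides,
            "protein_to_gene_ratios": list(self.protein_to_gene_ratios),
        }


def read_pairs_table(path):
    """Read a two-column (peptide, protein) TSV, one protein per line."""
    df = pd.read_csv(_open_text(path), sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"pairs table {path} needs columns peptide, protein")
    return list(zip(df[cols[0]], df[cols[1]]))


def build_incidence(pairs) -> IncidenceMatrix:
    return IncidenceMatrix.from_pairs(pairs)


def adjacency_from_incidence(I: IncidenceMatrix) -> AdjacencyMatrix:
    a = (I.matrix.T @ I.matrix).tocsr()
    return AdjacencyMatrix(list(I.proteins), a)


def _components_to_ccs(labels, proteins, I: IncidenceMatrix):
    """Group proteins by component label and annotate peptides from I."""
    prot_pos = {p: j for j, p in enumerate(I.proteins)}
    by_label: dict = {}
    for prot, lab in zip(proteins, labels):
        by_label.setdefault(lab, []).append(prot)
    csc = I.matrix.tocsc()
    ccs = []
    # deterministic order: by first-appearance of the first member protein
    for lab in sorted(by_label, key=lambda l: min(prot_pos[p] for p in by_label[l])):
        members = sorted(by_label[lab], key=lambda p: prot_pos[p])
        pep_rows = sorted(
            {int(i) for p in members for i in csc.getcol(prot_pos[p]).tocoo().row}
        )
        ccs.append(
            ConnectedComponent(
                proteins=tuple(members),
                peptides=tuple(I.peptides[i] for i in pep_rows),
                kind=SINGLE_PROTEIN if len(members) == 1 else MULTI_PROTEIN,
            )
        )
    return ccs


def connected_components(A: AdjacencyMatrix, I: IncidenceMatrix):
    """Connected components of the protein adjacency graph.

    Proteins are partitioned via nonzero off-diagonal adjacency; each CC is
    annotated with every peptide mapping to its member proteins.
    """
    n, labels = _cs_cc(A.matrix, directed=False)
    return _components_to_ccs(labels, A.proteins, I)


def reduced_cc(I: IncidenceMatrix):
    """Multi-protein CCs computed on the pruned incidence matrix.

    Proteins sharing no peptide, and the peptides unique to them, are removed
    before the adjacency cross-product; the components of the pruned matrix
    are exactly the multi-protein CCs of the full computation. Peptides are
    annotated from the original matrix so results coincide with
    :func:`connected_components`.
    """
    deg = I.peptide_degree()
    shared = {p for p, d in zip(I.peptides, deg) if d >= 2}
    sharing_proteins = set()
    coo = I.matrix.tocoo()
    for i, j in zip(coo.row, coo.col):
        if deg[i] >= 2:
            sharing_proteins.add(I.proteins[j])
    if not sharing_proteins:
        return []
    pruned = I.subset(keep_peptides=shared, keep_proteins=sharing_proteins)
    a = adjacency_from_incidence(pruned)
    _, labels = _cs_cc(a.matrix, directed=False)
    return _components_to_ccs(labels, pruned.proteins, I)


def protein_groups(I: IncidenceMatrix):
    """Partition proteins by exact equality of their peptide sets.

    Subset relations are not merged: a protein whose peptides are a strict
    subset of another's forms its own group.
    """
    csc = I.matrix.tocsc()
    key_to_members: dict = {}
    order = []
    for j, prot in enumerate(I.proteins):
        key = frozenset(int(i) for i in csc.getcol(j).tocoo().row)
        if key not in key_to_members:
            key_to_members[key] = []
            order.append(key)
        key_to_members[key].append(prot)
    groups = []
    for key in order:
        members = key_to_members[key]
        peps = tuple(I.peptides[i] for i in sorted(key))
        groups.append(
            ProteinGroup(
                proteins=tuple(members),
                peptides=peps,
                kind="SINGLE" if len(members) == 1 else "MULTI",
            )
        )
    return groups


def ambiguity_metrics(ccs, I: IncidenceMatrix, gene_map=None) -> AmbiguityMetrics:
    """Summary metrics of protein-inference ambiguity.

    ``pct_single_protein_cc`` is the percentage of CCs holding one protein;
    ``pct_specific_peptides`` the percentage of peptides mapping to exactly
    one protein; per multi-protein CC, the protein-to-gene ratio is
    |proteins| / |distinct genes|, counting unannotated proteins as their own
    gene.
    """
    gene_map = gene_map or {}
    n_single = sum(1 for c in ccs if c.kind == SINGLE_PROTEIN)
    n_multi = sum(1 for c in ccs if c.kind == MULTI_PROTEIN)
    n_cc = len(ccs)
    n_spec = len(I.specific_peptides())
    ratios = []
    for c in ccs:
        if c.kind != MULTI_PROTEIN:
            continue
        genes = {gene_map.get(p, p) for p in c.proteins}
        ratios.append(len(c.proteins) / len(genes))
    return AmbiguityMetrics(
        n_cc=n_cc,
        n_single_protein_cc=n_single,
        n_multi_protein_cc=n_multi,
        pct_single_protein_cc=100.0 * n_single / n_cc if n_cc else 0.0,
        pct_specific_peptides=100.0 * n_spec / len(I.peptides) if I.peptides else 0.0,
        protein_to_gene_ratios=ratios,
    )


def cc_graph(cc: ConnectedComponent, I: IncidenceMatrix, expression=None) -> nx.Graph:
    """Bipartite networkx graph of one CC, with vertex annotations."""
    specific = I.specific_peptides()
    g = nx.Graph()
    for prot in cc.proteins:
        attrs = {"kind": "protein"}
        if expression is not None:
            attrs["expressed"] = bool(prot in expression)
        g.add_node(prot, **attrs)
    for pep in cc.peptides:
        g.add_node(pep, kind="peptide", specific=bool(pep in specific))
    members = set(cc.proteins)
    for pep in cc.peptides:
        for prot in I.proteins_of(pep) & members:
            g.add_edge(pep, prot)
    return g


def export_cc(cc, I: IncidenceMatrix, path, fmt="graphml", expression=None):
    """Write one CC as a bipartite graph file (GraphML or DOT)."""
    g = cc_graph(cc, I, expression=expression)
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "dot":
        _write_dot(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def _write_dot(g: nx.Graph, path):
    # minimal DOT writer; pydot/pygraphviz are deliberately not required
    def q(s):
        return '"' + str(s).replace('"', r"\"") + '"'

    with _open_text(path, "wt") as fh:
        fh.write("graph bipartite {\n")
        for node, attrs in g.nodes(data=True):
            kv = ", ".join(f"{k}={q(v)}" for k, v in sorted(attrs.items()))
            fh.write(f"  {q(node)} [{kv}];\n")
        for u, v in g.edges():
            fh.write(f"  {q(u)} -- {q(v)};\n")
        fh.write("}\n")
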