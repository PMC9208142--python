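"""Transcriptome-informed reduction of a reference protein database.

A reduced database is a plain subset of the reference FASTA: a protein is
retained iff at least one of its transcripts is expressed in the
sample-matched transcriptome (FPKM strictly above a threshold, default 1).
Ensembl guarantees a one-to-one transcript-to-protein correspondence, but the
mapping type tolerates many-to-many annotations; any expressed transcript
retains the protein. Transcript identifiers are version-stripped before
matching because Ensembl dumps are inconsistent across releases.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .msio import _open_text

logger = logging.getLogger(__name__)

_VERSION_RE = re.compile(r"\.\d+$")


def strip_version(identifier: str) -> str:
    """Drop a trailing Ensembl-style version suffix (ENST...​.3 -> ENST...)."""
    return _VERSION_RE.sub("", identifier)


@dataclass
class ExpressionSet:
    """Transcript abundances (FPKM) with an expression threshold."""

    records: dict
    threshold: float = 1.0

    def __post_init__(self):
        clean = {}
        for tid, fpkm in self.records.items():
            fpkm = float(fpkm)
            if not fpkm >= 0.0:
                raise ValueError(f"negative or non-finite FPKM for {tid!r}")
            clean[strip_version(tid)] = fpkm
        self.records = clean


@dataclass
class ProteinTranscriptMap:
    """protein accession -> transcript ids, with optional gene annotation."""

    pairs: dict
    gene_map: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pairs = {
            acc: {strip_version(t) for t in tids} for acc, tids in self.pairs.items()
        }
        for acc, tids in self.pairs.items():
            if not acc or not tids:
                raise ValueError("empty protein accession or transcript set in map")


def read_expression_table(path, threshold: float = 1.0) -> ExpressionSet:
    """Read a two-column TSV (transcript_id, FPKM; header required)."""
    df = pd.read_csv(_open_text(path), sep="\t")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"expression table {path} needs columns transcript_id, FPKM")
    records = dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(float)))
    return ExpressionSet(records, threshold=threshold)


def read_mapping_table(path) -> ProteinTranscriptMap:
    """Read a protein_id, transcript_id[, gene_id] TSV."""
    df = pd.read_csv(_open_text(path), sep="\t")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"mapping table {path} needs protein_id, transcript_id")
    pairs: dict = {}
    genes: dict = {}
    for row in df.itertuples(index=False):
        acc = str(row[0])
        pairs.setdefault(acc, set()).add(str(row[1]))
        if len(cols) >= 3 and not pd.isna(row[2]):
            genes[acc] = str(row[2])
    return ProteinTranscriptMap(pairs, gene_map=genes)


def expressed_transcripts(expr: ExpressionSet) -> set:
    """Transcripts expressed strictly above the threshold (FPKM > threshold)."""
    return {tid for tid, fpkm in expr.records.items() if fpkm > expr.threshold}


def expressed_proteins(expr: ExpressionSet, mapping: ProteinTranscriptMap) -> set:
    """Proteins with at least one expressed transcript.

    Proteins absent from the mapping are not expressed by definition.
    """
    on = expressed_transcripts(expr)
    return {acc for acc, tids in mapping.pairs.items() if tids & on}


def reduce_database(db, expr: ExpressionSet, mapping: ProteinTranscriptMap):
    """Subset a target database to proteins whose transcript is expressed.

    Record identity is preserved (the output is literally a subset of the
    input list). Proteins absent from the mapping are dropped and their count
    logged. Decoys are generated afterwards, from the reduced set.
    """
    if any(r.is_decoy for r in db):
        raise ValueError("reduce_database expects a target-only database")
    keep = expressed_proteins(expr, mapping)
    unmapped = sum(1 for r in db if r.accession not in mapping.pairs)
    if unmapped:
        logger.info(
            "reduce_database: %d of %d proteins absent from the transcript map "
            "were dropped", unmapped, len(db),
        )
    reduced = [r for r in db if r.accession in keep]
    if not reduced:
        raise ValueError("reduced database is empty; nothing searchable")
    return reduced
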