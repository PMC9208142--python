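"""Reading/writing of protein databases and PSM tables, decoy generation,
and PSM validation prefilters.

A peptide-spectrum match (PSM) assigns an MS/MS spectrum (a *query*) to a
candidate peptide with a search-engine score, higher meaning better. A search
against a concatenated target-decoy database yields, per spectrum, candidate
matches to real (target) proteins and to reversed (decoy) proteins. Before any
FDR control, search results are prefiltered the way post-search validation
tools do it:

1. candidates whose score lies within a small tolerance of the spectrum's best
   score are considered of equal quality and share *pretty rank* 1;
2. a single best-scoring PSM is retained per spectrum (ties among pretty-rank-1
   candidates broken uniformly at random, seeded, so that targets and decoys
   keep an equal chance of winning);
3. PSMs whose peptide is shorter than a minimum length are discarded.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_DECOY_PREFIX = "rev_"
DEFAULT_CONTAMINANT_PREFIX = "CON_"

# 20 canonical residues plus the common ambiguity/rare codes X, B, Z, U.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYXBZU")

PSM_COLUMNS = ["spectrum_id", "peptide", "proteins", "score", "is_decoy"]


@dataclass(frozen=True)
class ProteinRecord:
    """One sequence of a protein database."""

    accession: str
    sequence: str
    is_decoy: bool = False
    is_contaminant: bool = False

    def __post_init__(self):
        if not self.accession:
            raise ValueError("empty accession")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for {self.accession!r}")


@dataclass(frozen=True)
class Psm:
    """A single candidate match of one spectrum to one peptide.

    ``proteins`` holds every accession the peptide maps to; ``is_decoy`` is
    true iff all of them are decoys.
    """

    spectrum_id: str
    peptide: str
    proteins: frozenset
    score: float
    is_decoy: bool = False
    is_contaminant: bool = False
    rank: int = 1

    def __post_init__(self):
        if not np.isfinite(self.score):
            raise ValueError(f"non-finite score for spectrum {self.spectrum_id!r}")
        if len(self.peptide) < 1:
            raise ValueError(f"empty peptide for spectrum {self.spectrum_id!r}")
        if not self.proteins:
            raise ValueError(f"empty protein set for spectrum {self.spectrum_id!r}")


@dataclass
class PsmTable:
    """A list of PSMs plus provenance metadata.

    After :func:`apply_prefilters` the table holds at most one PSM per
    spectrum.
    """

    psms: list
    database: str = ""
    label: str = ""

    def __len__(self):
        return len(self.psms)

    def __iter__(self):
        return iter(self.psms)

    def spectrum_ids(self):
        return [p.spectrum_id for p in self.psms]

    def scores(self):
        return np.array([p.score for p in self.psms], dtype=float)

    def decoy_mask(self):
        return np.array([p.is_decoy for p in self.psms], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spectrum_id": [p.spectrum_id for p in self.psms],
                "peptide": [p.peptide for p in self.psms],
                "proteins": [";".join(sorted(p.proteins)) for p in self.psms],
                "score": [p.score for p in self.psms],
                "is_decoy": [p.is_decoy for p in self.psms],
            }
        )


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _locate_bad_char(path, accession, char):
    """Best-effort line number of an offending sequence character."""
    try:
        with _open_text(path) as fh:
            in_record = False
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(">"):
                    in_record = line[1:].split()[0] == accession if line[1:].split() else False
                elif in_record and char in line.upper():
                    return lineno
    except OSError:
        pass
    return None


def read_fasta(
    path,
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
    contaminant_prefix: str = DEFAULT_CONTAMINANT_PREFIX,
) -> list:
    """Read a FASTA protein database into a list of :class:`ProteinRecord`.

    The accession is the first whitespace-delimited token of the header.
    Decoy and contaminant status are inferred from accession prefixes.
    Gzip-compressed input (``.gz``) is transparently handled.
    """
    records = []
    seen = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            accession = rec.id
            seq = str(rec.seq).upper()
            if accession in seen:
                raise ValueError(f"duplicate accession {accession!r} in {path}")
            seen.add(accession)
            bad = set(seq) - VALID_RESIDUES
            if bad:
                ch = sorted(bad)[0]
                lineno = _locate_bad_char(path, accession, ch)
                where = f"line {lineno}" if lineno else f"record {accession!r}"
                raise ValueError(
                    f"non-amino-acid character {ch!r} in sequence of "
                    f"{accession!r} ({where})"
                )
            records.append(
                ProteinRecord(
                    accession=accession,
                    sequence=seq,
                    is_decoy=accession.startswith(decoy_prefix),
                    is_contaminant=accession.startswith(contaminant_prefix),
                )
            )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(db, path):
    """Write records as FASTA, sequences wrapped at 60 characters."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in db
    ]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecs)


def generate_decoys(db, prefix: str = DEFAULT_DECOY_PREFIX) -> list:
    """Generate one decoy per target by full sequence reversal.

    The decoy accession is ``prefix`` + target accession. The input must not
    already contain decoys; output size equals input size, so that an
    equivalent number of decoy sequences can be appended to the target space.
    """
    if any(r.is_decoy for r in db):
        raise ValueError("database already contains decoy records")
    return [
        ProteinRecord(
            accession=prefix + r.accession,
            sequence=r.sequence[::-1],
            is_decoy=True,
            is_contaminant=r.is_contaminant,
        )
        for r in db
    ]


def _classify_proteins(
    accessions,
    decoy_prefix: str,
    contaminant_prefix: str,
):
    """Resolve a raw accession set into (proteins, is_decoy, is_contaminant).

    A match mixing target and decoy accessions is classified target and its
    decoy accessions are dropped: reversed tryptic peptides occasionally
    coincide with target peptides, and counting such matches as decoys would
    inflate the decoy count.
    """
    accs = frozenset(accessions)
    targets = frozenset(a for a in accs if not a.startswith(decoy_prefix))
    if targets:
        accs = targets
        is_decoy = False
    else:
        is_decoy = True
    is_contaminant = any(
        a[len(decoy_prefix):].startswith(contaminant_prefix)
        if a.startswith(decoy_prefix)
        else a.startswith(contaminant_prefix)
        for a in accs
    )
    return accs, is_decoy, is_contaminant


def read_psm_table(
    path,
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
    contaminant_prefix: str = DEFAULT_CONTAMINANT_PREFIX,
    database: str = "",
    label: str = "",
) -> PsmTable:
    """Read a PSM table from TSV.

    Required columns: ``spectrum_id``, ``peptide``, ``proteins``
    (semicolon-separated accessions), ``score``. Optional ``is_decoy``; when
    absent, decoy status is inferred from accession prefixes.
    """
    df = pd.read_csv(_open_text(path), sep="\t", dtype=str, keep_default_na=False)
    for col in ("spectrum_id", "peptide", "proteins", "score"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        row = int(np.flatnonzero(scores.isna().to_numpy())[0])
        raise ValueError(
            f"unparseable score {df['score'].iloc[row]!r} at data row {row + 1}"
        )
    has_flag = "is_decoy" in df.columns
    psms = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = [a for a in str(row.proteins).split(";") if a]
        if not raw:
            raise ValueError(f"empty proteins field at data row {i + 1}")
        accs, inferred_decoy, is_cont = _classify_proteins(
            raw, decoy_prefix, contaminant_prefix
        )
        if has_flag and str(row.is_decoy).strip() != "":
            is_decoy = str(row.is_decoy).strip().lower() in ("1", "true", "t", "yes")
        else:
            is_decoy = inferred_decoy
        psms.append(
            Psm(
                spectrum_id=row.spectrum_id,
                peptide=row.peptide,
                proteins=accs,
                score=float(scores.iloc[i]),
                is_decoy=is_decoy,
                is_contaminant=is_cont,
            )
        )
    return PsmTable(psms, database=database, label=label)


def write_psm_table(table: PsmTable, path):
    """Write a PSM table as TSV (UTF-8, tab separator, '.' decimal)."""
    table.to_frame().to_csv(_open_text(path, "wt"), sep="\t", index=False)


def apply_prefilters(
    table: PsmTable,
    tie_tolerance: float = 0.1,
    min_len: int = 7,
    seed: int = 0,
) -> PsmTable:
    """Apply the standard post-search validation prefilters.

    Per spectrum, candidates whose score differs from the best by strictly
    less than ``tie_tolerance`` share pretty rank 1; exactly one of them is
    retained, chosen uniformly at random (seeded). Retained PSMs with peptide
    length below ``min_len`` are then removed, dropping their spectrum
    entirely. The output carries at most one PSM per spectrum and is
    idempotent under re-application.
    """
    if tie_tolerance < 0:
        raise ValueError("tie_tolerance must be >= 0")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    rng = np.random.default_rng(seed)
    by_spectrum: dict = {}
    order = []
    for p in table.psms:
        if p.spectrum_id not in by_spectrum:
            by_spectrum[p.spectrum_id] = []
            order.append(p.spectrum_id)
        by_spectrum[p.spectrum_id].append(p)
    kept = []
    for sid in order:
        cands = by_spectrum[sid]
        best = max(c.score for c in cands)
        rank1 = [c for c in cands if best - c.score < tie_tolerance]
        choice = rank1[rng.integers(len(rank1))] if len(rank1) > 1 else rank1[0]
        if len(choice.peptide) >= min_len:
            kept.append(replace(choice, rank=1))
    return PsmTable(kept, database=table.database, label=table.label)
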