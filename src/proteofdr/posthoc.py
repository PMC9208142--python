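"""Transcriptome-informed post hoc filtering of full-database identifications.

Instead of searching a reduced database, identifications from the full search
can be filtered afterwards using transcript expression. Three options of
increasing conservatism operate on the peptide-protein incidence matrix
(option 2 is the default, the variant employed for the reference analyses):

* option 1 — remove every protein without transcript expression, and the
  peptides mapping only to removed proteins (specific or shared among them);
* option 2 — remove proteins with no transcript expression AND no specific
  peptide, then the peptides only shared between removed proteins; a protein
  carrying a specific peptide is immune regardless of expression;
* option 3 — additionally require that every peptide of a removed protein is
  shared with at least one retained protein, so that no peptide identification
  is lost; only proteins are filtered out.

Peptide specificity is always evaluated on the unfiltered input matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dbtools import ExpressionSet, ProteinTranscriptMap, expressed_proteins
from .pepgraph import IncidenceMatrix

OPT1, OPT2, OPT3 = "OPT1", "OPT2", "OPT3"


@dataclass
class FilterReport:
    option: str
    removed_proteins: set
    removed_peptides: set
    incidence: IncidenceMatrix

    def as_dict(self):
        return {
            "option": self.option,
            "n_removed_proteins": len(self.removed_proteins),
            "n_removed_peptides": len(self.removed_peptides),
            "n_retained_proteins": len(self.incidence.proteins),
            "n_retained_peptides": len(self.incidence.peptides),
        }


def _protein_peptides(I: IncidenceMatrix):
    csc = I.matrix.tocsc()
    return {
        prot: {int(i) for i in csc.getcol(j).tocoo().row}
        for j, prot in enumerate(I.proteins)
    }


def _finish(I, option, removed_proteins):
    """Drop removed proteins, then peptides left with no retained parent."""
    prot_peps = _protein_peptides(I)
    retained = [p for p in I.proteins if p not in removed_proteins]
    covered = set()
    for p in retained:
        covered |= prot_peps[p]
    removed_peptides = {
        pep for i, pep in enumerate(I.peptides) if i not in covered
    }
    keep_peps = [p for p in I.peptides if p not in removed_peptides]
    filtered = I.subset(keep_peptides=keep_peps, keep_proteins=retained)
    return FilterReport(option, set(removed_proteins), removed_peptides, filtered)


def filter_option1(
    I: IncidenceMatrix, expr: ExpressionSet, mapping: ProteinTranscriptMap
) -> FilterReport:
    """Remove unexpressed proteins and peptides mapping only to them."""
    on = expressed_proteins(expr, mapping)
    removed = {p for p in I.proteins if p not in on}
    return _finish(I, OPT1, removed)


def filter_option2(
    I: IncidenceMatrix, expr: ExpressionSet, mapping: ProteinTranscriptMap
) -> FilterReport:
    """Remove unexpressed proteins lacking specific peptides.

    Peptides only shared between removed proteins are removed with them.
    """
    on = expressed_proteins(expr, mapping)
    deg = I.peptide_degree()
    prot_peps = _protein_peptides(I)
    removed = {
        p
        for p in I.proteins
        if p not in on and not any(deg[i] == 1 for i in prot_peps[p])
    }
    return _finish(I, OPT2, removed)


def filter_option3(
    I: IncidenceMatrix, expr: ExpressionSet, mapping: ProteinTranscriptMap
) -> FilterReport:
    """Remove unexpressed, specific-peptide-free proteins whose every peptide
    stays covered by a retained protein; no peptide identification is lost.

    Candidates are visited in first-appearance order and removed greedily:
    a candidate goes only if each of its peptides maps to some other protein
    not removed so far. With mutually dependent candidates (peptides shared
    only among themselves) the earlier one is removed and the later one kept,
    which preserves every peptide; the scan is repeated until stable, and the
    outcome is deterministic.
    """
    on = expressed_proteins(expr, mapping)
    deg = I.peptide_degree()
    prot_peps = _protein_peptides(I)
    pep_prots: dict = {}
    for prot, peps in prot_peps.items():
        for i in peps:
            pep_prots.setdefault(i, set()).add(prot)
    candidates = [
        p
        for p in I.proteins
        if p not in on and not any(deg[i] == 1 for i in prot_peps[p])
    ]
    removed: set = set()
    changed = True
    while changed:
        changed = False
        for p in candidates:
            if p in removed:
                continue
            if all(pep_prots[i] - removed - {p} for i in prot_peps[p]):
                removed.add(p)
                changed = True
    report = _finish(I, OPT3, removed)
    assert not report.removed_peptides  # contract: option 3 keeps all peptides
    return report


_FILTERS = {OPT1: filter_option1, OPT2: filter_option2, OPT3: filter_option3,
            1: filter_option1, 2: filter_option2, 3: filter_option3}


def posthoc_filter(I, expr, mapping, option=OPT2) -> FilterReport:
    """Apply one of the three filter options (default option 2)."""
    try:
        fn = _FILTERS[option]
    except KeyError:
        raise ValueError(f"unknown filter option {option!r}") from None
    return fn(I, expr, mapping)
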