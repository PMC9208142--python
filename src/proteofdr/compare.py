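"""Spectrum-level comparison of a full-database and a reduced-database search.

Each spectrum's best match in the two searches is paired and classified as
target, decoy or no match on either side. A *reallocation* is a spectrum
matched in both searches but to different peptides. An *additional
identification* is a spectrum validated as a target in the reduced search but
not in the full search; it is attributed either to the lower score cutoff the
reduced search obtains at the same FDR level, or — when the reduced-search
score would also pass the full-database cutoff — to a *pure reallocation*,
i.e. a genuine change of best match rather than a threshold effect.

The valid-decoy loss table asks the converse question: what happens, under the
full-database cutoff, to the spectra that matched valid targets or valid
decoys in the full search once the database shrinks. Decoys, being random
matches, lose their best candidates far more often than targets whose correct
sequence was deliberately retained; the resulting decoy deficit is what drags
the TDC cutoff down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .msio import PsmTable

TARGET, DECOY, NO_MATCH = "TARGET", "DECOY", "NO_MATCH"


@dataclass(frozen=True)
class MatchSide:
    kind: str  # TARGET / DECOY / NO_MATCH
    peptide: str = ""
    score: float = float("-inf")


@dataclass(frozen=True)
class MatchPair:
    spectrum_id: str
    full: MatchSide
    reduced: MatchSide

    @property
    def reallocated(self) -> bool:
        """Both searches matched this spectrum, to different peptides."""
        return (
            self.full.kind != NO_MATCH
            and self.reduced.kind != NO_MATCH
            and self.full.peptide != self.reduced.peptide
        )


@dataclass
class AdditionalIdBreakdown:
    """Decomposition of reduced-search additional identifications.

    Spectrum-level counts; ``peptides`` holds the same decomposition after
    deduplicating by peptide sequence against the full-search valid peptide
    set. Categories are disjoint and sum to the total.
    """

    n_additional_total: int = 0
    n_lower_cutoff_no_realloc: int = 0
    n_lower_cutoff_realloc_from: dict = field(
        default_factory=lambda: {TARGET: 0, DECOY: 0, NO_MATCH: 0}
    )
    n_pure_reallocations: int = 0
    peptides: dict = field(default_factory=dict)

    def category_sum(self):
        return (
            self.n_lower_cutoff_no_realloc
            + sum(self.n_lower_cutoff_realloc_from.values())
            + self.n_pure_reallocations
        )

    def as_dict(self):
        return {
            "n_additional_total": self.n_additional_total,
            "n_lower_cutoff_no_realloc": self.n_lower_cutoff_no_realloc,
            "n_lower_cutoff_realloc_from": dict(self.n_lower_cutoff_realloc_from),
            "n_pure_reallocations": self.n_pure_reallocations,
            "peptides": dict(self.peptides),
        }


def _sides(table: PsmTable):
    sides = {}
    for p in table.psms:
        if p.spectrum_id in sides:
            raise ValueError(f"duplicate spectrum {p.spectrum_id!r}; prefilter first")
        sides[p.spectrum_id] = MatchSide(
            kind=DECOY if p.is_decoy else TARGET, peptide=p.peptide, score=p.score
        )
    return sides


def pair_searches(full: PsmTable, reduced: PsmTable):
    """One MatchPair per spectrum appearing in either prefiltered table."""
    fs, rs = _sides(full), _sides(reduced)
    no = MatchSide(NO_MATCH)
    order = list(fs)
    order += [s for s in rs if s not in fs]
    return [MatchPair(sid, fs.get(sid, no), rs.get(sid, no)) for sid in order]


def reallocation_score_check(pairs):
    """Score comparison of reallocated spectra between the two searches.

    Returns counts of reallocations whose reduced-search score is lower,
    equal or higher than the full-search score, split by the reduced-side
    match kind, plus the number of reallocations onto a target with a score
    increase — expected to be zero whenever the reduced database is a subset
    of the full one.
    """
    out = {
        kind: {"lower": 0, "equal": 0, "higher": 0} for kind in (TARGET, DECOY)
    }
    n_target_gain = 0
    for p in pairs:
        if not p.reallocated:
            continue
        bucket = out[p.reduced.kind]
        if p.reduced.score < p.full.score:
            bucket["lower"] += 1
        elif p.reduced.score == p.full.score:
            bucket["equal"] += 1
        else:
            bucket["higher"] += 1
            if p.reduced.kind == TARGET:
                n_target_gain += 1
    out["n_target_realloc_score_increase"] = n_target_gain
    return out


def decompose_additional(pairs, cutoff_full: float, cutoff_reduced: float):
    """Classify the reduced-search additional identifications.

    A spectrum is *additional* when its reduced-search PSM is a valid target
    (score >= cutoff_reduced, inclusive) while its full-search side is not a
    valid target (invalid score, decoy, or absent). It is a *pure
    reallocation* when it is a reallocation onto a target whose reduced score
    would also pass the full-database cutoff; otherwise it is attributed to
    the lower cutoff, sub-classified by the full-search match kind.

    Peptide-level counts keep, per category, the additional peptide sequences
    absent from the full search's valid target peptide set; a peptide backed
    by several additional spectra is counted once, in the category of its
    best-scoring spectrum.
    """
    full_valid_peps = {
        p.full.peptide
        for p in pairs
        if p.full.kind == TARGET and p.full.score >= cutoff_full
    }
    br = AdditionalIdBreakdown()
    pep_best: dict = {}  # peptide -> (score, category)
    for p in pairs:
        if p.reduced.kind != TARGET or p.reduced.score < cutoff_reduced:
            continue
        if p.full.kind == TARGET and p.full.score >= cutoff_full:
            continue  # already validated in the full search
        br.n_additional_total += 1
        if p.reallocated and p.reduced.score >= cutoff_full:
            cat = "pure_reallocation"
            br.n_pure_reallocations += 1
        elif p.reallocated:
            cat = f"lower_cutoff_from_{p.full.kind}"
            br.n_lower_cutoff_realloc_from[p.full.kind] += 1
        else:
            cat = "lower_cutoff_no_realloc"
            br.n_lower_cutoff_no_realloc += 1
        pep = p.reduced.peptide
        if pep not in full_valid_peps:
            prev = pep_best.get(pep)
            if prev is None or p.reduced.score > prev[0]:
                pep_best[pep] = (p.reduced.score, cat)
    pep_counts = {
        "n_additional_total": len(pep_best),
        "pure_reallocation": 0,
        "lower_cutoff_no_realloc": 0,
        f"lower_cutoff_from_{TARGET}": 0,
        f"lower_cutoff_from_{DECOY}": 0,
        f"lower_cutoff_from_{NO_MATCH}": 0,
    }
    for _, cat in pep_best.values():
        pep_counts[cat] += 1
    br.peptides = pep_counts
    return br


def decoy_loss_analysis(pairs, cutoff_full: float):
    """Fate, in the reduced search, of the full search's valid matches.

    For spectra whose full-search PSM passes ``cutoff_full``, separately for
    targets and decoys, tabulates the reduced-search outcome under the same
    (transferred) cutoff, and reports the net percentage change of the valid
    populations.
    """
    fates = {}
    for kind in (TARGET, DECOY):
        rows = [
            p for p in pairs if p.full.kind == kind and p.full.score >= cutoff_full
        ]
        fate = {
            "same_valid": 0,
            "same_invalid": 0,
            "realloc_valid_same_kind": 0,
            "realloc_valid_cross_kind": 0,
            "realloc_invalid": 0,
            "no_match": 0,
        }
        for p in rows:
            r = p.reduced
            if r.kind == NO_MATCH:
                fate["no_match"] += 1
            elif r.peptide == p.full.peptide:
                fate["same_valid" if r.score >= cutoff_full else "same_invalid"] += 1
            elif r.score >= cutoff_full:
                fate[
                    "realloc_valid_same_kind"
                    if r.kind == kind
                    else "realloc_valid_cross_kind"
                ] += 1
            else:
                fate["realloc_invalid"] += 1
        n_full = len(rows)
        n_reduced = sum(
            1
            for p in pairs
            if p.reduced.kind == kind and p.reduced.score >= cutoff_full
        )
        fates[kind] = {
            "n_valid_full": n_full,
            "n_valid_reduced_at_full_cutoff": n_reduced,
            "net_loss_pct": (
                100.0 * (n_full - n_reduced) / n_full if n_full else 0.0
            ),
            "fate": fate,
        }
    return fates
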