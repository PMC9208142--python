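"""Score-cutoff estimation for PSM validation at a requested FDR level.

Two estimators are provided. *Target-decoy competition* (TDC) accepts all
PSMs with score at or above a cutoff chosen so that the nominal FDR estimate
(d + 1)/t — with t valid targets and d valid decoys in the acceptance set —
stays at or below the requested level alpha, maximizing t. The *Benjamini-
Hochberg* (BH) step-up procedure converts target scores to p-values and
rejects the k smallest, k = max{i : p(i) <= i*alpha/m}; it requires no decoys
and is the natural choice for target-only searches.

A cutoff estimated on one search can also be *transferred* to another search
to ask what would have been validated under it — the device used to expose
how database reduction erodes the valid-decoy population.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .msio import PsmTable

MASCOT_LOG10 = "mascot_log10"
EMPIRICAL_DECOY = "empirical_decoy"


@dataclass(frozen=True)
class PvalueConvention:
    """How a search-engine score maps to a p-value.

    ``mascot_log10`` inverts the Mascot-style score definition
    s = -10*log10(p), i.e. p = 10**(-s/10) clipped to (0, 1].
    ``empirical_decoy`` ranks the score against an observed decoy score
    population: p = (1 + #{decoys >= s}) / (1 + #decoys).
    """

    kind: str = MASCOT_LOG10
    decoy_scores: tuple = ()

    def pvalues(self, scores) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        if self.kind == MASCOT_LOG10:
            return np.minimum(10.0 ** (-scores / 10.0), 1.0)
        if self.kind == EMPIRICAL_DECOY:
            d = np.sort(np.asarray(self.decoy_scores, dtype=float))
            if d.size == 0:
                raise ValueError("empirical_decoy convention requires decoy scores")
            n_ge = d.size - np.searchsorted(d, scores, side="left")
            return (1.0 + n_ge) / (1.0 + d.size)
        raise ValueError(f"unknown p-value convention {self.kind!r}")


@dataclass(frozen=True)
class FdrResult:
    """Outcome of a validation: cutoff plus acceptance-set counts.

    ``nominal_fdr`` is (d+1)/t for TDC/transfer results and carries the
    requested alpha for BH results (BH reports no decoy count).
    """

    alpha: float
    cutoff: float
    n_valid_targets: int
    n_valid_decoys: int
    nominal_fdr: float
    method: str

    def as_dict(self):
        return {
            "method": self.method,
            "alpha": self.alpha,
            "cutoff": self.cutoff,
            "n_valid_targets": self.n_valid_targets,
            "n_valid_decoys": self.n_valid_decoys,
            "nominal_fdr": self.nominal_fdr,
        }


def nominal_fdr(t: int, d: int) -> float:
    """Nominal FDR estimate (d + 1)/t of a TDC acceptance set."""
    if t < 1:
        raise ValueError("nominal FDR undefined for t = 0")
    if d < 0:
        raise ValueError("negative decoy count")
    return (d + 1) / t


def _check_alpha(alpha):
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")


def tdc_cutoff(table: PsmTable, alpha: float) -> FdrResult:
    """Estimate the TDC score cutoff controlling the FDR at ``alpha``.

    The cutoff is the smallest score c such that the acceptance set
    {PSMs with score >= c} maximizes the valid-target count t subject to
    (d + 1)/t <= alpha. If no acceptance set satisfies the constraint the
    result is empty with cutoff +inf. Contaminant matches count as targets.
    """
    _check_alpha(alpha)
    scores = table.scores()
    decoy = table.decoy_mask()
    if scores.size == 0:
        return FdrResult(alpha, math.inf, 0, 0, math.nan, "TDC")
    if not decoy.any():
        warnings.warn(
            "no decoy PSMs present; TDC estimate reduces to (0 + 1)/t",
            stacklevel=2,
        )
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    d_cum = np.cumsum(decoy[order])
    t_cum = np.arange(1, s.size + 1) - d_cum
    # candidate cutoffs are group boundaries of tied scores
    boundary = np.ones(s.size, dtype=bool)
    boundary[:-1] = s[:-1] > s[1:]
    feasible = boundary & (t_cum > 0) & ((d_cum + 1) <= alpha * t_cum)
    if not feasible.any():
        return FdrResult(alpha, math.inf, 0, 0, math.nan, "TDC")
    # t is non-decreasing along prefixes, so the last feasible boundary
    # maximizes t and, among equal-t sets, has the lowest cutoff
    i = int(np.flatnonzero(feasible)[-1])
    t, d = int(t_cum[i]), int(d_cum[i])
    return FdrResult(alpha, float(s[i]), t, d, nominal_fdr(t, d), "TDC")


def score_to_pvalue(score, convention: PvalueConvention = PvalueConvention()):
    """Convert one score (or an array of scores) to p-values."""
    p = convention.pvalues(np.atleast_1d(score))
    return float(p[0]) if np.isscalar(score) else p


def bh_cutoff(
    table: PsmTable,
    alpha: float,
    convention: PvalueConvention = PvalueConvention(),
) -> FdrResult:
    """Benjamini-Hochberg validation of the target PSMs of a table.

    Decoy PSMs are ignored (a target-only search has none). Scores are
    converted to p-values under ``convention`` and the step-up rule is
    applied; the cutoff is the score of the lowest-scoring rejected PSM.
    """
    _check_alpha(alpha)
    scores = np.array([p.score for p in table.psms if not p.is_decoy], dtype=float)
    if scores.size == 0:
        raise ValueError("no target PSMs for BH validation")
    pvals = convention.pvalues(scores)
    reject = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    k = int(reject.sum())
    if k == 0:
        return FdrResult(alpha, math.inf, 0, 0, alpha, "BH")
    # p-values are monotone non-increasing in score under both conventions,
    # so the k rejections are exactly the k highest-scoring targets
    cutoff = float(np.sort(scores)[::-1][k - 1])
    return FdrResult(alpha, cutoff, k, 0, alpha, "BH")


def transfer_cutoff(table: PsmTable, cutoff: float, alpha: float = math.nan) -> FdrResult:
    """Apply an externally estimated score cutoff to this table.

    Reports t, d and the nominal FDR (d+1)/t of the set {score >= cutoff} —
    e.g. what a reduced-database search would have validated had it used the
    full-database cutoff.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    scores = table.scores()
    decoy = table.decoy_mask()
    valid = scores >= cutoff
    t = int((valid & ~decoy).sum())
    d = int((valid & decoy).sum())
    nom = nominal_fdr(t, d) if t > 0 else math.nan
    return FdrResult(alpha, float(cutoff), t, d, nom, "TRANSFER")


def valid_spectra(table: PsmTable, cutoff: float, targets_only: bool = True):
    """Spectrum ids of PSMs accepted at ``cutoff`` (score >= cutoff)."""
    return {
        p.spectrum_id
        for p in table.psms
        if p.score >= cutoff and (not targets_only or not p.is_decoy)
    }
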