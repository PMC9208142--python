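"""Ground-truth simulation of paired full/reduced database searches.

The generator abstracts a database search the standard way: every spectrum
scores against k candidate peptides, each candidate drawing an independent
match probability u ~ U(0, 1); the engine reports the best candidate with the
score s = -10*log10(k_full * u), i.e. the Mascot-like -10*log10 of the match
probability Bonferroni-corrected at the full-database scale. Database size
enters as candidate count: the best incorrect match of a search over k
candidates is the minimum of k uniform draws, so smaller databases yield
stochastically lower incorrect-match scores. Because the correction scale is
fixed, scores are comparable across searches and p = 10**(-s/10) is a valid
(slightly conservative) p-value for the best incorrect target match of either
search — which is what makes Benjamini-Hochberg control honest on these
tables.

A fraction pi1 of spectra have their correct peptide in the database; its
score is drawn once from a Gaussian on the score scale and reused in both
searches (transcriptome-informed reduction never removes a correct sequence).
Reduction removes a fraction r of the random candidate mass from targets and
decoys alike — the draws are subset-coupled, so a reduced-search score can
never exceed the full-search score for the same spectrum. The target side
additionally carries ``k_homolog`` near-miss candidates: peptides of proteins
genuinely present in the sample (homologous or modified forms) that resemble
the spectra and survive transcriptome-informed reduction, while decoys —
random sequences — enjoy no such protection. In a large database this extra
mass is negligible and target-decoy competition is calibrated; in a heavily
reduced database it dominates the surviving random mass, incorrect target
matches outscore decoys, the equal-chance assumption breaks, and TDC turns
anti-conservative. Setting ``k_homolog = 0`` restores exact target/decoy
exchangeability at any database size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fdr import PvalueConvention, bh_cutoff, tdc_cutoff, valid_spectra
from .msio import Psm, PsmTable

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _encode(i: int, width: int = 6) -> str:
    """Deterministic amino-acid encoding of an integer (base 20)."""
    out = []
    for _ in range(width):
        out.append(_AA20[i % 20])
        i //= 20
    return "".join(reversed(out))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one paired-search simulation.

    ``k_full`` is the incorrect-candidate count of the full database;
    ``reduction_rate`` the fraction of random candidate mass absent from the
    reduced database; ``k_homolog`` the near-miss target candidate mass that
    survives reduction (0 recovers exact target/decoy symmetry);
    ``correct_loc``/``correct_scale`` parametrize the Gaussian correct-match
    score (score units, i.e. -10*log10 of a match probability).
    """

    n_spectra: int = 5000
    pi1: float = 0.7
    k_full: int = 2000
    reduction_rate: float = 0.5
    k_homolog: int = 50
    correct_loc: float = 35.0
    correct_scale: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.n_spectra < 1 or self.k_full < 1:
            raise ValueError("n_spectra and k_full must be positive")
        if not (0.0 <= self.pi1 <= 1.0):
            raise ValueError("pi1 must lie in [0, 1]")
        if not (0.0 <= self.reduction_rate < 1.0):
            raise ValueError("reduction_rate must lie in [0, 1)")
        if self.k_homolog < 0:
            raise ValueError("k_homolog must be >= 0")

    @property
    def k_reduced(self) -> int:
        """Random candidate mass surviving reduction."""
        return int(math.ceil((1.0 - self.reduction_rate) * self.k_full))


@dataclass
class SimTruth:
    """Per-spectrum ground truth of a simulated search pair."""

    frame: pd.DataFrame

    def target_only_table(self, search: str = "full") -> PsmTable:
        """The target-only search view: every spectrum's best target match."""
        psms = [
            Psm(
                spectrum_id=row.spectrum_id,
                peptide=getattr(row, f"{search}_target_peptide"),
                proteins=frozenset({getattr(row, f"{search}_target_protein")}),
                score=getattr(row, f"{search}_target_score"),
                is_decoy=False,
            )
            for row in self.frame.itertuples(index=False)
        ]
        return PsmTable(psms, database=f"{search}-targets-only", label="simulated")


def _best_null_u(rng: np.random.Generator, k: int, n: int) -> np.ndarray:
    """Minimum of k iid U(0,1) draws per spectrum (inf when k = 0)."""
    if k <= 0:
        return np.full(n, np.inf)
    u = rng.random(n)
    return 1.0 - (1.0 - u) ** (1.0 / k)


def _score(u: np.ndarray, k_ref: int) -> np.ndarray:
    """Engine score -10*log10(k_ref * u); -inf for absent candidates."""
    with np.errstate(divide="ignore"):
        s = -10.0 * np.log10(np.where(np.isfinite(u), k_ref * u, np.inf))
    return np.where(np.isfinite(u), s, -np.inf)


def simulate_pair(config: SimConfig, seed=None):
    """Simulate one paired full/reduced search.

    Returns ``(full, reduced, truth)`` where the two :class:`PsmTable` hold
    the per-spectrum competition winner (best of correct target, best
    incorrect target, best decoy) and :class:`SimTruth` the per-spectrum
    best-target/best-decoy scores and correctness labels for both searches.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, kf = config.n_spectra, config.k_full
    k_keep = config.k_reduced
    k_drop = kf - k_keep

    # subset-coupled random candidate mass: the reduced search sees only the
    # "keep" partition, the full search the minimum over both partitions
    u_t_keep = _best_null_u(rng, k_keep, n)
    u_t_drop = _best_null_u(rng, k_drop, n)
    u_d_keep = _best_null_u(rng, k_keep, n)
    u_d_drop = _best_null_u(rng, k_drop, n)
    u_homolog = _best_null_u(rng, config.k_homolog, n)

    has_correct = rng.random(n) < config.pi1
    s_correct = np.where(
        has_correct,
        rng.normal(config.correct_loc, config.correct_scale, n),
        -np.inf,
    )

    idx = np.arange(n)
    spectrum_ids = np.array([f"s{i:06d}" for i in idx])
    pep = {
        "correct": np.array(["TR" + _encode(i) for i in idx]),
        "keep_t": np.array(["KT" + _encode(i) for i in idx]),
        "drop_t": np.array(["DT" + _encode(i) for i in idx]),
        "homolog": np.array(["HM" + _encode(i) for i in idx]),
        "keep_d": np.array(["KD" + _encode(i) for i in idx]),
        "drop_d": np.array(["DD" + _encode(i) for i in idx]),
    }
    target_protein = np.array(["P" + _encode(i) for i in idx])
    decoy_protein = np.array(["rev_P" + _encode(i) for i in idx])

    def one_search(reduced: bool):
        t_rows = [s_correct, _score(u_t_keep, kf), _score(u_homolog, kf)]
        t_names = ["correct", "keep_t", "homolog"]
        d_rows = [_score(u_d_keep, kf)]
        d_names = ["keep_d"]
        if not reduced:
            t_rows.append(_score(u_t_drop, kf))
            t_names.append("drop_t")
            d_rows.append(_score(u_d_drop, kf))
            d_names.append("drop_d")
        t_stack = np.vstack(t_rows)
        d_stack = np.vstack(d_rows)
        t_arg = np.argmax(t_stack, axis=0)
        t_best = t_stack[t_arg, np.arange(n)]
        d_arg = np.argmax(d_stack, axis=0)
        d_best = d_stack[d_arg, np.arange(n)]
        t_pep = np.vstack([pep[name] for name in t_names])[t_arg, np.arange(n)]
        d_pep = np.vstack([pep[name] for name in d_names])[d_arg, np.arange(n)]
        return {
            "target_score": t_best,
            "target_peptide": t_pep,
            "target_correct": (t_arg == 0) & has_correct,
            "decoy_score": d_best,
            "decoy_peptide": d_pep,
        }

    searches = {"full": one_search(False), "reduced": one_search(True)}

    data = {"spectrum_id": spectrum_ids, "has_correct": has_correct}
    for name, s in searches.items():
        data[f"{name}_target_score"] = s["target_score"]
        data[f"{name}_target_peptide"] = s["target_peptide"]
        data[f"{name}_target_protein"] = target_protein
        data[f"{name}_target_correct"] = s["target_correct"]
        data[f"{name}_decoy_score"] = s["decoy_score"]
        data[f"{name}_decoy_peptide"] = s["decoy_peptide"]
        decoy_wins = s["decoy_score"] > s["target_score"]
        data[f"{name}_winner_is_decoy"] = decoy_wins
        data[f"{name}_winner_score"] = np.where(
            decoy_wins, s["decoy_score"], s["target_score"]
        )
        data[f"{name}_winner_correct"] = ~decoy_wins & s["target_correct"]
    truth = SimTruth(pd.DataFrame(data))

    def table(name: str) -> PsmTable:
        s = searches[name]
        decoy_wins = s["decoy_score"] > s["target_score"]
        psms = []
        for i in range(n):
            if decoy_wins[i]:
                psms.append(
                    Psm(
                        spectrum_id=spectrum_ids[i],
                        peptide=str(s["decoy_peptide"][i]),
                        proteins=frozenset({decoy_protein[i]}),
                        score=float(s["decoy_score"][i]),
                        is_decoy=True,
                    )
                )
            else:
                psms.append(
                    Psm(
                        spectrum_id=spectrum_ids[i],
                        peptide=str(s["target_peptide"][i]),
                        proteins=frozenset({target_protein[i]}),
                        score=float(s["target_score"][i]),
                        is_decoy=False,
                    )
                )
        return PsmTable(psms, database=name, label="simulated")

    return table("full"), table("reduced"), truth


def empirical_fdp(valid, truth: SimTruth, search: str = "reduced") -> float:
    """Fraction of accepted target matches that are incorrect (0 if empty).

    ``valid`` holds spectrum ids of accepted target PSMs (decoy PSMs, if any
    were passed, are excluded via the ground truth winner labels for
    competition tables; for target-only tables every spectrum is a target).
    """
    frame = truth.frame
    mask = frame["spectrum_id"].isin(set(valid))
    correct = frame.loc[mask, f"{search}_target_correct"].to_numpy()
    if correct.size == 0:
        return 0.0
    return float((~correct).mean())


def calibration_experiment(
    configs,
    alphas=(0.005, 0.01, 0.05),
    n_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Nominal-vs-empirical FDR of TDC and BH across database sizes.

    ``configs`` maps a label to a :class:`SimConfig`. For every config,
    replicate and alpha, both searches of a simulated pair are validated by
    TDC (on the competed target-decoy tables) and by BH (on the target-only
    views, Mascot p-value convention), and the empirical false discovery
    proportion of each acceptance set is measured against the ground truth.
    One tidy row per (config, rep, alpha, method).
    """
    if not configs:
        raise ValueError("empty configuration grid")
    if isinstance(configs, (list, tuple)):
        configs = {f"config{i}": c for i, c in enumerate(configs)}
    rows = []
    mascot = PvalueConvention()
    for ci, (label, config) in enumerate(configs.items()):
        for rep in range(n_reps):
            rep_seed = int(
                np.random.SeedSequence([seed, ci, rep]).generate_state(1)[0] % (2**31)
            )
            full, reduced, truth = simulate_pair(config, seed=rep_seed)
            tonly = {s: truth.target_only_table(s) for s in ("full", "reduced")}
            for alpha in alphas:
                for method in ("TDC", "BH"):
                    res = {}
                    for sname, table in (("full", full), ("reduced", reduced)):
                        if method == "TDC":
                            r = tdc_cutoff(table, alpha)
                            ids = valid_spectra(table, r.cutoff)
                        else:
                            r = bh_cutoff(tonly[sname], alpha, mascot)
                            ids = valid_spectra(tonly[sname], r.cutoff)
                        res[sname] = (r, empirical_fdp(ids, truth, sname))
                    rf, rr = res["full"][0], res["reduced"][0]
                    rows.append(
                        {
                            "config": label,
                            "rep": rep,
                            "alpha": alpha,
                            "method": method,
                            "cutoff_full": rf.cutoff,
                            "cutoff_reduced": rr.cutoff,
                            "cutoff_shift": rr.cutoff - rf.cutoff,
                            "fdp_full": res["full"][1],
                            "fdp_reduced": res["reduced"][1],
                            "nominal_full": rf.nominal_fdr,
                            "nominal_reduced": rr.nominal_fdr,
                            "t_full": rf.n_valid_targets,
                            "d_full": rf.n_valid_decoys,
                            "t_reduced": rr.n_valid_targets,
                            "d_reduced": rr.n_valid_decoys,
                        }
                    )
    return pd.DataFrame(rows)


def summarize_calibration(df: pd.DataFrame) -> pd.DataFrame:
    """Mean FDP, cutoffs and absolute cutoff shift per (config, alpha, method)."""
    g = df.groupby(["config", "alpha", "method"], sort=False)
    out = g.agg(
        mean_fdp_full=("fdp_full", "mean"),
        mean_fdp_reduced=("fdp_reduced", "mean"),
        sd_fdp_reduced=("fdp_reduced", "std"),
        mean_cutoff_full=("cutoff_full", "mean"),
        mean_cutoff_reduced=("cutoff_reduced", "mean"),
        mean_nominal_reduced=("nominal_reduced", "mean"),
        mean_abs_cutoff_shift=("cutoff_shift", lambda s: s.abs().mean()),
        n_reps=("rep", "nunique"),
    ).reset_index()
    return out


def simulate_inference_graph(
    n_singletons: int = 600,
    n_clusters: int = 160,
    cluster_size: int = 3,
    specific_rate: float = 3.0,
    cluster_specific_rate: float = 0.5,
    shared_rate: float = 2.5,
    frac_unexpressed: float = 0.5,
    frac_shared_gene: float = 0.5,
    seed: int = 0,
):
    """Synthetic peptide-protein identifications with transcript expression.

    Emulates a validated identification set: singleton proteins carry only
    specific peptides; homology clusters of ``cluster_size`` isoform-like
    proteins share core peptides mapped to every member, plus a few specific
    peptides each. A fraction of proteins (uniformly at random) lacks
    transcript expression (FPKM below 1); every protein maps 1:1 to a
    transcript, Ensembl-style, and clusters may share a gene.

    Returns ``(pairs, expression, mapping)`` ready for the graph, reduction
    and post hoc filtering machinery.
    """
    from .dbtools import ExpressionSet, ProteinTranscriptMap

    rng = np.random.default_rng(seed)
    pairs = []
    accs = []
    genes = {}
    pep_counter = 0

    def new_pep():
        nonlocal pep_counter
        pep_counter += 1
        return "PEPTIDE" + _encode(pep_counter)

    for i in range(n_singletons):
        acc = f"SP{_encode(i)}"
        accs.append(acc)
        genes[acc] = f"G_{acc}"
        for _ in range(max(1, rng.poisson(specific_rate))):
            pairs.append((new_pep(), acc))
    for c in range(n_clusters):
        members = [f"CL{_encode(c)}{_AA20[m]}" for m in range(cluster_size)]
        shared_gene = rng.random() < frac_shared_gene
        for m, acc in enumerate(members):
            accs.append(acc)
            genes[acc] = f"G_CL{_encode(c)}" if shared_gene else f"G_{acc}"
            for _ in range(rng.poisson(cluster_specific_rate)):
                pairs.append((new_pep(), acc))
        for _ in range(max(1, rng.poisson(shared_rate))):
            pep = new_pep()
            for acc in members:
                pairs.append((pep, acc))

    unexpressed = rng.random(len(accs)) < frac_unexpressed
    fpkm = np.where(
        unexpressed,
        rng.uniform(0.0, 0.9, len(accs)),
        np.exp(rng.normal(2.0, 1.0, len(accs))) + 1.0,
    )
    expr = ExpressionSet({f"T_{acc}": float(v) for acc, v in zip(accs, fpkm)})
    mapping = ProteinTranscriptMap(
        {acc: {f"T_{acc}"} for acc in accs}, gene_map=genes
    )
    return pairs, expr, mapping
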