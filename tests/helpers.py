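"""Independent brute-force oracles and fixture builders for the test suite.

These deliberately avoid the code paths they check: the TDC oracle enumerates
every candidate cutoff, the BH oracle evaluates the step-up rule literally,
and the component oracle runs a plain depth-first search on the bipartite
graph.
"""

import numpy as np

from proteofdr.msio import Psm, PsmTable


def make_table(specs, prefix="spec"):
    """PsmTable from (is_decoy, score) tuples, one spectrum per entry."""
    psms = []
    for i, (is_decoy, score) in enumerate(specs):
        acc = ("rev_P%d" if is_decoy else "P%d") % i
        psms.append(
            Psm(
                spectrum_id=f"{prefix}{i}",
                peptide="PEPTIDEK",
                proteins=frozenset({acc}),
                score=float(score),
                is_decoy=bool(is_decoy),
            )
        )
    return PsmTable(psms)


def random_table(rng, max_psms=100):
    n = int(rng.integers(1, max_psms + 1))
    scores = np.round(rng.normal(10, 5, n), 3)
    decoys = rng.random(n) < rng.uniform(0.1, 0.9)
    return make_table(list(zip(decoys, scores)))


def brute_tdc(scores, decoys, alpha):
    """Exhaustive cutoff enumeration: max-t acceptance set with (d+1)/t <= alpha.

    Returns (cutoff, t, d) or None if no acceptance set is feasible. Among
    equal-t feasible sets the lowest cutoff wins.
    """
    scores = np.asarray(scores, dtype=float)
    decoys = np.asarray(decoys, dtype=bool)
    best = None
    for c in np.unique(scores):
        sel = scores >= c
        t = int((sel & ~decoys).sum())
        d = int((sel & decoys).sum())
        if t > 0 and (d + 1) / t <= alpha:
            if best is None or t > best[1] or (t == best[1] and c < best[0]):
                best = (float(c), t, d)
    return best


def stepup_bh(pvals, alpha):
    """Literal Benjamini-Hochberg step-up: k = max{i : p(i) <= i*alpha/m}."""
    p = sorted(pvals)
    m = len(p)
    k = 0
    for i in range(1, m + 1):
        if p[i - 1] <= i * alpha / m:
            k = i
    return k


def dfs_protein_components(pairs):
    """Protein partition of a bipartite peptide-protein graph by plain DFS.

    Returns a set of frozensets of protein accessions.
    """
    pep_to_prots = {}
    prot_to_peps = {}
    for pep, prot in pairs:
        pep_to_prots.setdefault(pep, set()).add(prot)
        prot_to_peps.setdefault(prot, set()).add(pep)
    seen = set()
    comps = set()
    for start in prot_to_peps:
        if start in seen:
            continue
        comp = set()
        stack = [start]
        while stack:
            prot = stack.pop()
            if prot in comp:
                continue
            comp.add(prot)
            for pep in prot_to_peps[prot]:
                for other in pep_to_prots[pep]:
                    if other not in comp:
                        stack.append(other)
        seen |= comp
        comps.add(frozenset(comp))
    return comps


def random_bipartite_pairs(rng, max_vertices=60):
    """Random peptide-protein pair list with <= max_vertices vertices total."""
    n_prot = int(rng.integers(1, max_vertices // 2))
    n_pep = int(rng.integers(1, max_vertices - n_prot))
    pairs = []
    for i in range(n_pep):
        deg = 1 + rng.binomial(min(3, n_prot - 1), 0.3)
        for j in rng.choice(n_prot, size=min(deg, n_prot), replace=False):
            pairs.append((f"pep{i}", f"prot{j}"))
    # every protein listed must map to something; drop untouched proteins
    return pairs


def random_incidence_instance(rng):
    """Random incidence + expression + mapping for post hoc filter properties."""
    from proteofdr.dbtools import ExpressionSet, ProteinTranscriptMap

    pairs = random_bipartite_pairs(rng, max_vertices=40)
    prots = sorted({p for _, p in pairs})
    fpkm = {
        f"T_{p}": float(rng.choice([0.0, 0.5, 5.0], p=[0.3, 0.2, 0.5]))
        for p in prots
    }
    expr = ExpressionSet(fpkm)
    mapping = ProteinTranscriptMap({p: {f"T_{p}"} for p in prots})
    return pairs, expr, mapping
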