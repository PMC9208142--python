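# proteofdr

FDR control and transcriptome-informed post-processing for bottom-up
proteomics.

## The problem

Proteogenomics pipelines often search MS/MS spectra against a *reduced*
protein database — the subset of a reference proteome whose transcripts are
expressed (FPKM > 1) in a sample-matched transcriptome. Reduced databases
promise fewer candidates, less peptide-sharing ambiguity and, apparently,
extra identifications. But the standard false-discovery-rate estimator,
target-decoy competition (TDC), is only asymptotically accurate: on a
heavily reduced database the decoy population no longer mimics the incorrect
target matches (near-miss matches to proteins genuinely present in the
sample survive the reduction, random decoy matches do not), the equal-chance
assumption breaks, and the score cutoff that nominally controls the FDR at
level α admits far more false discoveries than α. This toolkit packages the
machinery needed to study, and guard against, that artifact.

## What it provides

- **`proteofdr.msio`** — FASTA and PSM-table (TSV) I/O, reversed-sequence
  decoy generation, and the standard post-search prefilters (pretty-rank
  ties below a 0.1 score difference, one PSM per spectrum, peptide length
  ≥ 7).
- **`proteofdr.fdr`** — score-cutoff estimation at level α by TDC, which
  maximizes the valid-target count t subject to the nominal FDR
  (d + 1)/t ≤ α over acceptance sets {score ≥ c}, and by the
  Benjamini–Hochberg step-up rule k = max{i : p(i) ≤ iα/m} on target-only
  searches (Mascot-style p = 10^(−s/10) or empirical-decoy p-values), plus
  cutoff transfer between searches.
- **`proteofdr.dbtools`** — reduced transcriptome-informed databases as
  strict subsets of a reference FASTA, driven by transcript FPKM tables.
- **`proteofdr.pepgraph`** — bipartite peptide–protein graphs: incidence
  matrix I, protein adjacency A = IᵀI, connected components (full and
  pruned-matrix strategies), protein groups (identical peptide sets), and
  ambiguity metrics (% single-protein components, % specific peptides,
  protein-to-gene ratios), with GraphML/DOT export.
- **`proteofdr.posthoc`** — the three transcriptome-informed post hoc
  filters of full-database identifications, from aggressive (option 1) to
  peptide-preserving (option 3).
- **`proteofdr.compare`** — spectrum-level pairing of a full and a reduced
  search: reallocation classes, "pure reallocations", the decomposition of
  additional identifications, and valid-decoy loss under a transferred
  cutoff.
- **`proteofdr.simulate`** — a ground-truth generator of paired searches in
  which database size enters as candidate count (best incorrect match = max
  of k null draws), plus calibration experiments measuring the empirical
  false discovery proportion (FDP) of TDC and BH across database sizes.

## Worked example

```python
from proteofdr.simulate import SimConfig, simulate_pair, empirical_fdp
from proteofdr.fdr import tdc_cutoff, bh_cutoff, valid_spectra

# paired searches: 5000 spectra, 70% with their correct peptide present,
# reduced database retaining 1% of the random candidate mass
cfg = SimConfig(reduction_rate=0.99, seed=1)
full, reduced, truth = simulate_pair(cfg)

for name, table in (("full", full), ("reduced", reduced)):
    r = tdc_cutoff(table, alpha=0.01)
    fdp = empirical_fdp(valid_spectra(table, r.cutoff), truth, name)
    print(f"{name:8s} TDC cutoff={r.cutoff:7.2f} t={r.n_valid_targets} "
          f"d={r.n_valid_decoys} nominal={r.nominal_fdr:.4f} FDP={fdp:.4f}")

b = bh_cutoff(truth.target_only_table("reduced"), alpha=0.01)
print(f"reduced  BH  cutoff={b.cutoff:7.2f} t={b.n_valid_targets}")
```

Output:

```
full     TDC cutoff=  16.04 t=3491 d=33 nominal=0.0097 FDP=0.0120
reduced  TDC cutoff=  -4.05 t=3612 d=35 nominal=0.0100 FDP=0.0338
reduced  BH  cutoff=  21.84 t=3314
```

On the full database, TDC's nominal 1% estimate matches the true FDP. On
the reduced database the cutoff collapses (16.0 → −4.1): whole decoy
candidate sets vanished, so too few decoys pass any threshold and TDC keeps
lowering the cutoff to "recover" them — validating ~120 extra targets while
the true false fraction climbs to 3.4%, more than three times the nominal
1%. The BH cutoff on the same data barely moves and stays conservative.

## Command line

```bash
proteofdr decoy      --fasta ref.fasta --out target_decoy.fasta
proteofdr reduce-db  --fasta ref.fasta --expr expr.tsv --map map.tsv --out reduced.fasta
proteofdr validate   --in psms.tsv --method tdc --alpha 0.01 --out valid.tsv --report report.json
proteofdr graph-cc   --pairs pairs.tsv --out-metrics metrics.json
proteofdr posthoc    --pairs pairs.tsv --expr expr.tsv --map map.tsv --option 2 --out filtered.tsv
proteofdr compare    --full full.tsv --reduced reduced.tsv --cutoff-full 16.1 --cutoff-reduced 13.4 --out cmp.json
proteofdr simulate   --reduction-rate 0.99 --seed 1 --out-dir runs/
```

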