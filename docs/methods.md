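# Methods

## Scope and data model

The toolkit post-processes peptide-spectrum match (PSM) tables — it does not
run a search engine. A PSM assigns one spectrum to one peptide with a score
(higher is better) and the set of protein accessions the peptide maps to; a
PSM is a decoy match iff every accession carries the decoy prefix (default
`rev_`, reversal convention). A match mixing target and decoy accessions is
classified target and its decoy accessions dropped, because reversed tryptic
peptides occasionally coincide with target peptides and counting them as
decoys would inflate the decoy count. Contaminant accessions (default
prefix `CON_`) count as targets during FDR estimation and carry a flag for
optional downstream exclusion.

### Prefilters

Before FDR control, raw candidate lists are reduced to one PSM per spectrum:
candidates within a strict score difference of 0.1 of the spectrum's best
candidate share *pretty rank* 1; exactly one rank-1 candidate is retained,
chosen uniformly at random under a caller-supplied seed; retained PSMs with
peptide length below 7 are discarded together with their spectrum. The
random tie-break (rather than, say, target-preference) keeps targets and
decoys on an equal footing, which target-decoy competition requires. The
boundary is strict: a difference of exactly 0.1 is not a tie. The operation
is idempotent.

## FDR control

### Target-decoy competition (TDC)

Decoys are full sequence reversals, one per target, appended so target and
decoy spaces have equal size. After competition (one best match per
spectrum), the acceptance set at score cutoff c is {PSMs with score ≥ c};
with t valid targets and d valid decoys its nominal FDR is (d + 1)/t. The
estimator returns the smallest cutoff whose acceptance set maximizes t
subject to (d + 1)/t ≤ α; if no set qualifies the result is empty with
cutoff +∞. The +1 makes the estimate valid (not merely unbiased
asymptotically) and guards the small-d regime. Acceptance is inclusive
(score equal to the cutoff is valid) throughout the package. A table
without decoys triggers a warning and the same rule with d = 0; an
unconditional "lowest target score" answer would violate the α constraint
the result advertises.

### Benjamini–Hochberg (BH)

For target-only searches, scores are converted to p-values and the step-up
rule rejects the k smallest with k = max{i : p(i) ≤ iα/m}. Two conversions
are offered: `mascot_log10`, p = 10^(−s/10), inverting the Mascot score
definition (the default, since Mascot-style scores are the primary input
this package expects); and `empirical_decoy`,
p = (1 + #{decoys ≥ s})/(1 + #decoys), engine-agnostic but requiring an
observed decoy score population. The exact conversion a given laboratory
pipeline uses is an implementation choice; both are monotone non-increasing
in score, so the k rejections are the k best-scoring targets and the cutoff
is the k-th best score. Decoy PSMs, if present, are ignored under BH. The
step-up evaluation itself is delegated to
`statsmodels.stats.multitest.multipletests`; the test suite checks it
against an independent literal implementation. BH is applied per table; no
separate-class partitioning (e.g. for variant peptides) is attempted.

### Cutoff transfer

`transfer_cutoff` applies an externally estimated cutoff to another search
and reports t, d and (d + 1)/t. This is the instrument used to ask what a
reduced-database search would have validated under the full-database
cutoff, which is where the valid-decoy deficit becomes visible.

## Reduced transcriptome-informed databases

A protein of the reference FASTA is retained iff at least one of its
transcripts has FPKM strictly above the threshold (default 1.0). The output
is literally a subset of the input records; decoys are generated afterwards
from the reduced set. Proteins mapped to several transcripts are kept if
*any* is expressed — with Ensembl's one-to-one protein–transcript
correspondence this reduces to the plain rule, and it is the safe
generalization elsewhere. Proteins absent from the mapping are dropped (and
counted in the log): absence of evidence of expression is treated the same
as evidence of absence, consistent with "retain only what is expressed".
Transcript identifiers are version-stripped on both sides before matching.
Expression must be transcript-level; gene-level tables are not accepted,
because the retention rule is defined on transcripts.

## Bipartite peptide–protein graphs

Identifications are encoded as an incidence matrix I (peptides × proteins,
0/1, sparse, first-appearance ordering so all outputs are byte-stable). The
protein adjacency is the cross-product A = IᵀI: off-diagonal entries count
shared peptides, the diagonal counts each protein's peptides. Connected
components of A (computed by scipy's sparse component routine; the test
suite holds an independent depth-first-search oracle) partition proteins
into single-protein components — unambiguous identifications, all peptides
specific — and multi-protein components bundling proteins entangled by
shared peptides.

For large matrices the multi-protein components can be computed on a pruned
incidence from which proteins sharing no peptide (and their peptides, all
specific by construction) were removed; the result provably equals the
multi-protein subset of the full computation, and component peptide sets
are annotated from the original matrix so the two strategies coincide
exactly.

Protein groups collect proteins with *identical* peptide sets
(indistinguishable identifications). Strict equality is used; parsimony-
style merging of subset relations is deliberately out of scope, so group
counts may differ from tools that subsume subsets.

Ambiguity metrics: % single-protein components among components, % specific
peptides among peptides, and per multi-protein component the ratio of
protein members to the distinct genes encoding them (unannotated proteins
count as their own gene). Peptide identity is the bare sequence;
modifications are ignored and isoleucine/leucine are distinct.

## Transcriptome-informed post hoc filtering

Three options operate on the incidence matrix of full-database
identifications, with protein expression defined as for database reduction
and peptide specificity always evaluated on the unfiltered input:

1. remove proteins with no expressed transcript, and every peptide left
   without a retained parent;
2. remove proteins with no expressed transcript *and* no specific peptide
   (a specific peptide immunizes its protein regardless of expression),
   then the peptides only shared among removed proteins — the default;
3. as option 2, but a protein is removed only if each of its peptides is
   also carried by a retained protein, so no peptide identification is ever
   lost.

Option 3's "retained" is self-referential. It is resolved greedily:
candidates (unexpressed, no specific peptide) are visited in
first-appearance order and removed only if every one of their peptides
currently touches another live protein; the scan repeats until stable. For
mutually dependent candidates — two proteins sharing a peptide only with
each other — the earlier one is removed and the later kept. The outcome is
deterministic and provably never orphans a peptide, at the price of
depending on input order for such cycles; a simultaneous "recompute each
pass" formulation was rejected because it oscillates on exactly those
cycles. Removal sets nest across options (1 ⊇ 2 ⊇ 3) and each option is
idempotent; both properties are enforced by tests.

## Paired-search comparison

Spectra are paired across a full and a reduced search; each side is target,
decoy or no-match. A reallocation is a spectrum matched on both sides to
different peptides. An *additional identification* is a spectrum whose
reduced-side PSM is a valid target while its full side is not a valid
target; it is a *pure reallocation* if it is a reallocation onto a target
whose reduced score also passes the full-database cutoff, and otherwise
attributed to the lower cutoff (sub-classified by full-side kind). The
categories are disjoint and sum to the total, at spectrum and at peptide
granularity; an additional peptide is a sequence absent from the full
search's valid target peptides, counted once under its best-scoring
spectrum's category. The decoy-loss table gives, for spectra valid in the
full search, their reduced-search fate under the transferred cutoff,
separately for targets and decoys, plus net percentage losses.

## The simulator

### Generative model

Each spectrum scores against k candidates; each candidate draws a match
probability u ~ U(0, 1) and the engine reports the best candidate with
score s = −10·log10(k_full · u) — the Mascot-like −10·log10 of the match
probability, Bonferroni-corrected at the *fixed* full-database scale
k_full. Consequences, in order of importance:

- database size acts through selection: the best of k draws is the minimum
  of k uniforms, so smaller databases give stochastically lower
  incorrect-match scores;
- the score scale is identical in both searches, so scores are comparable,
  a correct match keeps its score, and (with subset-coupled draws, below) a
  reduced-search score can never exceed the full-search score for the same
  spectrum;
- p = 10^(−s/10) is a valid, slightly conservative p-value for the best
  incorrect target match of either search (Bonferroni at k_full bounds the
  survival function of a maximum over at most k_full candidates), which is
  what makes the BH arm of the calibration honest. Because the null scale
  is pinned by this convention, the null distribution deliberately has no
  free location/scale parameters; only the correct-match distribution does.

A fraction pi1 of spectra (default 0.7) carry their correct peptide; its
score is drawn once from a Gaussian on the score scale (default mean 35,
s.d. 8 — well separated from the null, whose scores concentrate below ~25)
and reused in both searches, encoding the premise that transcriptome-
informed reduction retains every correct sequence. Random candidate mass is
split into a "keep" and a "drop" partition: the full search sees the
minimum over both, the reduced search only the keep partition of size
⌈(1 − r)·k_full⌉ (reduction rate r, default 0.5, a typical fraction of a
reference proteome without expressed transcript in one sample; the
small-database experiments use r = 0.99). Targets and decoys lose random
mass at the same rate.

The asymmetry that breaks TDC lives in one extra parameter: `k_homolog`
(default 50) near-miss target candidates per spectrum — peptides of
proteins genuinely present in the sample (homologs, modified or chimeric
forms) that resemble the spectrum population and are therefore *retained*
by transcriptome-informed reduction. Decoys, being random sequences, have
no analogue. In the full database (k_full = 2000) this mass shifts the
incorrect-target odds only marginally (2050 : 2000) and TDC remains
calibrated within Monte-Carlo error; in the 99%-reduced database it
dominates (70 : 20), incorrect targets outscore decoys, too few decoys pass
any cutoff, TDC lowers the cutoff to recover them, and its empirical FDP at
nominal 1% roughly triples. With `k_homolog = 0` targets and decoys are
exactly exchangeable and TDC is provably calibrated at *any* database size
— that symmetric construction is kept as a tested control, because it shows
the artifact requires an equal-chance violation, not merely a small
database.

All randomness flows from one integer seed through numpy's SeedSequence;
identical seed and configuration give byte-identical tables.

### Calibration experiments

For each configuration, replicate and α (defaults 0.5%, 1%, 5%), both
searches are validated by TDC (competed target-decoy tables) and BH
(target-only views), and the empirical false discovery proportion — the
true fraction of incorrect accepted targets — is measured against ground
truth. The default problem size, 5000 spectra × 200 replicates, keeps the
Monte-Carlo standard error of a mean FDP near 1% at roughly 2·10⁻⁴ while a
full calibration run completes in about a minute on one CPU.

### The identification-graph generator

A second generator emulates a validated identification set for the graph
and filtering machinery: 600 singleton proteins with only specific peptides
(Poisson mean 3, at least 1), and 160 homology clusters of 3 isoform-like
proteins sharing core peptides mapped to every member (Poisson mean 2.5, at
least 1) plus sparse specific peptides (Poisson mean 0.5); half the
clusters share a gene. Half the proteins, uniformly at random, lack
transcript expression (FPKM < 1; expressed transcripts draw FPKM from a
shifted log-normal). Core peptides mapping to *all* cluster members make
"filtering never increases ambiguity" a theorem for option 2 rather than a
tendency: each multi-protein component maps to at most one component after
filtering and single-protein components are immune, so the single-protein
percentage cannot decrease. With pairwise-only sharing this would not hold
in general (removing a bridge protein can split one multi-protein component
into two).

### What the simulator does and does not show

It reproduces the *mechanism* — anti-conservative TDC on excessively small
databases, conservative and size-stable BH, additional identifications
dominated by the lower cutoff, valid-decoy loss under cutoff transfer, and
ambiguity reduction by expression filtering — under a stylized score model.
It does not attempt dataset-specific percentages from real
proteome/transcriptome pairs, which depend on the search engine's actual
score distribution, spectrum quality, and the true overlap between
transcriptome and proteome; its score scale is not calibrated to any
engine, spectra are independent (no shared peptides across spectra, no
retention-time or charge structure), and the homolog mass is a scalar
abstraction of sequence redundancy. Passing tests therefore certify the
estimators and the direction and rough magnitude of the effects, not any
real dataset's numbers.

## Numerical and degenerate-input conventions

Score ties at a cutoff are valid (inclusive acceptance). TDC candidate
cutoffs are evaluated at tied-score group boundaries only, so the
acceptance set always equals {score ≥ cutoff}. Empty acceptance sets carry
cutoff +∞ and, where (d + 1)/t is undefined (t = 0), a NaN nominal FDR.
The empirical FDP of an empty set is 0 by convention. Incidence matrices
reject empty pair lists at construction, but filtering may legitimately
empty a matrix. Gzip-compressed text inputs are accepted everywhere.
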