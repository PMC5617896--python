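# Methods

This note documents the models behind each stage of `facreg`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Study design and conventions

The design is a full factorial over deletions of three activators, written
with single-letter codes in the fixed order G < A < R (GaaR, AraR, RhaR).
A *genotype* is the set of deleted TFs (`"ref"`, `"G"`, …, `"GAR"`); the
seven mutants are reported in the order G, A, R, GA, AR, GR, GAR.
Dependency expressions are monotone DNF formulas over the same literals with
clauses sorted canonically, so `A∨G` and `G∨A` compare equal after
canonicalisation.

## Synthetic data generator

Each gene has a baseline log2 mean count (uniform on [5, 11] by default,
i.e. ~32–2000 fragments at the reference library size of 5·10⁶), a gene
length (0.6–4 kb), an NB dispersion α (default 0.05; Var = μ + αμ², α → 0
degenerates to Poisson), and a monotone DNF over {G, A, R} drawn from a
configurable class mix (default: none 0.5, single 0.3, and 0.1, or 0.1).
Each clause carries a log2 effect drawn from [2, 4]; a clause contributes its
full effect when all of its TFs are deleted and satisfied clauses add on the
log2 scale. Class counts are the largest-remainder rounding of the mix.
Per-sample expected library sizes vary by a log-uniform factor in
[0.8, 1.25] so that size-factor normalisation is genuinely exercised.

Three TF genes (gaaR/araR/rhaR) are appended with dependency on their own
deletion; their counts are hard zeros (not NB draws) in every genotype that
deletes them, matching the abolition of a deleted gene's transcript.

The second timepoint shifts each gene's baseline by a small N(0, 0.25) log2
offset; the regulatory logic itself is time-invariant. The generator
therefore does **not** emulate temporal regulatory switches, nor read-level
artefacts, GC/positional bias, or count correlation between timepoints —
passing tests show the inference chain recovers the model class it assumes,
not that real data satisfy those assumptions.

Promoters are 1 kb of i.i.d. background (uniform by default) with planted
motif instances for every TF a gene's dependency mentions (default motifs:
GaaR `CC[ACTG]CCAA`, AraR `CCCC[ATCG]CC`, RhaR `TG[CAG][GTA]GGG`), at
uniform positions and strands, non-overlapping. Degenerate positions are
sampled with geometrically decaying letter weights (ratio 0.35, ≈
0.70/0.25/0.09 for a three-letter set) rather than uniformly: real binding
sites are sharper than their IUPAC summary — a site model flat over the
allowed letters has a best-window tail probability of 9/4⁷ ≈ 5.5·10⁻⁴ and
could therefore never produce a single site at the p < 10⁻⁴ threshold used
for site calling. The discovery fixture (`planted_motif_fixture`) plants two
instances per positive promoter, consistent with target promoters typically
carrying more than one occurrence. With flat single-instance planting the
element's information content (≈10.8 bits) falls below the ≈11 bits needed
to localise one site in 2×994 candidate windows, and no occurrence-based
method could recover it.

## FPKM and expression status

`FPKM_gs = counts_gs / (length_g/10³) / (total_s/10⁶)` with `total_s` the
column sum; by construction Σ_g FPKM·length_kb = 10⁶ per sample. Status is
taken from the reference strain's replicate-mean FPKM per timepoint:
< 1 not expressed, in [1, 20] low (both boundaries classed low; the
not-expressed cut is strict), > 20 expressed. Heatmap matrices are
log₂(mean FPKM + 1) per genotype × timepoint (base configurable).

## Negative-binomial Wald test

Counts are normalised by median-of-ratios size factors (median over genes
with no zero in any sample of count / gene geometric mean). For a contrast
(mutant vs reference at one timepoint), `log2FC = log2((m_mut + 0.5) /
(m_ref + 0.5))` on normalised group means. The dispersion is a pooled
method-of-moments estimate from within-group residuals,
α = (s² − μ̄_w) / μ̄²_w with df-weighted group means, floored at 10⁻⁸.
Standalone `nb_test` pools the two groups of the contrast; the pipeline
(`run_contrasts`) estimates α once per gene from **all** genotype×timepoint
groups of the design (df = 16 for the default 32-sample design) and shares
it across contrasts — at two replicates a per-contrast estimate has 2 df and
the Wald reference distribution is unusable.

The squared SE of log2FC is the delta-method sum
`(m_g + c·α·m_g²) / n_g / (m_g + 0.5)²` over both groups (÷ ln²2), where
`c = df/(df−2)` for df > 2 is the unbiasedness factor of the inverse
chi-square: the Wald statistic divides by an *estimated* variance, and
without this correction the two-sided normal p-values are noticeably
anticonservative at small df (null rejection ≈ 0.09 instead of ≈ 0.06 at
5 vs 5 with α = 0.1). Genes with zero counts in both groups get p = 1.
BH adjustment is applied within each contrast; calls require fold change
strictly > 1.5, padj ≤ 0.05 (inclusive), and the matching sign.
No dispersion shrinkage across genes is performed (deliberately out of
scope); gene-level results will not be numerically identical to any
particular external DE package.

## Dependency classification

The 7-bit regulation pattern is extended to the 8-genotype truth table with
the reference fixed false. If the true set is upward-closed under inclusion,
its minimal elements are the clauses of the unique minimal monotone DNF
(fewest clauses, then fewest literals — verified exhaustively against a
brute-force clause search over all 19 monotone-consistent patterns).
Patterns violating monotonicity are labelled `complex`. Classes: `single`
(one 1-literal clause), `and` (one multi-literal clause), `or` (several
1-literal clauses), `mixed` (otherwise). The predominant TF of a multi-TF
call is the one with the extreme single-deletion log2FC in the call's
direction; TFs within 0.1 log2 units (configurable) of the extreme tie, and
a missing single-mutant value yields an explicit `undetermined`. Venn
regions assign a gene to circle X iff literal X appears in its expression;
`none` and `complex` fall into the none bucket. Temporal switches compare
canonicalised expressions between timepoints. Up-regulation (antagonistic
responses) is classified by the same machinery with direction `up` and
reported separately. "Abolished" (mutant FPKM < 1 while the reference is
expressed) is annotated via the recovery metrics but never alters the
Boolean pattern.

## Clustering

Complete-linkage agglomeration on Euclidean row distances, implemented
directly so ties are reproducible: among minimum-distance pairs the pair of
clusters containing the smallest original row indices merges first. Rows are
clustered as provided (no scaling/centering, matching the logged-FPKM
heatmap convention); columns are not clustered. Merge heights were checked
against SciPy's complete linkage on random instances; output uses the SciPy
linkage-matrix format so standard cutting/plotting tools apply.

## Motif machinery

*Position convention.* For a promoter of length L (5'→3' on the upstream
strand, ending at the start codon), a window with leftmost 1-based
coordinate s is reported at `upstream_position = L − s + 1` on both strands;
the anchor is always the leftmost base of the matched window on the forward
sequence, with strand reported separately.

*IUPAC scanning* is exact, both strands, overlaps included; N never matches.

*PWM scanning.* Log-odds scores (bits, against a 0-order background) are
discretised at 10⁻³ bits; the null distribution of the integer window score
is computed exactly by convolving per-position score distributions, and the
p-value of a window is the tail probability of its integer score. Scanning
shares the discretisation, so DP p-values equal exhaustive enumeration
(verified for widths ≤ 8). The minus strand scores with the
reverse-complement matrix and its own null distribution, which keeps
p-values exact under asymmetric backgrounds. Hits require p strictly below
the threshold (default 10⁻⁴).

*ZOOPS-EM discovery.* Zero-or-one site per sequence, both strands, mixture
prior λ/(2m) per placement; the 0-order background is estimated from the
input; the M-step adds a Dirichlet pseudocount of 0.25 per cell. Because of
the pseudocount this is MAP-EM: the provably non-decreasing quantity is the
MAP objective (observed log-likelihood + 0.25·Σ log θ), which the
implementation records and the tests assert; the raw likelihood can drift by
tiny amounts. Starting points are the `seed_pool` (default 800) most
frequent w-mers by Hamming ≤ 1 occurrence count, each expanded into a seed
PWM from its occurrence-weighted Hamming-1 neighbourhood — this keeps
conserved positions sharp and genuinely degenerate positions soft, which
matters when individual motif variants are rare. Candidates are ranked by a
one-E-step likelihood and the best `n_seeds` (default 5) are refined by full
EM (default 50 iterations, tolerance 10⁻⁶). Across widths (default 6–10)
motifs are ranked by the ZOOPS log-likelihood ratio minus a BIC penalty of
1.5·ln(n_sites) nats per column (3 free parameters per column, estimated
from the ~n_sites aligned sites). The penalty is essential: EM realignment
gains ~1.5–3.5 nats per spurious flanking column, so unpenalised likelihood
always prefers the widest motif, even on pure background. The score
threshold (default 0) stands in for an E-value cut-off; no MEME-style
E-value is re-derived. Discovered consensus sequences are compared to a
reference pattern by best ungapped alignment over both orientations
(pattern positions aligned to disallowed letters plus unaligned pattern
positions), since two-strand discovery may return either orientation and
occasionally an off-by-one width.

*Enrichment.* Presence enrichment uses a 2×2 table (target vs background
promoters, with/without ≥1 hit), proportions, an odds ratio with the
Haldane–Anscombe 0.5 correction when any cell is zero, and a two-sided
Fisher exact p computed by direct hypergeometric enumeration (verified
against an independent implementation). Conservation scans report the
per-species fraction of ortholog promoters containing the motif and a
majority flag (> 0.5); ortholog identification is an input, not performed
here.

## Numerical and degenerate-input conventions

Zero-total samples, empty groups, missing contrasts, NaNs in clustering
input, empty bracket or unknown characters in patterns, zero background
frequencies for letters present in sequences, and planting that cannot fit
the promoter all raise informative errors rather than propagating silently.
All randomness flows through `numpy.random.default_rng(seed)`; identical
seeds give byte-identical outputs, including serialized models and every
pipeline TSV.

## Problem sizes

Default sizes keep a full run fast on one CPU: 300 simulated genes for the
end-to-end pipeline (~1 s), 10,000 genes for the null-calibration study,
5,000 for the power study, 1,000 random 1-kb promoters for scanner-oracle
agreement, and the 34-promoter (28 planted) fixture for discovery
(~25 s, dominated by seed scoring across the five widths).

## Known limitations

* Dispersion is estimated per gene without cross-gene shrinkage; very low
  replicate numbers outside the factorial pooling path give conservative
  floors rather than moderated estimates.
* The fold-change screen is applied to normalised counts, not FPKM; for
  equal-length comparisons of the same gene the two are equivalent up to the
  normaliser.
* `complex` patterns are reported, not interpreted; the classifier never
  invents a non-monotone Boolean explanation.
* The ZOOPS score threshold is a pragmatic stand-in for a calibrated
  E-value; weak motifs near the detection limit may rank below the fallback
  top-1 return.
* Real promoter backgrounds are not i.i.d.; discovery performance on real
  genomes will differ from the uniform-background fixtures.
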