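# Methods

`screenkit` re-implements the computational stack of a genome-scale pooled
shRNA viability screen: sequencing deconvolution, replicate quality control,
depletion-score processing, cell-line identity fingerprinting, and an
information-theoretic feature-matching method (RNMI) for linking genomic
contexts to gene dependencies. This note records the models, conventions and
numerical choices behind each module, and what the synthetic data used for
testing does and does not emulate.

## Screen model and deconvolution

A pooled screen transduces a library of hairpins (one construct per cell) into
each cell line, propagates the population for ~16 doublings, and reads out
endpoint hairpin abundances by sequencing. Each 45-base read carries a 4-mer
PCR barcode identifying the screening replicate, followed by the 21-mer
hairpin sequence. Deconvolution bins reads by barcode and counts hairpins by
exact string match against the reference 21-mer list; no mismatch tolerance,
quality filtering or alignment is attempted, because the constructs are known
sequences and the custom sequencing primer fixes both position and
orientation. Reads whose hairpin window matches nothing are tallied as
unmatched; in scan mode (constant-region length unknown) a read matching
reference hairpins at more than one offset is tallied as ambiguous. These
tallies satisfy the accounting identity
`matched + unmatched + ambiguous = reads per barcode`, which is asserted in
tests.

Counts are normalized to logged reads-per-million:

    normalized = log2((raw / column_total) * 1e6) + 1

The formula is -inf at zero reads. The package default adds a pseudocount of
1 to the numerator only (column totals are computed from raw counts), keeping
downstream correlations and quantile normalization finite; `pseudocount=0`
reproduces the formula literally and is used wherever exact agreement with
the printed form matters. The per-replicate minimum-depth check defaults to
1e7 reads and is report-only.

## Quality control

Two per-replicate metrics:

* **Reproducibility** — Pearson correlation with same-cell-line siblings. The
  threshold is either the fixed historical constant 0.6795 or, with
  `threshold="auto"`, the 75th percentile of all non-replicate pair
  correlations in the dataset at hand. A replicate passes if its *maximum*
  sibling correlation clears the threshold (a replicate is bad only when it
  agrees with none of its siblings); mean/median aggregation is available via
  `agg=`. A zero-variance replicate has undefined correlations and fails as
  "degenerate".
* **Distribution** — each replicate is scored by the 75th percentile of its
  logged normalized counts; replicates scoring below `mean − 1·SD` of all
  scores fail.

Percentiles use linear interpolation between order statistics and the SD is
the population SD: fixed, documented conventions rather than platform
defaults. Any cell line with fewer than 3 replicates passing both metrics is
removed whole, then curated manual removals (e.g. engineered lines) apply.
The PCA batch report projects replicate samples (hairpins as features,
centered, unscaled) onto the first two principal components and joins
annotation categories for batch-effect inspection.

## Depletion processing chain

The post-QC chain runs in a fixed order that `run_pipeline` refuses to
permute, because the order is part of the method:

1. **Low-abundance filter** — drop hairpins whose median logged normalized
   count in the plasmid DNA pool is ≤ 1 (boundary inclusive). Poorly
   represented constructs cannot report depletion reliably.
2. **Overlap filter** — drop one of any same-gene pair of hairpins whose
   sequences overlap at an offset of < 3 bases (offset 3 keeps both).
   Overlap is detected as sequence-shift equality — a proxy for genomic
   offset, since the data files carry no coordinates. The survivor is the
   member with higher plasmid-pool abundance (ties: lexicographically
   smaller barcode), applied greedily in priority order so the surviving set
   contains no overlapping pair. Near-identical hairpins share both on- and
   off-target spectra, so their measurements are not independent.
3. **Sample removal** — apply the QC verdicts and manual list.
4. **Fold change** — logged sample minus logged reference-pool column, each
   replicate mapped to the reference of its own sequencing-chemistry batch;
   batches merge into one matrix only after this step.
5. **Quantile normalization** — every column is forced onto the mean
   empirical distribution (sorted values replaced by across-column means of
   order statistics); ranks are preserved, ties receive the average of the
   tied target values. Note that with a heavy depleted tail this step
   slightly compresses extreme depletion scores toward the column average —
   visible in the synthetic screen as a ~0.3 log2 attenuation of a −4
   planted effect.
6. **Replicate collapse** — arithmetic mean per cell line (median by
   config); mean is the conventional collapse for ≤ 4 replicates.
7. **Gene mapping** — each hairpin row is annotated with its gene symbol(s)
   from the `.chip` map in the Description column; rows are never
   aggregated (gene-level summarization is a separate algorithm, out of
   scope). Multi-symbol hairpins get semicolon-joined symbols so rows stay
   unique; unmapped hairpins get `NO_SYMBOL`.

## SNP fingerprinting

Cell-line identity is verified by the fraction of concordant genotype calls
between a post-screen panel and a reference panel over shared dbSNP sites.
`NoCall` on either side excludes the SNP; heterozygotes are allele-sorted
(AB ≡ BA) before comparison because calling platforms disagree on allele
order. Fewer than `min_snps` (default 20) comparable sites yields an
"insufficient" verdict instead of an exception. The match threshold defaults
to 0.8: for a ~79-SNP biallelic panel, unrelated lines agree at the
Hardy–Weinberg chance level Σ_g P(g)², around 0.4 for intermediate allele
frequencies, so 0.8 separates identity from chance with a wide margin. Both
numbers are configuration, not biology.

## RNMI feature matching

Given a target profile t (e.g. mutation status across cell lines) and an
essentiality profile x (depletion scores of one hairpin or gene solution),
the score is built from kernel density estimates of the joint distribution:

    H(t,x)    = -∬ P(t,x) log P(t,x) dt dx          (joint entropy, nats)
    MI(t,x)   =  ∬ P(t,x) log[P(t,x)/(P(t)P(x))] dt dx
    NMI(t,x)  =  MI(t,x) / H(t,x)
    RNMI(t,x) =  sign(ρ(t,x)) · NMI(t,x) / NMI(t,t)

Normalizing MI by the joint entropy makes scores comparable across profiles
with different entropies; rescaling by the self-score NMI(t,t) pins a perfect
match at +1; the Pearson-correlation sign supplies directionality, so a
perfect anti-match is −1 and a random pair ~0. Unlike correlation, MI also
responds to non-linear dependence (e.g. x = t² scores high NMI at ρ ≈ 0).

**Estimation.** Continuous pairs use a product Gaussian kernel evaluated on a
64×64 grid spanning each variable's range ± 3 bandwidths; the joint is
renormalized to unit mass, marginals are row/column sums, and entropy/MI are
Riemann sums with a density floor of 1e−12 before logs; MI is clipped at 0
and |RNMI| at 1. Everything is in nats; only ratios matter downstream. The
grid construction is mirror-consistent: negating x mirrors the grid and the
kernel exactly, so NMI(t,−x) = NMI(t,x) and RNMI(t,−t) = −1 to floating-point
accuracy.

**Binary targets.** A two-valued target (the flagship mutation-status case)
is treated as discrete: the joint is class prior × class-conditional 1-D KDE
of x, and the integrals run over the mixed discrete-continuous grid. KDE over
a two-valued coordinate would be ill-posed. The self-score of a binary target
is the discrete-discrete case, where MI(t,t) and H(t,t) both equal the
Shannon entropy of the class prior, so NMI(t,t) = 1 exactly.

**Bandwidths.** Two selectors: the Silverman rule
0.9·min(sd, IQR/1.349)·n^(−1/5), and leave-one-out least-squares
cross-validation over a 13-point log ladder of multipliers {0.25…4} × rule of
thumb (closed-form LSCV risk for the Gaussian kernel; ties to the smaller
bandwidth; falls back to the rule of thumb if the risk is degenerate).
Single-pair estimation (`estimate_density`, `nmi`, `rnmi`) defaults to CV.
Cross-feature ranking (`score_all`, `permutation_significance`) defaults to
the Silverman rule: at screen-typical sample sizes (n ≈ 60) the CV-selected
multiplier fluctuates between 0.5 and 2.0 across identically distributed
features, which moves the joint-entropy denominator of NMI — and therefore
the ranking — with selection noise rather than signal. CV remains available
everywhere via `bandwidth="cv"`.

**Degenerate cases.** Constant profiles are refused. If the joint
differential entropy is ≤ 0 (possible for very peaked densities), NMI's sign
would be meaningless; the package raises an "entropy underflow" error and
suggests `rank_transform=True`, a normal-scores transform that restores
H > 0.

**Significance.** The target values are permuted `n_perm` times (default
1000) and re-scored against every profile; all permuted scores pool into one
global null. Matches and anti-matches are distinct discoveries, so a
feature's nominal p compares its score with the null scores of its own sign:

    p = (1 + #{same-sign null at least as extreme}) / (1 + family size)

which is uniform under the null (verified by a KS check in the acceptance
suite). `two_sided=True` collapses to |RNMI| against |null|. FDR is
Benjamini–Hochberg over the nominal p-values; an empirical
ratio-of-tail-rates FDR is reported as an extra column on request. For binary
targets the permutation engine is vectorized: each profile's kernel matrix on
its own grid is invariant under permutation of t, so a permutation reduces to
class sums, and 1000 permutations × 200 features run in about a second.
Continuous targets take a per-profile loop and are proportionally slower.
Results are bit-reproducible given the seed.

## Synthetic data: what it models

The generator draws plasmid abundances log-normal (default σ = 0.5 on the
natural-log scale; the real library's dispersion is not published, so this is
a free parameter), assigns each gene a label (neutral, always-essential, or
context-dependent on a binary per-line feature with 30% positives), and grows
hairpin i in line j over D doublings as a_i · 2^{D(1−s_ij)} for per-doubling
fitness deficit s_ij. Replicate noise multiplies abundances by
exp(N(0, σ_rep²)) (default σ_rep = 0.1) and sequencing draws a multinomial of
the configured read depth. The closed-form expected log2 fold change,
−D·s_ij minus a small pool-renormalization shift, is recorded in the truth
table and anchors the parameter-recovery tests: the default deficit s = 0.25
over D = 16 doublings gives −4.

Default desk-scale conditions: 5,000 hairpins over 1,000 genes (5 per gene),
12 lines in quadruplicate, 16 doublings, 10^6 reads per replicate.
`ScreenSimConfig.full_scale()` gives the library-scale 54,020-hairpin /
102-line configuration; tests use desk scale. The dilution-series generator
mixes four equal subsets of a 45,000-hairpin library at 1:1:1:1 and
1:4:16:64 concentrations from shared per-plasmid abundances and sequences
each pool multinomially; the recovery analysis summarizes each pool's
subsets by the median normalized value of detected hairpins and differences
the pools per subset, because at 10^6 reads the most dilute subset averages
~1 read per hairpin and per-hairpin log differences are dominated by the
undetected (-inf) tail. Genotype panels are Hardy–Weinberg draws with allele
frequencies uniform on (0.1, 0.9) plus per-call error and NoCall dropout.

Not modeled: sequencing errors (exact-match counting makes them equivalent
to a small uniform loss), clonal heterogeneity, passage bottlenecks,
infection-rate variation, or batch-specific chemistry artifacts. Passing
tests therefore demonstrate the correctness of the computational chain under
a clean generative model, not robustness to every artifact of real screens.

## Problem sizes and determinism

Every generator and every stochastic analysis takes a seed and is a pure
function of (configuration, seed). The test suite runs at desk scale
(seconds per module); the planted-context recovery uses 60 lines × 200
features × 1000 permutations and the null-uniformity check the same shape.
All percentile, tie-break and floor conventions mentioned above are fixed in
code, not left to platform defaults.
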