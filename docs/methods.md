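# Methods

## The question

LD-pruning before an exhaustive gene–gene interaction screen trades two risks
against each other: leaving correlated SNPs in produces redundant epistasis
findings and inflates the multiple-testing burden, while pruning can delete
the causal SNPs themselves, leaving only tagging pairs to carry the signal.
This package implements the full simulation machinery to quantify that
trade-off for an MB-MDR-style screen: synthetic founder panels with block-LD
structure, forward-time expansion with allele-frequency trajectory control, a
pure-epistasis disease model, rejection-sampled case–control cohorts, the
H/L/O two-locus contrast test with Westfall–Young maxT correction, and
replicate-level sensitivity/FWER criteria.

## Disease model

The trait is Bernoulli with logistic penetrance

    logit(pi) = b0 + b1*g1 + b2*g2 + b3*g1*g2,

with `g1 in {1,2,3}` coding the DSL2 risk-allele dosage (0/1/2 copies) and
`g2 in {0,1}` the DSL1 carrier indicator.  Defaults `b0 = -5`, `b1 = b2 = 0`
give *pure* epistasis (no marginal effects on the logit scale) and a
prevalence K near 1%; each extra DSL2 risk allele multiplies the odds by
`exp(b3)` — 1.65 / 2.12 / 2.46 for `b3` = 0.50 / 0.75 / 0.90 — but only in
DSL1 carriers.  This mirrors the epistatic-recessive masking reported between
HLA-B*27 and ERAP1 in Ankylosing Spondylitis.  The reference allele
frequencies are DSL1 risk MAF 0.05 and DSL2 risk-allele frequency 0.60 (the
DSL2 *minor* allele, frequency 0.40, is protective: the risk allele is the
major one, and the sampler converts dosage accordingly).

Heritability is computed in the literal nine-cell form

    h2 = sum_i [ pi(G_i) p(G_i) - K ]^2 / ( K (1 - K) )

over the nine expanded two-locus genotype combinations (the DSL1 heterozygote
and minor homozygote are separate cells even though they share the carrier
penetrance).  This form — with the cell frequency *inside* the squared
deviation — is what produces the reference values 0.083 / 0.071 / 0.059 and
is deliberately not the textbook genotypic-variance decomposition, which is
shipped alongside as `heritability_genotypic` (it gives ~0.025 at b3 = 0.90).
The two must not be conflated when comparing effect sizes across studies.

## Synthetic founder panels

Real block-LD haplotypes are emulated, not downloaded.  Each of two
chromosome segments (defaults 964 and 787 sites, mimicking two 250-kbp
regions on chr7 and chr8) is tiled by blocks; within a block every one of the
2x91 founder haplotypes copies one of `pool_size` ancestral haplotypes with
per-site flip probability `flip_rate`.  Small pools / low flip rates give
tight blocks (r2 near 1 among pool-informative sites); large pools / high
flip rates dissolve them.  Blocks are generated independently, so cross-block
and cross-segment r2 is zero in expectation — the panels reproduce the
qualitative feature that matters here (blocks of differing size and
intensity, separated by low-LD gaps), not any particular empirical block map.
Ancestral site frequencies are uniform on (0.05, 0.5); flip noise adds a tail
of rare variants, some of which fail QC, as in real panels.

Causal-site placement supports the four study settings: DSL2 in the same
block as DSL1 (A), mid-block in another block (B), at a block edge (C,
defined as the outermost two sites), or on the other chromosome (D).  The
placement picks the role-compatible site whose founder MAF is closest to the
target (0.09 for DSL1; 0.42/0.33/0.35/0.19 for DSL2 A–D) and, if none is
within ±0.03, re-draws that column through the block's ancestral pool —
re-choosing which pool haplotypes carry the minor allele so the expected
count matches, then flipping a minimal random set of entries to hit the
target count exactly.  This preserves the column's block LD while pinning its
frequency.

Marker QC retains sites with MAF > 1%, missingness < 10% and an exact
Hardy–Weinberg test p ≥ 5e-15.  The HWE test enumerates the conditional
(Levene–Haldane) distribution of the heterozygote count with the standard
recurrence; no mid-p correction.  The generator itself produces complete
data; the missingness rule exists for external PED/MAP input.

## Forward-time expansion

The founder cohort grows linearly (`N_g = round(N0 + g (Nf - N0)/G)`, i.e.
the same increment each generation) to 10,000 individuals over 500
generations under random mating with two distinct parents per offspring, no
recombination, no mutation, no migration, no selection.  Under those rules
transmission is label copying, so individuals are stored as pairs of
founder-haplotype labels per segment (segments assort independently) and the
full expansion runs in well under a second; genotypes are materialised on
demand.  Every haplotype in every generation is literally one of the 182
founder haplotypes — the closure property the tests assert.

Disease-predisposing-allele frequencies at the causal sites are steered to
their final targets (0.05 and 0.40) by trajectory control: a generation is
accepted only if each controlled frequency lies within a band around the
straight line from its founder frequency to its target.  The band is
relative ±20% of the current path value with an absolute floor of ±0.02
(the floor dominates for the rare DSL1 allele); a generation that fails 100
redraws restarts the whole run on a fresh random substream.  Band width and
restart policy are configuration, not biology: the tighter the band, the
closer the landing but the higher the redraw cost.  With these defaults a
full-scale run typically lands DSL1 within ±0.015 of 0.05.

## Case–control sampling

Cohorts are drawn by rejection sampling: individuals uniformly **with
replacement** from the standing final generation, status Bernoulli(pi(G)) by
their two-locus genotype, accepted until each arm quota (default 1000/1000)
is filled.  Replacement is necessary — a population of 10,000 at K ≈ 1%
holds only ~100 affected individuals — and an alternative mode draws fresh
random-mating offspring per draw instead.  The case arm's nine-cell genotype
distribution is pi(G)p(G)/K and the control arm's (1-pi)p(G)/(1-K); both are
verified by goodness-of-fit at n = 10,000.

## The screen

For each SNP pair the 3x3 genotype cells are labelled H/L/O: cells with
fewer than `min_cell = 10` subjects are O; otherwise a 1-df Pearson
chi-square of (cell vs all other cells) x (case vs control) at
`alpha_cell = 0.1` decides evidence, with direction given by the cell's case
proportion.  The pair statistic pools H-cell and L-cell subjects into a 2x2
(H/L x case/control) table, excluding O subjects, and takes the 1-df Pearson
chi-square; no H or no L cells mean statistic 0.  `alpha_cell` and
`min_cell` follow common MB-MDR practice and are exposed as configuration;
no main-effect correction is applied since the simulated signals are pure
epistasis.

Significance is Westfall–Young step-down maxT: B permutations (999 at full
scale, 199 desk-scale) of the status vector on one shared stream, the full
scan recomputed per permutation, adjusted p from successive maxima with
monotonicity enforced; zero-statistic pairs get p = 1 outright.  The
implementation builds the whole (B+1) x pairs statistic matrix from one
dense matrix product per pair chunk (permuted status vectors times cell
one-hot indicators), so a 199-permutation scan of ~20,000 pairs takes
seconds.  On independent-SNP null data the realised FWER at alpha = 0.05 is
close to nominal, with a mild conservative lean from ties in the discrete
statistic.  Real LD landscapes have been reported to make maxT markedly
conservative (a subset-pivotality issue under correlated tests); the
synthetic block panels here do not reproduce that strong effect, so the
package reports the block-LD estimate with its CI rather than asserting
conservatism.

## Pruning and performance criteria

Pruning slides a 10-SNP window in steps of 2 along each chromosome (never
across chromosomes); within a window, surviving pairs are scanned in index
order and the *later* member of any pair with r2 above the threshold is
removed, removed SNPs staying removed.  Dropping the later member (the
common greedy choice) keeps the first-seen representative and makes the
procedure deterministic; which member to drop and the scan order are
documented configuration, since different tools differ.  Note that survivor
sets at different thresholds are *not* nested in general — only on cleanly
bimodal block structure.

Tag sets are built on the complete, unpruned panel: all sites with r2 ≥ 0.20
(or 0.45) to a causal site, no window restriction.  Exact sensitivity is the
fraction of replicates in which the exact causal pair is significant at
adjusted p ≤ 0.05 (a replicate whose pruned input lost a causal SNP is a
miss by construction); signal sensitivity accepts any significant pair with
one member in each causal site's tag set (one-to-one; a pair cannot use the
same SNP for both sides).  FWER is the fraction of status-randomised null
replicates with any significant pair, genotypes held fixed across
replicates.  All three are Bernoulli means reported with binomial standard
errors (Clopper–Pearson CIs where an interval is needed).

## Desk-scale study conditions

The full grid — 4 settings x 3 effect sizes x 100 replicates of 1000+1000
subjects over 1751 SNPs with 999 permutations — is the default
configuration and is scheduled but not executed in the test suite.  The
analysis drivers and acceptance checks run a scaled variant chosen once:
two 100-SNP segments, expansion 91 → 2,000 over 100 generations, 500 cases +
500 controls, 20 replicates, 199 permutations, and a single effect size
b3 = 1.2.  The larger effect compensates the halved sample size (at n = 1000
total, the b3 ≤ 0.9 effects would rarely reach corrected significance, so
the orderings under study would be vacuous), and 199 permutations keep the
smallest attainable adjusted p (0.005) well below alpha = 0.05.  The scaled
grid reproduces the directional findings — signal ≥ exact sensitivity
everywhere, collapse of exact sensitivity when pruning removes a causal SNP,
wider tag sets capturing at least as much signal — but its absolute power
values are not comparable to the full-scale study, and nothing in this
package can reproduce absolute results that depend on the real GBR
haplotypes (published tag counts, per-setting power tables, the <1%
block-LD FWER figures).

## What the synthetic panels do not model

No recombination map, no mutation, no phasing ambiguity, no genotyping
error, no population substructure, and block boundaries are generator
artefacts rather than estimated haplotype blocks.  Passing tests therefore
demonstrate the statistical machinery and its orderings under controlled LD,
not performance on any particular empirical LD landscape.

## Numerical notes

- All randomness flows through `numpy` Generators from explicit seeds;
  grid-cell seeds derive from the master seed via `SeedSequence` spawning,
  so every table is bit-reproducible.
- r2 is the squared Pearson correlation of 0/1/2 dosages with
  pairwise-complete handling of missing calls; zero-variance columns yield
  NaN, which pruning treats as 0 (never prune on undefined LD).
- Permutation comparisons use ≥, the conservative convention for ties; the
  permutation count enters p-values as 1/(B+1).
- `top_k` breaks ties by larger statistic, then lexicographic pair order,
  for stable output.
- The statistic engine carries counts as float32 through the BLAS product
  and float64 through the chi-square arithmetic; with n ≤ 2000 subjects all
  counts are exactly representable.
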