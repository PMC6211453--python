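# Methods

## Model

`clippeaks` segments each gene independently into four hidden states: P
(peak: CLIP enriched over background), B1 (background enriched over CLIP),
B2 (both channels comparable) and N (little or no coverage anywhere). The
per-position emission is the product of a coverage likelihood and a
diagnostic-event likelihood, both evaluated jointly over all CLIP and
background replicates.

### Coverage

Counts are negative binomial with variance `mu + c*mu^2`, `c >= 0` a single
genome-wide scalar (`c = 0` is evaluated as an exact Poisson branch). The
log mean for library *w* at a position of gene *g* is

    CLIP:        P: l_w + b_g + b_e    B1: l_w + b_g - b_e    B2: l_w + b_g    N: l_w + b_0
    background:  P: l_w + b_g - b_e    B1: l_w + b_g + b_e    B2: l_w + b_g    N: l_w + b_0

with `b_e >= 0` the shared enrichment coefficient (one value for both the
CLIP-over-background and background-over-CLIP directions) and `b_0` the
abundance of un-annotated/silent regions. Library sizes `l_w` are fixed
offsets, estimated once as the log of the median over genes of the gene's
mean per-position coverage (genes with zero coverage in the library are
excluded); they are stored on the log scale so the predictors stay additive.

Fitting maximizes the state-posterior-weighted likelihood. Observations are
additionally weighted by the inverse total posterior mass of their state so
the rare P state is fitted as well as the abundant ones. Because the GLM
mean is constant within a (gene, library, state) cell, the IRLS working
weights and responses depend on the data only through two per-cell sums
(posterior mass, and posterior-weighted counts); the solver therefore runs
on G x L x 4 aggregated rows with a 2-nonzero-per-row sparse design and a
sparse LU factorization of the normal equations. This aggregation is exact
— no per-position design matrix is ever formed and no subsampling of
positions is needed for the beta step. IRLS stops at max |delta beta| <
1e-4 or 50 iterations; a tiny ridge (1e-8) keeps the normal equations
nonsingular for genes with vanishing posterior mass. The enrichment
coefficient is clamped at zero from below after each solve.

The dispersion `c` alternates with the beta step (up to 5 alternations):
a bounded scalar MLE of log c on [log 1e-6, log 1e3], evaluated on a seeded
subsample of at most 20,000 positions (all libraries and states, with their
posterior weights). The subsample is frozen across EM iterations so the
alternation does not jitter from resampling. On the datasets used here the
subsample covers 5% or more of all positions and the estimate is stable to
well under the 50% tolerance the recovery tests demand.

At emission time, genes fitted below the silent level (`b_g < b_0`) are
lifted to `b_0 + b_e + 1e-5` in a copy of the parameters, so that every
gene prefers one of the expressed states over N; the fitted values are left
untouched.

### Diagnostic events

Events are counted in M = 18 categories — 12 substitutions, 4 single-base
deletions and the two read ends — plus a trailing "no event" slot that
completes each vector to the position's coverage. Both ends are encoded so
5'-truncation protocols (iCLIP/eCLIP) and any future 3'-anchored chemistry
are representable; the mixture learns which categories carry signal.
Conversions in the first or last two bases of a read are discarded as
likely mis-mapped ends; deletions and end events are never offset-dropped.
Insertions are not counted as events.

At a position, the replicates' event vectors share one latent multinomial
rate `q` drawn from a Dirichlet; the marginal is the closed-form product of
multinomial coefficients times a multivariate-Beta ratio. A K = 10 mixture
of such Dirichlet-multinomials is fitted by EM: responsibilities in the
E-step, mixture weights and a digamma fixed-point update of each alpha
(two inner iterations, entries floored at 1e-6) in the M-step. Because
event vectors repeat massively along the genome, all bulk evaluations and
the EM itself operate on unique aggregated rows with multiplicities.
Training runs on at most 1,000,000 covered positions; each fit runs four
uniform-random initializations (alpha ~ U(0.5, 2), uniform weights)
alongside the previous iteration's solution and keeps the best likelihood.

Two mixtures are maintained: the *peak* class, trained on CLIP-library
events at the current peak positions, and the *background* class, trained
on background-library events at the same positions. Positions where genes
overlap are excluded from training (antisense reads would dilute the
signal), as are SNP-masked positions. Before any peaks exist (first
iteration), the top 1% of CLIP-covered positions serve as provisional peak
positions. For emission, state P scores CLIP events under the peak mixture
and background events under the background mixture; all other states score
every library under the background mixture — only the peak state asserts
crosslink chemistry, and only in the CLIP channel. Without background
libraries, the background mixture falls back to CLIP events at non-peak
covered positions.

### Transitions and EM

The probability of remaining in the current state at each step is
`f = sigmoid(w0 + w1 * log1p(total coverage))` at the step's source
position, with the remaining mass split uniformly over the other three
states; the initial distribution is uniform. (w0, w1) are fitted to the
expected stay posteriors by minibatch SGD with a decaying step over a fixed
epoch budget, keeping the best full-batch objective seen. Degenerate
targets (all stay posteriors at 0 or 1) keep the prior parameters.

The outer EM runs at least 5 and at most 10 iterations, stopping early
when the total log evidence improves by less than 1e-3 relative. The
forward–backward and Viterbi recursions exploit the stay/switch transition
structure (O(states) per step) and are compiled with numba; a generic
log-space implementation handles arbitrary transition stacks and serves as
the cross-check. Because the M-steps are mildly stochastic (mixture
restarts, subsampled dispersion), the evidence can occasionally dip; the
returned model is the best-evidence iterate.

### Peak calling

Peaks are maximal runs of P in the Viterbi path. An optional additive log
penalty on the P state (e.g. -5 for eCLIP-style data, off by default) is
applied at decode time only and narrows calls to peak cores. The peak
score is the summed per-position log-likelihood ratio of P against the
best competing state ("best" rather than the sum — the ratio then measures
the margin over the strongest alternative explanation). The p-value sums
the expected mean and variance of CLIP coverage under the non-enriched,
expression-matched B2 state over the peak's positions and CLIP libraries,
moment-matches a negative binomial (`r = mu^2/(var-mu)`,
`p = mu/var`) and takes the upper tail of the observed total; if the
summed variance does not exceed the mean the Poisson tail is used.
Bonferroni correction uses the number of candidate peaks genome-wide;
peaks with adjusted p above 0.05 are dropped. The summit is the position
with maximal CLIP-event log-odds (peak mixture minus background mixture).
Viterbi ties break toward the state order P < B1 < B2 < N.

### Read handling

Reads with more than two mismatches, or on the wrong strand when strand
information exists, are discarded. Coverage counts full read footprints
clipped to the gene span. Positions whose pooled background coverage is at
least 20 reads with at least 20% conversions are masked as likely SNPs
(pooled across background libraries rather than per-library): they keep
their coverage but contribute no event counts. Positions in annotated
miRNA genes are zeroed entirely. Gene positions covered by another gene on
either strand are flagged and excluded from event-model training only.
Coordinates are 0-based half-open internally; GTF input is converted from
1-based closed; BED output is 0-based half-open. Multi-mapper policy is
left to the upstream aligner.

## Simulator

The generator emulates a PAR-CLIP-style experiment with a deliberately
non-canonical diagnostic event (A>T) so that nothing downstream can rely on
a hard-coded event type:

- per-gene abundance `g = exp(N(10, 4))`; per-replicate transcript counts
  NB with mean `g` and variance `g + 0.1 g^2` (six replicates: two
  background, two CLIP, two held-out non-specific);
- a random single-chromosome genome of 200 single-exon, forward-strand
  genes of 1.5–2.5 kb with 1 + Poisson(1.5) planted Pumilio-like motif
  instances each (consensus TGTAAATA, sampled from the PWM with the fourth
  base forced to A so it is crosslinkable);
- per-library fragment sampling proportional to replicate counts at 2x10^5
  reads of 30 bp; background libraries are used as-is;
- CLIP libraries keep only fragments overlapping a predicted motif match
  (PWM log2-odds >= 3.0, pseudocount 5e-5, forward strand), retained with
  probability `(s - s_min)/(s_max - s_min)` where `s` is the read's best
  overlapped motif score — so stronger motifs collect more reads;
- retained reads covering their motif's fourth base receive an A>T
  conversion with probability 0.5 (recorded per read in the truth object);
- 10% of each final CLIP library is admixed from the held-out libraries.

The stated retention sentence in the original description of this scheme is
ambiguous about direction; this package implements the monotone-increasing
retention that realizes stronger signal at stronger motifs, and exposes
`literal_retention=True` for the opposite reading. Ground truth records
the true abundances, every crosslinkable site (fourth base of each motif
match whose base is A — threshold matches in random background sequence are
included, since reads are retained around them too) and per-read conversion
labels. What the simulator does not emulate: splicing and multi-isoform
structure, antisense transcription, paired ends, sequencing errors, mapping
ambiguity, UMI/PCR duplication. Passing tests therefore demonstrate
correct inference under the generative assumptions, not robustness to
alignment artifacts or annotation errors in real data.

## Scales, defaults and numerics

The shipped defaults (200 genes x ~2 kb, 2+2 replicates, 2x10^5 reads per
library) are a desk-scale version of a chromosome-wide experiment, chosen
so a full double fit completes in minutes; all sizes are config fields.
The acceptance script and tests run at exactly these defaults. Other
numerical choices: linear predictors clamped to ±30 before exponentiation;
emission likelihoods are finite for all observed counts; empty genes decode
to N; positions with all-(-inf) emissions raise with the offending
position named. Determinism: every stochastic step draws from a
`numpy` Generator seeded from the single run seed, so identical seeds give
byte-identical outputs.

## Known limitations

- Genes are processed as independent chains; peaks cannot span gene
  boundaries, and intergenic signal is invisible.
- A single dispersion is shared across libraries and states; strongly
  heteroskedastic replicates would be better served per-library.
- The Bonferroni-corrected NB tail p-value is conservative and treats
  positions within a peak as summable without within-peak correlation.
- The background mixture for CLIP-only data (no background libraries) is
  trained on non-peak CLIP positions, which biases it toward silent
  positions; results with a real background/input library are preferable.
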