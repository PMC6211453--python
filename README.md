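# clippeaks

Probabilistic peak calling for CLIP-seq experiments (PAR-CLIP, HITS-CLIP,
iCLIP, eCLIP and related protocols), for researchers mapping protein–RNA
interaction sites from aligned sequencing reads.

CLIP libraries pile up reads at binding sites, but peak height is confounded
by transcript abundance, local biases and library depth, while the
nucleotide-level evidence of crosslinking — diagnostic events such as T>C
conversions, deletions or read truncations — differs between protocols.
`clippeaks` addresses both problems with an unsupervised, per-gene
segmentation:

- **Coverage model.** The count `X_i^w` of library *w* at position *i* of
  gene *g* is negative binomial with `log mu = l_w + beta_g ± beta_{G+1}`
  (state-dependent sign of the shared enrichment coefficient; `l_w` a
  library-size offset, `beta_g` gene expression) and variance
  `mu + c*mu^2`. Fitting is posterior-weighted IRLS on a sparse design,
  alternated with a bounded scalar MLE for the overdispersion `c`.
- **Diagnostic-event model.** Event-count vectors over M = 18 categories
  (12 substitutions, 4 deletions, 5'/3' read ends) plus a "no event" slot
  follow a K = 10 component Dirichlet-multinomial mixture with the latent
  rate vector shared across replicates; a *peak* mixture is learned from
  CLIP events at peak positions and a *background* mixture from the
  background libraries, so the relevant event chemistry is learned from the
  data rather than assumed.
- **Segmentation.** A four-state non-homogeneous HMM (P peak, B1/B2
  background-dominated/comparable, N silent) whose stay probability is a
  logistic function of local coverage; EM alternates forward–backward
  E-steps with M-steps for the GLM, the two mixtures and the transition
  logistic. Peaks are maximal Viterbi P-runs, scored by the log-likelihood
  ratio against the best competing state, with an upper-tail NB p-value for
  the observed CLIP coverage against the expression-matched null and
  Bonferroni control at 0.05. Each peak's summit is the position with the
  strongest peak-vs-background event log-odds.

A matching simulator generates complete experiments — log-normal gene
expression `exp(N(10, 4))`, NB replicate counts with variance
`mu + 0.1*mu^2`, motif-anchored A>T crosslinks in 50% of covering reads,
motif-score-dependent read retention and 10% non-specific admixture — with
full ground truth (FASTA/GTF/SAM/BED/JSON), so the whole method is testable
without external data.

## Worked example

`examples/simulate_and_call.py` simulates 30 genes with planted crosslinks,
fits the model and calls peaks:

```
significant peaks: 63
fitted dispersion c: 0.620
fitted enrichment beta: 0.755
expression recovery (Spearman rho): 0.972
summit-at-crosslink fraction: 0.873

first peaks (chrom start end gene summit score p_adj):
  chr1 447 477 gene_0000 476 20.8 7.18e-03
  chr1 598 630 gene_0000 604 55.1 5.75e-15
  ...
```

The Spearman rho measures how well the fitted per-gene coefficients
`beta_g` order the true simulated abundances; the summit fraction is the
share of peaks whose maximal diagnostic-event log-odds position coincides
exactly with the planted crosslink base (the fourth base of the motif). The
other examples demonstrate individual components: `glm_expression_recovery`
(IRLS parameter recovery), `diagnostic_event_mixture` (DMM class recovery)
and `motif_scan` (PWM scoring).

## Command line

```
clippeaks simulate --out simdata --seed 1
clippeaks run --clip simdata/clip_1.sam --clip simdata/clip_2.sam \
    --background simdata/background_1.sam --background simdata/background_2.sam \
    --annotation simdata/genes.gtf --out run1
clippeaks score-motifs --fasta simdata/genome.fa --out motifs.bed
clippeaks shuffle-control --peaks run1/peaks.bed --annotation simdata/genes.gtf \
    --fasta simdata/genome.fa --out control_scores.txt
```

`run` writes `peaks.bed` (BED6 + summit offset, p, Bonferroni-adjusted p),
`model.json` (all fitted parameters) and a plain-text report. An
eCLIP-style `--peak-penalty -5` narrows calls to peak cores.

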