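# Methods

`halosrna` implements the computational core of a small-noncoding-RNA
(sRNA) landscape analysis for a haloarchaeon under a two-condition stress
design: classification of assembled transcripts against a gene annotation,
TPM-based filtering, paired sRNA-vs-target expression tests, count-based
differential expression, regulatory cross-tabulation with category
enrichment, and basal promoter (BRE/TATA) motif analysis. Every stage can
be exercised on synthetic data with planted ground truth.

## Coordinates and gene models

Internal coordinates are 0-based half-open, so the overlap of two
intervals is `min(ends) − max(starts)` with no ±1 corrections; GFF3/GTF
I/O converts to and from the formats' 1-based inclusive convention at the
boundary. Gene models are unspliced — a single CDS with optional 5′/3′
UTR sub-features, adequate for archaea/bacteria — and only single-exon
transcripts are accepted. UTRs are annotation inputs, never predicted; a
gene without an annotated 5′ UTR is leaderless, common in *Haloferax
volcanii*, and contributes zero 5′ UTR length to region binning.

## Classification

A transcript is **antisense** if it overlaps at least one gene (gene span
including UTRs — the annotated regulatory elements) on the opposite
strand by ≥ `min_overlap` nt (default 8) and overlaps no gene on its own
strand; **intergenic** if it overlaps no gene on either strand. Two
exclusion classes keep the calls honest: same-strand overlaps are
excluded outright (with strand-specific libraries a sense-internal sRNA
cannot be separated from its host gene's signal), and opposite-strand
overlaps of 1–7 nt are excluded as sub-threshold. A transcript that is
antisense to a gene *and* runs on into intergenic space is antisense:
the informative event is the overlap.

Each antisense sRNA is paired with every qualifying opposite-strand gene
(cis targets), sorted by descending overlap; the largest-overlap gene is
the primary target. The binding region label (5′UTR / 3′UTR / CDS) is the
region holding the maximal share of the per-base overlap breakdown; exact
ties break by 5′UTR > 3′UTR > CDS, preferring the mechanistically more
informative UTR contact. Missing UTRs are zero-length regions.
Overlap-length summary statistics (median/mean/range, 50-nt histogram)
are computed over primary pairs only, one value per sRNA.

## Quantification and filtering

TPM is the standard length-normalized relative abundance
`TPM_i = 10^6 (c_i/L_i) / Σ_j (c_j/L_j)`; every non-degenerate sample
column sums to 10^6 (relative tolerance 1e-9), and all-zero columns map
to all-zero output with a warning. The sRNA filter requires, per
condition, (i) presence — nonzero TPM — in ≥ 4 of 5 replicate libraries
and (ii) a condition-mean TPM at or above a class threshold: 40 TPM for
antisense, 14 TPM for intergenic sRNAs. The threshold is applied to the
condition mean by default (`mode="mean"`); a stricter per-replicate mode
is available since the prose description of such filters is often
ambiguous. Filtering is evaluated per condition, so an sRNA may pass in
one condition only.

## Paired expression tests

For each cis pair the per-replicate TPM of sRNA and target are compared
with a paired two-sided t-test on the differences
(`t = mean(d)/(sd(d)/√n)`, df = n−1); all-zero difference vectors give
t = 0, p = 1. Significance is raw p < α (0.05) — no multiplicity
correction at this stage, which reports a per-pair expression asymmetry
rather than a family-wise discovery. Raw TPM is compared by default
(log2(x+1) available via `log_transform`); an unpaired Welch option
exists behind `paired=False`.

## Differential expression

A deliberately transparent negative-binomial pipeline with
`Var = μ + αμ²`:

- **Size factors**: median-of-ratios against a per-feature geometric-mean
  reference over features with no zero counts, rescaled to geometric
  mean 1. Exact closed form: with a single shared condition mean the
  factors are exactly proportional to the true depths.
- **Dispersion**: per-feature pooled within-condition method of moments
  `α̂ = (s² − μ)/μ²`, df-weighted across conditions, floored at 1e-8. No
  shrinkage — the module's contract is calibration and recovery, not
  emulation of any specific DE package.
- **Wald test**: `log2FC = log2((m_s + c)/(m_c + c))` with pseudo-count
  c = 0.5 for stability at zero; the standard error comes from the delta
  method with the NB variance of each condition mean; two-sided p from
  the normal reference.
- **FDR**: Benjamini–Hochberg (via statsmodels), with an *inclusive*
  call at q ≤ 0.05.

Method-of-moments dispersion at n = 5 is noisy and the normal reference
is approximate; the calibration tests verify what matters for the
downstream claims: the null false-call rate at FDR 0.05 stays ≤ 0.07 and
planted |log2FC| = 2 at high expression is recovered with correct sign in
≥ 80% of features.

## Regulatory effects

Cross-tabulation assigns each cis pair its (sRNA call, target call)
combination; discordant pairs (up/down or down/up) are the expression
signature of negative regulation in cis. Pairs with an `ns` member are
counted in their own cells, and unresolvable pairs are listed, never
silently dropped. The `discordant_fraction` reported is discordant pairs
over pairs whose sRNA has a DE call. Category enrichment of asRNA target
sets is a one-sided hypergeometric upper tail per category with BH across
categories; the universe defaults to genes carrying a DE call, and the
category map is user-supplied (the synthetic fixture uses the gene
product strings).

## Promoter motifs

Windows of 100 nt up/downstream of each sRNA TSS are extracted in
transcription orientation — position 0 is the TSS base on both strands,
upstream negative, minus-strand windows reverse-complemented — truncated
and flagged at replicon edges. Motifs are log-odds PWMs against a uniform
background; the shipped defaults are *synthetic* archaeal-style consensus
strings (BRE `CGAAACGT`, TATA `TTTATATA`), user-replaceable, with
thresholds admitting only full-consensus matches. Scanning is
single-orientation (promoter elements are directional) and confined to a
basal-promoter search region of −60…−10 nt by default (`scan_range`),
the same positional restriction idea as central-enrichment motif tools;
this keeps rare chance 8-mers elsewhere in the window from entering the
positional statistics. A hit is the maximal-score placement (ties to the
most-upstream position), reported as the TSS-relative position of the
motif's first base. The **centroid** of a motif is the mean hit position
over sRNAs with a hit; an sRNA *has a promoter* when both BRE and TATA
hits lie within each model's tolerance (±5 nt) of its expected centroid
(−38 / −29), and the relaxed mode widens the tolerances by 3 nt.

## Synthetic data

The generator emulates the study design: one replicon with
non-overlapping genes (default 60 genes on 150 kb; CDS 600–1500 nt; ~50%
leaderless; 5′ UTR 20–100 nt, 3′ UTR 30–150 nt; gaps 300–1500 nt), two
conditions × 5 replicates, NB counts with dispersion α = 0.05 and
per-sample library scales spanning a factor of 2 so size-factor
estimation is non-trivial.

Planted structure and the reasoning behind the defaults:

- 30 antisense sRNAs over distinct genes, intended binding regions drawn
  at 7% 5′UTR / 26% 3′UTR / 67% CDS; 10 intergenic sRNAs strictly between
  genes; lengths 50–1000 nt. Transcripts keep ≥150 nt clear of replicon
  edges so promoter windows always fit.
- Decoys the pipeline must remove: 5 sense-overlapping transcripts
  (classifier) and 5 genomically valid asRNAs planted at 1–5 TPM
  (expression filter).
- Expression: genes and intergenic sRNAs log-uniform over 50–5000
  relative units (normalized to a million, so units read as TPM); each
  asRNA at a 2–20× multiple of its cis target, planting the
  sRNA-above-target asymmetry the paired test detects.
- Fold changes: every asRNA is DE at |log2FC| = 2 with *random sign* —
  balanced up/down as in real stress-response data — and 25% of cis pairs
  (`anti_corr_fraction`) get the opposite sign planted on the target. A
  one-sided design would make ~40% of this small feature set DE in one
  direction and visibly bias median-of-ratios normalization, which
  realistic data of this shape does not do.
- Motifs: BRE/TATA consensus written at −38/−29 for 30% of non-decoy
  sRNAs, strand-aware.

What the generator does **not** model: read-level effects (FASTQ,
mapping, positional bias), GC/length biases in counting, overdispersion
heterogeneity across features, multi-replicon genomes, overlapping genes,
and operonic structure. Passing tests therefore demonstrate algorithmic
and statistical correctness under the stated model, not robustness to
alignment artifacts or annotation errors in real data.

## Determinism and problem sizes

All randomness flows from a single integer seed (`numpy` Generator;
sub-streams spawned per stage), so fixture bundles and pipeline runs are
byte-identical under a fixed seed; the pipeline report embeds the
parameters and SHA-256 checksums of every input, and `audit_report`
recomputes every summary count from the stage artifacts. The test suite
and `scripts/acceptance.py` use reduced problem sizes chosen to estimate
each quantity well — e.g. 1,000 random genomes of 3–12 genes for the
classification oracle, 2,000 null pairs for paired-test calibration, 50
seeds × 200 features for DE calibration, 50 seeds of the default study
for cross-tab and motif recovery — keeping any single check within
seconds while leaving Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

- The Wald test's normal reference and unshrunk MoM dispersion are crude
  at n = 5; calls near the threshold are less reliable than a
  shrinkage-based DE package's would be.
- Intergenic sRNA target prediction is out of scope (no tractable signal
  without hybridization modeling).
- The default PWMs are synthetic consensus models, not
  organism-calibrated matrices; real promoter analysis should supply
  measured matrices via `MotifModel`.
- Multi-exon transcripts and multi-replicon interval queries per
  transcript are unsupported by design.
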