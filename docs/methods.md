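# Methods

This note documents the models, conventions and numerical choices behind
`mutpat`, and what its synthetic benchmarks do and do not show.

## Coordinates, classification and merging

All internal coordinates are 0-based half-open; VCF (1-based) and BED
(0-based) are converted once at the IO boundary. Only PASS records are
read by default — every downstream statistic assumes stringently filtered
somatic calls, because systematic artifacts masquerade as mutational
patterns.

Variants are classified by allele lengths: 1→1 SBS, 2→2 DBS, k→k (k ≥ 3)
MBS; unequal lengths are trimmed of shared prefix/suffix bases and
classified insertion/deletion when one side empties. Complex
substitutions (unequal, both sides non-empty after trimming) are labeled
`other`, excluded from all counting, and reported in a warning — there is
no consensus channel system for them. Runs of positionally adjacent SBSs
within one sample and contig are merged into DBS/MBS events before type
selection, so the SBS spectrum is not contaminated by dinucleotide
events; strict positional adjacency is required (a masked base between
two SBSs breaks a run). Callers that emit DBS/MBS records directly are
trusted via `predefined_dbs_mbs=True`; note that such records can combine
a germline with a somatic SNV — this caveat is documented, not detected.

## Context systems

SBS contexts are pyrimidine collapsed: purine-reference substitutions are
reverse complemented with flanks swapped and complemented. Channel order
is substitution class major (C>A, C>G, C>T, T>A, T>C, T>G), then 5' and
3' flank alphabetical — the COSMIC publication order, so matrices align
row-for-row with catalog files. Contexts containing N are excluded (and
tallied), never imputed.

DBS channels collapse the 16 × 9 both-base-changing dinucleotide pairs by
joint reverse complement onto 78 channels over the canonical reference
set {AC, AT, CC, CG, CT, GC, TA, TC, TG, TT}. For the four palindromic
references the alternative allele is canonicalized to the
lexicographically smaller of itself and its reverse complement — an
internal convention (the published files are not byte-identical on this
point, but the 78-channel partition is the same). A "DBS" that changes
only one base has no COSMIC channel and is excluded with an error.

Indels follow ID-83. The event sequence is left-aligned against the
reference, then the 3' flank is scanned for additional copies
(homopolymer length for 1-bp events, repeat units for longer ones;
deletions count the deleted copy itself). Deletions with no extra full
copy are checked for microhomology — the maximum of the common prefix of
the deleted sequence with the 3' flank and its common suffix with the 5'
flank, capped one below the deletion length. 1-bp events are pyrimidine
collapsed; the flank run length is orientation invariant, so the scan is
done on the reference strand. Channel names are
`{len}:{Del|Ins}:{C|T|R|M}:{k}`.

MBS counts use length categories {3..9, 10+}; no COSMIC consensus exists
for MBS contexts.

Stranded SBS matrices (192 channels) label a mutation "untranscribed"
when its pyrimidine representation lies on the overlapping gene's coding
strand, "transcribed" otherwise; replication mode maps region strand `+`
to a rightward-moving fork ("right"). Mutations outside the annotation,
or covered by conflicting strands, are excluded and tallied.

## Spectra and spectrum comparison

Spectrum summaries compute per-sample relative spectra first and then
average, so samples are equally weighted regardless of load; dispersion
is the standard deviation, SEM, or 95% CI as mean ± 1.96·SEM. Regional
spectra are compared with a Pearson chi-squared statistic whose null is
simulated with fixed row and column margins (sequential multivariate
hypergeometric draws, the conditional-on-margins distribution); the
p-value uses the add-one rule `(1 + #{sim ≥ obs}) / (n_sim + 1)` so it is
never exactly zero. Default `n_sim = 2000` balances Monte-Carlo error
(~1%) against runtime. FDR control is Benjamini–Hochberg throughout the
package.

## Regional analyses

The Poisson enrichment test compares a region's observed load against
`total mutations × region_bp / surveyed_bp` with a two-sided exact test
(minlike convention: sum of outcome probabilities not exceeding the
observed one). The surveyed territory defaults to full contig lengths; a
callable-region set can override it. Significance is rendered as
asterisks at FDR < 0.05/0.01/0.001.

Density binning estimates local density on fixed tiles (default 1 Mb) and
assigns tiles to quantile strata, which together cover the genome exactly
once.

The regional-similarity scan slides windows of `window_size` consecutive
SBSs (default 100), advanced by `stepsize` mutations (default 25), and
computes the cosine between each window's SBS-96 profile and the profile
of all *remaining* mutations (the window is excluded from the global
profile, also in corrected mode). Windows spanning more than
`max_window_size_gen` (default 10 Mb) are dropped as uninformative. With
`oligo_correction` both profiles are divided channel-wise by their own
territory's trinucleotide frequencies and renormalized, removing dips
that merely reflect unusual local base composition. The defaults were
chosen so windows are dense at the scale the scan is designed for
(catalogs of ~100,000 substitutions); with 100-mutation windows the
per-window cosine carries substantial multinomial noise for flat
profiles, which is why planted-anomaly tests use concentrated processes.
All run settings are recorded in the result object.

## Lesion segregation

A substitution sits on the "+" strand when its reference base is a
pyrimidine, "−" when a purine. The binomial mode counts adjacent
same-strand pairs (never across contigs) and applies a two-sided exact
binomial test against 1/2. The rl20 statistic decomposes each contig into
maximal same-strand runs, sorts run lengths (in mutations) descending,
takes the smallest prefix reaching 20% of the sample's mutations, and
reports the shortest run in that prefix — the run completing the
threshold is included (tie handling at the 20% boundary is a convention;
alternatives shift rl20 by at most one run). The genomic bp extent of
those runs relative to the extent of all mutations is reported
separately. Under a fair-coin null rl20 is ≤ 5 in ≥ 99% of simulated
samples, consistent with the published "> 5 indicates lesion segregation"
threshold.

## Signature refitting

Plain refitting solves `min_{c≥0} ‖m − S c‖₂` per sample by NNLS.
`filter_low_contribution` implements the "regular_10+" heuristic: drop
signatures under 10 attributed mutations and refit the remainder.

Strict backwards elimination starts from the full NNLS fit and repeatedly
removes the lowest-contributing signature (ties broken lexicographically;
exact zeros are dropped one at a time by the same rule so the stop rule
is applied uniformly) and refits. When one elimination lowers the
reconstruction cosine by more than `max_delta`, the procedure stops and
returns the fit *before* that drop — the better-reconstructing set. The
elimination path does not depend on `max_delta`, so the implementation
computes the path once and applies the stop rule afterwards; sweeping
`max_delta` (as the evaluation harness does) reuses one path per sample.
The default `max_delta` is 0.004; 0.015 is a documented stricter working
setting. Best-subset search evaluates every signature combination of each
size and applies the same stop rule; it is refused above 15 signatures
unless forced, because the cost is binomial in the catalog size.

Bootstrapping redraws each sample's mutations multinomially from its
observed channel profile (equivalent to resampling the mutation list with
replacement — the resampling unit is the mutation because contributions
are mutation counts) and refits per iteration; default 1000 iterations.
Summaries follow the presence-fraction / mean-nonzero convention, and
per-sample Pearson correlations of contributions across iterations expose
signature pairs the refit cannot separate (strongly negative correlation
= the fit trades one for the other).

De novo extraction uses multiplicative-update NMF under Frobenius loss
with random restarts (best of `n_runs` kept), factor columns normalized
to probability vectors. Rank selection is offered as a
reconstruction-error survey across candidate ranks (the error is
non-increasing in rank; the elbow marks diminishing returns) — a
deliberate design choice in place of a variational Bayesian rank
estimate. Extracted signatures can be renamed `<reference>-like` when
their best catalog cosine reaches a cutoff.

## Damage potential

For each gene, CDS positions (exons concatenated in transcription order,
phase from the annotation, genes with CDS length not divisible by three
skipped with a warning) are mutated to each alternative base and
classified by the standard genetic code: stop_gain when the new codon is
a stop and the old is not, synonymous when the amino acid is unchanged,
otherwise missense (which also absorbs the rare stop-loss change). Splice
sites are defined as the two intronic bases on each side of internal CDS
exon junctions (canonical donor/acceptor); all three changes of those
positions count as splice_site and are tallied separately from the CDS
consequences. Each possible change is binned by its SBS-96 context on the
genomic strand (pyrimidine collapsed); per context, ratios divide by the
context's total enumerated possibilities, so they sum to one across
consequences. Signature scores are context-weighted sums of those ratios
normalized by the flat signature (weight 1/96 per context), which
therefore scores exactly 1 by construction. Contexts absent from the gene
set contribute to neither numerator (a warning reports incomplete
coverage — unavoidable on toy gene sets). Chromatin state and expression
are deliberately ignored; they are tissue specific.

## Synthetic signature catalogs

The bundled catalogs behind `get_known_signatures` are **synthetic
stand-ins** for the published COSMIC v3.1/v3.2, SIGNAL v1 and
SparseSignatures v1 matrices: deterministic profiles generated from fixed
seeds, with

* etiology-informed shapes for well-characterized signatures (SBS1 mass
  on N[C>T]G CpG deamination; SBS2/SBS13 on T[C>T/G]N APOBEC contexts;
  SBS7a on pyrimidine-dimer C>T; SBS10a on T[C>A]T; SBS18 broad C>A;
  near-flat clock-like SBS3/SBS5/SBS40; ID1/ID2 on long-T-run slippage;
  DBS1 on CC>TT),
* signature families (SBS7a–d, SBS17a/b) generated as perturbations of a
  shared base shape, so the catalog contains the strongly collinear
  groups that make refitting hard in practice, and
* heterogeneous sparsity for the remainder (per-signature Dirichlet
  concentration drawn log-uniformly).

Catalog sizes, naming and the artifact flag list (SBS27, SBS43,
SBS45–SBS60, the publicly documented possible-sequencing-artifact set)
follow the published catalogs; the numerical values do not. Consequently
any statistic that depends on the published values — e.g. the cosine
between the real SBS2 and SBS30 (published: 0.46), or damage scores of
specific real signatures on real cancer genes — will differ when computed
on the stand-ins. Statistics that depend on the *structure* of the
problem (channel arithmetic, refitting behavior on mixtures drawn from
the catalog itself, calibration of exact tests) are unaffected, which is
what the test suite and acceptance script measure.

## Simulation benchmark

The refitting benchmark draws, per sample, 4 signatures uniformly from
the first 30 columns of the loaded catalog (artifact signatures excluded,
matching how the catalog is used) and samples an equal number of
mutations per signature multinomially from each; 300 samples per
condition at 50/100/500/1000 mutations per signature. Performance is
scored as presence/absence precision and recall over all sample ×
signature decisions (a presence call is any nonzero contribution;
sweepable threshold for plain NNLS), the fraction of correctly attributed
mutations (`Σ min(attributed, true)` per true signature over total), and
the trapezoidal area under the recall–precision curve traced by sweeping
strictness — `max_delta` over 20 log-spaced values in [10⁻⁴, 0.2] for
strict refitting, the presence threshold for plain NNLS; the curve is
completed to recall 0 at the strictest point's precision. A companion
ROC-AUC helper is provided for comparison. "Recovers the true signature
set" in the recovery benchmark means exact support equality at the
default `max_delta`.

These simulations emulate signature mixing only: no sequencing error, no
coverage variation, no caller behavior, and channel counts are drawn
directly rather than placed on a genome. Passing them shows the
estimators are correct and well calibrated under the stated model, not
that any particular real dataset is free of artifacts.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen as the package's own
defaults: 300-sample simulation matrices, 2000–4000 fair-coin null
samples, 2 × 120 kb toy genomes for the regional scan, and toy gene sets
for damage enumeration. All randomness flows through
`numpy.random.Generator` objects seeded explicitly; the acceptance script
derives every sub-seed from its `--seed` argument, and identical seeds
give byte-identical outputs.

## Known limitations

* The bundled catalogs are synthetic (above); refitting real cohorts
  requires loading a real catalog TSV.
* Splice-site definition is the minimal 2-bp donor/acceptor; extended
  splice regions are not scored.
* Best-subset refitting is exponential in catalog size and intentionally
  refused above 15 signatures.
* The regional scan assumes sorted, deduplicated SBS positions and skips
  contigs with fewer mutations than one window.
* No lift-over: catalogs and genomes must share a build, and contig names
  must match exactly (only a `strip_chr_prefix` convenience is offered).
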