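# mutpat

Analysis of mutational processes from catalogs of somatic variants.

The collection of somatic mutations in a genome records the mutagenic and
DNA-repair processes that were active in a cell. `mutpat` extracts that
record from standard file formats and quantifies it:

* **Mutation types and contexts** — single (SBS), double (DBS) and multi
  (MBS) base substitutions and small indels are read from VCF, with
  neighboring SBSs merged into DBS/MBS events so a dinucleotide lesion is
  never counted as two independent substitutions. Contexts follow the
  COSMIC channel systems: SBS with any flank extension (96 channels at
  ext=1, 1536 at ext=2), DBS-78, ID-83 (homopolymer / repeat-unit /
  microhomology structure) and MBS by length.
* **Regional analyses** — splitting mutations by labeled regions, exact
  Poisson enrichment/depletion tests with Benjamini–Hochberg FDR,
  mutation-density strata, Monte-Carlo chi-squared comparison of regional
  spectra, and an unsupervised sliding-window scan that flags genomic
  windows whose mutation profile differs (cosine) from the rest of the
  genome.
* **Lesion segregation** — Watson/Crick strand-asymmetry statistics:
  exact binomial runs test, per-context variant, and the rl20 run
  statistic (values above 5 indicate lesion segregation).
* **Signature analysis** — non-negative least-squares refitting against
  known signature catalogs, *strict* refitting by backwards elimination
  (stop when one elimination drops the reconstruction cosine by more than
  `max_delta`) or best-subset search, bootstrapped refitting with
  presence/stability summaries and contribution correlations, signature
  merging, and de novo NMF extraction with rank surveys and
  similarity-based renaming.
* **Damage potential** — for a gene set, every possible coding change is
  enumerated and classified (stop-gain / missense / synonymous /
  splice-site) by codon translation; signature-level scores are
  context-weighted sums normalized against a flat signature, so a score of
  3.6 means "3.6× as likely as a uniform mutational process to cause a
  stop gain on these genes".

The refitting model is `min_{c ≥ 0} ‖m − S c‖₂` per sample, where `m` is a
channel count vector and `S` a channels × signatures probability matrix;
reconstruction quality is the cosine similarity between `m` and `S c`.

**Bundled catalogs.** `get_known_signatures` exposes catalogs under the
familiar names (COSMIC v3.1/v3.2 SBS/DBS/ID, SIGNAL, SparseSignatures)
with correct channel systems, column normalization, and artifact flagging
— but the bundled matrices are deterministic **synthetic stand-ins**, not
the published values (see `docs/methods.md`). Use
`SignatureMatrix.from_tsv` to refit against a real downloaded catalog.

## Worked example

Simulate two samples as mixtures of three signatures (200 mutations each)
and compare plain NNLS refitting with strict refitting:

```python
import mutpat as mp

S = mp.get_known_signatures("snv", "COSMIC_v3.1")
m, truth = mp.simulate_mixture_matrix(S, n_samples=2, k_sigs=3,
                                      muts_per_sig=200, seed=7)
pool = S.select(S.signatures[:30])
plain = mp.fit_to_signatures(m, pool)
strict = mp.fit_strict(m, pool, max_delta=0.015)
```

With seed 7 the true signatures are `SBS22 + SBS15 + SBS17a` (sample 1)
and `SBS19 + SBS6 + SBS17b` (sample 2). The fitted contributions
(mutations attributed, nonzero only) print as:

```
plain NNLS                 sample_1: cosine=0.982  SBS6=11, SBS7d=5, SBS10a=3, SBS10b=3, SBS11=1, SBS15=170, SBS17a=184, SBS22=210, SBS24=31
plain NNLS                 sample_2: cosine=0.992  SBS4=2, SBS6=219, SBS7b=2, SBS9=3, SBS11=2, SBS15=4, SBS16=20, SBS17a=7, SBS17b=201, SBS19=164, SBS20=1, SBS21=7
strict (max_delta=0.015)   sample_1: cosine=0.980  SBS15=179, SBS17a=185, SBS22=237
strict (max_delta=0.015)   sample_2: cosine=0.978  SBS6=239, SBS17b=208
```

Plain NNLS spreads small spurious contributions over many signatures
(overfitting); strict refitting prunes them at almost no cost in
reconstruction cosine. Sample 2 also shows the trade-off: at this strict
setting the weakest true signature (SBS19) was pruned too — `max_delta`
tunes that sensitivity/specificity balance.

## Command line

Every analysis is also a `mutpat` subcommand operating on files:

```bash
mutpat simulate --outdir fixtures --seed 1          # toy genome + VCF
mutpat matrix --vcf fixtures/toy_variants.vcf \
              --fasta fixtures/toy_genome.fa \
              --dialect sbs -o matrix.tsv           # 96-row count matrix
mutpat refit --matrix matrix.tsv --signatures COSMIC_v3.1 \
             --strict --max-delta 0.015 -o contrib.tsv
mutpat lesion-seg --vcf ... --fasta ... --mode rl20 -o rl20.tsv
```

Subcommands: `split-types`, `matrix`, `spectrum`, `cos-sim`,
`regional-sim`, `enrichment`, `lesion-seg`, `refit`, `extract`, `damage`,
`simulate`. A YAML file passed via `--config` pre-sets any option; CLI
flags override it.

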