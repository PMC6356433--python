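# bindsig

From promoter binding affinity and dual ChIP-seq binding to a prognostic
expression signature.

`bindsig` is a reusable pipeline for a regulatory-genomics workflow that
links transcription-factor (TF) binding evidence to patient survival. It
was motivated by the observation that some WNT-responsive, TATA-less
promoters (such as *RhoU*'s) are induced through many disseminated
low-affinity sites rather than a single responsive element, so the TFs
acting on them are best nominated by a promoter-level affinity score rather
than by single-site matches. The pipeline then asks whether genes bound in
vivo by two cooperating TFs (here SP1 and STAT3) form a coherent, pathway-
enriched gene signature whose expression stratifies tumor survival.

## What it computes

**Total Binding Affinity (TBA).** For a motif of length *L* with
position-probability matrix *p* and background *b*, the TBA of a promoter
window *S* is

    TBA(S) = Σ_{σ ∈ {+,−}} Σ_i Π_{j=0}^{L−1}  p(S_σ[i+j], j) / b(S_σ[i+j])

the sum over both strands and every sliding start of the likelihood ratio
of the *L*-mer, so many weak sites can outscore one strong site. Promoter
windows default to −756/+235 bp around the TSS (991 bp), the
experimentally mapped WNT-responsive region of the *RhoU* promoter. Motifs
(JASPAR PFM format) are ranked per promoter by log TBA, optionally
normalized by mononucleotide-shuffle z-scores.

**Dual-bound genes.** Each TF's ChIP-seq peaks (BED) are assigned to their
single closest gene by edge-to-edge gap and retained when the gap is
≤ 5 kb; genes with retained peaks from *both* TFs form the dual-bound
list. TSS-proximal binding (peak midpoint within ±1 kb of the TSS) is
summarized per TF.

**Enrichment and signature.** The dual-bound list is tested against each
curated gene set (GMT) with a one-sided Fisher exact test
(hypergeometric upper tail) over the gene-annotation universe. The two
top-ranking significant sets A and B define the combined signature
(dual ∩ A) ∪ (dual ∩ B); BH q-values are reported alongside but raw p
drives selection.

**Survival.** The per-sample signature score is the sum of signature-gene
expression. Samples are split at the median score (strictly above =
"high"), survival curves are Kaplan-Meier product-limit estimates, group
separation is the unstratified two-sample log-rank test, and univariate
GLMs relate the standardized score to clinical covariates (Gaussian for
continuous/ordinal features, logistic for binary ones). All survival/GLM
estimators are implemented from first principles and cross-validated
against lifelines/statsmodels in the test suite only.

**Synthetic data.** `bindsig simulate` generates every input the pipeline
consumes — gene annotation + genome FASTA, two peak tracks with a planted
co-binding fraction, gene sets with a planted overlap against the
dual-bound truth, and a log-normal expression matrix with an exponential
proportional-hazards cohort — plus a `truth.json` sidecar, so the whole
chain can be validated end to end without any download.

## Worked example

```sh
bindsig simulate --outdir demo/sim --seed 1
bindsig run \
  --genes demo/sim/genes.bed \
  --tf1-bed demo/sim/peaks_tf1.bed --tf2-bed demo/sim/peaks_tf2.bed \
  --gmt demo/sim/gene_sets.gmt \
  --expression demo/sim/expression.tsv --clinical demo/sim/clinical.tsv \
  --outdir demo/out
```

prints

```
[simulate] wrote inputs + truth.json to demo/sim (42 planted dual-bound genes)
[dualbind] running
[enrich] running
[survive] running
[run] dual-bound=42 signature=36 logrank_p=9.52e-15
```

Reading: the default simulation plants 42 dual-bound genes; the peak
assignment recovers exactly those 42; both planted gene sets are selected
(see `demo/out/enrichment.tsv`), yielding a 36-gene signature; and the
median split of the signature score separates overall survival with
log-rank p ≈ 1e-14, reflecting the planted hazard ratio of 3. The output
directory also contains the KM plot with censoring ticks
(`km_plot.svg`), the GLM coefficient plot, all tables as TSV, and
`manifest.json` with input checksums and every headline number.

Stages can be run individually (`bindsig tba`, `dualbind`, `enrich`,
`survive`); see `bindsig <cmd> --help`.

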