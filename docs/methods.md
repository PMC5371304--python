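# Methods

This note records the models, conventions and design choices behind
`cirrnet`, in the order data flows through the pipeline.

## Expression model and differential testing

Array intensities enter on the log2 scale as an analyte × sample matrix.
Quantile normalization replaces each value by the across-sample mean of the
column-sorted values at its rank; ties within a column receive the mean of
the reference values at their tied ranks. On tie-free data every column
ends with an identical multiset of values and the operation is exactly
idempotent (the implementation restores bit-exactness where floating-point
summation of identical values would drift by an ulp). With ties, the
tie-averaging rule necessarily perturbs the shared multiset — a documented
trade-off in favour of not splitting tied intensities arbitrarily.

Unofficial lncRNA probes are harmonized to official transcript IDs by
genomic overlap: an array transcript maps to an official transcript on the
same chromosome and strand when the overlap exceeds 90% of the **array**
transcript's length (strictly; the matching direction is array → official,
which fixes the denominator the overlap rule needs). The best fraction
wins; exact ties go to the lexicographically smallest official ID. Probes
mapping to the same official ID are averaged; unmapped probes are dropped.
All coordinates are 0-based half-open (BED convention).

The two-sample test is the empirical-Bayes moderated t. Per analyte g the
pooled residual variance s²_g has d_g = n₁+n₂−2 df; variances are assumed
exchangeable under σ²_g ~ s₀²·d₀/χ²_{d₀}. Writing z_g = log s²_g, the
marginal law s²_g ~ s₀²·F(d_g, d₀) gives
E[z] = log s₀² + ψ(d_g/2) − log(d_g/2) − ψ(d₀/2) + log(d₀/2) and
Var[z] = ψ′(d_g/2) + ψ′(d₀/2), so (d₀, s₀²) are estimated by matching the
empirical mean and variance of z through the digamma/trigamma functions
(trigamma inverted by Newton iteration). Zero variances carry no log-scale
information and are excluded from the fit; a fully degenerate fit falls
back to the unmoderated t with a warning. The posterior variance is the
df-weighted blend of prior and sample variance and t_g is referred to a t
distribution on d₀ + d_g df. When the moment matching finds no excess
dispersion the prior degenerates to a point mass: d₀ = ∞, s₀² = mean(s²),
and the normal limit is used for p-values. Forcing d₀ = 0 reproduces the
classical pooled t exactly, which the tests exploit as an oracle; the
finite-d₀ path is cross-checked against Bioconductor limma to 1e-12.

Significance policy: BH step-up FDR (hand-implemented from the definition,
verified against it and statsmodels), strict `stat < 0.05`, inclusive fold
change ≥ 2 or ≤ 0.5 computed as 2^(difference of log2 means). Arrays gate
on FDR; miRNAs gate on raw p — at small-RNA sample sizes the FDR gate
returns nothing, which is why the raw-p regime exists. miRNA testing runs
on log2 TPM including the 0.0001 pseudo-value cells.

## Small-RNA quantification

Reads are truncated at the first occurrence of the 3' adapter's 8-nt
prefix. QC keeps a read iff length ≥ 16 nt AND ≥ 90% of bases have
Phred ≥ 20 AND ≤ 5% of bases are N ("base uncertainty" is interpreted as
the N-call fraction; both percentage boundaries inclusive). Failures are
attributed to the first violated rule in the fixed order length → quality →
uncertainty so reports are reproducible. Contaminant removal drops reads
that are exact same-strand substrings of any reference (rRNA/tRNA/snRNA
style) sequence; miRNA counting requires exact equality with a unique
mature sequence. Exactness is a deliberate choice over alignment
tolerance: it keeps every count bit-stable and testable. TPM is
count·10⁶/total per sample; miRNAs with zero counts in all samples are
dropped, then remaining zero cells are set to 0.0001 so log-scale testing
is defined. Pre-replacement TPM columns sum to 10⁶ by construction.

## Networks

The promoter window spans 1500 bp upstream to 500 bp downstream of the
TSS, where "downstream" includes the TSS base: [tss−1500, tss+500) on '+',
mirrored to [tss−499, tss+1501) on '−', clamped at zero. A TF–miRNA edge
requires ≥ 1 bp overlap between a binding site and the window of a DE
miRNA; site strand is ignored (ChIP signals are unstranded) and TFs are
not required to be DE (a `restrict_de_tfs` flag enables the stricter
reading). miRNA–target edges keep table rows whose two endpoints are DE,
without a direction constraint by default — a requirement of ceRNA
analysis, where co-downregulated targets of a shared miRNA are exactly the
interesting case.

ceRNA pairs are all unordered pairs of transcripts targeted by the same
miRNA, merged across miRNAs with the union of shared miRNAs. PPI support
(allowed channels: experiments, text mining, co-expression, database;
≥ 1 DE endpoint) is an annotation, not a filter, since the ceRNA edge is
defined by the shared miRNA; `strict_ppi` drops unsupported pairs. A node
is immune when annotated to ≥ 1 immune-response GO term; an edge is an
immune pair only when both endpoints are. Subnetwork extraction keeps the
anchor mRNAs, miRNAs adjacent to them, TFs/lncRNAs adjacent to those
miRNAs, and the induced edges, recomputing degrees. Node display
attributes follow the field's conventions: size by degree, colour by
enrichment score −log₁₀(p) (p floored at 1e-300). Exports (SIF, attribute
TSVs, GraphML) are canonically sorted so identical networks are
byte-identical on disk.

## Enrichment

The hypergeometric upper tail P(X ≥ k) is computed in log space (log-gamma
PMF + log-sum-exp); the universe is every gene carrying ≥ 1 annotation
(the DAVID-style default), terms need ≥ 2 universe genes (singleton terms
are artifacts) and ≥ 1 DE member, and BH runs across exactly the tested
terms. Term direction is a strict majority vote of the DE members (up /
down / mixed). The significance gate defaults to FDR < 0.05 and is
configurable to raw p. Cross-contrast comparison reports shared
significant terms with their direction pair and an immune flag.

## Synthetic-data generator

The generator is the package's experimental bench: it emulates the
structure of a three-group liver study (normal / cirrhosis / early HCC
arrays; normal / cirrhosis small-RNA libraries at 9 + 15) and plants the
truth the pipeline should recover.

* **Expression.** x_gs = μ_g + β_g·1[s ∈ cirrhosis] + β'_g·1[s ∈ HCC] +
  ε_gs with ε_gs ~ N(0, σ²_g), σ²_g ~ s₀²·d₀/χ²_{d₀} — the conjugate model
  of the moderated t, so hyperparameter recovery is a meaningful test.
  Defaults d₀ = 4, s₀² = 0.05, baselines N(8, 1.5²). A de_fraction of 10%
  of analytes per class receives |β| ≥ 2 (log2) with random sign. The HCC
  contrast plants its own effects; 25% of them sit on cirrhosis-DE genes
  and mostly (80%) reverse direction, emulating the reversal of
  immune-response expression during malignant progression.
* **Small RNA.** Unique 18–24 nt mature sequences (screened so the adapter
  prefix cuts exactly at the insert junction and no mature sequence hides
  inside a contaminant); per-miRNA group means proportional to log-normal
  abundances times the planted fold change, floored at 20 expected reads so
  every miRNA stays quantifiable; counts NegativeBinomial(mean,
  dispersion 0.2) at 100 000 reads/sample. Fixed fractions of reads copy
  contaminant substrings (2%) or are constructed to fail exactly one QC
  rule (5%, cycling short / low-quality / N-rich), with per-sample
  bookkeeping so filters can be checked read-for-read.
* **Annotations.** miRNA loci occupy disjoint slots (≥ 12 kb margins) on a
  synthetic 10 Mb chromosome; planted TF sites land inside their miRNA's
  promoter window, planted negatives ≥ 10 kb from every window, so
  intersection tests are unambiguous. Target tables contain all planted
  edges (DE × DE) plus decoys strictly among null analytes — with perfect
  DE calls the emitted pairs equal the planted set exactly. Core PPI rows
  lie on the planted ceRNA structure; distractor rows use disallowed
  channels or lack DE endpoints. GO terms: background terms of mean size
  25; two planted immune terms with baseline membership 5% (immune-response
  terms are among the largest GO categories) boosted at odds ratio 10 among
  genes up in cirrhosis or down in HCC.
* **Determinism.** All randomness flows from one seed through named
  generator streams (truth / expression / small-RNA / annotations);
  identical configs give byte-identical bundles, and the bundle manifest
  records a SHA-256 config hash and per-file checksums.

What the generator does **not** emulate: probe-level microarray physics
(RMA background correction is accepted as already applied), sequencing
error beyond the constructed failures, isomiRs, correlated expression
between genes, and database noise (target tables are clean lists). Passing
recovery tests therefore demonstrates the pipeline's correctness on data
satisfying its assumptions, not robustness to real-data artifacts.

## Problem sizes and numerical choices

Shipped defaults are desk-scale: 2000 mRNAs / 300 lncRNAs / 150 miRNAs,
chosen so a complete study (generation + full pipeline) runs in minutes
while leaving every statistical property measurable; calibration checks
(type-I error, prior recovery) run at 20 000 analytes where binomial noise
is small. The acceptance fixtures for exact end-to-end recovery use a
"well-separated" configuration (|β| ≥ 3, d₀ = 16, s₀² = 0.02): under the
heavy-tailed d₀ = 4 prior no finite effect size separates all analytes, so
occasional false negatives there are statistics, not bugs. Degenerate
inputs are handled explicitly: empty matrices pass through normalization;
zero-variance analytes fall back to the unmoderated t; a zero-total
small-RNA sample is an error naming the sample; empty bundles still write
valid manifests. Run manifests include timestamps, which are the only
non-deterministic bytes a run produces.
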