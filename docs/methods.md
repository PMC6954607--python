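# Methods

## Scope and model

`refpick` selects internal control genes for RNA-seq normalization from
the data being analyzed. The working assumptions are the usual ones for
reference-gene selection: (i) within-sample abundance is adequately
summarized by TPM, so gene length and sequencing depth are divided out
before any cross-sample comparison; (ii) the log-abundance distribution
of a bulk sample is bimodal, with a weakly expressed mode (ambient
transcription, mapping noise) and an expressed mode, and only expressed
genes are eligible references; (iii) a good reference gene has a low
coefficient of variation of TPM across the samples that will be
compared. The pipeline is deliberately simple — no annotation beyond
gene lengths, no pre-selected candidate list, no spike-ins.

## TPM

`TPM_gj = 10^6 (c_gj/L_g) / Σ_i(c_ij/L_i)`. Lengths are annotated exonic
union lengths (for GTF input: 1-based inclusive exon intervals merged
per gene, strand ignored). By default no fragment-length correction is
applied; `counts_to_tpm(..., mean_fragment_length=µ)` switches to the
effective length `max(L−µ+1, 1)` for users whose upstream quantifier
used it. CV uses the n−1 (sample) standard deviation and is reported in
percent, on linear TPM, not log TPM. A sample with all-zero counts has
undefined TPM and is an error; a gene with zero mean has an undefined CV
and is flagged rather than dropped.

## Data-adaptive expression cutoff

Per sample: drop zeros, take log₂, and sweep quantile cutoffs from
`q0 = round(fraction of values tied at the minimum, 2)` to 0.50 in steps
of 0.005 (linear-interpolation quantiles). At each cutoff `c_q` the
values above it are scored by the Kolmogorov–Smirnov sup-norm distance
`D_q` to a normal fitted by maximum likelihood (mean, ddof-0 SD). The KS
distance is used as a raw descriptive statistic, never as a test — the
parameters come from the same data, so its null distribution would be
invalid; only the shape of `D_q` over `c_q` matters. While the low mode
contaminates the tail, `D_q` is large; once it is excised, `D_q` drops.

The bend is located with a forward-stepwise hinge regression of `D_q` on
`c_q`: starting from intercept + linear term, hinge pairs
`(max(0, c−t), max(0, t−c))` with candidate knots at observed interior
cut values are added greedily by residual-sum-of-squares reduction,
stopping when a step's R² gain falls below 0.005 or 21 basis terms are
reached. The base model includes the linear term so an exactly linear
trace retains no knot. These sweep and fit constants (grid step, R²
threshold, term cap) are fixed defaults of this package, chosen for
reproducibility; results are insensitive to them on clearly bimodal
data.

The cutoff is the smallest retained knot above 0 (log₂ TPM = 0, TPM =
1) — a meaningful floor on the TPM scale, where weak expression sits
below 1 TPM. When no knot qualifies the sweep falls back to its smallest
cut value with a logged flag, i.e. filtering fails open rather than
silently discarding genes. The `min-interior` knot rule (smallest
interior knot regardless of sign) is available for data whose weak mode
sits above TPM = 1. Note that on distributions whose inter-mode valley
lies below 0 the >0 rule triggers the fallback by construction; its
intended regime is TPM-scale data with the noise mode below 1 TPM.

The entire procedure is deterministic, invariant to duplicating the gene
set, and — because TPM is scale-free — invariant to per-sample count
scaling.

## Active genes and selection

The per-sample cutoffs are aggregated as their arithmetic mean κ̄; a
gene is active iff all its TPM values are positive and its mean log₂
TPM ≥ κ̄. The stricter alternative (above its own sample's cutoff in
every sample) is available as `active_rule="every-sample"` and recorded
in the output provenance; the mean-vs-mean rule is the default because
it is the least stringent reading and small replicate numbers make
per-sample rules noisy. The reference set is the
`max(min_genes, round_half_up(fraction · n_active))` active genes with
the smallest CV, ties broken lexicographically by gene ID. The default
fraction is 0.005 with a floor of one gene, so stringent settings on
homogeneous data cannot return an empty set; the fraction is exposed
because very heterogeneous data may warrant fewer references and very
homogeneous data would otherwise select thousands.

## geNorm

`M_i` is the mean over partners k of the n−1 SD across samples of
`log₂TPM_i − log₂TPM_k`. Ranking removes the worst-M gene from the
surviving set iteratively (ties removed in lexicographic order, for
determinism) until two genes remain; the terminal pair shares rank 1.
Pairwise variation `V_{n,n+1}` is the SD across samples of
`log₂(NF_n/NF_{n+1})`, with `NF_n` the per-sample geometric mean of the
n best-ranked genes' linear TPM; the series runs from n = 2 to n−1.

## NormFinder-style stability

Log₂ TPM, one two-way decomposition per group g: residuals
`r_igj = x_igj − x̄_i·g − x̄_·gj + x̄_··g` give the raw per-gene variance
`v_ig = Σ_j r²/(n_g−1)`, shrunk as `σ̂²_ig = max(0, v_ig − mean_i(v)/ (I−1))`
— a gene is not penalized for variation the whole candidate set shares.
The inter-group difference `d_ig = (x̄_i·g − x̄_i··) − (x̄_··g − x̄_···)`
is shrunk by the empirical-Bayes factor `γ_i = τ²/(τ² + mean_g(σ̂²_ig/n_g))`
with `τ² = max(0, var_g(d_ig) − mean_g(σ̂²_ig/n_g))` (variance across
groups with n−1 denominator). The stability value is
`ρ_i = mean_g(|γ_i d_ig| + sqrt(σ̂²_ig/n_g))`; with one group it reduces
to `sqrt(σ̂²_i1)`. This is a fixed, testable reconstruction of the
variance-decomposition-with-shrinkage scheme; exact numerical identity
with the original spreadsheet add-in is not claimed — correctness is
established against an explicit-loop ANOVA oracle and by ordering
behavior (planted unstable genes receive the largest ρ). The
conventional suitability threshold 0.5 is exported as
`SUITABILITY_THRESHOLD`.

Log-based metrics use log₂ TPM with **no pseudocount**; genes with a
zero in any sample are excluded from them (with a warning) but keep
their CV entry. A pseudocount would silently distort M and ρ, and a gene
with dropouts could not serve as a reference anyway.

## Control-gene size factors

Median-of-ratios restricted to a reference list: per usable reference
(all counts positive) compute its geometric-mean count across samples;
per sample take the median ratio of count to geometric mean; rescale
factors to unit geometric mean so factor sets from different reference
choices are directly comparable. With all genes as the reference set and
no zeros this is the classic all-gene estimator.

## Synthetic data

The simulator emulates a small two-genotype bulk design (defaults:
12 000 genes, 2 groups × 4 replicates, ~20 M expected fragments per
sample). Gene lengths are log-uniform on [200, 10 000] bp. Log₂
abundance is bimodal: a noise mode N(−2, 1) holding 30% of genes and an
expressed mode N(5, 2). One hundred planted stable genes come from the
upper half of the expressed mode with dispersion 10⁻⁴ and zero fold
change; 10% of the remaining expressed genes are DE with |log₂ FC| ~
Uniform(0.5, 3), signs random — bounded fold changes model moderate
transcriptome remodeling; an unbounded tail would let a single abundant
transcript swing the per-sample TPM denominator by several percent,
which is not the regime a reference-gene method is meant for (and on
such data no CV-based selection can succeed). Other expressed genes use
dispersion 0.05 and noise genes 0.1, typical biological-replicate values
for bulk RNA-seq. Library size factors are log-uniform on [0.5, 2].
Counts are gamma-Poisson (negative binomial, variance µ + αµ²).

What the simulator does **not** model: GC and positional bias,
transcript-level ambiguity, correlated co-expression modules, batch
effects, and outlier samples. Passing tests therefore show that the
pipeline recovers planted structure under idealized noise, not that it
is robust to every artifact of real libraries.

## Numerical choices and degenerate inputs

Quantiles: numpy's default linear interpolation. Hinge fits: ordinary
least squares via `lstsq`. A sweep trace with (numerically) constant
`D_q` falls back immediately. Selection rounding is half-up. Reports
write floats with 6 significant digits and round-trip through their
readers. All randomness lives in the simulator and is controlled by a
single integer seed; the analysis path is fully deterministic.

## Problem sizes

The shipped tests and the acceptance script run the pipeline on the
default 12 000-gene, 8-sample simulation (a few seconds per dataset; the
10-seed recovery test dominates the suite at roughly a minute). These
sizes already place the quantile grid, the KS sweep and the stability
indices in their asymptotic regime; real Arabidopsis-scale matrices
(~25 000 genes) run the same code unchanged.

## Known limitations

* The >0 knot rule presumes the weak mode sits below TPM = 1; use
  `min-interior` otherwise.
* CV-based selection inherits any shared per-sample multiplicative
  wobble (e.g. composition shifts); references selected under strong
  global remodeling should be cross-checked with the stability report.
* The NormFinder-style index needs ≥3 candidates and ≥2 samples per
  group; with exactly two groups the shrunken inter-group variance is
  estimated from two values and is accordingly coarse.
* geNorm's M is relative to the candidate set: a set of genes that
  co-vary strongly all receive low M regardless of their absolute
  stability.
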