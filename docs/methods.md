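# Methods

`brcalike` quantifies whether tumors carrying a given gene aberration —
germline mutation, somatic mutation, homozygous deletion, or promoter
hypermethylation — have somatic-mutation-signature or gene-expression
profiles that are unusually homogeneous, or unusually similar to a
"BRCA-like" reference group (all carriers of any BRCA1/BRCA2 aberration).
The analysis chain is: aberration cataloguing → molecular feature calling →
signature-weight fitting → classical MDS to two dimensions → a
median-pairwise-distance permutation test with Holm correction → downstream
correlation and classification summaries.

## The core statistic

Profiles (per-tumor signature-weight vectors, or log-transformed expression
profiles) are reduced to two dimensions by classical multidimensional
scaling. For a patient group G embedded at coordinates x_i, homogeneity is
the median over all C(|G|,2) pairwise Euclidean distances; similarity of two
disjoint groups G1, G2 is the median over all |G1|·|G2| cross-pair
distances. The null distribution is obtained by drawing groups of the same
sizes uniformly without replacement from the full embedded cohort B times
(default B = 100,000) and recomputing the statistic. Because a *small*
median distance indicates an unusually tight or mutually similar group, the
one-sided empirical p-value is

    p = max(b, 1) / B,     b = #{null statistics ≤ observed},

so the smallest reportable value is 1/B (0.00001 at the default B). A
`(b+1)/(B+1)` convention is available by flag and agrees at the displayed
precision. Families of tests are adjusted by Holm's step-down method
(delegated to `statsmodels.stats.multitest`); family membership is always
explicit in the caller.

Two groups compared against each other first have shared patients removed
from both sides (`exclude_overlap`); a comparison whose groups empty out is
skipped and reported, never silently dropped.

## Signature-weight fitting

Somatic SNVs are summarized as counts over the 96 canonical
substitution-in-trinucleotide-context channels (pyrimidine-strand
convention; purine-reference variants are reverse-complemented, channel
order is substitution-major, then 5' base, then 3' base). A tumor's
normalized spectrum f is decomposed over a row-stochastic signature matrix
S (K × 96) by non-negative least squares,

    min_w || f − wᵀS ||₂   s.t.  w ≥ 0,

using `scipy.optimize.nnls`. Weights below a cutoff (default 0.06, the
convention of the wrapped-tool ecosystem) are zeroed and the survivors
rescaled to the pre-cutoff total; the unexplained residual fraction
1 − Σw (pre-cutoff) is reported. Tumors with fewer than `min_mutations`
(default 10) variants are skipped with a warning. The solver is plain NNLS
rather than a forward-selection search: the analysis consumes the weights,
not the search path, and NNLS is the exact minimizer of the same objective.
Trinucleotide-abundance renormalization is off by default. No signature
matrix ships with the package; any K × 96 row-stochastic TSV is accepted
and the synthetic generator produces compatible ones.

## Classical MDS

Torgerson double-centering of the squared-distance matrix, eigendecomposition,
coordinates = eigenvector × √eigenvalue. Classical (not SMACOF) scaling is
used because it is deterministic and exact for configurations whose
intrinsic dimension is at most the target dimension — the property the test
suite pins (relative distance error ≤ 1e-8 for planar configurations
embedded in 27-D). Numerical choices: eigenvalues within machine noise of
zero (|λ| ≤ eps·n·λ_max) are treated as exactly zero, so collinear inputs
get an exactly-zero second axis; negative eigenvalues among the leading
axes zero that axis with a warning; the sign ambiguity is resolved by
flipping each axis so the sample with the largest absolute coordinate is
positive, which makes the embedding invariant under input reordering.
Expression profiles are log2(x+1)-transformed before distance computation
(configurable); signature weights are embedded raw.

## Outlier-based feature calling

Hypermethylation and low-expression events are called by a univariate,
distribution-fit outlier detector. The model (normal, lognormal or
exponential) is fitted by least squares of the observed order statistics on
the model quantiles at plotting positions i/(n+1), restricted to a central
quantile window FLim (default (0.1, 0.9)); R² of this quantile regression is
reported as the goodness of fit.

* **Method I** (used for low expression: lognormal, α = 1e-6 each side,
  FLim (0.1, 0.9)) flags y as a right outlier when its fitted tail
  probability 1 − F̂(y) < α_R, symmetrically on the left; a
  ρ-parameterization (expected number of more extreme observations) is
  supported with α = ρ/N.
* **Method II** (used for hypermethylation: exponential, α = 0.05 each
  side) flags the i-th order statistic when its position is inconsistent
  with order-statistic fluctuation under the fitted model: with
  u_i = F̂(y_(i)) and U_(i) ~ Beta(i, n+1−i), y_(i) is a right outlier when
  P(U_(i) > u_i) falls below the per-observation level implied by α. By
  default α is calibrated family-wise — the model probability that *any*
  tail observation crosses its limit (Šidák-adjusted) — which matches the
  detector's intended behavior of flagging at most a handful of values in a
  clean sample of 1000. A per-observation (`marginal`) calibration is
  available. A normal-quantile threshold on raw residuals was rejected:
  extreme order statistics are Gumbel-tailed and heteroscedastic, and no
  residual-sd rule controls their false-positive rate (measured 3–7% on
  clean exponential samples versus ~0% for the exact calibration).

Only observations outside the fit window are eligible for flagging, and
flags are completed monotonically (everything beyond a flagged value is
flagged). Decision limits on the data scale are reported as diagnostics.

Gene-level methylation is the per-sample median beta over probes mapping
within 300 nucleotides of the gene's TSS; probes with missing distances are
dropped, and genes left without probes are omitted with a warning. Platform
merging, when both 27K and 450K summaries exist, prefers the 450K value.
Expression zeros receive a per-gene half-minimum-positive pseudocount before
the lognormal fit (lognormal support excludes 0); a hard zero is therefore
at least as extreme as the smallest observed positive value, but is not
automatically an outlier.

## Aberration catalog

The somatic-variant filter excludes a variant when ANY criterion holds:
synonymous consequence; LOW/MODIFIER predicted effect; SIFT tolerated AND
PolyPhen benign; population allele frequency > 1%. The union reading (rather
than conjunction) is deliberate: a conjunction is near-vacuous because
synonymous variants never carry damaging functional predictions. BRCA1/BRCA2
somatic variants are additionally kept only when classified pathogenic,
likely pathogenic or VUS. Every excluded variant carries its reason codes,
making the rule auditable. Germline events enter the catalog only when
classified pathogenic or likely pathogenic (upstream human curation is
consumed, never recomputed). Homozygous deletions are GISTIC calls of −2
exactly. LOH flags are carried as annotations and never alter group
membership. Groups are built per gene × event type, plus a per-gene "any"
union group and the BRCA-like reference group (union over BRCA1/BRCA2, all
four event types).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, so
every stage is testable without any external data.

* **Signatures**: K rows (default 27) drawn from a sparse Dirichlet
  (concentration 0.1), redrawn until pairwise cosine similarity < 0.99 —
  peaked, identifiable signatures at desk scale.
* **Weights**: background tumors draw Dirichlet(1) over K; members of an
  enriched group add δ ∈ [0,1] to the designated HRD-like signature (row 0)
  and renormalize.
* **Spectra**: multinomial draws of the per-tumor mutation count from
  wᵀS. Counts are negative binomial (mean 100, dispersion 1, floored at 1)
  by default — a realistic exome-scale burden — or a fixed count.
* **Expression**: 5 Gaussian clusters in a 50-dimensional latent space
  (separation 3.0), mapped linearly to genes and exponentiated (lognormal
  scale, baseline log-expression 5.0, residual sd 0.3). Genes named in group
  specs are included; hypermethylation or deletion group members get the
  affected gene knocked down ×1e-4 (recorded as ground-truth low
  expressors).
* **Methylation**: probes at TSS distances 50, 150, 250, 350, 450 …
  (three in-window by default); background betas from an exponential (rate
  20) truncated to [0,1]; hypermethylated members get in-window betas
  uniform in [0.5, 0.9].
* **Clinical indicators**: Bernoulli with log-odds ±2·z where z is the
  standardized true distance to the reference group in weight space — the
  correlation screen therefore has a known sign.

Everything injected is recorded as ground truth; identical config + seed
reproduces byte-identical tables. What the generator does *not* emulate:
sequencing noise and variant-calling error, copy-number mechanics, LOH,
batch effects, realistic gene–gene correlation, or the heavy-tailed
mutation-burden structure of hypermutators. Passing tests therefore
demonstrate that the statistical machinery behaves as documented under its
own assumptions, not that the biological conclusions transfer to any real
cohort.

## Study conditions used in tests and the acceptance script

* **Floor reporting**: a 1000-sample configuration with a 20-member
  coincident group; its observed median (0) falls below all 100,000
  permuted medians, so the reported p is exactly 1/B.
* **Monte-Carlo consistency**: cohorts of 8 with groups of 3 admit 56
  subsets; exact enumeration p versus B = 50,000 Monte-Carlo p.
* **Type-I calibration**: 400 within-group tests (10 random groups of 10
  from each of 40 independent null cohorts of 150 patients, B = 1,000).
* **Power**: 50 replicate cohorts of 1000 patients at 500 mutations/tumor.
  The BRCA-like reference mirrors the study population's structure
  (22 + 22 germline carriers plus somatic, deletion and hypermethylation
  events, ~125 members in total); the single enriched candidate group
  (n = 20, δ = 0.6) is tested between-vs-reference, with an unenriched
  group (n = 15, δ = 0) present in the cohort as background. Reference-group
  size is decisive for this design's power — small references (n ≈ 44)
  leave the test underpowered at these effect sizes. Null-group behavior is
  characterized separately by the type-I study.
* **Outlier recovery**: 20 genes × 1000 samples with 5 injected
  hypermethylation events each; 10 genes × 1000 samples with one injected
  near-zero expressor in half of them.

## Known limitations

* The detector re-implements the tail-rule contract of the extremevalues
  approach, not the R package's numerics; per-gene flags can differ from `extremevalues` in
  boundary cases even though both recover injected events.
* The empirical p-value direction follows the reported results (small
  distances are significant); the alternative "union of pairs"
  between-statistic reading is available behind a flag and is not part of
  the tested defaults.
* Permutation draws treat the embedded cohort as exchangeable; no
  stratification or covariate adjustment is provided.
* Classifier metrics at the 0.5 threshold depend on the class-weighting
  convention (minority weight = majority/minority frequency ratio); AUROC
  is the threshold-free summary.
* With fewer than ~10 informative samples per gene, feature calling is
  skipped rather than attempted; downstream counts reflect this.
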