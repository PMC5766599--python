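# Methods

This note documents the models, the numerical choices, and the synthetic
data the test suite runs on — including what those tests do and do not
demonstrate about real data.

## Paired negative-binomial GLM

Counts are modeled per feature *g* and sample *s* as

    y_gs ~ NB(mu_gs, phi),   Var(y) = mu + phi mu^2,
    log mu_gs = x_s' beta_g + o_s,

with offset `o_s = log(effective library size)`. The dispersion phi is
edgeR's convention (the NB shape is `1/phi`); the gamma–Poisson mixture
used by the simulator matches it exactly. For a matched design the full
model's covariates are an intercept, patient indicators (first patient as
reference) and a tumor indicator; the reduced model drops the tumor
indicator. The per-feature test is the likelihood-ratio statistic
`2(l_full − l_reduced)` against chi-square with 1 df, and
`log2FC = beta_tumor / log 2`. The patient covariates absorb between-pair
baseline differences, which is what makes a 3-pair design usable at all.

**Fitting.** IRLS with working weights `mu/(1+phi mu)`, vectorised across
features that share a design matrix (this is what keeps 100-cohort
calibration runs in seconds). Convergence is declared when the maximum
coefficient step drops below 1e-8 **or** the log-likelihood plateaus
(relative change < 1e-11). The plateau criterion is deliberate: features
with all-zero counts in one condition — precisely the strongest
candidates in shallow lncRNA data — have their MLE at infinity, so the
coefficient never stops moving while the likelihood converges to its
supremum. Dropping such features as "non-converged" would discard the
best hits; instead the linear predictor is clamped to ±30 (the likelihood
at the clamp is within ~1e-12 of the supremum) and the reported |log2FC|
for such features is large and clamp-dependent, which downstream code
treats as a direction, not a magnitude. A reduced-model likelihood
exceeding the full model beyond `1e-4·(|l|+1)` raises an error rather
than being clipped.

**Normalization.** TMM: per sample against a reference (the sample whose
75th count-fraction percentile is closest to the mean), M and A values
over features positive in both, 30% two-tailed trim on M and 5% on A,
precision-weighted mean of the surviving M values, factors rescaled to
geometric mean 1. An all-zero sample is an error. Note that TMM factors
are not exactly invariant to rescaling one sample's counts (the
precision weights depend on depth); the residual effect on log2FC is
below 0.05 at moderate expression and is dominated by count discreteness
at very low counts — multiplying a count of 1 by 4 genuinely changes the
information in the likelihood, so exact invariance is not attainable or
expected there.

**Dispersion.** A common phi maximising the summed Cox–Reid adjusted
profile likelihood (`l_g − ½ log det X'W X`) under the full model, by
bounded scalar search on log10 phi in [−6, 1]. Features identical in
every sample carry no information and are excluded (logged). With 3
pairs, per-feature (tagwise) estimation alone is far too unstable; the
common estimate is the default and recovers a true phi of 0.16 to within
a few percent at 2000 features.

**Filtering and multiplicity.** Features with nonzero counts in fewer
than 2 samples (configurable, logged) are reported untested with missing
statistics, so feature accounting stays exact. Benjamini–Hochberg is
applied over features with a p-value; missing p-values propagate as
missing FDRs. Thresholds: FDR < 0.2 in the discovery cohort, FDR < 0.05
in the confirmation cohort, both strict and both exposed as flags.

## Confirmation, partition, novelty

Confirmation intersects the two cohorts' results by feature id at the
two thresholds and, by default, requires the same direction of change
(the separate reporting of confirmed up- and down-lists implies it).
Censored printed values such as "<0.001" in the packaged worked-example
table are parsed as the interval midpoint (0.0005); any censored value is
below every threshold used here, so this choice cannot affect membership.
Novelty is a case-sensitive exact symbol match against a user-supplied
known list; the packaged list has the 7 literature-known symbols.

## qPCR statistics

Relative expression is `2^-(Ct_target − Ct_reference)`; duplicate wells
are averaged on the Ct scale (one missing replicate falls back to the
other; a fully undetermined Ct propagates as missing and drops the pair,
with counts logged — never as expression 0). The reference gene is a
parameter, not a constant.

* **Wilcoxon signed-rank** (matched tumor vs normal): zeros dropped,
  midranks on ties; the exact null is computed by subset-sum convolution
  over doubled ranks — identical to enumerating all 2^n sign assignments
  — for up to 25 non-zero pairs, then a normal approximation with tie and
  continuity corrections.
* **Kruskal–Wallis** (stages): H with tie correction against chi-square
  (k−1).
* **Steel–Dwass** (all stage pairs): each pair is ranked alone, the rank
  sum standardized with tie correction, and `q = |z|·sqrt(2)` referred to
  the studentized range with k groups and infinite df, so the family-wise
  level is respected asymptotically. At k=2 this reduces exactly to the
  two-sided normal rank-sum test. Because the rank-sum statistic is
  discrete, the asymptotic p can differ from the exact permutation null
  by a few hundredths at group sizes near 8 (they agree to ±0.02 by
  n≈25); `method="permutation"` therefore calibrates the same statistics
  against their joint max-statistic permutation null for small samples.
  Stage comparisons run Kruskal–Wallis first and append the Steel–Dwass
  table only below alpha, excluding stages with fewer than 2 tumors.

All of these are rank-based and hence invariant to strictly monotone
transforms of the measurements, so whether 2^-ΔCt or −ΔCt is analysed is
immaterial.

## Correlation-rank enrichment

Expression is transformed to log2(CPM + 0.5) (flag: raw counts), and
every candidate gene is ranked by Pearson correlation with the target
lncRNA over tumor samples (rank 1 = most positive; ties broken by feature
id so rankings are deterministic; zero-variance features are excluded and
recorded; a zero-variance target is a hard error). Set enrichment is a
Mann–Whitney shift test of set ranks versus background ranks: exact by
subset-sum enumeration for rankings of ≤ 40 genes, otherwise the
tie-free normal approximation with continuity correction. The one-sided
p targets "set more positively correlated than background". This is the
direct statistical reading of rank-based GO enrichment; graph-aware term
decorrelation is out of scope.

## Co-expression network

Vertices: features below both FDR thresholds in both cohorts, classified
by the annotation into lncRNA and protein-coding (unclassified features
are excluded with a warning). Edges: over all defined lncRNA×PCG
correlation pairs P (same transform and sample subset as enrichment),
the `ceil(0.005·P)` largest correlations become positive edges and the
`ceil(0.005·P)` smallest negative edges. The percentile is taken over
signed r (not |r|), globally over all candidate pairs (a per-lncRNA
variant exists behind a flag); ceiling guarantees at least one edge per
sign from a nonempty pool; ties at the cutoff are resolved
lexicographically by (lncRNA id, PCG id) so edge lists are deterministic.
The graph is bipartite by construction and asserted; isolated candidate
vertices are dropped by default. Hubs are lncRNAs ranked by degree with
per-sign edge counts; neighbor-set overlap between two hubs is Jaccard.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design the pipeline targets, with all
randomness derived from one seed:

| parameter | default | rationale |
|---|---|---|
| discovery pairs | 3 | matched surgical-cohort scale |
| confirmation cohort | 682 tumors / 41 normals | public-cohort scale |
| features | 2000 | enough for stable TMM/dispersion at test cost |
| lncRNA fraction | 0.3 | lncRNAs are a large minority of annotated transcripts |
| lncRNA / PCG baseline mean | 5 / 200 counts | "mostly less than 10" reads for lncRNAs vs well-expressed mRNAs |
| true DE features | 150 (7.5%) | modest for tumor vs normal tissue |
| lncRNA \|log2FC\| | U(3, 8) | the extreme fold changes near-zero baselines produce |
| PCG \|log2FC\| | U(1, 3) | realistic for well-expressed genes; also keeps the library composition stable enough that CPM correlations reflect structure rather than compositional artifacts |
| dispersion phi | 0.16 | biological CV 0.4, typical human tissue |
| patient effect SD | 0.5 (log scale) | strong between-patient baselines, shared by each pair |
| library-size log-SD | 0.3 | exercises normalization; on by default |
| latent factor loading | 0.6 | the factor explains ~2/3 of log-variance of its genes (pairwise r ≈ 0.65), a coherent-pathway level |
| planted set | 25 protein-coding DE genes | a GO-slice of the DE set that leaves a real non-planted background in the vertex pool |
| qPCR | 139 pairs, ΔΔCt 1.0, noise SD 0.5 | validation-cohort scale; ~2× up-regulation |

Patient effects are scalar per patient on the log scale and shared by the
pair, mirroring the GLM's patient regressor; the latent co-expression
factor loads only on tumor samples of the confirmation cohort, matching
where network correlations are computed. The simulator does **not**
emulate per-gene patient×gene interactions, GC/length biases, isoform
structure, batch effects, or compositional extremes — so passing tests
demonstrate that the statistics recover the structure they model, not
that they are robust to every artifact of real libraries. Problem sizes
in the test suite (e.g. 50–100 null cohorts of 2000 features, 500
recovery features, 1000 calibration cohorts of 150 features) were chosen
as the smallest sizes at which the checked quantities are statistically
stable.

## Degenerate inputs and tie-breaking (summary)

Empty files, duplicate ids, unknown vocabulary tokens, all-zero samples,
constant targets and out-of-range thresholds raise typed errors naming
the offender; nothing is silently coerced. All orderings that could
depend on iteration order (correlation rankings, edge selection, hub
reports) carry explicit id-based tie-breaks. Every writer/reader pair
round-trips exactly, and `run-all` with one seed is bit-reproducible
(checksums recorded in its manifest).

## Known limitations

* The common-dispersion model understates per-feature dispersion
  heterogeneity. The optional shrunk mode (per-feature Cox–Reid
  estimates shrunk on the log scale toward the common value, weight 0.7)
  runs mildly liberal at 3 pairs (~9–10% rejections at nominal 5% in the
  simulated regime) because tagwise information is thin; common is the
  default for exactly this reason.
* Asymptotic chi-square p-values at n=3 pairs are calibrated in the
  simulated regime (type-I ≈ 5% at nominal 5%) but are not exact.
* The Steel–Dwass studentized-range p is asymptotic; use the permutation
  mode for group sizes below ~15 when exact family-wise control matters.
* Library-composition artifacts in CPM-scale correlations are attenuated
  by the simulator's mild protein-coding effect sizes; strongly
  compositional real datasets may need a different normalization before
  the network stage.
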