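# Methods

## Data model and assumptions

`pathdyn` analyses a genes × arrays matrix of non-negative intensities in
which each array is one (phenotype group, cell line, timepoint) combination
and each group contributes at least two lines, treated as independent
duplicate experiments. All statistics operate on the log₂ scale. The core
assumptions are: (i) a large majority of genes is either below detection
(background) or equally expressed across arrays, so internal standards can
be estimated from the data; (ii) per-array distortions are affine in log
intensity; (iii) residual technological noise is approximately Gaussian and
homoscedastic across above-background genes; (iv) within one experiment a
gene's expression profile over the T timepoints is the sampling unit for
correlation-based statistics (so T limits the precision of every
correlation, which is exactly why the workflow demands duplication).

## Normalization

**Background cohort.** Per-gene median log₂ intensities are sorted and
trimmed from the upper tail (1% of the current set per step) until the
remaining set passes a two-sided KS test against a fitted normal
(p > 0.05). The fitted (μ_bg, σ_bg) define the detection threshold
μ_bg + 3σ_bg. The construction assumes background forms the lowest
intensity mode; it errors below 20 surviving genes.

**Equally expressed cohort.** Above-background genes qualify when (a) the
SD of their within-array intensity rank, normalized by the number of
above-background genes, falls below an adaptive cutoff (shrunk so the
cohort reaches 600 members when available, never above 0.10), and (b) their
temporal swing — the range of per-timepoint mean log₂ expression — stays
below 1.0 log₂ (2-fold). Ranks are invariant to any monotone per-array
distortion, which is what makes this criterion usable *before*
normalization; the swing criterion excludes strongly dynamic genes whose
high baseline would otherwise let them keep a stable rank. The exact
construction of this cohort is a design choice of this package.

**Per-array regression.** Each array's cohort log₂ intensities are
regressed on the cohort's median profile by iteratively re-weighted least
squares with Tukey bisquare weights (statsmodels RLM), and the inverse
affine map is applied to the whole array. Two numerical points matter.
First, an affine normalization is identified only up to one global affine
gauge; we fix it by forcing the geometric mean of slopes to 1 and the mean
intercept to 0. Second, regression on a noisy median profile carries a
small attenuation bias common to all arrays; the anchored fit is therefore
repeated against the re-computed median until the corrections become the
identity (tolerance 1e-10, geometric convergence in a handful of passes).
The converged map is a fixed point: re-normalizing the output reproduces it
to better than 1e-8, which the tests assert. Zero intensities are floored
at half the smallest positive value before logging.

**Residuals.** residual(g, array) = normalized(g, array) − mean over
control arrays at the same timepoint. Control residuals therefore sum to
zero per gene and timepoint by construction. For the global KS normality
check the residual columns are first standardized by the design factor
√(1 − 1/m) (control) or √(1 + 1/m) (case), m the number of control arrays
at that timepoint — subtracting an m-array mean leaves unequal variances
that would otherwise fail the test for purely structural reasons — and at
most 2000 values (deterministic subsample) enter the test, since at tens of
thousands of points a KS test rejects deviations with no practical
consequence.

## Reference group and selection statistics

**Pooled technological variance.** The reference group starts from all
above-background genes and iteratively removes genes whose residual
variance exceeds the pool by a one-sided F-test at p < 0.05 until stable.
The pooled variance itself is estimated from the lowest 80% of per-gene
variances with an exact chi-square truncation correction (the conditional
mean of χ²_df below the 80% quantile is divided out). A naively trimmed
mean would be biased low and silently inflate every downstream F statistic;
the corrected estimator is unbiased under the null — the test suite
verifies that a null dataset then yields ≈1 false hypervariable call per
1000 genes, the designed rate — while the fixed 20% trim keeps it robust to
a realistic fraction of genuinely hypervariable genes.

**HVE selection** compares a gene's variance among the samples of one
experiment (about its own mean, df = n−1) to the pooled variance
(F-test, df_ref = Σ(n−1) over members) at P < 1/N. Temporal variability is
measured on *normalized* per-line profiles, not on residuals from the
control profile: dynamics shared by all lines cancel in those residuals, so
residual variance measures line-to-line irreproducibility rather than
dynamic range. The pipeline selects HVE per group and duplicate and keeps
the intersection across duplicates.

**Differential expression** at baseline uses the residual matrix: Student
t-test between the groups' replicates (p < 0.05) AND the associative
t-test — a pooled-variance two-sample t of the gene's case replicates
against the reference pool's thousands of residuals, effectively a z-test —
at p < 0.05/N (Bonferroni over above-background genes; the original
correction is not printed anywhere, and this matches the 1/N logic of the
HVE threshold). Classes: A1/A2 by direction; A3/A4 when the gene is above
background in only one group and above the minimum-expression floor
(default 20 on the linear normalized scale). With a single replicate after
jackknifing, the Student step falls back to a z-test with the reference
variance. Jackknife reproducibility is the percentage of the n×m
leave-one-out-per-group reruns that select the gene.

**Profile reproducibility** keeps genes whose duplicate time profiles have
Pearson r ≥ cc_min (default 0.8) in at least one phenotype group; constant
profiles are excluded and logged.

## Clustering

Profile compatibility is an F-test of var(profile_i − profile_j)
(df = T−1) against **twice** the pooled reference variance (df_ref): a
difference of two profiles carries the technological noise of both, so
without the factor 2 two identical-shaped genes would sit at F ≈ 2 and
be rejected about half the time. Connectivity is the count of compatible
genes; seeding proceeds from the most connected unassigned gene (ties by
input order, documented and deterministic), each cluster absorbing *every*
compatible gene, so clusters may overlap; zero-connectivity genes stay
unclustered. Genes already absorbed are not used as later seeds — the two
readings of the original description differ only on overlapping structures.
The correlation variant replaces the F-test by r ≥ threshold (default 0.8,
matching the profile-reproducibility cutoff). Mosaics order genes
cluster-block by cluster-block (seed first) and reuse the first group's
ordering for the second group so the two matrices are directly comparable.

## Network inference

Environments use |r| ≥ t_e and the PC statistics use |pr|; the sign is
carried on the edge (negative associations could otherwise never pass the
positive thresholds). Threshold comparisons are inclusive (≥). A pair's
conditioning set is the union of the two genes' environments — a symmetric
reading; conditioning genes with |r| ≥ 1 − 1e-9 to either endpoint are
dropped (a perfect copy of an endpoint makes the formula 0/0 and carries no
information). With an empty conditioning set, |r_xy| stands in for both PC
statistics — this affects only isolated pairs. Classification: essential if
PC_m ≥ t_m and PC_a ≥ t_a; exactly one hole → indirect via the hole gene,
or triangle when the (x, z) row has the reciprocal hole at y; two or more
holes → no edge. Both essential and triangle classifications keep the edge.
Edges must be kept in **all** duplicates of a group with agreeing
correlation sign (disagreements are dropped and logged); provenance records
which groups retained the edge.

**Monte-Carlo calibration** draws i.i.d. standard-normal replicate matrices
(two independent draws per simulation under duplication) and runs the full
edge pipeline. Two false-positive normalisations are reported, because
"rate" is ambiguous on null data: the proportion of *evaluated* pairs
(pairs entering environment testing, i.e. |r| ≥ t_e in every duplicate)
that are retained, and the proportion of *all* gene pairs retained. Under
the single-experiment design the evaluated-pairs rate is dominated by
near-empty conditioning sets and is much larger than 5%, while the
all-pairs rate is well under 5%; under the duplicated design both rates are
small. The acceptance script reports the evaluated-pairs rate for the
duplicated design, the stricter of the two readings.

## Synthetic data

The generator emulates the study conditions: 8 timepoints
(0–24 h, default), two phenotype groups × two lines (= duplicates), a
log-normal background mode (μ 6.0, σ 0.35 log₂), a uniform 4-log₂ band of
stable baselines ≥ 5σ above background, peak-time clusters with a
piecewise-linear rise/decay in sampling order (amplitude 2.5 log₂),
planted couplings realized as signed copies of a smooth random source shape
plus per-line "link noise" (0.3 log₂), chains x→z→y in which y follows z's
*realized* per-line trajectory — without this the mediator could never
explain the x–y association and no hole would exist — group effects
(constitutive offsets, group-unique dynamics), per-array affine distortions
(slope σ 0.03, offset σ 0.2 log₂) and i.i.d. measurement noise
(0.15 log₂). Noise magnitudes are chosen for testability — small enough
that planted structure is recoverable, large enough that every estimator is
exercised — not fitted to any particular platform. What the generator does
*not* emulate: probe-level effects, intensity-dependent noise,
cross-hybridization, batch structure beyond one affine map per array, and
autocorrelated biological drift; passing tests therefore demonstrate
correctness of the statistics under the stated model, not performance on
any specific real dataset. The randomized-null generator is plain standard
normal — the network statistics are correlation-based, hence scale-free.

Default planted structure: two chains and four couplings (one negative, one
case-only, one control-only) among dedicated "free" genes with independent
smooth source shapes; five group-effect genes. All planted-structure genes
live outside the background/stable/cluster ranges so every truth set is
unambiguous.

## Known limitations

* With T = 8 timepoints per experiment, a sample partial correlation has a
  null SD near 0.45; single-experiment hole classification is accordingly
  noisy, which is precisely the argument for the duplication filter. Tests
  of mediator recovery pool a group's duplicates (16 samples) and accept
  identification in either phenotype group.
* The equally-expressed-cohort construction and the associative-test
  correction are this package's reconstructions of procedures whose
  original details are in prior literature or unpublished.
* The pipeline assumes complete arrays (no missing intensities) and at
  least one control array per timepoint.
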