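# Methods

## Data model and validation

The unit of computation is the isomiR observation: one row per
(miRNA, sample) carrying `len_trim` (nucleotides removed from the
canonical 3′ end), `tail_seq` (nucleotides appended after trimming),
`reads`, and `ratio` (the isomiR's frequency among all retained isomiRs
of that miRNA in that sample).  The signed 3′ end position is
`len(tail_seq) − len_trim`.  5′-end variation is carried in an optional
signed `LEN_5P` column (positive = nucleotides trimmed from the 5′ end);
it shifts coverage profiles but never alters the 3′ end position, which
by construction ignores the 5′ end.

Validation mirrors the upstream isomiR quantifier's read filters, all
configurable: read length 17–26 nt, |5′ distance| ≤ 3, |3′ distance| ≤ 5,
per-isomiR minimum 10 reads.  Records failing a filter are dropped and
counted per reason; ratios are then renormalized over retained records,
so `ratio` always sums to 1 within each (miRNA, sample) group.  Tail
nucleotides are treated as untemplated: templated 3′ extensions are
indistinguishable in this table format and are counted as tailing.

Abundance filtering keeps miRNAs whose mean reads-per-million (RPM,
denominator = per-sample total endogenous miRNA reads, spike-ins
excluded) reaches a threshold, 10 by default and boundary-inclusive
(`≥ 10`); an exclusive variant (`> 10`) is available for the targeting
analysis, where either convention appears in practice.  Technical
replicates (samples sharing a `replicate_group` and identical
covariates) are collapsed to their per-miRNA mean end score before
regression.

## The 3′ end score and its regression

Per miRNA and sample, the score is the frequency-weighted sum of a
per-isomiR quantity: the signed end position (`total`), the trim length
(`trim`), or the count of one nucleotide in the tail (`tail_A` …
`tail_U`).  Units are nucleotides throughout; with the validation
filters the total score lies in [−5, +5].

Each miRNA's score vector is fit by ordinary least squares on
`[intercept, age, covariates]`.  The age term is linear in days by
default; a natural-log option serves designs whose ages span orders of
magnitude (e.g., a human cohort from days to decades).  Categorical
covariates get treatment coding with the first sorted level as
reference.  The fit is shared-design multi-response least squares
(`numpy.linalg.lstsq` over a miRNA-indexed response matrix), with the
age coefficient's two-sided t-test p-value computed from the residual
degrees of freedom; an explicit normal-equations solver and
`statsmodels.OLS` serve as independent cross-checks in the test suite.
Benjamini–Hochberg FDR is applied across the miRNAs tested in one call,
i.e., one multiplicity family per score mode — the per-modification
regressions form new families rather than reusing the total-score
family, matching their presentation as separate analyses.  Classes:
shortened (estimate < 0, FDR < α), extended (estimate > 0, FDR < α),
else ns, with α = 0.05 by default.

Degenerate cases follow fixed conventions: a zero-variance response
gets estimate 0 and p = 1 (avoids NaN propagation); a rank-deficient
design raises an error naming the aliased columns; miRNAs with missing
(miRNA, sample) cells are dropped from that regression rather than
imputed, since imputing a score of 0 would read as "exactly canonical".

Because the end position decomposes as `e = Σ_N count_N(tail) − trim`
and OLS is linear in the response, the age estimates satisfy
`β_total = Σ_N β_tail_N − β_trim` per miRNA exactly whenever all modes
share the same design and sample set; the test suite holds this to
1e-8.  For poly(A)-based library preparations (Combo-Seq), terminal A
nucleotides present before library preparation cannot be distinguished
from the added poly(A) tail, so `tail_A` results are computed but
flagged not-interpretable (`exclude_a_tail`); shortening via trimming
appears as a *positive* trim-score slope, and the trim-mode slope is
what is reported (the mapping to the total-score sign is the identity
above).

## PCA screening

PCA runs on per-miRNA-centered (unscaled — scores share units) scores
with samples as observations.  The outlier rule replaces a visual
screen: a sample is flagged when its distance from the coordinate-wise
median of the first two components exceeds the median distance by more
than k·MAD (k = 5).  Flags are advisory and nothing is removed
automatically; on data with strong age structure a whole extreme age
group can be flagged, which is exactly why removal is left to the
analyst.

## Coverage profiles

Positions are 1-based on each miRNA's canonical coordinate system
(position 1 = canonical first nucleotide; ≤ 0 = 5′ extension; beyond
the canonical length = tail).  Per sample, each record's reads cover
`[1 + len_5p, L − len_trim + len(tail)]`; summed reads per position are
divided by the sample's total reads, and sample profiles are *averaged*
within groups (not read-pooled, so samples with unequal depth weigh
equally).  The end-shift summary sums the coverage difference to a
reference group over the 3′ flank (positions within 5 nt of the
reads-weighted modal canonical length); negative values mean 3′ ends
sit left of (shorter than) the reference.  The 5′ flank summary is the
stability control.

## Expression stages

**Spike-in ratio trend.**  Per sample, total endogenous miRNA counts
over total small-spike-in counts; since spike-ins enter at constant
expectation, sequencing depth cancels and the OLS slope of the ratio on
age measures real change in total miRNA output that per-feature
normalization would erase.

**Normalization.**  Median-of-ratios size factors computed on the
combined endogenous + spike-in matrix (reference features = those with
all-positive counts), or per-million scaling within each feature class.

**Age-trend DE.**  Features with < 10 total raw counts are removed.
Each feature's `log2(normalized + 0.5)` is tested with a Gaussian
nested-model F test: full model (covariates + age) vs. reduced
(covariates only), BH FDR, direction from the age coefficient's sign.
This is a declared simplification of a negative-binomial
likelihood-ratio test; the output contract (estimate, FDR, direction,
cluster) is kept so an NB-backed run can be substituted externally.
The pseudocount 0.5 is the standard log-count stabilizer; the log2
transform stands in for a regularized log, which it approximates for
well-covered features but does not shrink low counts.

**Pattern clustering.**  Significant features are summarized as
z-scores of per-age-group mean log expression (age categorical),
clustered hierarchically with distance 1 − Pearson r and average
linkage; the cut is chosen by maximum mean silhouette over k ∈ 2..8.
Human cohorts can be binned to six lifespan groups (infant < 1 y, child
1–12, adolescent 13–18, young adult 19–29, adult 30–64, elderly 65+;
lower edges inclusive, 365 days/year).

## Target correlations

Predicted interactions from multiple databases are reduced to unique
(miRNA, target) pairs with their supporting sources and filtered to
≥ 2 tools, abundant miRNAs, and detected targets.  Pearson r with its
exact two-sided t-transform p-value is computed per pair across shared
samples (≥ 3); zero-variance series yield r = NA, kept in the record
but excluded from summaries.  Correlation p-values are reported but not
FDR-filtered — the stratification is by r, not p.  Histograms (bin
width 0.1) are stratified by target DE direction and colored by miRNA
3′-end class; the extreme sets {target down, r < lower cutoff} and
{target up, r > upper cutoff} are exported for external enrichment
tools.  The cutoffs are configuration (±0.5 default; ±0.25 and ±0.75
are reasonable alternatives depending on sample size).  Class-level
contrasts (per-miRNA DE estimate; per-miRNA count of detected predicted
targets, counted per mature miRNA id) use Kruskal–Wallis followed by
pairwise two-sided Wilcoxon rank-sum with Holm adjustment; classes with
fewer than 2 members are excluded with a warning.

## Synthetic-data generator

The generator emulates the structure of an aging small-RNA study, with
ground truth for every entity.  Defaults define the reference study:
ages {22, 40, 60, 120} days, 8 samples per age, 30% of miRNAs truly
shortened at 0.01–0.02 nt/day, half via trimming and half via U-tail
decline.

*End positions.*  Each miRNA draws a baseline distribution over a small
support around the canonical terminus (within the distance filters)
from a Dirichlet: stable miRNAs over [−3, +2], trimming-mechanism
miRNAs over [−3, 0] with empty tails, U-tail-mechanism miRNAs over
[0, +2] with pure-U tails.  Aging applies an exponential-family tilt to
the distribution, calibrated so the expected end position moves at the
requested nt/day near the mean age.  The *true* slope is defined as the
OLS slope of the analytic expected end position over the design ages,
so saturation of the tilt near the support boundary is part of the
truth rather than a recovery bias.  Configurations whose requested
slope would exceed the support span over the age range are rejected
before sampling.

*Counts.*  Per-miRNA totals are negative binomial (mean × log-normal
library factor; dispersion 0.1) split multinomially across isomiRs,
with optional per-sample Dirichlet overdispersion of the isomiR weights
(concentration 150).  Setting dispersion and overdispersion off yields
the deterministic regime (counts = expectations) used for
law-of-large-numbers checks.  Records below 10 reads are not emitted,
so generated tables pass default validation unchanged.

*Expression and interactions.*  Spike-ins have constant expectation
(library factor only); endogenous features carry log-linear age trends.
Shortened miRNAs receive a +0.02 log2/day expression trend — the
motivating data showed 3′-shortened miRNAs increasing with age — which
also guarantees that targets linked to them inherit a detectable trend.
A designated set of (shortened miRNA, DE target) pairs receives
correlated profiles: the linked target's mean profile is an affine
transform of its partner miRNA's realized counts (sign positive for
up-targets, negative for down-targets) mixed with an independent
trend profile at the configured link strength, so link strength 1 in
the deterministic regime produces |r| = 1 exactly.  An option erases
pure-A tails before table emission to mimic poly(A)-based library
chemistry.

*What the generator does not emulate:* sequencing error, 5′
heterogeneity, templated-vs-untemplated ambiguity, miRNA-family
cross-mapping, GC or length biases, batch-by-age confounding, and
secondary-structure effects.  Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under a realistic
noise model, not that real libraries are free of these artifacts.

## Problem sizes and tolerances

The test and acceptance runs use 25–100 miRNAs (1,000 for null
calibration), 32 samples, and 300 targets — sizes at which every stage's
behavior is already asymptotic while the full suite runs in well under
a minute per stage.  Numerical tolerances: end-score oracle agreement
1e-12, OLS vs. normal equations 1e-10, decomposition identity 1e-8,
ratio sums 1e-6.  Null calibration accepts a raw-p fraction below 0.05
of 0.05 ± 0.02; recovery demands sensitivity ≥ 0.9, empirical FDR
≤ 0.1, and slope RMSE ≤ 25% of the mean true slope magnitude.

## Known limitations

- The Gaussian F test on log counts is less powerful than an NB LRT at
  very low counts and does not model mean–variance coupling.
- The MAD-based PCA flag is a screen, not a decision rule; it
  over-flags structured designs (see above).
- RATIO is normalized over retained records only; if the upstream tool
  normalized before its minimum-reads filter, frequencies differ
  slightly for miRNAs with many sub-threshold isomiRs.
- Interaction support counts treat all source tools equally; no
  evidence weighting.
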