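# Methods

`flypheno` reimplements a behavioral-phenomics stratification workflow for
*Drosophila* disease models: raw single-fly positional traces are scored
into sleep/activity architecture, per-fly daily sleep profiles are
decomposed by non-negative matrix factorization (NMF), genotypes are
clustered on the combined feature space, and the resulting behavior groups
are validated against an independent genetic-interaction (GI) screen on
electroretinogram (ERG) amplitudes, with concordance quantified by Jaccard
similarity against a permutation null.  Everything is exercised on synthetic
cohorts with known ground truth.

## Sleep annotation and features

Positions are reduced to a 10-s interval grid anchored at the first frame
(half-open windows `[start, start + 10 s)`).  An interval is **moving** when
any frame-to-frame Euclidean displacement within it is at least 0.25 mm;
otherwise it is immobile.  The per-frame corrected velocity is
`v = 10^(d/1000) / (dt · fps · a)` with `d = 1000 · log10(displacement)` and
the empirical correction factor `a = 0.0042` mm; for positive displacements
this reduces to `displacement / (dt · fps · a)`, and a zero displacement is
assigned `v = 0` (the log-distance is undefined).  **Sleep** follows the
5-min rule: a maximal immobile run strictly longer than 300 s is one sleep
bout and all of its intervals count as sleep, including the first five
minutes.

Quality control: the first recording day is always excluded (habituation),
and a fly that is continuously immobile from some onset through the end of
the recording for at least 24 h is flagged dead and censored from the onset.
The 24-h window is the conventional choice of common fly sleep-analysis
frameworks; the criterion is isolated in `detect_death` so it can be
replaced.  Missing intervals (recording gaps) are excluded from all
denominators, never imputed.

Per-fly features, averaged over retained light/dark cycles (ZT in
`[0, photoperiod)` is light): sleep fraction by day and night; latency from
lights-off (ZT12) to the onset of the night's longest bout, with nights
weighted by the retained fraction of their dark phase (the weighting rule is
a package choice — alternatives such as bout-count weights are not
distinguishable from the available description); mean bout length and bout
count per night, with bouts clipped to the dark window; mean corrected
velocity over moving intervals (rescaled to mm/s); total distance per 24 h;
and morning anticipation, computed per night as activity in the final 3 h of
dark divided by activity in the final 6 h (0.5 = flat, >0.5 = anticipatory
ramp; this standard last-3/last-6 index sits behind one function so it can
be swapped).

## Temporal sleep vectors and NMF

Each fly is summarized by a 1440-bin vector (one bin per minute of clock
time): the fraction of retained intervals, pooled over days, whose strictly
preceding 5-min window was at least 99% immobile ("time spent sleeping").
A Gaussian blur with sigma = 5 bins smooths the vector; the default edge
mode is `reflect` (matching common image-filter implementations), with a
`wrap` option since clock time is periodic.  Vectors are kept as fractions
in [0, 1]; the scale is irrelevant to NMF up to a constant factor.

The blurred vectors of `l` flies form the non-negative matrix
`M (1440 × l)`, factorized as `M ≈ W H` with `W ≥ 0 (1440 × k)` the shared
temporal components and `H ≥ 0 (k × l)` the per-fly encodings.  Fitting uses
multiplicative/coordinate-descent NMF with a deterministic NNDSVD
initialization plus random restarts (best reconstruction error kept; all
seeds recorded).  Explained variance is `1 − ||M − WH||²_F / TSS` with TSS
the column-mean-centered total sum of squares.  The rank is chosen at the
elbow of the explained-variance curve, operationalized as the most negative
discrete second difference; a curve with no concave elbow falls back to the
smallest k whose marginal gain is below 0.02 (with a warning).  As an
alternative criterion the Calinski–Harabasz index is computed on the fly
encodings with each fly assigned to its dominant component — the argmax of
its encoding column of `H` (the dominant component is a property of the
encoding, not of the time-bin matrix `W`).  Degenerate clusterings (zero
within-cluster dispersion) report an infinite sentinel.

## Genotype clustering, PCA and stability

Genotype means of the behavioral features — excluding morning anticipation,
which is nearly collinear with the temporal components — are joined with the
per-genotype mean encodings, and each column is z-scored with the sample
(n−1) standard deviation.  Rows (genotypes) are clustered on correlation
distance (`1 − Pearson`) with McQuitty/WPGMA linkage, in which a merged
cluster's distance to any third cluster is the plain average of its two
constituents' distances, independent of cluster size.  The tree is cut both
into 2 coarse behavior groups and into 5 subgroups (one flat 5-way cut;
nested cutting would be an alternative reading and both cuts are reported).
PCA runs on the already-scaled matrix with centering only; scree fractions
are squared singular values over total variance, and per-feature `cor²`
values are squared Pearson correlations between feature columns and PC
scores.

Leave-one-feature-out stability drops one column at a time from the raw
matrix, re-scales, re-clusters, cuts to 5 subgroups, and scores every
reference subgroup by its best-match Jaccard similarity (the maximizing new
group; the matching rule is a package choice).  Values are binned into the
categories 0–0.34, 0.35–0.69 and 0.7–1, with 0.35 the threshold for
substantial overlap.

## Genetic-interaction screen

ERG depolarization amplitudes are normalized to the mean control amplitude
of their experimental batch, which absorbs any batch gain.  Under the
multiplicative non-interacting model the expected double-heterozygous
amplitude is the product of the two normalized single-mutant means; the GI
strength of a pair is the mean over double-mutant replicates of
(observed − expected).  A pair interacts only when |strength| ≥ 0.3.  Sign
convention: a **lower**-than-expected amplitude means a worse phenotype,
hence *aggravating*; a higher one is *alleviating*.  Note the reachable
strength range is bounded below by `−expected` (amplitudes are
non-negative), so strongly aggravating interactions are only detectable for
pairs whose singles are mild.  Gene profiles (rows of the symmetric
gene × gene strength matrix, untested self-pairs set to 0) are clustered
with Euclidean distance and WPGMA and cut into two GI groups.

## Bayesian interaction model

Per pair, the normalized single-mutant fractions get scaled-Beta priors
`α, β ~ 1.05 · Beta(2, 5)` — support (0, 1.05) so slight increases above
control remain possible, skewed toward values nearer 1, prior mean 0.30 —
and the additive interaction term gets `ι ~ Normal(0, 1)`.  The
double-mutant mean is `α·β + ι`.  The description of the model stops at the
priors and the contribution equation, so the observation process is a
package decision: replicates are observed with Normal noise, one scale per
genotype, each with a HalfNormal(0.2) prior (weakly informative on the
normalized scale); the likelihood lives in one class and can be replaced.

Sampling uses an affine-invariant ensemble MCMC sampler (32 walkers,
vectorized log-density; default 1000 warmup + 2000 retained ensemble steps).
Because walkers of an ensemble sampler are mutually coupled and individually
autocorrelated, split-R̂ is computed over pooled walker groups (default 4);
values above 1.01 raise a warning.  The 95% highest-density interval (HDI)
of ι is the narrowest interval containing 95% of the pooled draws (sorted
minimal-width window); a pair is called interacting when 0 lies outside it.
Calibration at the default conditions (σ = 0.05, 20 replicates): the null
false-call rate is at the nominal few-percent level and ι = ±0.5 is
recovered with the correct sign essentially always (see
`tests/test_acceptance.py` and `scripts/acceptance.py`, which compute these
rates at run time).

## Partition concordance

Jaccard similarity (intersection over union) compares a behavior-defined
group with each GI-defined group.  Significance is a one-sided permutation
test: 10,000 random draws of mutually disjoint groups from the gene
universe with the same size distribution as the real GI groups; the p-value
is the fraction of draws in which the best random-group similarity
**strictly** exceeds the observed best similarity, with no
multiple-comparison correction.  Ties do not count as exceedances and no +1
correction is applied (both available by flag), matching the method's
stated definition; consequently p = 0 is reportable and — because the
max-Jaccard statistic on a ~24-gene universe is coarsely discrete — the
test is mildly anticonservative at nominal levels (exact enumeration of the
hypergeometric intersection distribution puts the true rejection rate at a
nominal 0.05 between roughly 0.06 and 0.14 depending on group sizes).  The
tie-counting variant is conservative instead; users comparing small gene
sets should prefer it when strict level control matters.

## Synthetic cohorts

The track generator emulates multi-day tube recordings (defaults: 2
frames/s, 12:12 light:dark, 65-mm tube, ≥5 recording days with the first
discarded).  Each fly alternates asleep/awake through a two-state
semi-Markov process on a 10-s grid: the sleep-entry hazard is
`bout_rate · intensity(t)` with a 1440-point per-minute intensity curve,
ramped in after lights-off with time constant `latency_lights_off` and
suppressed linearly over the last 3 h of night by `anticipation_ramp`; the
wake hazard is the inverse mean bout length (night value, scaled by
`day_sleep_scale` in the light phase).  Awake frames step with speed drawn
around the archetype's awake speed (kept above the movement threshold so
states are recoverable); asleep frames jitter uniformly in [0, 0.1] mm,
always below threshold.  Position is one-dimensional along the tube with
reflecting boundaries and tiny transverse jitter.  Per-fly RNG streams are
spawned from `(seed, fly index)`, so output is bit-identical for a given
seed regardless of chunking.

The ERG generator draws per-batch control means around the global control
mean (5% CV) to exercise per-batch normalization, and produces replicate
amplitudes around `control · (eA·eB + ι)` for doubles.  The two supplied
behavior archetypes ("reduced sleep, long latency" vs "high sleep, short
latency with a morning bout") were parameterized once to reproduce the
qualitative phenotype contrast of the modeled screen.

What the generator does **not** emulate: positional preference along the
tube, micro-movements (grooming), arousal-threshold structure, aging trends
across days, or between-experiment batch effects in behavior.  Passing
recovery tests therefore show that the pipeline inverts its own generative
assumptions at realistic noise levels — not that it is robust to every
artifact of real video tracking.

## Problem sizes and numerical choices

Simulation-backed tests use cohorts of 12 genotypes × 30 flies at 2-day
recordings (one retained day), NMF at k = 3 with 1 random restart and 150
iterations; calibration suites use 100 seeded screens for the
multiplicative GI model, 100 + 100 posterior runs (400 warmup + 400
retained steps) for the Bayesian model and 200 permutation replicates at
10,000 iterations.  `scripts/acceptance.py` uses the same conditions with 5
end-to-end seeds and 40 + 40 posterior runs.  These sizes were chosen so the
whole suite runs comfortably on a single CPU while keeping Monte-Carlo error
well below the decision margins being tested.

Other numerics: NMF tolerance 1e-6; zero-variance feature columns are a
hard error during scaling (they carry no information and would divide by
zero); linkage ties resolve deterministically through the condensed-distance
implementation; the HDI of a point mass has zero width; an empty Jaccard
union is an error rather than a convention.

## Known limitations

* The death rule cannot distinguish a fly that dies moments before the
  recording ends (censoring requires ≥24 h of terminal immobility).
* The elbow operationalization (second differences) assumes the variance
  curve is concave after the true rank; heavily noisy curves may need the
  Calinski–Harabasz alternative.
* The Bayesian observation model is intentionally simple (Normal,
  per-genotype scale); heavy-tailed replicate noise would widen HDIs rather
  than be rejected.
* GI strengths below `−expected` are unreachable, so aggravating calls
  saturate for pairs with strong single effects.
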