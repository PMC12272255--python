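# Methods

This note records the statistical conventions the package implements, the
design choices made where the methodology is genuinely open, what the
synthetic cohort does and does not emulate, and the known limitations.

## Conjunction selection of lateralized regions

For homotopic pair j with left/right contrasts L_j, R_j across n
participants, the package computes a one-sample t of each hemisphere's mean
against zero and a paired t on L_j − R_j. A region is selected on the
hemisphere favored by the asymmetry (the sign of the paired t) when both
that hemisphere's activation and the asymmetry are significant at the
per-test level α/N (family rate α = 0.05, N = 185 pairs by default, i.e.
≈ 2.7·10⁻⁴).

*Sidedness.* "Significantly positive" is read as two-sided p < α/N together
with t > 0, equivalent to a one-sided test at half the level; the one-sided
reading at the full level is available via `two_sided=False`. The choice is
a convention — the source methodology does not disambiguate.

*The "overall conjunction level".* The product (α/N)² is reported as the
nominal overall level, as the methodology defines it. It is exact only if
the two tests are independent. They are not: the activation statistic of
the favored hemisphere and the paired asymmetry statistic share that
hemisphere's noise and correlate at 1/√2 when left and right noise are
independent with equal variance. The true null level of the implemented
rule is the bivariate-normal orthant probability at the per-test critical
value, doubled for the two sides — far above (α/N)² but well below the
per-test level α/N, so Bonferroni control over pairs is preserved. The
Monte-Carlo acceptance test validates the rate against this closed form.
(The product level would be exact had activation been tested on the pair
mean (L+R)/2, which is orthogonal to L − R; the per-hemisphere convention
is retained because it is what the methodology specifies.)

## Group connectivity and dissimilarity

Per-participant matrices are Pearson correlations of region time series.
The group matrix averages on the Fisher scale, tanh(mean(atanh r)); an
off-diagonal |r| = 1 makes the transform infinite and is reported as an
error with the offending participant and region pair rather than silently
clipped. The clustering dissimilarity is d = √((1 − r)/2), which maps
[−1, 1] monotonically onto [1, 0]. The printed form of this equation in the
source methodology is typographically ambiguous ("d = 1 − r2"); the package
follows the formula used throughout the lateralized-atlas lineage the
method descends from, and exposes the alternative reading d = 1 − r² behind
`rule="one_minus_r_squared"` for comparison (it is not monotone in r and
folds anticorrelation onto correlation, so it is not the default).

Inter-network coupling deliberately uses a different average: the plain
mean over participants of each participant's mean cross-network
correlation, matching the methodology's own description of that summary.

## Ward clustering and the cluster-count vote

Ward's criterion is applied to the supplied (unsquared) dissimilarities —
the Ward.D2 dialect, via `scipy.cluster.hierarchy.linkage(method="ward")`.
The merge sequence is cross-checked in the test suite against an
independent brute-force Lance–Williams agglomerator on all small instances.

The original analysis chose the cluster count with a 17-index consensus
whose index list is not published. The package implements an explicit,
auditable stand-in: five internal validity indices computed purely from the
distance matrix — pseudo-F (Calinski–Harabasz from pairwise squared
distances), average silhouette width, Davies–Bouldin with medoid centres,
Dunn, and the C-index — each voting for its best k over the candidate
range (2–10 by default), majority wins, ties toward smaller k (parsimony).
Every index's score at every k is reported so a divergent vote can be
audited. This battery is a documented approximation, not a claim of
equivalence to the original consensus.

## Sign test

The exact sign test drops zero values, then computes
p = min(1, 2·min(P(X ≤ k), P(X ≥ k))) with k the number of positive values
and X ~ Binomial(n_pos + n_neg, 1/2): the smaller observed tail, doubled
and capped. Dropping zeros (rather than splitting them) is the documented
default. Significance uses the Bonferroni level α / C(k, 2) over network
pairs — 0.05/10 = 0.005 for five networks.

## Centralities and the hub rule

Within a network of N ≥ 3 regions, edges exist exactly where r > 0.
Degree centrality is the weighted strength (sum of incident positive
correlations). Betweenness converts weights to lengths — 1/r by default,
so strong correlations are short; the literal "lowest sum of correlations"
reading is exposed as `one_minus_r` — and accumulates over ordered pairs
the fraction of shortest paths through each region (all minimal paths
counted; unreachable pairs contribute nothing).

Betweenness is reported raw (the ordered-pair sum) by default. The printed
formula in the source carries a 1/((N−1)(N−2)) factor, which is
inconsistent with the magnitudes it reports (normalized betweenness cannot
exceed 1); both variants are available, and the hub rule is invariant to
the choice because it compares regions within one network.

Participant-averaged centralities carry normal-approximation 95% CIs
(mean ± z·sd/√n); the CI construction in the source is unstated. Hub
thresholds are the across-region mean plus across-region sample SD
(denominator N−1) of the participant-averaged values; the dual-threshold
comparison is inclusive (≥), so a region sitting exactly on a threshold
qualifies — with the degenerate corollary that a perfectly homogeneous
network (SD 0) flags all regions. One printed worked example in the source
(a hub whose printed DC sits 0.03 below its printed threshold) cannot be
reproduced by any fixed comparison rule at printed precision and is treated
as a rounding artifact of the printed values.

## Synthetic cohort

The generator reproduces the study's dimensions — 130 participants, 185
homotopic pairs, 240 rest volumes at TR = 2 s, band 0.01–0.1 Hz — and
plants the structure the analysis is meant to find. All randomness derives
from one seed (independent streams per stage), and identical configurations
give bit-identical output.

*Contrasts.* Unit-variance Gaussian noise per participant, pair and
hemisphere. A planted pair adds the activation effect to both hemispheres
and ±(asymmetry effect)/2 split across hemispheres, so the pair mean
carries only activation and the difference only asymmetry. Defaults of 1.5
and 1.0 noise-SD units are conventions chosen for comfortable power at
n = 130 (per-pair miss probability ≪ 10⁻⁴), not estimates of real effect
sizes, which the source does not report.

*Rest series.* Each module has a latent signal; region i in module m is
x_i = λ s_m + σ ε_i with λ = 1 and σ = 1 by default, giving within-module
region correlations ≈ 0.5. Latents are correlated according to
between-module targets specified on the region scale and mapped to latent
correlations by undoing the attenuation (λ² + σ²)/λ²; a region-level target
can therefore never exceed the within-module correlation — a structural
property of latent-factor models, which is why the demo's between-module
magnitudes are modest (±0.02–0.09) while carrying the full planted sign
pattern. Connector hubs load additionally on secondary module latents
(0.25) and have their idiosyncratic noise scaled by 0.45, which raises both
their within-network strength and their betweenness (paths reroute through
the uniformly best-connected region). All components are white Gaussian
series masked to the passband in the frequency domain — an ideal zero-phase
filter, so out-of-band power is numerically zero and the effective number
of independent samples is set by the band (≈ 88 of 240 at the defaults).

*What is not emulated.* No hemodynamic response, voxel level, motion or
physiological confounds, scanner drift, spatial autocorrelation, or
heavy-tailed noise; nuisance regression is assumed already applied.
Passing recovery tests therefore show that the pipeline recovers the
structure it assumes, under that model — not that the model captures every
property of real fMRI data.

*Demo conditions.* The demo plants the packaged atlas's 95 regions as the
first 95 of 185 pairs, with module sizes 12/25/23/20/15 and one connector
hub in each network except Visu. Default generator parameters were fixed
once so that the planted structure sits comfortably inside the pipeline's
recovery range (five-network vote, ARI 1.0 at k = 5, hub and sign-pattern
recovery across seeds); they are package conventions, stable under modest
perturbation.

## Numerical conventions

* Shortest-path ties: all minimal paths are counted; the enumeration oracle
  in the tests treats lengths equal within a 10⁻¹² relative tolerance as
  tied. Exact float ties do not occur with continuous random weights.
* Degenerate inputs are errors, not warnings: zero-variance contrast
  vectors, constant time series, |r| = 1 off-diagonals, all-equal
  dissimilarities, all-zero sign-test inputs, networks below three regions.
* Region tables store MNI coordinates as integers exactly as printed
  (−0 normalized to 0); unassigned networks serialize as the literal
  token `NA`.
* Optimal-k ties break toward smaller k at both levels (within an index
  and in the vote).

## Problem sizes in the test suite

The statistical property tests run 200 null replicates at 50 pairs for the
conjunction level and 20 full-scale demo cohorts (10 of them through the
betweenness stage) for recovery; these sizes give the Monte-Carlo checks
useful power while keeping the default test run lightweight.

## Known limitations

* The five-index vote is a stand-in for an unpublished 17-index consensus.
* The (α/N)² "overall conjunction level" is an independence approximation;
  see above for the exact level of the implemented rule.
* Confidence intervals use the normal approximation across participants.
* The generator's latent-factor covariance cannot represent between-module
  correlations exceeding within-module ones.
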