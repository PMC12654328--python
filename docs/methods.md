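# Methods

## The analysis problem

A fly in a T-maze makes a sequence of binary choices: run toward the
illuminated arm (+1) or away from it (−1). Forty trials per fly give two
per-fly summaries — the light-choice probability (LCP, the fraction of
+1 trials, in [0, 1]) and the phototaxis index (the mean of the ±1
scores, in [−1, +1]; identically 2·LCP − 1). The scientific questions
are about treatment groups of flies: do treatments shift the *mean*
choice tendency, and do they change the *between-fly spread* of
tendencies (behavioral individuality)? Because a fly's 40 trials are
correlated through its latent tendency, the fly — never the trial — is
the unit of inference.

## Location inference

Group centrality on LCP is tested with a permutation Kruskal–Wallis: the
usual tie-corrected H on ranks,

H = [12 / (N(N+1))] Σ_g n_g R̄_g² − 3(N+1),   divided by
1 − Σ(t³ − t)/(N³ − N),

referred to its own permutation null (group labels shuffled across all
flies, group sizes fixed) rather than the chi-square approximation. Tie
correction is on by default and matters: with 40 trials the LCP takes at
most 41 values, so ties are massive (an uncorrected H is available as a
sensitivity switch). Pairwise contrasts are permutation tests on the
absolute difference of group means, with the signed difference reported
as the effect; the two groups in the contrast are re-permuted between
themselves (a two-group relabeling null), and the family of all C(4,2)=6
pairs is Holm step-down adjusted.

## Dispersion inference

Between-fly spread within a group is the median absolute deviation of
the per-fly phototaxis indices and its normalised form
MADn = 1.4826 × MAD, comparable to a standard deviation under normality
and insensitive to tail behavior. The global test statistic is the range
max_g MADn_g − min_g MADn_g; pairwise statistics are |ΔMADn|, Holm
adjusted, with the same permutation scheme as the location family.
Per-group uncertainty is a bias-corrected and accelerated (BCa)
bootstrap interval (resampling flies within group):

- bias correction z0 = Φ⁻¹ of the fraction of bootstrap replicates below
  the point estimate, with exact ties counted at half weight — on a
  40-trial grid bootstrap MADn replicates tie with the point estimate
  constantly, and a strictly-less rule would bias z0;
- acceleration a from jackknife skewness,
  a = Σ(θ̄ − θ₋ᵢ)³ / (6[Σ(θ̄ − θ₋ᵢ)²]^{3/2}), set to 0 when the
  leave-one-out values are all equal (the symmetric limit of 0/0);
- endpoints are bootstrap quantiles at
  Φ(z0 + (z0 + z_{α/2}) / (1 − a(z0 + z_{α/2}))) and its upper analogue.
  When z0 = 0 and a = 0 this is exactly the percentile interval.
  Degenerate bootstrap distributions collapse the interval to the point
  with a flag; a z0 numerator of 0 or 1 is clamped to
  [1/(B+1), B/(B+1)] with a flag.

## Permutation conventions

All permutation statistics here are non-negative departures (a range, an
absolute difference, H), so the two-sided test is the one-tailed
exceedance on the statistic. Two p-value conventions are implemented:
`proportion_ge` (#{null ≥ observed}/B, the default) and `plus_one`
((1 + #{null ≥ observed})/(1 + B), never below 1/(B+1) and exactly
level-controlling; used by the calibration test-suite). Ties count as
exceedances, judged with a 10⁻⁹ relative tolerance: permuted replicates
that are mathematically tied with the observed statistic can differ in
the final float digits through summation order, and dropping those ties
demonstrably biases Monte-Carlo p below the exact enumeration value on
gridded data.

Seeding: one master seed; every named analysis step (each test family,
each group's bootstrap) derives an independent stream from
(seed, step-name) via a hashed spawn key, so adding or reordering steps
never perturbs another step's draws, and a fixed config reproduces every
number exactly.

## Pooled descriptives

Pooling all trials of a group treats trials as independent, which the
per-fly analyses contradict; everything pooled is therefore flagged
descriptive and is never used for confirmatory claims. Per group:
pooled proportion with a Wilson score interval (exact 0/1 endpoints at
x = 0 and x = n); across groups: a G×2 Pearson chi-square; per pair: a
pooled-variance two-proportion z-test without continuity correction
(unpooled variance by switch) and a MOVER-W interval that recombines the
two Wilson intervals in quadrature around the point difference.

## Robustness screens

A single-pass outlier screen flags flies whose LCP sits more than k = 3
MADs (raw MAD units by default; MADn by switch, which widens the
threshold 1.4826×) from their group median; a group with MAD = 0 is
degenerate and flags nothing. Balance diagnostics are descriptive: a
group × lane contingency chi-square on retained flies and the pooled
toward-rate split by which side was lit, each with Wilson intervals.
They verify the randomized design, not a causal model.

## Synthetic cohorts

The generator draws, per fly, a latent choice probability
p_i ~ Beta(μ(1−ρ)/ρ, (1−μ)(1−ρ)/ρ), so E p_i = μ and the intraclass
correlation is ρ (ρ = 0 degenerates to every fly sharing p = μ). Trials
are then independent coins at p_i with a fair-coin lit side; a
Bernoulli(dropout) subset of flies stops at a Uniform{1..39} trial
count, exercising the completion filter. The variance of the per-fly
proportion over m trials is μ(1−μ)[ρ + (1−ρ)/m], which the moment tests
verify.

The study-like preset uses four arms sized 308/318/307/330 before
dropout (≈301/310/301/321 after), mean LCPs 0.73/0.73/0.65/0.52, 40
trials per fly, and per-arm ICCs 0.100/0.100/0.079/0.109. The ICCs are
a calibration, chosen once by simulation so that expected group MADn
levels on the index scale are ≈0.31 for the first three arms and ≈0.39
for the escitalopram-like arm — a dispersion excess of ≈0.074
concentrated in the SSRI arm.

What the generator does *not* emulate: serial dependence or learning
across a fly's 40 trials, lane- or time-of-day effects (lit side and
lane are uniform), and any shape feature of the real phenotype
distribution beyond its mean and ICC. Two consequences are worth
knowing. First, a beta-tailed population puts a few percent of flies
beyond 3 raw MADs, so the outlier screen flags a handful of synthetic
flies per cohort even though nothing is wrong — on light-tailed real
data it can flag none. Second, the phototaxis index lives on a 41-point
lattice (spacing 0.05), so a group's sample MADn takes a handful of
atomic values ≈0.037 apart. Under the beta-binomial the population
deviation-CDF crossing always sits within sampling distance of an atom
boundary at n ≈ 300, so sample MADn hops between atoms; permutation
nulls of MADn statistics carry large tie mass (making those tests
conservative on lattice data), and bootstrap intervals for MADn inherit
the well-known inconsistency of quantile-type statistics on discrete
data — their realized coverage oscillates around the nominal level as
parameters move crossings between atoms. Passing tests on synthetic
cohorts therefore validate the machinery and its calibration under the
stated model, not the tail behavior of real flies.

## Degenerate inputs and tie-breaks

Medians of even-length samples are midpoints (stated because MAD
iterates the median). All-equal pooled values give a tie-correction
factor of 0 and H is reported as 0 with a degeneracy flag. A pooled
proportion of 0 or 1 makes the two-proportion z undefined; p is reported
as 1 with a flag. A fly logging more than the scheduled trial count is a
data error, never truncated; trial-index gaps simply yield an incomplete
fly, excluded by the completion filter.

## Problem sizes

Defaults mirror the study: 10,000 permutations and 10,000 bootstrap
resamples. The test suite's simulation studies use 500 null cohorts of
4×60 flies at B=1,000 for type-I calibration, 100 cohorts of 4×300
flies at B=2,000 for power, and 1,000 cohorts of 300 flies at B=1,000
for bootstrap coverage; these sizes give binomial Monte-Carlo error
around one percentage point on the estimated rates while keeping the
suite quick.
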