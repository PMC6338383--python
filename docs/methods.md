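# Methods

## Problem and data model

The package analyses cohorts of participants described by 18 binary DSM ADHD
symptom indicators — nine inattentive (IA) and nine hyperactive/impulsive
(HI) — a group label (ADHD vs control), and optional continuous or binary
outcome columns at baseline and/or follow-up.  Presentations ("subtypes")
follow the DSM count rule: predominantly inattentive (IA ≥ 6, HI < 6),
predominantly hyperactive/impulsive (HI ≥ 6, IA < 6), combined (both ≥ 6).
Subtype is always derived from the profile, never read from a file.  Control
rows that meet a domain threshold raise a validation *warning*, not an
error, mirroring screening workflows where such participants are flagged and
usually excluded rather than silently dropped.

## Configural frequency

All counting uses exact integer arithmetic (`math.comb`); no floating-point
factorials.  For the default 9+9 rule with threshold 6:

- single presentation: `[Σ_{k=6..9} C(9,k)] · [Σ_{j=0..5} C(9,j)] = 130 · 382
  = 49,660`;
- combined: `130² = 16,900`;
- any diagnosis: `2 · 49,660 + 16,900 = 116,220`.

"Qualifying for a diagnosis" means meeting the count rule in at least one
domain; impairment, pervasiveness and onset criteria are outside the
combinatorial model.  A rule whose threshold exceeds the domain size is
permitted and yields zero counts (the rule is simply unattainable) rather
than an error, so threshold sweeps are total.  Every closed-form count is
cross-checked in tests against brute-force enumeration of all 2¹⁸ profiles.
The observed census reports exact pattern frequencies, the number and
proportion of patterns carried by exactly one participant, and all modal
patterns (ties sorted lexicographically for determinism).

## Association networks

Binary items make the pairwise Pearson correlation the phi coefficient; the
matrix is computed pairwise-complete over missing outcomes (symptom data
must be complete).  Zero-variance items are kept as nodes, flagged
degenerate, with φ = 0 and p = 1 — dropping them would change the network's
node set between groups.

The per-edge test is the chi-square test of independence, `χ² = n φ²` with
1 df and no continuity correction (equivalent to Pearson's chi-square on the
2×2 table); the source analyses name only "family-wise error p < .05 using
Hochberg's procedure", and this is the standard significance test for φ.
The Hochberg family is all k(k−1)/2 = 153 node pairs, including degenerate
ones — the family is the full correlation matrix, not the post-hoc nonzero
edges.  Thresholding zeroes edges with adjusted p ≥ α and leaves surviving
weights untouched; because raw p-values are preserved, the operation is
idempotent.  Negative edges are retained with sign in the network; all
*metrics* use |w|.  The Fruchterman–Reingold layout (networkx
`spring_layout`, seeded) is visualization plumbing only.

## Graph metrics

Conventions, recorded in the centrality table's metadata:

- distance transform `1/|w|` (the convention of the network-psychometrics
  tooling this field uses), not `−log|w|`;
- betweenness: fractional credit across tied shortest paths, unnormalized;
- closeness: `(r−1)/Σd` over the r−1 reachable nodes — equal to the textbook
  `(n−1)/Σd` on connected graphs, well-defined on thresholded toys, 0 for
  isolated nodes;
- Zhang–Horvath clustering on weights normalized by the network maximum;
  reduces exactly to the classical clustering coefficient on {0,1} weights;
  0 when the denominator vanishes.

Dijkstra shortest paths and betweenness are delegated to networkx;
closeness and Zhang–Horvath clustering are computed in-package because the
conventions above are not library defaults.  All five quantities are tested
against exhaustive simple-path/triple-loop oracles on hundreds of random
weighted graphs of ≤ 6 nodes (tolerance 1e−9).

## Scores and outcome statistics

Weighted scores multiply each endorsed symptom by its node strength (or
clustering coefficient) from the ADHD-group *unthresholded* network by
default — the outcome question concerns individuals with ADHD, and the
unthresholded network preserves all pairwise information; both choices are
configurable and recorded with the scores.  Weights are used raw, not
rescaled to sum to 18: only participant ordering feeds the rank statistics.

Kendall's tau is the tau-b (tie-corrected) variant, since symptom counts are
heavily tied integers.  Intervals are non-parametric bootstrap (cases
resampled, default B = 2,000, 95% BCa): bias correction z₀ from the share of
bootstrap replicates below the estimate, acceleration from jackknife
skewness.  With z₀ = a = 0 the endpoints reduce exactly to the percentile
interval; an unbounded z₀ (statistic constant across resamples) falls back
to the percentile interval with a warning, and degenerate data yield a point
interval.  Correlation differences use the paired bootstrap of
τ(a, outcome) − τ(b, outcome) over jointly resampled participants; a
monotone transform of a score changes no resample's tau, so the difference
is identically zero there.  Cohen's d for binary outcomes uses the
df-weighted pooled SD; its sign convention defaults to
(outcome-absent − outcome-present), so a higher score in affected
participants gives negative d, and is configurable and logged because the
direction is a coding choice, not a mathematical one.  P-values are
two-sided, reported to 3 decimals, with no multiplicity adjustment across
outcomes.  A convenience power helper reports the detectable correlation
`r = tanh((z_{1−α/2} + z_power)/√(n−3))`.

## Synthetic cohorts

A two-correlated-trait probit item model: participant traits
(θ_IA, θ_HI) ~ bivariate normal with correlation ρ = 0.5, means 0 for
controls and δ = 2.0 SD for the ADHD group; symptom i is endorsed when
λ_i θ_domain(i) + ε_i > τ_i with ε_i ~ N(0,1) and λ_i = 0.9.  This is the
simplest mechanism producing the two signatures the analysis assumes: every
item endorsed more often under ADHD, and stronger within- than
between-domain phi coefficients.  An Ising-type generator would be a
plausible alternative but is not needed for those signatures.

Thresholds are probit-calibrated,
`τ = λm − √(λ²+1)·Φ⁻¹(p_target)`, to control-group endorsement targets
graded within each domain (distract .20 ≥ listen .18 ≥ org .16 ≥ … ≥ loses
.06 for IA; interrupt .25 easiest down to fidget .04 hardest for HI).  The
targets were chosen once so control mean symptom counts land near one per
domain, the regime community screening samples show, with the most/least
endorsed items in the positions community endorsement profiles report.
Default group sizes are 146 ADHD / 209 controls.  Outcomes: continuous
severity = 0.15·count + N(0, 2²) at each timepoint (modest rank correlations
of ~0.1–0.3 with the count, the magnitude clinical outcome tables show), and
a binary comorbidity via logit p = −3 + 0.25·count (≈ 50% prevalence at high
counts, a few percent at low).  Controls are *not* truncated below the
diagnostic threshold by default (a flag enables rejection sampling), so the
validation-warning path stays exercisable.

What the generator does **not** emulate: informant disagreement, item-level
residual correlations beyond the two-factor structure, longitudinal symptom
dynamics, floor/ceiling effects in outcome instruments, and the
ascertainment step that selects screened cases.  Passing tests therefore
show the pipeline's statistical machinery is correct under the assumed
two-factor binary-item world, not that real cohorts satisfy that world.

## Problem sizes and numerics

The test suite and examples run cohorts at the default 355 participants,
graph oracles at ≤ 6 nodes × 200 graphs, and bootstrap coverage at 500
replicates × B = 2,000 at n = 150 — sizes at which every oracle is exact or
its Monte-Carlo error is far below the asserted bands.  Floating-point path
ties in betweenness are resolved with tolerance 1e−10 in the brute-force
oracle; phi is clipped to [−1, 1] after symmetrization; tables are written
with 12 significant digits so text round-trips preserve comparisons at
1e−12.  All randomness flows through `numpy.random.default_rng` seeds
carried in the configuration objects and manifests.

## Known limitations

- Partial-correlation ("concentration") and regularized (graphical-lasso)
  networks, edge-stability and centrality-stability bootstraps are out of
  scope.
- The census and threshold analyses reproduce published dataset-bound
  numbers only when that dataset is supplied; the shipped tests use
  constructed cohorts whose right answers are known exactly.
- BCa intervals with very discrete statistics (tau at small n) can be
  slightly conservative or anti-conservative; the coverage test bounds this
  empirically (90–98% at n = 150).
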