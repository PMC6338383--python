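# sympnet

Symptom-network analysis of the 18 binary DSM ADHD criteria (9 inattentive +
9 hyperactive/impulsive), for researchers in psychiatric epidemiology and
network psychometrics who want the full pipeline — from diagnostic
combinatorics to outcome prediction — as a tested, scriptable Python library.

## What it computes

Two participants can share a diagnosis and a symptom count yet overlap in no
single symptom.  `sympnet` quantifies that heterogeneity and asks whether the
*position* of a symptom in the association network carries information the
plain count does not:

- **Configural frequency.**  Under the rule "≥ 6 of 9 symptoms in a domain",
  the number of qualifying 18-bit configurations is counted exactly with
  binomial sums, e.g. for the combined presentation
  `[Σ_{k=6..9} C(9,k)]² = 16,900`, and cross-checked by enumerating all
  2¹⁸ = 262,144 profiles.  An observed-pattern census reports how many
  participants carry a unique configuration.
- **Phi-coefficient networks.**  For binary items the zero-order Pearson
  correlation is the phi coefficient,
  `φ = (ad − bc)/√((a+b)(c+d)(a+c)(b+d))` on the pair's 2×2 table.  Edge
  significance uses `χ² = nφ²` (1 df), and family-wise error over all 153
  symptom pairs is controlled with Hochberg's step-up procedure at α = .05;
  thresholding zeroes non-surviving edges without rescaling survivors.
- **Weighted graph metrics.**  Node strength `s_i = Σ_j |w_ij|`, Dijkstra
  shortest paths on lengths `1/|w|`, fractional unnormalized betweenness,
  reachable-fraction closeness, and the Zhang–Horvath weighted clustering
  coefficient `C_i = Σ ŵ_ij ŵ_jk ŵ_ik / ((Σ_j ŵ_ij)² − Σ_j ŵ_ij²)`.
- **Weighted symptom scores and outcomes.**  Per participant: the symptom
  count, and strength- / clustering-weighted sums.  Associations with
  outcomes use Kendall's tau-b (continuous) or Welch's t with Cohen's d
  (binary), all intervals from the non-parametric bootstrap (2,000 resamples,
  95% BCa); differences between correlations use the paired bootstrap.
- **Synthetic cohorts.**  A two-correlated-trait probit item model generates
  cohorts (default 146 ADHD + 209 controls) with group-elevated endorsement
  and block-structured within-domain correlations, so every stage is testable
  without clinical data.

## Worked example

```sh
python examples/simulate_and_network.py
```

```
cohort: {'control': 209, 'ADHD': 146}
ADHD pattern census: 140/146 unique patterns (95.9%), modal pattern frequency 2
ADHD network: 153 nonzero edges, 33 survive FWE p<.05
mean |phi| within inattentive:  0.206
mean |phi| within hyperactive:  0.298
mean |phi| between domains:     0.144
```

Nearly every simulated patient carries a symptom configuration no one else
has; after family-wise-error control a fifth of the edges remain, and
within-domain associations dominate between-domain ones, so the network
separates into its two symptom clusters.  The other examples follow the same
pattern: `configural_counts.py` (the exact configuration census — 116,220
qualifying configurations in total), `centrality_profile.py` (per-symptom
centrality; hyperactive/impulsive symptoms come out stronger and more
clustered), and `weighted_scores_and_outcomes.py`, which prints the
outcome-association battery and ends with

```
tau(strength-weighted) - tau(unweighted) = -0.005, 95% BCa CI [-0.017, +0.009]
```

— weighting symptoms by network centrality leaves the outcome correlation
statistically indistinguishable from the plain count.

A thin CLI wraps the same calls:
`sympnet simulate | census | network | metrics | scores | outcomes | report`,
e.g. `sympnet report --seed 1 --out report/` writes the full tabular bundle
(endorsement frequencies, censuses, edge lists + GraphML, centrality,
scores, associations, manifest).

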