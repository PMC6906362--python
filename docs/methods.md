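# Methods

This note records the statistical models, defaults and conventions the
package implements, the design choices made where the construction was
genuinely open, and what the synthetic cohort does and does not
emulate.

## Outcome labeling

Improvement is Δz = z_entry − z_exit of the BMI-for-age z-score, so a
*decrease* in BMI/A z (the healthy direction in an obesity cohort)
yields a positive Δz. Children with first and last values of all three
biomarkers (insulin, triglycerides, HOMA-IR) are partitioned by
`labs_improved_all`: improvement requires *strict* movement toward the
healthy range in every analyte — zero change counts as "no change or a
worsening". The two Δz distributions are compared with a two-sided
Mann–Whitney U test (SciPy's default exact/asymptotic switching), and
the threshold is the arithmetic mean Δz of the all-improved group.
Classification is IMPV iff Δz ≥ threshold; the boundary tie is
inclusive by convention and tested. Healthy-range bounds are
configuration (clinical standards vary by assay and age); the shipped
defaults (insulin 15 µU/mL, triglycerides 100 mg/dL, HOMA-IR 2.5, all
"lower is healthier") matter only for reporting, since improvement is
judged by direction of change.

## Baseline prevalence model

Per characteristic and group, prevalence θ gets the posterior
Beta(k + a₀, n − k + b₀). A literal "α = number of expressing children"
is improper at k = 0, so the default prior offset is (1, 1);
Jeffreys (0.5, 0.5) is available. At the study group sizes (128/372)
the offset's influence is negligible. P(θ_IMPV > θ_MC) is the definite
integral ∫ f_I F_M dx computed by adaptive quadrature (`scipy.integrate.quad`,
absolute tolerance 1e−9; the closed-form integer-parameter sum and a
10⁶-draw Monte-Carlo estimator serve as independent test oracles).
The flag rule is two-sided at 0.9: probabilities ≤ 0.1 indicate the MC
direction by conservation of probability. A float slack of 1e−9 makes
the complement boundary (1 − 0.9) behave exactly.

Calibration note: for a characteristic with truly equal prevalence the
posterior probability is asymptotically Φ(Z) with Z standard normal, so
the two-sided 90% rule flags nulls at a ~20% rate. The pipeline reports
raw probabilities without multiplicity adjustment, so with 77
characteristics some baseline flags are expected to be noise; the
screening is a discovery filter, not a confirmatory test.

Epidemiological statistics are oriented exposure = expressed, outcome =
IMPV: OR = ad/bc, ARR = a/(a+b) − c/(c+d), PAR% = 100·(overall −
risk_unexposed)/overall. Zero cells get the Haldane–Anscombe +0.5
correction on all four cells, flagged in the output. PAR% is undefined
(named error) when no child is IMPV.

## Stay/Swap screening

Seeds are the characteristics clearing the 90% baseline rule. The
rarity filter reads "five or less times between the two populations" as
the *sum* of the tuple's co-occurrence counts across both groups ≤ 5;
a per-group reading would discard more tuples. Surviving tuples get the
same Beta comparison as the baseline (shared prior configuration), and:

- **Stay** — clears 90% toward the seed's direction;
- **Swap** — clears 90% toward the opposite direction;
- **Discarded (indeterminate)** — probability in (0.1, 0.9), kept
  distinct from rarity so that exports draw exactly the tuples that
  reached the rule.

When two seeds generate the same member set, both rows are reported
and the later one is marked a duplicate. A seed never pairs with
itself. The triad screen is the natural extension — (seed, partner
pair) with the same rarity filter and designation rule; the original
triadic methodology is not spelled out in the available material, so
this extension is an interpretation and is documented as such.

## Co-occurrence networks

Nodes are the characteristics expressed in both groups; including
single-group characteristics would bias the comparison, and the more
plausible reading of a trait seen in only one group is sampling
sparsity, not true absence. Edges join characteristics co-occurring in
at least one child of the group (no weight threshold by default;
configurable), weighted by co-occurrence count / group size. Isolated
shared nodes are retained.

Topological metrics are computed on the unweighted skeleton; only
`edge_weight` and `closeness_vitality` use weights. Conventions:

- `closeness_centrality`: Wasserman–Faust reachable-set scaling (the
  normalized [0, 1] form). The unnormalized distance-sum variant can be
  derived from exports; published tables with closeness means far above
  1 imply an unnormalized variant whose exact scale cannot be fixed
  without the original data.
- `all_pairs_node_connectivity`: a node's value is the mean vertex
  connectivity to every other node (unreachable pairs contribute 0) —
  a single node-level number requires an aggregation choice and the
  mean is the least arbitrary.
- `closeness_vitality`: weighted Wiener-index drop on node removal,
  with the Wiener index restricted to reachable pairs so the value
  stays finite at cut vertices (the usual definition returns −∞
  there). Values can be slightly negative when removing a hub
  lengthens many remaining paths.
- `number_of_cliques` / `node_clique_number`: count and maximum size of
  *maximal* cliques containing the node; an isolated node is its own
  maximal clique of size 1.
- `effective_size` / `constraint`: Burt's measures on the skeleton;
  isolated nodes get 0 (the raw definitions are undefined there).
- Edge-valued metrics (`edge_betweenness_centrality`, `edge_load`,
  `edge_weight`) are compared as per-edge distributions by default;
  per-node incident means are also available
  (`edge_metric_node_means`) since a "node-level" reading of an edge
  metric is ambiguous.
- `edge_load` follows the source-summed shortest-path load convention
  of its reference implementation (each directed edge is seeded with
  one unit per source; back-propagated load splits equally over
  shortest-path predecessors).

All 16 metrics are verified against independent brute-force
enumerations (Floyd–Warshall distances, exhaustive path/clique/subset
enumeration, literal textbook formulas) on random graphs of ≤ 8 nodes
and closed forms on K₅, P₃ and K₁,₄.

## BEST with gamma priors

Each group's metric values get a Student-t likelihood with its own
location μ_g and scale σ_g and a shared normality parameter ν. The
heavy-tailed likelihood is retained from the standard BEST construction;
what changes is the priors: because structural metrics are
non-negative, μ_g and σ_g get gamma priors whose means equal the pooled
sample mean and pooled SD respectively, with a coefficient of variation
of 2 (shape 0.25 — weakly informative). ν − 1 ~ Exponential(mean 29),
the customary shifted-exponential prior. An optional common shift is
applied when a metric distribution dips below zero (possible for the
finite-pair closeness vitality); the location *difference* is
shift-invariant and the shift is recorded.

Sampling is an affine-invariant ensemble MCMC (emcee, 16 walkers) in
log-parameter space with prior-density Jacobians, burn-in 1,000 and
10,000 retained iterations per walker by default, seeded for bit-level
determinism. Reported quantities: posterior means of μ_IMPV and μ_MC
(sample means are also emitted — for skewed data the t location tracks
the bulk, not the mean), the 90% highest-density interval of
μ_IMPV − μ_MC (positive = larger in IMPV), the posterior probability of
a positive difference, bulk ESS and split-chain R-hat (each walker
chain split in half). The HDI is the shortest contiguous interval
containing ⌈0.9·n⌉ sorted draws. Degenerate input (both groups constant
and equal) short-circuits to a zero-width posterior with a warning.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes,
with defaults fixed at the study conditions:

- **Groups**: 128 IMPV / 372 MC; sex 64% / 47% male; ages ~
  N(6.07, 2.24) and N(7.04, 2.24) years.
- **Characteristics**: 28 child + 49 guardian. Background prevalences
  cycle through {0.02, 0.03, 0.05, 0.08} — sparse traits typical of
  first-assessment records. Three characteristics at (0.40, 0.10) and
  three at (0.10, 0.40) are strong baseline signals; two at
  (0.25, 0.25) are designed nulls.
- **Planted dyads** via the 2×2 cell construction (cells q, p_i − q,
  p_j − q, 1 − p_i − p_j + q), which matches the stated marginals and
  joint exactly in expectation and fails loudly on Fréchet-bound
  violations. One stay dyad (joint 0.30/0.03 on IMPV-leaning members)
  and one swap dyad (members marginally IMPV-leaning, joint 0.01/0.10
  leaning MC).
- **Latent classes** drive within-group co-occurrence: the IMPV group
  mixes two broad communities, the MC group three smaller, tighter ones
  over the same 14 characteristics. Class-conditional prevalences are
  solved so the mixture marginal is 0.175 in *both* groups — the
  classes shape clustering, not baseline signals. Planted-dyad members
  are excluded from class overrides so their marginals stay exact.
- **Labs**: a random subset of 150 children carries a biomarker panel.
  Δz ~ N(1.1, 0.25) for IMPV and N(0.2, 0.25) for MC; the probability
  that all three labs improve is 0.85 above the generating threshold
  0.747 and 0.07 below it. Improved panels strictly decrease every
  analyte; non-improved panels force at least one analyte flat or
  worse. Baseline lab values are log-normal around typical elevated
  pediatric levels.

Ground truth (mixture-target and realized prevalences, planted joint
counts, class assignments, lab-improvement status) is recounted against
the emitted cohort on every generation.

What the generator does **not** emulate: real trait-trait correlation
beyond the planted pairs and latent classes; assessor effects;
missingness mechanisms; any fit to the real per-characteristic
marginals (unpublished). Passing recovery tests therefore shows the
*method* detects the structure it targets at realistic sizes, not that
real cohorts contain such structure. One consequence of the lab model:
the derived threshold on the default cohort exceeds the generating
0.747, because lab improvement concentrates among strongly improving
children and the threshold is the mean Δz of that subset — the derived
threshold is an estimator of a latent boundary, not of the generating
constant. A dedicated generator (`threshold_recovery_cohort`) draws
improvement status first and Δz | status ~ N(0.747, 0.2), under which
the derivation recovers 0.747 within ±0.05 on average.

## Numerical and procedural choices

- Sex-confound control: Fisher's exact test (two-sided) per
  characteristic on the expressed × sex table, α = 0.05 by default
  (both unstated in the source material; exact tests suit the small
  cells of 77 sparse traits). Zero-expression characteristics are
  retained with p = 1 and a warning.
- Quadrature is the primary route for the Beta comparison; the
  integer-parameter closed form appears only as a test oracle, keeping
  non-integer priors uniform.
- All randomness flows from explicit integer seeds (one generator per
  scenario; per-metric BEST seeds derived via `SeedSequence`). The
  pipeline manifest contains no timestamps, so reruns are
  byte-identical; per-stage timings go to a sidecar file.
- Problem sizes in the shipped tests: 100 seeded replicates for the
  baseline and dyad recovery studies, 500 for the rank-sum type-I
  study, 50 random graphs for the metric oracles, 20 seeded fits for
  the BEST calibration study at the default 1,000/10,000 schedule.

## Known limitations

- No multiple-testing control anywhere (deliberate: the source
  procedure reports raw probabilities); see the calibration note above.
- The triad screen is an interpretation, not a documented procedure.
- Closeness centrality's published scale cannot be reproduced without
  the original data; both variants are emitted.
- BEST location estimates are bulk (median-like) summaries under skewed
  metric distributions; sample means are reported alongside.
- The synthetic cohort is a study-condition emulator, not a calibrated
  model of any real clinical population.
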