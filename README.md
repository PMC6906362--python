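# psynet

Interactions among co-occurring binary psychological characteristics and
their association with the outcome of a pediatric nutritional
intervention.

Univariate associations between single psychological traits (a child's
loneliness, a guardian's lack of authority, ...) and intervention
outcomes are often inconclusive. `psynet` implements an analysis that
moves past the univariate view: it screens *pairs and triples* of
co-occurring characteristics for outcome associations that confirm or
reverse the members' individual tendencies, and compares the structure
of per-outcome co-occurrence networks. It is aimed at biostatisticians
and epidemiologists working with cohorts of children scored on sparse
binary trait catalogs alongside anthropometric and laboratory outcome
data. Because such clinical data are private, the package ships a
synthetic-cohort generator with known ground truth, so every stage is
testable end to end.

## The analysis

**Outcome labeling.** Improvement is measured as the BMI-for-age
z-score change Δz = z_entry − z_exit (positive = improvement). Children
with a complete biomarker panel (insulin, triglycerides, HOMA-IR,
first and last values) are split by whether all three labs moved
strictly toward their healthy ranges; the two Δz distributions are
compared with a two-sided Mann–Whitney U test, and the improvement
threshold is the mean Δz of the all-three-improved group. A child is
labeled IMPV (substantially improved) when Δz ≥ threshold, MC (minimal
change) otherwise.

**Baseline prevalence.** For each characteristic and outcome group the
prevalence gets a Beta posterior, Beta(k + a₀, n − k + b₀) with a
proper prior offset (default a₀ = b₀ = 1). The probability that the
IMPV prevalence exceeds the MC prevalence is

    P(θ_I > θ_M) = ∫₀¹ f_I(x) F_M(x) dx,

evaluated by adaptive quadrature. Probabilities ≥ 0.9 (or ≤ 0.1, the MC
direction by conservation of probability) flag the characteristic.
Odds ratio, absolute risk reduction and population attributable risk
percent are attached per characteristic (exposure = expressed, outcome
= IMPV; Haldane–Anscombe +0.5 correction on zero cells).

**Stay/Swap screening.** Characteristics clearing the 90% rule are
*seed variables*. Each (seed, partner) dyad — and (seed, partner,
partner) triad — is treated as a single entity: a child expresses the
tuple when expressing all members. Tuples occurring five or fewer times
across both groups are discarded (rarity). A surviving tuple that
clears 90% toward the seed's own direction is a **Stay**; toward the
opposite direction, a **Swap** — the signature of an interaction that
reverses the marginal association.

**Network effect.** Over the characteristics expressed in *both*
groups, a per-outcome undirected graph is built: an edge joins two
characteristics co-occurring in at least one child of the group,
weighted by the proportion of the group expressing both. Sixteen
node-level structural metrics (degree/closeness/betweenness
centralities, clique counts, triangles, clustering, square clustering,
node connectivity, closeness vitality, edge load, Burt's effective size
and constraint, edge weight, ...) are computed per network, and each
metric's two distributions are compared with BEST (Bayesian estimation
supersedes the t-test) adapted with gamma priors — structural metrics
are non-negative — reporting the posterior group means and the 90%
highest-density interval of the IMPV − MC difference. An HDI spanning 0
means no credible difference, itself an informative result.

## Worked example

```bash
psynet run-all --seed 1 --out out/
```

runs the whole pipeline on the built-in synthetic scenario (128 IMPV /
372 MC children, 28 child + 49 guardian characteristics, planted stay
and swap dyads) and prints the manifest summary. The stage results land
in `out/` as CSV/JSON/GraphML; with seed 1 the manifest records, among
other things:

```
sex_filter   n_removed=4  n_retained=73
label        threshold=1.157  n_impv=59  n_mc=441
baseline     n_characteristics=73  n_flagged=21
dyads        Stay=152  Swap=7  Discarded=1353
network      n_shared=68
best         n_metrics=16  n_hdi_excluding_zero=14
```

Reading: 4 characteristics were dropped for association with child sex;
the lab-anchored threshold derived from this cohort's biomarker subset
was a z-score reduction of 1.157, labeling 59 children IMPV; 21
characteristics cleared the 90% baseline rule and seeded the dyad
screen, which designated 152 stays and 7 swaps (the planted swap pair
among them); the two networks over the 68 shared characteristics
differed credibly (90% HDI excluding 0) on 14 of the 16 structural
metrics.

Equivalent library code:

```python
from psynet import (default_scenario, generate_cohort, baseline_scan,
                    dyad_scan)

cohort, truth = generate_cohort(default_scenario(rng_seed=1))
results, flagged = baseline_scan(cohort)          # Beta posteriors, 90% rule
dyads = dyad_scan(cohort, results)                # Stay/Swap designations
```

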