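# Methods

## Model

Two population layers live on a shared lattice of 100 × 100 km demes with a
binary land/sea mask; population sizes are measured in *gene copies*
(2 per diploid individual) and stored as continuous reals, while every
migrant or admixture flow is an integer count. Per generation (25 years)
and per layer the update order is fixed:

1. **Decline.** If the generation lies in `[222, e_DD)` and the layer is a
   decline target, its carrying capacity is multiplied by `(1 − s_DD)`; at
   the onset generation N is also truncated to the reduced K (a persistent
   "population decline", not merely a slow decay; the alternative —
   letting logistic dynamics erode N — is switchable via
   `ScenarioConfig(truncate_at_onset=False)`).
2. **Logistic growth** `N ← max(N·(1 + r·(1 − D/K)), 0)` with `D = N`, or
   `D = N_F + N_P` when Lotka–Volterra competition is on (interlayer
   coefficients fixed at 1; each layer keeps its own K in the shared term).
3. **Admixture** ("assimilation"): where both layers are present,
   `T = round(γ·N_F·N_P/(N_F+N_P))` gene copies are exchanged in *each*
   direction, capped at the smaller pool. Because the two directed
   transfers are equal, admixture swaps identities without changing either
   layer's size.
4. **Short-range migration.** `round(m·N)` emigrants (capped at `⌊N⌋` so a
   nearly-empty deme cannot overdraw), split equally among the deme's land
   neighbours (4-neighbourhood); integer remainders go to random distinct
   neighbours. Demes without land neighbours keep their migrants.
5. **Long-distance dispersal.** Each emigrant independently becomes an LDD
   migrant with probability `ldd_rate` (binomial per deme). A jump draws a
   uniform direction and a Gamma(shape 1.209, rate 0.15046 per deme)
   distance and lands in the deme containing the endpoint; landings on
   water or off-map are redrawn up to 20 times, then fall back to a random
   land neighbour. Destinations may be empty or occupied.

The farmer layer is seeded at its source deme with `N = K_F` at
generation 0; the pastoralist layer with `N = K_P` at generation 176.
Seeding precedes the generation's own update, so the onset generation
already moves migrants once.

Numerical note on the LDD kernel: the lattice-offset law of one jump
(direction, gamma distance, rounding to the nearest deme on both axes) is
precomputed once by midpoint quadrature of the landing density
`f_R(r)/(2πr)` over each unit cell (15×15 points within Chebyshev radius 2
of the origin, 3×3 to radius 12, 1 beyond; offsets to 100 demes; the null
offset is excluded, which is equivalent to redrawing same-deme landings).
Events then sample this table by the alias method inside a JIT-compiled
loop (inline xorshift128+ seeded from the caller's generator); a pure-numpy
`searchsorted` path with the identical law is used when numba is absent.
A test checks the table against direct Monte-Carlo draws of the continuous
kernel. With the rate reading of 0.15046 the mean jump is α/β ≈ 8.04 demes
≈ 800 km; the published parameter table calls 0.15046 a "scale", but only
the rate reading is consistent with the stated scale = 1/rate convention
and the stated 800-km mean, so the rate reading is implemented and the
800-km mean is asserted in the acceptance tests.

## Ancestry

A sampled gene copy is *steppe* if its lineage occupies the pastoralist
layer at that layer's onset. Two routes are implemented and tested against
each other:

- **Serial coalescent** (`trace_lineages`, the primary route): per locus,
  `2·n_genomes` copies per sample are traced backward. Provenance
  probabilities at each generation are proportional to the *recorded*
  integer inflows (stayers, the four directed short-range edges, LDD
  arrivals by source) relative to the deme's post-update pool, so forward
  and backward processes are exactly consistent; admixture is resolved as a
  layer switch with probability `T/N`. Co-located lineages of the same
  locus coalesce with probability `1 − (1 − 1/N)^(k(k−1)/2)` per generation
  (sequential pairwise at `1/N` per pair; at most one merger per deme per
  generation, a negligible truncation at `K ~ 10³–10⁴`), using the
  post-update N of the receiving generation. Tracing stops at the onset
  generation: the backward step through it resolves whether a copy belongs
  to the freshly seeded pastoralist source (steppe) or the farmer layer.
  Loci are fully independent coalescents sharing one demography.
- **Forward recursion** (`forward_proportions`): the expected steppe
  fraction of every (layer, deme) pool, propagated deterministically
  through the same flows. It is the exact expectation of the coalescent
  estimate; agreement within 3 Monte-Carlo standard errors at 500 loci on
  toy worlds is an acceptance test.

Flows are recorded from the pastoralist onset onward (earlier generations
are never visited by backward tracing); occupancy-only runs
(`record_flows=False`) serve screening tasks such as the demographic-filter
survey.

## Sampling design

Calibrated dates map to generations as `round((10000 − calBP)/25)`; all 30
printed generation indices of the observed table are reproduced by this
rule. Sampling times are drawn uniformly (integer, inclusive) on each
sample's window once per simulation and shared by that simulation's layer
combinations. The layer-combination space is the Cartesian product over
samples left "free" (2^10 = 1024; 2^6 = 64 with the four unambiguous
samples fixed). The demographic filter keeps a (simulation × combination)
only if every sample's assigned layer holds at least one gene copy in its
deme at its drawn time; per-sample feasibility is computed once and reused
across combinations. The packaged fixed-layer assignment (Esperstedt_MN,
HungaryGamba_CA → farmers; Corded_Ware_LN, Karsdorf_LN → pastoralists) can
be recomputed with `fix_sampling_layers`, which fixes a sample only when
the 99% HDI of its layer-indicator posterior clears 0.5 on the same side in
every compared scenario.

## ABC

Statistics are standardized by median absolute deviation before Euclidean
distances are computed (the 10 statistics share the [0, 1] scale, so the
effect is mild). `abc_posterior` retains the closest `⌈tol·n⌉` rows with
Epanechnikov weights and applies a weighted local-linear regression
adjustment, with bounded parameters adjusted on a logit scale; a
feed-forward-network adjustment (scikit-learn MLP) is available but the
deterministic local-linear form is the default for reproducibility.
Model choice uses rejection proportions within the retained set (optional
multinomial-logistic adjustment); Bayes factors assume equal scenario
priors and carry the verbal scale anecdotal (1–3) / moderate (3–10) /
strong (10–30) / very strong (30–100) / extreme (>100). The goodness-of-fit
p-value compares the observed vector's mean retained distance with the
distribution of the same statistic over held-out simulated rows.
Cross-validation reports a leave-one-out confusion matrix, the probability
of recovery `PR(s) = P(sel = s | gen = s)/P(sel = s)`, and prediction
errors `PE = Σ(θ̃ᵢ − θᵢ)²/Var(θᵢ)` for the weighted mean/median/mode
estimators (as printed; `normalized_pe=True` divides by the replicate
count, the convention under which published PE magnitudes of order 1
arise). Posterior summaries use weighted means/medians, a weighted
Gaussian-KDE mode (Silverman bandwidth), and the shortest interval holding
the target mass as the HDI.

## Priors and defaults

Uniform priors, applied to both layers independently where per-layer:
growth rate r ∈ [0.53, 0.70]; carrying capacity K ∈ [1000, 10000] gene
copies per deme; emigration rate m ∈ [0.40, 0.80]; admixture rate
γ ∈ [0, 0.03] per generation; LDD proportion ∈ [0, 0.05]; decline end
e_DD ∈ [230, 315] generations; decline strength s_DD ∈ [0.50, 0.80].
Derived migrant numbers Nm = K·m range over [400, 8000]. Structural
constants: decline onset generation 222 (~4,450 BP); pastoralist onset 176
(5,600 BP); 50 loci; 10 samples totalling 34 diploid genomes.

## The synthetic world

The packaged 60 × 50 mask is a deliberately coarse, hand-drawn Europe-like
world (western ocean, northern and Baltic-like seas, Mediterranean basins
with an Anatolian land bridge, a Black Sea, a Caspian-like lake). The
printed sample coordinates map onto it by `floor(coordinate/100 km)`; the
land-path distance from the pastoralist source to the sample demes is 41–48
demes and from the farmer source 42–55 demes, chosen so that the map
reproduces two structural properties of the study area: farmers occupy
Central Europe long before the earliest sampling window, and a short-range
pastoralist front (≤ ~0.7 demes/generation across the priors) cannot reach
the six most ancient samples in time without LDD. Real projections,
coastline accuracy and environmental heterogeneity are out of scope, so all
geography-dependent numbers are approximate; what passing tests show is
that the *mechanisms* (dilution along the expansion axis, the necessity of
LDD, decline signatures) behave as described, not that any particular
coastline detail matters.

`make_toy_world` provides small random connected worlds for oracle tests;
`generate_pseudo_observed` runs the full pipeline at known parameters for
recovery experiments, redrawing sampling times (and periodically the
forward run) until the demographic filter passes.

## Problem sizes and design choices

The pipeline simulates to generation 285 by default (the latest sampling
window closes at 281; later generations cannot influence any statistic);
`ScenarioConfig` itself defaults to the full 400. Desk-scale defaults —
18 prior draws per scenario in the acceptance script, 50 table draws plus
100 replicates in the γ-recovery test, 200 draws in the no-LDD survey, ABC
tolerance 0.05 on tables of a few thousand rows (retaining ~100 rows, the
scale at which the local-linear adjustment is stable) — are the package's
own choices for a single-CPU demonstration. The full design (30,000 draws
per scenario, 100,000-row tables, tolerance 0.01, 100-replicate
cross-validations) is embarrassingly parallel: run `build_simulation_table`
in independent seeded batches per scenario, concatenate, and apply the same
inference functions unchanged. At desk scale model-choice probabilities
fluctuate by several points between seeds; only their coarse ordering is
meaningful.

For recovery experiments the ten samples need concrete layers; the packaged
choice assigns the four optimization-fixed samples their layers and the
remaining six by their observed steppe contribution (≥ 0.4 → pastoralist).

## Known limitations

- The decline is phenomenological (a K reduction), agnostic about cause;
  no pathogen dynamics, sex structure, or environmental heterogeneity.
- No mutation model: the statistics depend only on source-origin
  proportions, so sequence-level simulation is unnecessary.
- The mask is approximate; absolute posterior probabilities inherit that
  approximation even at full scale.
- Occupancies are continuous with integer flows; demes count as occupied at
  ≥ 1 gene copy. Emigration is capped at `⌊N⌋`, which at near-empty demes
  slightly lowers realized emigration relative to `round(m·N)`.
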