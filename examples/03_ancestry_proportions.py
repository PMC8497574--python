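"""Steppe-ancestry proportions: serial coalescent vs forward oracle.

Simulates one parameter draw, then computes each sample's mean steppe
fraction over 50 independent loci by backward lineage tracing, in whichever
layers the demographic filter allows, and compares with the deterministic
forward-proportion recursion (the expectation of the coalescent estimate).
"""

import numpy as np

import steppesim as ss
from steppesim.ancestry import forward_proportions, trace_lineages
from steppesim.demography import ScenarioConfig, run_forward
from steppesim.sampling import draw_sampling_times, layer_feasibility

grid = ss.europe_grid()
obs = ss.load_observed(grid=grid)
rng = np.random.default_rng(7)

scenario = ScenarioConfig.draw(
    rng, decline_targets={"farmer", "pastoralist"},
    gamma_admix=0.01, ldd_rate=0.02, n_generations=285,
)
record = run_forward(scenario, grid, rng=rng)
times = draw_sampling_times(obs.samples, rng)
feas = layer_feasibility(record, obs.samples, times)

dup, layers, dup_t = [], [], []
for i, s in enumerate(obs.samples):
    for L, name in ((0, "farmer"), (1, "pastoralist")):
        if feas[i, L]:
            dup.append(s), layers.append(name), dup_t.append(int(times[i]))

props = trace_lineages(record, dup, n_loci=50, rng=rng, times=dup_t, layers=layers)
phi = forward_proportions(record)

print(f"{'sample':<18}{'gen':>5}{'layer':>13}{'coalescent':>12}{'oracle':>9}{'observed':>10}")
for k, (s, name, t) in enumerate(zip(dup, layers, dup_t)):
    lid = grid.land_id_of(s.deme)
    L = 0 if name == "farmer" else 1
    print(f"{s.name:<18}{t:>5}{name:>13}{props.means()[k]:>12.3f}"
          f"{phi[t, L, lid]:>9.3f}{s.observed_prop:>10.2f}")

print("\nPastoralist-layer samples carry high but westward/time-diluting steppe")
print("fractions; farmer-layer samples acquire steppe ancestry slowly through")
print("admixture - the mechanism that lets one parameter draw reproduce both")
print("the ~0.78 Corded Ware and the ~0 Middle Neolithic observations.")
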