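"""One forward simulation of the two-layer demography.

Runs the farmer and pastoralist layers on the default world under the
"F&P" scenario (demographic decline in both layers after contact), then
prints how each layer's range and size evolve.  The pastoralist expansion
starts at generation 176 (5,600 BP) in the Caucasus-region source and only
reaches Central Europe in time thanks to long-distance dispersal.
"""

import numpy as np

import steppesim as ss
from steppesim.demography import FARMER, PASTORALIST, ScenarioConfig, run_forward

grid = ss.europe_grid()
scenario = ScenarioConfig(
    r_F=0.6, r_P=0.6, K_F=5000, K_P=5000, m_F=0.6, m_P=0.6,
    gamma_admix=0.01, ldd_rate=0.02,
    decline_targets={"farmer", "pastoralist"}, decline_strength=0.65,
    decline_end_gen=272, n_generations=285, seed=1,
)
record = run_forward(scenario, grid, rng=np.random.default_rng(1))

print("gen   farmers(demes)  farmers(copies)  pastoralists(demes)  pastoralists(copies)")
for gen in (50, 120, 176, 185, 200, 222, 240, 260, 285):
    nf = record.N[gen, FARMER]
    np_ = record.N[gen, PASTORALIST]
    print(f"{gen:>4}{(nf >= 1).sum():>12}{nf.sum():>17.0f}"
          f"{(np_ >= 1).sum():>16}{np_.sum():>18.0f}")

print("\nThe farmer layer saturates the map long before the pastoralist onset;")
print("the decline window (generations 222-272 here) cuts both totals by ~65%,")
print("then carrying capacities recover.")
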