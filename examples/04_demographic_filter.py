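"""The demographic filter and why long-distance dispersal is necessary.

Counts, over prior draws with the LDD proportion forced to zero, how often
each population sample's deme is occupied by the pastoralist layer at its
drawn sampling time.  The six most ancient samples are never reachable: a
short-range front starting in the Caucasus region at generation 176 cannot
cross ~4,000 km of land before their sampling windows close.
"""

import steppesim as ss
from steppesim.pipeline import pastoralist_feasibility_survey

grid = ss.europe_grid()
obs = ss.load_observed(grid=grid)

templates = [
    dict(decline_targets=frozenset(), competition_on=False),                      # control
    dict(decline_targets=frozenset({"farmer", "pastoralist"}), competition_on=False),  # F&P
]
survey = pastoralist_feasibility_survey(
    grid, obs.samples, templates, n_sims=50, seed=1, ldd_rate=0.0)

print("pastoralist-layer sampleability with LDD = 0 "
      f"({survey['n_simulations'].iloc[0]} prior draws):")
print(survey["pastoralist_sampleable"].to_string())
print("\nZero counts for the most ancient samples reproduce the demographic-")
print("filter finding: without occasional ~800 km jumps the pastoralist")
print("expansion is too slow to explain when steppe ancestry appears in")
print("Central Europe.")
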