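"""The default world and the observed dataset.

Loads the 60x50 Europe-like deme lattice and the ten Bronze Age population
samples (34 paleogenomes), prints each sample's deme, generation window and
observed steppe-ancestry contribution, and sketches the land mask.
"""

import steppesim as ss

grid = ss.europe_grid()
obs = ss.load_observed(grid=grid)

print(f"World: {grid.n_cols} x {grid.n_rows} demes of 100 km, {grid.n_land} land")
print(f"Samples: {len(obs.samples)} populations, {obs.total_genomes} genomes\n")
print(f"{'sample':<18}{'deme':>10}{'window':>14}{'mean gen':>10}{'steppe':>8}")
for s in obs.samples:
    print(f"{s.name:<18}{f'({s.deme.col},{s.deme.row})':>10}"
          f"{f'{s.earliest_gen}-{s.latest_gen}':>14}{s.mean_gen:>10}"
          f"{s.observed_prop:>8.2f}")

print("\nLand mask ('#' land, '.' water, 'S' sample deme, F/P layer sources):")
marks = {(s.deme.row, s.deme.col): "S" for s in obs.samples}
from steppesim.demography import ScenarioConfig

sc = ScenarioConfig()
marks[(sc.farmer_source.row, sc.farmer_source.col)] = "F"
marks[(sc.pastoralist_source.row, sc.pastoralist_source.col)] = "P"
for r in range(grid.n_rows):
    print("".join(marks.get((r, c), "#" if grid.land_mask[r, c] else ".")
                  for c in range(grid.n_cols)))

# The generation clock: generation 0 is 10,000 BP, one generation = 25 years.
print("\n4450 calBP (decline onset) -> generation", ss.calbp_to_generation(4450))
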