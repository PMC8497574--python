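"""End-to-end simulation pipeline feeding the ABC analyses.

For each scenario template, parameter combinations are drawn from the
priors, the two-layer forward demography is run, sampling times are drawn,
the demographic filter determines which layers each sample can be drawn
from, steppe-ancestry statistics are computed by the serial coalescent for
every feasible (sample, layer) pair, and each surviving layer combination
becomes one row of the simulation table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ancestry import trace_lineages
from .demography import FARMER, PASTORALIST, LAYER_NAMES, ScenarioConfig, run_forward
from .geography import DemeGrid
from .sampling import draw_sampling_times, layer_feasibility
from .inference import SCENARIO_COL

__all__ = [
    "simulate_rows",
    "build_simulation_table",
    "pastoralist_feasibility_survey",
    "layer_bit_cols",
]

#: Forward horizon used by the pipeline: the latest sampling window closes at
#: generation 281, so generations beyond 285 cannot influence any statistic.
PIPELINE_GENERATIONS = 285


def layer_bit_cols(samples) -> list[str]:
    return [f"layer_{s.name}" for s in samples]


def simulate_rows(
    template: dict,
    grid: DemeGrid,
    samples,
    rng: np.random.Generator,
    scenario_name: str = "scenario",
    n_loci: int = 50,
    n_generations: int = PIPELINE_GENERATIONS,
    fixed_params: dict | None = None,
) -> pd.DataFrame:
    """One prior draw → the simulation-table rows it contributes.

    ``template`` supplies ``decline_targets`` and ``competition_on``; all
    other demographic parameters are drawn from the priors (overridable via
    ``fixed_params``).  Returns an empty frame when the demographic filter
    rejects every layer combination.
    """
    scenario = ScenarioConfig.draw(
        rng,
        decline_targets=template.get("decline_targets", frozenset()),
        competition_on=template.get("competition_on", False),
        n_generations=n_generations,
        **(fixed_params or {}),
    )
    record = run_forward(scenario, grid, rng=rng)
    times = draw_sampling_times(samples, rng)
    feas = layer_feasibility(record, samples, times)

    # admissible layers per sample: feasible among its allowed layer(s)
    allowed = []
    for i, s in enumerate(samples):
        if s.layer == "free":
            opts = [L for L in (FARMER, PASTORALIST) if feas[i, L]]
        else:
            L = LAYER_NAMES.index(s.layer)
            opts = [L] if feas[i, L] else []
        if not opts:
            return pd.DataFrame()
        allowed.append(opts)

    # coalescent statistics for every feasible (sample, layer) pair
    dup_samples, dup_layers, dup_times, key = [], [], [], {}
    for i, s in enumerate(samples):
        for L in allowed[i]:
            key[(i, L)] = len(dup_samples)
            dup_samples.append(s)
            dup_layers.append(LAYER_NAMES[L])
            dup_times.append(int(times[i]))
    props = trace_lineages(
        record, dup_samples, n_loci=n_loci, rng=rng, times=dup_times, layers=dup_layers
    )
    means = props.means()

    params = scenario.param_vector()
    combos = [[]]
    for opts in allowed:
        combos = [c + [L] for c in combos for L in opts]
    rows = []
    for combo in combos:
        row = {SCENARIO_COL: scenario_name, **params}
        for i, (s, L) in enumerate(zip(samples, combo)):
            row[f"layer_{s.name}"] = L
            row[f"stat_{s.name}"] = means[key[(i, L)]]
        rows.append(row)
    return pd.DataFrame(rows)


def build_simulation_table(
    suite,
    grid: DemeGrid,
    samples,
    n_sims: int = 100,
    seed: int | None = None,
    n_loci: int = 50,
    n_generations: int = PIPELINE_GENERATIONS,
    max_rows_per_scenario: int | None = None,
    fixed_params: dict | None = None,
) -> pd.DataFrame:
    """Simulation table over a :class:`~steppesim.synthetic.ScenarioSuite`.

    ``n_sims`` parameter draws are simulated per scenario; surviving
    (simulation × layer combination) rows are concatenated, optionally
    subsampled to ``max_rows_per_scenario`` (mirroring the random subset
    drawn when tables grow into the millions).
    """
    ss = np.random.SeedSequence(seed)
    samples = _apply_fixed_layers(samples, getattr(suite, "fixed_layers", {}))
    scenarios = suite.scenarios if hasattr(suite, "scenarios") else dict(suite)
    frames = []
    for name, template in scenarios.items():
        rng = np.random.default_rng(ss.spawn(1)[0])
        parts = []
        for _ in range(n_sims):
            part = simulate_rows(
                template, grid, samples, rng,
                scenario_name=name, n_loci=n_loci,
                n_generations=n_generations, fixed_params=fixed_params,
            )
            if not part.empty:
                parts.append(part)
        if parts:
            df = pd.concat(parts, ignore_index=True)
            if max_rows_per_scenario is not None and len(df) > max_rows_per_scenario:
                pick = rng.choice(len(df), size=max_rows_per_scenario, replace=False)
                df = df.iloc[np.sort(pick)].reset_index(drop=True)
            frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def _apply_fixed_layers(samples, fixed_layers: dict):
    if not fixed_layers:
        return list(samples)
    from dataclasses import replace

    return [
        replace(s, layer=fixed_layers[s.name]) if s.name in fixed_layers else s
        for s in samples
    ]


def pastoralist_feasibility_survey(
    grid: DemeGrid,
    samples,
    templates,
    n_sims: int = 100,
    seed: int | None = None,
    ldd_rate: float = 0.0,
    fixed_params: dict | None = None,
) -> pd.DataFrame:
    """How often each sample is sampleable in the pastoralist layer.

    Runs ``n_sims`` prior draws per template at a fixed LDD proportion
    (default 0: no long-distance dispersal) with occupancy-only forward
    runs, and counts, per sample, the simulations in which the pastoralist
    layer occupies its deme at its drawn sampling time.  With no LDD the
    pastoralist expansion front cannot reach the westernmost demes before
    the most ancient sampling windows close.
    """
    ss = np.random.SeedSequence(seed)
    fixed = dict(fixed_params or {})
    onset = fixed.get("pastoralist_onset_gen",
                      ScenarioConfig.__dataclass_fields__["pastoralist_onset_gen"].default)
    horizon = max(max(s.latest_gen for s in samples), onset) + 1
    fixed.setdefault("n_generations", horizon)
    counts = {s.name: 0 for s in samples}
    total = 0
    for template in (templates if isinstance(templates, (list, tuple)) else [templates]):
        rng = np.random.default_rng(ss.spawn(1)[0])
        for _ in range(n_sims):
            scenario = ScenarioConfig.draw(
                rng,
                decline_targets=template.get("decline_targets", frozenset()),
                competition_on=template.get("competition_on", False),
                ldd_rate=ldd_rate,
                **fixed,
            )
            record = run_forward(scenario, grid, rng=rng, record_flows=False)
            times = draw_sampling_times(samples, rng)
            feas = layer_feasibility(record, samples, times)
            for i, s in enumerate(samples):
                counts[s.name] += int(feas[i, PASTORALIST])
            total += 1
    out = pd.DataFrame(
        {"pastoralist_sampleable": pd.Series(counts), "n_simulations": total}
    )
    out.index.name = "sample"
    return out
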