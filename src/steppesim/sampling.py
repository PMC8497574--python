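"""Sampling design: dates, layers, combinations and the demographic filter.

The observed dataset consists of 10 population samples (34 paleogenomes in
total) with calibrated radiocarbon date windows, projected map coordinates
and estimated steppe-ancestry contributions.  This module converts dates to
simulation generations (25 years each, generation 0 = 10,000 BP), draws
per-simulation sampling times uniformly within each sample's date window,
enumerates the ``2^n`` assignments of samples to population layers, and
applies the *demographic filter*: a simulated parameter combination is only
usable if every sample's assigned layer actually occupies its deme at its
sampling time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .demography import FARMER, PASTORALIST, LAYER_NAMES, DemographyRecord
from .geography import DemeGrid, DemeIndex, coord_to_deme

__all__ = [
    "GENERATION_YEARS",
    "ORIGIN_CALBP",
    "SampleSpec",
    "calbp_to_generation",
    "samples_from_table",
    "draw_sampling_times",
    "enumerate_layer_combinations",
    "layer_feasibility",
    "demographic_filter",
    "fix_sampling_layers",
]

GENERATION_YEARS = 25
ORIGIN_CALBP = 10_000  # generation 0


@dataclass(frozen=True)
class SampleSpec:
    """One population sample's size, dates, location and layer assignment."""

    name: str
    n_genomes: int
    observed_prop: float
    earliest_gen: int
    latest_gen: int
    mean_gen: int
    deme: DemeIndex
    layer: str = "free"  # 'farmer' | 'pastoralist' | 'free'

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if not (self.earliest_gen <= self.mean_gen <= self.latest_gen):
            raise ValueError(
                f"{self.name}: generation window must satisfy earliest <= mean <= latest"
            )
        if not (0.0 <= self.observed_prop <= 1.0):
            raise ValueError("observed steppe proportion must lie in [0, 1]")
        if self.layer not in ("farmer", "pastoralist", "free"):
            raise ValueError(f"unknown layer {self.layer!r}")


def calbp_to_generation(calbp: float) -> int:
    """Convert a calibrated BP date to a generation index.

    Generation 0 is 10,000 BP and one generation spans 25 years, so
    ``gen = round((10000 − calBP) / 25)`` (nearest integer).
    """
    if not (0 <= calbp <= ORIGIN_CALBP):
        raise ValueError(f"calBP date {calbp} outside [0, {ORIGIN_CALBP}]")
    return int(round((ORIGIN_CALBP - calbp) / GENERATION_YEARS))


def samples_from_table(table, grid: DemeGrid, layers=None) -> list[SampleSpec]:
    """Build :class:`SampleSpec` records from the observed-data table.

    ``table`` is a DataFrame with columns ``name, n_genomes, steppe_prop,
    calbp_early, calbp_late, calbp_mean, x_m, y_m``.  Coordinates are mapped
    to the closest land deme of ``grid``; date columns are converted with
    :func:`calbp_to_generation` (note the *early* date is the older one,
    hence the smaller generation index).
    """
    layers = layers or {}
    out = []
    for row in table.itertuples(index=False):
        out.append(
            SampleSpec(
                name=row.name,
                n_genomes=int(row.n_genomes),
                observed_prop=float(row.steppe_prop),
                earliest_gen=calbp_to_generation(row.calbp_early),
                latest_gen=calbp_to_generation(row.calbp_late),
                mean_gen=calbp_to_generation(row.calbp_mean),
                deme=coord_to_deme(row.x_m, row.y_m, grid, name=row.name),
                layer=layers.get(row.name, "free"),
            )
        )
    return out


def draw_sampling_times(samples, rng: np.random.Generator) -> np.ndarray:
    """Integer sampling generation per sample, uniform on its date window.

    Draws are independent across samples and made once per simulation
    (shared by all layer combinations of that simulation).
    """
    return np.array(
        [rng.integers(s.earliest_gen, s.latest_gen + 1) for s in samples], dtype=np.int64
    )


def enumerate_layer_combinations(samples) -> list[tuple[str, ...]]:
    """All per-sample layer assignments: the Cartesian product over free samples.

    Samples with a fixed layer keep it in every combination, so the count is
    ``2^(number of free samples)`` — 1024 for ten free samples, 64 when four
    of the ten are fixed.
    """
    choices = [
        ("farmer", "pastoralist") if s.layer == "free" else (s.layer,) for s in samples
    ]
    return list(itertools.product(*choices))


def layer_feasibility(record: DemographyRecord, samples, times) -> np.ndarray:
    """Boolean ``(n_samples, 2)`` array: is each layer occupied (N ≥ 1 gene
    copy) at each sample's deme and drawn generation?"""
    feas = np.zeros((len(samples), 2), dtype=bool)
    for i, (s, t) in enumerate(zip(samples, times)):
        lid = record.grid.land_id_of(s.deme)
        for L in (FARMER, PASTORALIST):
            feas[i, L] = record.N[int(t), L, lid] >= 1.0
    return feas


def demographic_filter(record: DemographyRecord, samples, combination, times):
    """Keep a (simulation × layer combination) only if fully sampleable.

    Returns ``(keep, feasibility)`` where ``feasibility`` is the per-sample
    per-layer occupancy table from :func:`layer_feasibility` (useful for
    pruning the other combinations of the same simulation cheaply).
    """
    feas = layer_feasibility(record, samples, times)
    keep = all(
        feas[i, LAYER_NAMES.index(lay)] for i, lay in enumerate(combination)
    )
    return keep, feas


def fix_sampling_layers(posteriors, hdi_mass: float = 0.99) -> dict[str, str]:
    """Decide which samples can be fixed to one layer across scenarios.

    ``posteriors`` maps sample name → list of per-scenario posterior draw
    arrays of the binary layer indicator (0 = farmer, 1 = pastoralist),
    optionally weighted as ``(draws, weights)`` tuples.  A sample is fixed
    to the pastoralist layer if the lower bound of the 99% HDI exceeds 0.5
    in *every* scenario, to the farmer layer if the upper bound is below 0.5
    in every scenario, and left free otherwise.
    """
    from .inference import hdi as _hdi

    decisions = {}
    for name, per_scenario in posteriors.items():
        los, his = [], []
        for draws in per_scenario:
            draws, weights = draws if isinstance(draws, tuple) else (draws, None)
            draws = np.asarray(draws, dtype=float)
            if draws.size < 2:
                raise ValueError(f"sample {name!r}: need at least 2 posterior draws")
            lo, hi = _hdi(draws, mass=hdi_mass, weights=weights)
            los.append(lo)
            his.append(hi)
        if min(los) > 0.5:
            decisions[name] = "pastoralist"
        elif max(his) < 0.5:
            decisions[name] = "farmer"
        else:
            decisions[name] = "free"
    return decisions
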