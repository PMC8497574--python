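"""Steppe-ancestry proportions by backward lineage tracing.

A sampled gene copy carries *steppe ancestry* if its lineage, traced
backward through the recorded demography, sits in the pastoralist layer at
that layer's onset generation (i.e. it descends from the pastoralist source
population in the Pontic-steppe region).  Two routes to the same quantity
are provided:

``trace_lineages``
    The stochastic serial coalescent: for each of 50 independent loci,
    ``2 × n_genomes`` gene copies per population sample are traced backward
    generation by generation.  Provenance probabilities are computed from
    the integer migrant/admixture flows recorded during the forward run, so
    the backward process is exactly consistent with the forward one, and
    co-located lineages of the same locus may coalesce.

``forward_proportions``
    A deterministic forward recursion propagating the *expected* steppe
    fraction of every ``(layer, deme)`` pool through the same recorded
    flows.  It is the exact expectation of the coalescent estimate and
    serves as its validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import FARMER, PASTORALIST, LAYER_NAMES, DemographyRecord

__all__ = ["ProportionTable", "trace_lineages", "forward_proportions", "summarize_stats"]

# direction d moves by DIRECTIONS[d]; _OPP[d] is the reverse direction
_OPP = np.array([1, 0, 3, 2])


@dataclass
class ProportionTable:
    """Per-sample × per-locus steppe-ancestry fractions."""

    sample_names: list
    fractions: np.ndarray  # (n_samples, n_loci), values in [0, 1]

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.ndim != 2 or f.shape[0] != len(self.sample_names):
            raise ValueError("fractions must be (n_samples, n_loci)")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        self.fractions = f

    @property
    def n_loci(self) -> int:
        return self.fractions.shape[1]

    def means(self) -> np.ndarray:
        """Per-sample mean over loci (the ABC summary statistics)."""
        return self.fractions.mean(axis=1)

    def to_tsv(self, path) -> None:
        import csv
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["sample"] + [f"locus_{i}" for i in range(self.n_loci)] + ["mean"])
            for name, row, mu in zip(self.sample_names, self.fractions, self.means()):
                w.writerow([name] + [f"{v:.6g}" for v in row] + [f"{mu:.6g}"])


def summarize_stats(props: ProportionTable, expected_samples=None) -> np.ndarray:
    """Per-sample mean steppe fraction over loci, in table order."""
    if expected_samples is not None:
        missing = [s for s in expected_samples if s not in props.sample_names]
        if missing:
            raise ValueError(f"missing samples in proportion table: {missing}")
        order = [props.sample_names.index(s) for s in expected_samples]
        return props.means()[order]
    return props.means()


# ---------------------------------------------------------------------------
# Flow reconstruction shared by both routes
# ---------------------------------------------------------------------------

def _step_flows(record: DemographyRecord, t: int):
    """Reconstruct the per-deme flow decomposition of generation step ``t``.

    Returns ``(in_short, ldd_in, stay, N_g, T)`` where ``in_short[L, d, i]``
    counts migrants arriving at deme ``i`` from its direction-``d``
    neighbour, ``stay`` is the non-emigrating mass of the pre-migration
    pool, and ``N_g`` the pre-migration (post-growth, post-admixture) sizes.
    """
    grid = record.grid
    neigh = grid.neighbor_ids
    n_land = grid.n_land
    so = record.short_out[t].astype(np.float64)       # (2, 4, n_land)
    in_short = np.zeros((2, 4, n_land))
    for d in range(4):
        j = neigh[d]
        ok = j >= 0
        in_short[:, d, ok] = so[:, _OPP[d], j[ok]]
    ldd_in = np.zeros((2, n_land))
    for L in (FARMER, PASTORALIST):
        ev = record.ldd_events.get((t, L))
        if ev is not None:
            src, dst, cnt = ev
            ldd_in[L] = np.bincount(dst, weights=cnt, minlength=n_land)
    E_out = so.sum(axis=1) + record.ldd_out[t]
    N_t = record.N[t].astype(np.float64)
    stay = np.maximum(N_t - in_short.sum(axis=1) - ldd_in, 0.0)
    N_g = stay + E_out
    T = record.admix_T[t].astype(np.float64)
    return in_short, ldd_in, stay, N_g, T


def _require_flows(record: DemographyRecord, gen: int) -> None:
    if record.short_out is None or record.flows_from is None:
        raise ValueError("record was run without flow bookkeeping")
    if gen < record.flows_from:
        raise ValueError(
            f"flows recorded from generation {record.flows_from}, need {gen}"
        )


# ---------------------------------------------------------------------------
# Deterministic forward recursion (the ".prop" analogue)
# ---------------------------------------------------------------------------

def forward_proportions(record: DemographyRecord, upto_gen: int | None = None) -> np.ndarray:
    """Expected steppe fraction of every pool, ``phi[t, layer, land_id]``.

    The pastoralist source pool has fraction 1 at the onset generation and
    every farmer pool fraction 0; each generation a pool's new fraction is
    the inflow-weighted average of its contributing pools (growth preserves
    fractions, admixture and migration mix them).  Entries for generations
    before the onset are 0.
    """
    onset = record.scenario.pastoralist_onset_gen
    _require_flows(record, onset)
    gmax = record.n_generations if upto_gen is None else upto_gen
    grid = record.grid
    n_land = grid.n_land
    phi = np.zeros((gmax + 1, 2, n_land), dtype=np.float64)

    # state just before the onset step: only the freshly seeded source is steppe
    prev = np.zeros((2, n_land))
    prev[PASTORALIST, grid.land_id_of(record.scenario.pastoralist_source)] = 1.0

    for t in range(onset, gmax + 1):
        in_short, ldd_in, stay, N_g, T = _step_flows(record, t)
        # growth preserves fractions; admixture swaps T copies each way
        phi_a = prev.copy()
        for L, other in ((FARMER, PASTORALIST), (PASTORALIST, FARMER)):
            ok = N_g[L] > 0
            phi_a[L, ok] = (
                (N_g[L, ok] - T[ok]) * prev[L, ok] + T[ok] * prev[other, ok]
            ) / N_g[L, ok]
        np.clip(phi_a, 0.0, 1.0, out=phi_a)
        # migration mixes pools by recorded flows
        new = np.zeros((2, n_land))
        N_t = record.N[t].astype(np.float64)
        for L in (FARMER, PASTORALIST):
            num = stay[L] * phi_a[L]
            for d in range(4):
                j = grid.neighbor_ids[d]
                ok = j >= 0
                num[ok] += in_short[L, d, ok] * phi_a[L, j[ok]]
            ev = record.ldd_events.get((t, L))
            if ev is not None:
                src, dst, cnt = ev
                num += np.bincount(dst, weights=cnt * phi_a[L, src], minlength=n_land)
            ok = N_t[L] > 0
            new[L, ok] = num[ok] / N_t[L, ok]
        np.clip(new, 0.0, 1.0, out=new)
        phi[t] = new
        prev = new
    return phi


# ---------------------------------------------------------------------------
# Stochastic serial coalescent
# ---------------------------------------------------------------------------

def trace_lineages(
    record: DemographyRecord,
    samples,
    n_loci: int = 50,
    rng: np.random.Generator | None = None,
    times=None,
    layers=None,
) -> ProportionTable:
    """Trace sampled gene copies backward and score their steppe origin.

    Parameters
    ----------
    samples
        Sequence of :class:`~steppesim.sampling.SampleSpec`; each
        contributes ``2 × n_genomes`` gene copies per locus.
    times, layers
        Per-sample sampling generation and layer, overriding the specs'
        ``mean_gen`` / fixed ``layer`` (layers must be concrete, not
        ``"free"``).

    Every sampled ``(layer, deme, generation)`` must be occupied — the
    demographic filter guarantees this upstream; an unoccupied cell raises.
    """
    rng = np.random.default_rng() if rng is None else rng
    grid = record.grid
    scen = record.scenario
    onset = scen.pastoralist_onset_gen
    n_land = grid.n_land

    times = [s.mean_gen for s in samples] if times is None else list(times)
    layers = [s.layer for s in samples] if layers is None else list(layers)
    lay_idx = []
    for s, L in zip(samples, layers):
        if L not in LAYER_NAMES:
            raise ValueError(f"sample {s.name!r} needs a concrete layer, got {L!r}")
        lay_idx.append(LAYER_NAMES.index(L))

    # build the lineage arrays (all loci traced together; loci only interact
    # through coalescence, which is restricted to same-locus pairs)
    sam_i, loc_i, lay_i, dem_i, t_i = [], [], [], [], []
    for i, s in enumerate(samples):
        lid = grid.land_id_of(s.deme)
        t = int(times[i])
        if t > onset and record.N[t, lay_idx[i], lid] < 1:
            raise ValueError(
                f"sample {s.name!r}: {LAYER_NAMES[lay_idx[i]]} layer unoccupied "
                f"at deme {s.deme} generation {t}"
            )
        ncopies = 2 * s.n_genomes
        for locus in range(n_loci):
            sam_i += [i] * ncopies
            loc_i += [locus] * ncopies
            lay_i += [lay_idx[i]] * ncopies
            dem_i += [lid] * ncopies
            t_i += [t] * ncopies
    sam_i = np.array(sam_i); loc_i = np.array(loc_i)
    layer = np.array(lay_i, dtype=np.int64)
    deme = np.array(dem_i, dtype=np.int64)
    t_arr = np.array(t_i)
    M = layer.size
    parent = np.full(M, -1, dtype=np.int64)
    alive = np.zeros(M, dtype=bool)
    steppe = np.zeros(M, dtype=bool)

    gmax = int(t_arr.max(initial=onset))
    if gmax > onset:
        _require_flows(record, onset)

    for g in range(gmax, onset - 1, -1):
        alive |= t_arr == g
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            continue
        in_short, ldd_in, stay, N_g, T = _step_flows(record, g)

        # 1) provenance: stayed / immigrated along a short edge / LDD arrival
        li, di = layer[idx], deme[idx]
        masses = np.vstack(
            [stay[li, di]]
            + [in_short[li, d, di] for d in range(4)]
            + [ldd_in[li, di]]
        )  # (6, n_active)
        cum = np.cumsum(masses, axis=0)
        tot = cum[-1]
        u = rng.random(idx.size) * np.where(tot > 0, tot, 1.0)
        cat = np.argmax(u[None, :] < cum, axis=0)
        cat[tot <= 0] = 0  # degenerate pools: treat as stayed
        new_deme = di.copy()
        for d in range(4):
            sel = cat == d + 1
            if sel.any():
                new_deme[sel] = grid.neighbor_ids[d, di[sel]]
        ldd_sel = np.nonzero(cat == 5)[0]
        if ldd_sel.size:
            for L in (FARMER, PASTORALIST):
                ev = record.ldd_events.get((g, L))
                if ev is None:
                    continue
                src, dst, cnt = ev
                order = np.argsort(dst, kind="stable")
                dst_s, src_s, cnt_s = dst[order], src[order], cnt[order]
                bounds = np.searchsorted(dst_s, np.arange(n_land + 1))
                for k in ldd_sel:
                    if li[k] != L:
                        continue
                    a, b = bounds[di[k]], bounds[di[k] + 1]
                    w = cnt_s[a:b].astype(float)
                    new_deme[k] = src_s[a + rng.choice(w.size, p=w / w.sum())]
        deme[idx] = new_deme

        # 2) admixture resolution at the pre-migration deme
        li, di = layer[idx], deme[idx]
        denom = N_g[li, di]
        p_switch = np.where(denom > 0, np.minimum(T[di] / np.where(denom > 0, denom, 1.0), 1.0), 0.0)
        flip = rng.random(idx.size) < p_switch
        layer[idx[flip]] = 1 - layer[idx[flip]]

        if g == onset:
            # pre-growth state of the onset step: the pastoralist pool is the
            # freshly seeded source population
            steppe[idx] = layer[idx] == PASTORALIST
            alive[idx] = False
            break

        # 3) coalescence at the receiving generation's post-update pools
        key = (loc_i[idx] * 2 + layer[idx]) * n_land + deme[idx]
        order = np.argsort(key, kind="stable")
        key_s = key[order]
        starts = np.nonzero(np.r_[True, key_s[1:] != key_s[:-1]])[0]
        ends = np.r_[starts[1:], key_s.size]
        for a, b in zip(starts, ends):
            k = b - a
            if k < 2:
                continue
            members = idx[order[a:b]]
            Nprev = float(record.N[g - 1, layer[members[0]], deme[members[0]]])
            npairs = k * (k - 1) / 2
            p_merge = 1.0 - (1.0 - 1.0 / max(Nprev, 1.0)) ** npairs
            if rng.random() < p_merge:
                i1, i2 = rng.choice(k, size=2, replace=False)
                child, keep = members[i1], members[i2]
                parent[child] = keep
                alive[child] = False

    # lineages sampled before the onset can only be of local (farmer) origin;
    # coalesced lineages inherit their surviving partner's label
    roots = np.arange(M)
    while np.any(parent[roots] >= 0):
        has = parent[roots] >= 0
        roots[has] = parent[roots[has]]
    steppe_final = steppe[roots]

    cell = sam_i * n_loci + loc_i
    n_cells = len(samples) * n_loci
    hits = np.bincount(cell, weights=steppe_final.astype(float), minlength=n_cells)
    tot = np.bincount(cell, minlength=n_cells)
    fractions = (hits / tot).reshape(len(samples), n_loci)
    return ProportionTable(sample_names=[s.name for s in samples], fractions=fractions)
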