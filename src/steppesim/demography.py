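"""Forward-in-time demography of the two interacting population layers.

Two superimposed lattices of demes are simulated generation by generation
(25 years each): a *farmer* layer seeded in the south-east of the map at
generation 0 (the onset of the Neolithic, 10,000 BP) and a *pastoralist*
layer seeded in a North-Caucasus-like region at generation 176 (5,600 BP).
Within each layer a deme grows logistically toward its carrying capacity and
exchanges migrants with its four neighbours; a small fraction of emigrants
instead undertake long-distance dispersal (LDD) with a gamma-distributed
distance.  Where both layers occupy the same deme they exchange gene copies
symmetrically at the admixture rate γ ("assimilation": the exchange swaps
identities without changing either layer's size).  Scenarios may impose a
temporary demographic decline — a reduction of carrying capacity by a factor
``s_DD`` from generation 222 until ``e_DD`` — on one or both layers, and may
couple the layers through Lotka–Volterra competition.

Population sizes are measured in *gene copies* (2 per diploid individual)
and kept as continuous reals; migrant and admixture flows are integer counts
so that the backward coalescent can re-use them exactly.

Update order within one generation: carrying-capacity decline → logistic
growth → admixture exchange → short-range migration → long-distance
dispersal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .geography import DemeGrid, DemeIndex

try:  # optional JIT acceleration of the per-event dispersal loop
    from numba import njit as _njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is part of the supported stack
    HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f

        return wrap

__all__ = [
    "FARMER",
    "PASTORALIST",
    "PRIORS",
    "ScenarioConfig",
    "DemographyRecord",
    "logistic_step",
    "admix_exchange",
    "effective_K",
    "migrate_short",
    "migrate_ldd",
    "draw_ldd_distances",
    "run_forward",
]

FARMER, PASTORALIST = 0, 1
LAYER_NAMES = ("farmer", "pastoralist")

#: Uniform prior ranges for the drawn demographic parameters.  Growth (r),
#: carrying capacity (K, gene copies) and emigration rate (m) apply to both
#: layers independently; the admixture rate γ and the LDD proportion are
#: shared; e_DD / s_DD parameterize the demographic decline (end generation
#: and strength as a fraction of K).
PRIORS: dict[str, tuple[float, float]] = {
    "r": (0.53, 0.70),
    "K": (1000.0, 10000.0),
    "m": (0.40, 0.80),
    "gamma": (0.0, 0.03),
    "ldd": (0.0, 0.05),
    "edd": (230.0, 315.0),
    "sdd": (0.50, 0.80),
}

#: Long-distance dispersal kernel: distance in demes ~ Gamma(shape, rate).
#: With shape 1.209 and rate 0.15046 per deme the mean jump is ~8.04 demes,
#: i.e. ~800 km for 100-km demes.
LDD_SHAPE = 1.209
LDD_RATE = 0.15046


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario's demographic parameters.

    All rates must lie within the prior ranges in :data:`PRIORS`; fixed
    structural settings (onset generations, decline start, kernel shape)
    default to the study design and rarely need changing.
    """

    r_F: float = 0.615
    r_P: float = 0.615
    K_F: float = 5000.0
    K_P: float = 5000.0
    m_F: float = 0.6
    m_P: float = 0.6
    ldd_rate: float = 0.0
    ldd_shape: float = LDD_SHAPE
    ldd_rate_param: float = LDD_RATE
    gamma_admix: float = 0.01
    competition_on: bool = False
    decline_targets: frozenset = frozenset()
    decline_start_gen: int = 222
    decline_end_gen: int = 272
    decline_strength: float = 0.65
    farmer_onset_gen: int = 0
    pastoralist_onset_gen: int = 176
    farmer_source: DemeIndex = DemeIndex(30, 40)
    pastoralist_source: DemeIndex = DemeIndex(18, 21)
    n_generations: int = 400
    truncate_at_onset: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "decline_targets", frozenset(self.decline_targets))
        checks = [
            ("r_F", self.r_F, "r"), ("r_P", self.r_P, "r"),
            ("K_F", self.K_F, "K"), ("K_P", self.K_P, "K"),
            ("m_F", self.m_F, "m"), ("m_P", self.m_P, "m"),
            ("gamma_admix", self.gamma_admix, "gamma"),
            ("ldd_rate", self.ldd_rate, "ldd"),
            ("decline_strength", self.decline_strength, "sdd"),
        ]
        for name, val, key in checks:
            lo, hi = PRIORS[key]
            if not (lo <= val <= hi):
                raise ValueError(f"{name}={val} outside prior range [{lo}, {hi}]")
        if self.decline_targets - {"farmer", "pastoralist"}:
            raise ValueError("decline_targets must be a subset of {'farmer','pastoralist'}")
        if not self.decline_start_gen < self.decline_end_gen:
            raise ValueError("decline_start_gen must precede decline_end_gen")
        if not (self.farmer_onset_gen < self.n_generations
                and self.pastoralist_onset_gen < self.n_generations):
            raise ValueError("layer onset generations must precede n_generations")

    @staticmethod
    def draw(
        rng: np.random.Generator,
        decline_targets=frozenset(),
        competition_on: bool = False,
        **fixed,
    ) -> "ScenarioConfig":
        """Draw one parameter combination from the uniform priors.

        ``fixed`` keyword arguments override drawn or structural fields
        (e.g. ``gamma_admix=0.01`` or ``n_generations=285``).
        """
        u = lambda key: rng.uniform(*PRIORS[key])
        params = dict(
            r_F=u("r"), r_P=u("r"), K_F=u("K"), K_P=u("K"),
            m_F=u("m"), m_P=u("m"),
            gamma_admix=u("gamma"), ldd_rate=u("ldd"),
            decline_end_gen=int(round(rng.uniform(*PRIORS["edd"]))),
            decline_strength=u("sdd"),
            decline_targets=frozenset(decline_targets),
            competition_on=competition_on,
        )
        params.update(fixed)
        return ScenarioConfig(**params)

    def param_vector(self) -> dict[str, float]:
        """Drawn parameters as a flat mapping (for simulation tables)."""
        return {
            "r_F": self.r_F, "r_P": self.r_P,
            "K_F": self.K_F, "K_P": self.K_P,
            "m_F": self.m_F, "m_P": self.m_P,
            "gamma": self.gamma_admix, "ldd": self.ldd_rate,
            "edd": float(self.decline_end_gen), "sdd": self.decline_strength,
        }


# ---------------------------------------------------------------------------
# Elementary per-generation operations
# ---------------------------------------------------------------------------

def logistic_step(N, r, K, N_other=0.0, competition_on: bool = False):
    """One generation of logistic growth: ``N · (1 + r·(1 − D/K))``, ≥ 0.

    The density ``D`` regulating growth is ``N`` alone, or ``N + N_other``
    under Lotka–Volterra competition with interlayer coefficient 1 (each
    layer keeps its own carrying capacity in the shared-density term).
    """
    N = np.asarray(N, dtype=float)
    if np.any(np.asarray(K) <= 0):
        raise ValueError("carrying capacity K must be positive")
    D = N + np.asarray(N_other, dtype=float) if competition_on else N
    return np.maximum(N * (1.0 + r * (1.0 - D / K)), 0.0)


def admix_exchange(N_F, N_P, gamma_admix):
    """Symmetric assimilation exchange between cohabiting layers.

    Both directed transfers equal ``γ·N_F·N_P/(N_F+N_P)`` (0 when either
    layer is absent), so the per-deme two-layer sum — indeed each layer's
    size — is unchanged; only gene-copy identities are swapped.
    """
    if not (0.0 <= gamma_admix <= 1.0):
        raise ValueError("admixture rate must lie in [0, 1]")
    N_F = np.asarray(N_F, dtype=float)
    N_P = np.asarray(N_P, dtype=float)
    tot = N_F + N_P
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(tot > 0, gamma_admix * N_F * N_P / np.where(tot > 0, tot, 1.0), 0.0)
    return T, T.copy() if isinstance(T, np.ndarray) else T


def effective_K(K, gen: int, scenario: ScenarioConfig, layer) -> float:
    """Carrying capacity at ``gen`` given the scenario's decline window.

    Within ``[decline_start_gen, decline_end_gen)`` a targeted layer's K is
    multiplied by ``(1 − s_DD)``; outside the window (or for untargeted
    layers, e.g. in the control scenario) K is unchanged.
    """
    name = LAYER_NAMES[layer] if isinstance(layer, (int, np.integer)) else layer
    if (
        name in scenario.decline_targets
        and scenario.decline_start_gen <= gen < scenario.decline_end_gen
    ):
        return K * (1.0 - scenario.decline_strength)
    return K


def _split_short(counts: np.ndarray, grid: DemeGrid, rng: np.random.Generator) -> np.ndarray:
    """Split per-deme integer emigrant counts equally among land neighbours.

    Returns directed out-counts of shape ``(4, n_land)``; integer remainders
    go to distinct neighbours chosen by seeded draw.  Demes without land
    neighbours keep their migrants.
    """
    neigh = grid.neighbor_ids
    k = grid.n_neighbors
    counts = np.where(k > 0, counts, 0)
    out = np.zeros((4, grid.n_land), dtype=np.int64)
    base = np.where(k > 0, counts // np.maximum(k, 1), 0)
    rem = np.where(k > 0, counts % np.maximum(k, 1), 0)
    valid = neigh >= 0
    out += base * valid
    if rem.any():
        # rank the valid directions of every deme in random order; the first
        # `rem` of them receive one extra migrant each
        pri = rng.random((4, grid.n_land))
        pri[~valid] = np.inf
        ranks = np.argsort(np.argsort(pri, axis=0), axis=0)
        out += (ranks < rem) & valid
    return out


def _apply_short(occ: np.ndarray, out: np.ndarray, grid: DemeGrid) -> np.ndarray:
    """Remove directed out-counts from sources and add them at destinations."""
    new = occ - out.sum(axis=0)
    neigh = grid.neighbor_ids
    for d in range(4):
        sel = neigh[d] >= 0
        np.add.at(new, neigh[d, sel], out[d, sel])
    return new


def migrate_short(occupancies, m: float, grid: DemeGrid, rng=None, ldd_share: float = 0.0):
    """Short-range (1-deme) migration for one layer.

    Each deme emits ``round(m · N · (1 − ldd_share))`` migrants, split
    equally among its land neighbours (remainders by seeded draw).  The
    layer's total size is conserved exactly.

    Returns ``(updated occupancies, directed out-counts of shape (4, n_land))``.
    """
    rng = np.random.default_rng() if rng is None else rng
    occ = np.asarray(occupancies, dtype=float)
    counts = _emigrant_counts(occ, m * (1.0 - ldd_share))
    out = _split_short(counts, grid, rng)
    return _apply_short(occ, out, grid), out


def _emigrant_counts(occ: np.ndarray, m: float) -> np.ndarray:
    """Integer emigrants ``round(m·N)``, capped at ``floor(N)`` so a nearly
    empty deme can never emit more gene copies than it holds."""
    return np.minimum(np.round(m * occ), np.floor(occ)).astype(np.int64)


def draw_ldd_distances(rng: np.random.Generator, n: int,
                       shape: float = LDD_SHAPE, rate: float = LDD_RATE) -> np.ndarray:
    """Draw LDD jump distances (in demes) from the gamma kernel."""
    return rng.gamma(shape, 1.0 / rate, size=n)


@lru_cache(maxsize=8)
def _displacement_table(shape: float, rate: float, max_r: int = 100):
    """Discrete law of one LDD jump's lattice offset, tabulated once.

    A jump draws a uniform direction and a gamma distance (in demes) and
    lands in the deme containing the endpoint, i.e. the offset is the
    component-wise nearest-integer rounding of the polar displacement.  The
    exact probability of each offset is the integral of the landing density
    ``f_R(r)/(2πr)`` over the offset's unit cell, evaluated here by midpoint
    quadrature (finer near the origin, where the density is steep).  The
    null offset is excluded — a jump that would stay in its source deme is
    redrawn — and the tail beyond ``max_r`` demes (< 1e-5 mass for the
    default kernel) is folded in by renormalization.
    """
    from scipy.stats import gamma as gamma_dist

    offs = np.arange(-max_r, max_r + 1)
    dc, dr = np.meshgrid(offs, offs, indexing="ij")
    dc, dr = dc.ravel(), dr.ravel()
    rad = np.hypot(dc, dr)
    keep = (rad <= max_r) & ~((dc == 0) & (dr == 0))
    dc, dr = dc[keep], dr[keep]
    dist = gamma_dist(shape, scale=1.0 / rate)

    def cell_mass(cs, rs, sub):
        g = (np.arange(sub) + 0.5) / sub - 0.5
        xx, yy = np.meshgrid(g, g, indexing="ij")
        x = cs[:, None] + xx.ravel()[None, :]
        y = rs[:, None] + yy.ravel()[None, :]
        r = np.hypot(x, y)
        dens = dist.pdf(r) / (2.0 * np.pi * np.maximum(r, 1e-12))
        return dens.mean(axis=1)

    prob = np.empty(dc.size)
    near = np.maximum(np.abs(dc), np.abs(dr)) <= 2
    mid = ~near & (np.maximum(np.abs(dc), np.abs(dr)) <= 12)
    far = ~near & ~mid
    prob[near] = cell_mass(dc[near].astype(float), dr[near].astype(float), 15)
    prob[mid] = cell_mass(dc[mid].astype(float), dr[mid].astype(float), 3)
    prob[far] = cell_mass(dc[far].astype(float), dr[far].astype(float), 1)
    prob = np.maximum(prob, 0.0)
    order = np.argsort(-prob, kind="stable")
    dc, dr, prob = dc[order], dr[order], prob[order]
    nz = prob > 1e-15
    dc, dr, prob = dc[nz], dr[nz], prob[nz]
    cum = np.cumsum(prob / prob.sum())
    cum[-1] = 1.0
    return dc.astype(np.int64), dr.astype(np.int64), cum


def _sample_offsets(rng: np.random.Generator, n: int, shape: float, rate: float):
    dc, dr, cum = _displacement_table(shape, rate)
    idx = np.searchsorted(cum, rng.random(n), side="right")
    return dc[idx], dr[idx]


@lru_cache(maxsize=8)
def _alias_table(shape: float, rate: float):
    """Vose alias tables for O(1) sampling of the displacement law."""
    dc, dr, cum = _displacement_table(shape, rate)
    p = np.diff(np.concatenate([[0.0], cum]))
    K = p.size
    scaled = p * K
    accept = np.ones(K)
    alias = np.arange(K)
    small = [i for i in range(K) if scaled[i] < 1.0]
    large = [i for i in range(K) if scaled[i] >= 1.0]
    while small and large:
        s, l = small.pop(), large.pop()
        accept[s] = scaled[s]
        alias[s] = l
        scaled[l] = scaled[l] + scaled[s] - 1.0
        (small if scaled[l] < 1.0 else large).append(l)
    return (dc.astype(np.int32), dr.astype(np.int32),
            accept.astype(np.float64), alias.astype(np.int32))


@_njit(cache=True)
def _ldd_event_loop(counts, land_cols, land_rows, land_id_dense,
                    dc_tab, dr_tab, accept_tab, alias_tab, neigh_ids,
                    seed, max_redraws):
    """Per-event LDD destinations (JIT loop; mirrors the numpy path).

    Uses an inline xorshift128+ generator (seeded per call via splitmix64)
    for speed; destinations are alias-method draws from the displacement
    table, redrawn on water/off-map landings.
    """
    # splitmix64 initialization of the xorshift128+ state
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    s0 = z ^ (z >> np.uint64(31))
    z = np.uint64(seed) + np.uint64(2) * np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    s1 = z ^ (z >> np.uint64(31))
    inv53 = 1.0 / 9007199254740992.0

    total = int(counts.sum())
    src = np.empty(total, np.int64)
    dst = np.empty(total, np.int64)
    n_rows, n_cols = land_id_dense.shape
    K = accept_tab.size
    k = 0
    for i in range(counts.size):
        c0 = land_cols[i]
        r0 = land_rows[i]
        for _m in range(counts[i]):
            d = -1
            for _t in range(max_redraws):
                t1 = s0
                t0 = s1
                s0 = t0
                t1 ^= t1 << np.uint64(23)
                t1 ^= t1 >> np.uint64(17)
                t1 ^= t0 ^ (t0 >> np.uint64(26))
                s1 = t1
                u = float((t0 + t1) >> np.uint64(11)) * inv53 * K
                lo = int(u)
                if u - lo >= accept_tab[lo]:
                    lo = alias_tab[lo]
                c2 = c0 + dc_tab[lo]
                r2 = r0 + dr_tab[lo]
                if 0 <= c2 < n_cols and 0 <= r2 < n_rows:
                    cand = land_id_dense[r2, c2]
                    if cand >= 0:
                        d = cand
                        break
            if d < 0:
                nvalid = 0
                for dd in range(4):
                    if neigh_ids[dd, i] >= 0:
                        nvalid += 1
                if nvalid == 0:
                    d = i
                else:
                    t1 = s0
                    t0 = s1
                    s0 = t0
                    t1 ^= t1 << np.uint64(23)
                    t1 ^= t1 >> np.uint64(17)
                    t1 ^= t0 ^ (t0 >> np.uint64(26))
                    s1 = t1
                    pick = int(float((t0 + t1) >> np.uint64(11)) * inv53 * nvalid)
                    seen = 0
                    for dd in range(4):
                        if neigh_ids[dd, i] >= 0:
                            if seen == pick:
                                d = neigh_ids[dd, i]
                                break
                            seen += 1
            src[k] = i
            dst[k] = d
            k += 1
    return src, dst


def _disperse_ldd(occ, counts, grid: DemeGrid, rng: np.random.Generator,
                  shape: float, rate: float, max_redraws: int = 20,
                  aggregate: bool = True):
    """Disperse per-deme integer LDD counts; returns (updated occ, src, dst, cnt).

    Each event draws a uniform direction then a gamma distance; landings on
    water, off-map, or in the source deme are redrawn up to ``max_redraws``
    times and then fall back to a short-range move (a random land neighbour,
    or staying home for isolated demes).  Destinations may be empty or
    occupied; migrants join the same layer there.
    """
    total = int(counts.sum())
    new = occ - counts
    if total == 0:
        e = np.empty(0, dtype=np.int64)
        return new, e, e.copy(), e.copy()
    if HAVE_NUMBA:
        dc_tab, dr_tab, accept_tab, alias_tab = _alias_table(shape, rate)
        src, dst = _ldd_event_loop(
            counts.astype(np.int64), grid.land_cols.astype(np.int64),
            grid.land_rows.astype(np.int64), grid.land_id,
            dc_tab, dr_tab, accept_tab, alias_tab, grid.neighbor_ids,
            int(rng.integers(2**32)), max_redraws,
        )
    else:
        src = np.repeat(np.arange(grid.n_land), counts)
        cols = grid.land_cols[src].astype(np.int64)
        rows = grid.land_rows[src].astype(np.int64)
        dst = np.full(total, -1, dtype=np.int64)
        pending = np.arange(total)
        for _ in range(max_redraws):
            if pending.size == 0:
                break
            oc, orr = _sample_offsets(rng, pending.size, shape, rate)
            c2 = cols[pending] + oc
            r2 = rows[pending] + orr
            ok = (c2 >= 0) & (c2 < grid.n_cols) & (r2 >= 0) & (r2 < grid.n_rows)
            cand = np.full(pending.size, -1, dtype=np.int64)
            cand[ok] = grid.land_id[r2[ok], c2[ok]]
            good = cand >= 0
            dst[pending[good]] = cand[good]
            pending = pending[~good]
        if pending.size:
            # fall back to a uniformly chosen land neighbour of the source
            neigh = grid.neighbor_ids[:, src[pending]]      # (4, n_pending)
            pri = rng.random(neigh.shape)
            pri[neigh < 0] = -np.inf
            choice = np.argmax(pri, axis=0)
            fallback = neigh[choice, np.arange(pending.size)]
            dst[pending] = np.where(fallback >= 0, fallback, src[pending])
    new += np.bincount(dst, minlength=grid.n_land)
    if not aggregate:
        e = np.empty(0, dtype=np.int64)
        return new, e, e.copy(), e.copy()
    pair = src * grid.n_land + dst
    uniq, cnt = np.unique(pair, return_counts=True)
    return new, (uniq // grid.n_land), (uniq % grid.n_land), cnt.astype(np.int64)


def migrate_ldd(occupancies, ldd_rate: float, ldd_shape: float, ldd_rate_param: float,
                grid: DemeGrid, rng: np.random.Generator, emigration_rate: float = 1.0):
    """Long-distance dispersal for one layer.

    An ``ldd_rate`` fraction of each deme's ``round(m·N)`` emigrants (drawn
    binomially per emigrant) disperses long-distance.  With ``ldd_rate=0``
    the occupancies are returned unchanged.

    Returns ``(updated occupancies, (src, dst, count) arrays)``.
    """
    if not (0.0 <= ldd_rate <= PRIORS["ldd"][1]):
        raise ValueError(f"ldd_rate must lie in [0, {PRIORS['ldd'][1]}]")
    occ = np.asarray(occupancies, dtype=float)
    emig = _emigrant_counts(occ, emigration_rate)
    counts = rng.binomial(emig, ldd_rate)
    new, src, dst, cnt = _disperse_ldd(occ, counts, grid, rng, ldd_shape, ldd_rate_param)
    return new, (src, dst, cnt)


# ---------------------------------------------------------------------------
# Full forward simulation with bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class DemographyRecord:
    """Everything the backward coalescent needs from one forward run.

    ``N[t, layer, land_id]`` is the occupancy (gene copies) *after* the
    update of generation ``t``; ``N[0]`` is the initial farmer seeding.
    Flow arrays are recorded for generations ``t >= flows_from`` (index
    aligned with ``N``): ``short_out[t, layer, direction, src]`` directed
    short-range migrants, ``ldd_out[t, layer, src]`` total LDD emigrants,
    ``ldd_events[(t, layer)] = (src, dst, count)`` LDD arrivals, and
    ``admix_T[t, land_id]`` the symmetric admixture transfer count.
    """

    grid: DemeGrid
    scenario: ScenarioConfig
    N: np.ndarray
    flows_from: int | None = None
    short_out: np.ndarray | None = None
    ldd_out: np.ndarray | None = None
    admix_T: np.ndarray | None = None
    ldd_events: dict = field(default_factory=dict)

    @property
    def n_generations(self) -> int:
        return self.N.shape[0] - 1

    def occupancy(self, layer, deme: DemeIndex, gen: int) -> float:
        lid = self.grid.land_id_of(deme)
        layer = LAYER_NAMES.index(layer) if isinstance(layer, str) else layer
        return float(self.N[gen, layer, lid])

    def occupancy_grid(self, layer, gen: int) -> np.ndarray:
        """Occupancy as a dense ``(n_rows, n_cols)`` array (NaN on water)."""
        layer = LAYER_NAMES.index(layer) if isinstance(layer, str) else layer
        out = np.full((self.grid.n_rows, self.grid.n_cols), np.nan)
        out[self.grid.land_rows, self.grid.land_cols] = self.N[gen, layer]
        return out

    def total(self, layer, gen: int) -> float:
        layer = LAYER_NAMES.index(layer) if isinstance(layer, str) else layer
        return float(self.N[gen, layer].sum())

    def occupancy_tsv(self, path, gens=None) -> None:
        """Write per-generation layer totals and occupied-deme counts."""
        import csv
        gens = range(self.n_generations + 1) if gens is None else gens
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["generation", "layer", "total_gene_copies", "occupied_demes"])
            for t in gens:
                for L in (FARMER, PASTORALIST):
                    w.writerow([t, LAYER_NAMES[L], f"{self.N[t, L].sum():.1f}",
                                int((self.N[t, L] >= 1).sum())])


def run_forward(
    scenario: ScenarioConfig,
    grid: DemeGrid,
    rng: np.random.Generator | None = None,
    record_flows: bool = True,
    record_flows_from: int | None = None,
) -> DemographyRecord:
    """Run the two-layer forward demography and record its bookkeeping.

    The farmer layer is seeded at ``farmer_source`` with ``N = K_F`` at
    generation 0 and the pastoralist layer at ``pastoralist_source`` with
    ``N = K_P`` at its onset generation.  Per generation the update order is
    decline → growth → admixture → short-range migration → LDD.

    ``record_flows_from`` controls how far back migrant/admixture flows are
    kept (default: the pastoralist onset, the earliest generation backward
    lineage tracing ever visits); pass 0 to keep everything or set
    ``record_flows=False`` for occupancy-only runs (e.g. filter screening).
    """
    for name, src in (("farmer", scenario.farmer_source), ("pastoralist", scenario.pastoralist_source)):
        if not grid.is_land(src):
            raise ValueError(f"{name} source {src} is not a land deme")
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    n_land = grid.n_land
    ngen = scenario.n_generations
    flows_from = (
        None if not record_flows
        else (scenario.pastoralist_onset_gen if record_flows_from is None else record_flows_from)
    )

    N = np.zeros((ngen + 1, 2, n_land), dtype=np.float64)
    short_out = ldd_out = admix_T = None
    ldd_events: dict = {}
    if flows_from is not None:
        short_out = np.zeros((ngen + 1, 2, 4, n_land), dtype=np.int32)
        ldd_out = np.zeros((ngen + 1, 2, n_land), dtype=np.int32)
        admix_T = np.zeros((ngen + 1, n_land), dtype=np.int32)

    cur = np.zeros((2, n_land), dtype=np.float64)
    src_F = grid.land_id_of(scenario.farmer_source)
    src_P = grid.land_id_of(scenario.pastoralist_source)
    cur[FARMER, src_F] = scenario.K_F
    if scenario.pastoralist_onset_gen == 0:
        cur[PASTORALIST, src_P] = scenario.K_P
    N[0] = cur

    r = (scenario.r_F, scenario.r_P)
    K = (scenario.K_F, scenario.K_P)
    m = (scenario.m_F, scenario.m_P)

    for t in range(1, ngen + 1):
        if t == scenario.pastoralist_onset_gen:
            cur[PASTORALIST, src_P] = scenario.K_P
        rec = flows_from is not None and t >= flows_from

        # decline + growth
        for L in (FARMER, PASTORALIST):
            K_eff = effective_K(K[L], t, scenario, L)
            if (
                scenario.truncate_at_onset
                and t == scenario.decline_start_gen
                and LAYER_NAMES[L] in scenario.decline_targets
            ):
                np.minimum(cur[L], K_eff, out=cur[L])
            cur[L] = logistic_step(
                cur[L], r[L], K_eff,
                N_other=cur[1 - L], competition_on=scenario.competition_on,
            )

        # symmetric admixture (identity exchange; sizes unchanged)
        T, _ = admix_exchange(cur[FARMER], cur[PASTORALIST], scenario.gamma_admix)
        T = np.minimum(np.round(T),
                       np.floor(np.minimum(cur[FARMER], cur[PASTORALIST]))).astype(np.int64)
        if rec:
            admix_T[t] = T

        # migration
        for L in (FARMER, PASTORALIST):
            emig = _emigrant_counts(cur[L], m[L])
            n_ldd = rng.binomial(emig, scenario.ldd_rate) if scenario.ldd_rate > 0 else np.zeros_like(emig)
            n_short = emig - n_ldd
            out = _split_short(n_short, grid, rng)
            cur[L] = _apply_short(cur[L], out, grid)
            cur[L], s, d, c = _disperse_ldd(
                cur[L], n_ldd, grid, rng, scenario.ldd_shape, scenario.ldd_rate_param,
                aggregate=rec,
            )
            if rec:
                short_out[t, L] = out
                ldd_out[t, L] = n_ldd
                if s.size:
                    ldd_events[(t, L)] = (
                        s.astype(np.int32), d.astype(np.int32), c.astype(np.int32),
                    )

        np.maximum(cur, 0.0, out=cur)
        N[t] = cur

    return DemographyRecord(
        grid=grid, scenario=scenario, N=N, flows_from=flows_from,
        short_out=short_out, ldd_out=ldd_out, admix_T=admix_T, ldd_events=ldd_events,
    )
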