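"""Forward-time spatially explicit two-wave range-expansion simulator.

A raster world of demes exchanges migrants with 4-neighbours. A first
(hunter-gatherer) wave expands from an origin cell; a second (farming) wave
with its own carrying capacity, growth and migration rates starts later and
absorbs resident demes on contact (full-merger layer interaction). An
optional coastal discontinuity sets the carrying capacity of a cell set to
zero inside a generations-before-present window, after which the cells are
recolonized by migrants from their neighbours.

Demography (deterministic logistic growth + proportional migration) is
independent of genetics; genetics replays the recorded deme sizes and
resamples allele frequencies binomially each generation (drift, no
mutation), so rerunning genetics with a new seed leaves the deme history
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, PairMatrix, SiteTable
from .differentiation import wc_fst
from .ordination import classical_mds, procrustes_protest
from .spatial import bearing_correlogram

#: Demes smaller than this are treated as extinct.
MIN_DEME = 0.5


@dataclass
class LatticeWorld:
    """Rectangular deme lattice with a habitability mask and geo transform.

    Cells are indexed row-major; row 0 is the southern edge. ``cell_deg``
    maps cells to (lat, lon) centroids for the sampled SiteTable.
    """

    n_cols: int
    n_rows: int
    habitable: np.ndarray | None = None  # bool (n_rows, n_cols)
    lat0: float = 50.0
    lon0: float = 3.0
    cell_deg: float = 0.05

    def __post_init__(self) -> None:
        if self.habitable is None:
            self.habitable = np.ones((self.n_rows, self.n_cols), dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def flat(self, col: int, row: int) -> int:
        return row * self.n_cols + col

    def coords_of(self, cells) -> np.ndarray:
        """(lat, lon) centroids of flat cell indices."""
        cells = np.asarray(cells)
        rows, cols = divmod(cells, self.n_cols)
        return np.column_stack(
            [self.lat0 + rows * self.cell_deg, self.lon0 + cols * self.cell_deg]
        )

    def neighbours(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge list (from, to) of 4-neighbour pairs among habitable cells."""
        idx = np.arange(self.n_cells).reshape(self.n_rows, self.n_cols)
        pairs = []
        for (sa, sb) in (((slice(None), slice(None, -1)), (slice(None), slice(1, None))),
                         ((slice(None, -1), slice(None)), (slice(1, None), slice(None)))):
            a, b = idx[sa].ravel(), idx[sb].ravel()
            pairs.append(np.column_stack([a, b]))
            pairs.append(np.column_stack([b, a]))
        e = np.vstack(pairs)
        hab = self.habitable.ravel()
        e = e[hab[e[:, 0]] & hab[e[:, 1]]]
        return e[:, 0], e[:, 1]


@dataclass
class WaveConfig:
    """One expansion wave: origin, onset, demographic parameters."""

    origin: tuple[int, int]  # (col, row)
    start_gen: int  # generations before present
    K: float
    growth_rate: float
    migration_rate: float
    init_size: float = 100.0

    def validate(self) -> "WaveConfig":
        if not (0 <= self.migration_rate <= 1):
            raise ValueError("migration rate must be in [0, 1]")
        if self.growth_rate <= 0:
            raise ValueError("growth rate must be positive")
        if self.start_gen <= 0:
            raise ValueError("start generation must be a positive integer")
        return self


@dataclass
class Discontinuity:
    cells: np.ndarray  # flat indices
    start_gen: int = 70  # inclusive
    end_gen: int = 35  # exclusive (cells empty for end_gen < g <= start_gen)


@dataclass
class ScenarioConfig:
    world: LatticeWorld
    palaeolithic: WaveConfig
    neolithic: WaveConfig
    discontinuity: Discontinuity | None = None
    sample_cells: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    n_snps: int = 1000
    maf_min: float = 0.03
    samples_per_cell: int = 20
    seed: int = 0

    def validate(self) -> "ScenarioConfig":
        self.palaeolithic.validate()
        self.neolithic.validate()
        hab = self.world.habitable.ravel()
        for w in (self.palaeolithic, self.neolithic):
            if not hab[self.world.flat(*w.origin)]:
                raise ValueError(f"wave origin {w.origin} is not habitable")
        if self.discontinuity is not None:
            d = self.discontinuity
            if not (0 < d.end_gen < d.start_gen <= self.palaeolithic.start_gen):
                raise ValueError("discontinuity window outside the simulated span")
        return self


@dataclass
class DemeHistory:
    """Recorded deme sizes per generation before present (index = g)."""

    N_mid: np.ndarray  # post-growth, pre-migration sizes, (T+1, n_cells)
    N_end: np.ndarray  # post-migration sizes
    neo: np.ndarray  # farming-layer flag per generation, bool
    colonized_gen: np.ndarray  # first generation BP with N > 0; -1 if never
    open_hist: np.ndarray  # bool (T+1, n_cells): K > 0 that generation


def run_demography(scenario: ScenarioConfig) -> DemeHistory:
    """Deterministic two-wave demography on the lattice."""
    scenario.validate()
    w = scenario.world
    pal, neo_w = scenario.palaeolithic, scenario.neolithic
    T = pal.start_gen
    nc = w.n_cells
    hab = w.habitable.ravel()
    efrom, eto = w.neighbours()

    N = np.zeros(nc)
    neo = np.zeros(nc, dtype=bool)
    N[w.flat(*pal.origin)] = pal.init_size
    N_mid = np.zeros((T + 1, nc), dtype=np.float32)
    N_end = np.zeros((T + 1, nc), dtype=np.float32)
    neo_hist = np.zeros((T + 1, nc), dtype=bool)
    open_hist = np.zeros((T + 1, nc), dtype=bool)
    colonized = np.full(nc, -1)
    colonized[N > 0] = T
    N_mid[T] = N_end[T] = N
    neo_hist[T] = neo

    disc = scenario.discontinuity
    for g in range(T - 1, -1, -1):
        if g == neo_w.start_gen:
            o = w.flat(*neo_w.origin)
            N[o] += neo_w.init_size
            neo[o] = True
        K = np.where(neo, neo_w.K, pal.K) * hab
        if disc is not None and disc.end_gen < g <= disc.start_gen:
            K[disc.cells] = 0.0
        open_hist[g] = K > 0
        r = np.where(neo, neo_w.growth_rate, pal.growth_rate)
        grow = K > 0
        N[grow] = N[grow] + r[grow] * N[grow] * (1.0 - N[grow] / K[grow])
        N[~grow] = 0.0
        N = np.minimum(N, K)
        N_mid[g] = N

        # emigration: m*N/4 per open 4-neighbour; migrants towards closed
        # cells stay home, so front speed is uniform across the lattice
        m = np.where(neo, neo_w.migration_rate, pal.migration_rate)
        open_target = K > 0
        deg = np.bincount(efrom, weights=open_target[eto].astype(float), minlength=nc)
        per_edge = (m[efrom] * N[efrom] / 4.0) * open_target[eto]
        out = m * N * deg / 4.0
        inflow = np.zeros(nc)
        np.add.at(inflow, eto, per_edge)
        neo_in = np.zeros(nc)
        np.add.at(neo_in, eto, per_edge * neo[efrom])
        N = N - out + inflow
        neo = (neo | (neo_in > 0)) & (N > 0)
        N[N < MIN_DEME] = 0.0
        N = np.minimum(N, np.where(neo, neo_w.K, pal.K) * (K > 0))
        N_end[g] = N
        neo_hist[g] = neo
        colonized[(colonized < 0) & (N > 0)] = g

    return DemeHistory(N_mid, N_end, neo_hist, colonized, open_hist)


def _genetics_pass(
    scenario: ScenarioConfig, hist: DemeHistory, n_snps: int, rng, p0=None
) -> np.ndarray:
    """One forward pass of allele frequencies; returns present-day per-cell
    frequencies (NaN for unoccupied cells)."""
    from scipy import sparse

    w = scenario.world
    pal, neo_w = scenario.palaeolithic, scenario.neolithic
    T = pal.start_gen
    nc = w.n_cells
    efrom, eto = w.neighbours()
    # fixed-structure flow matrix M[to, from]; data refreshed each generation
    M = sparse.csr_matrix(
        (np.arange(len(efrom), dtype=float), (eto, efrom)), shape=(nc, nc)
    )
    edge_order = M.data.astype(int)
    M = M.astype(float)

    p = np.full((nc, n_snps), np.nan)
    if p0 is None:
        p0 = rng.uniform(0.05, 0.95, n_snps)
    p[w.flat(*pal.origin)] = p0

    for g in range(T - 1, -1, -1):
        if g == neo_w.start_gen:
            # the farming wave seeds from the gene pool at its origin cell
            o = w.flat(*neo_w.origin)
            if np.isnan(p[o]).all():
                p[o] = p0
        N_pre = hist.N_mid[g].astype(float)
        occupied_pre = (N_pre > 0) & ~np.isnan(p[:, 0])
        m = np.where(hist.neo[g], neo_w.migration_rate, pal.migration_rate)
        open_target = hist.open_hist[g]
        deg = np.bincount(efrom, weights=open_target[eto].astype(float), minlength=nc)
        out = np.where(occupied_pre, m * N_pre * deg / 4.0, 0.0)
        stay = np.where(occupied_pre, N_pre, 0.0) - out
        per_edge = (
            m[efrom] * np.where(occupied_pre[efrom], N_pre[efrom], 0.0) / 4.0
        ) * open_target[eto]

        M.data = per_edge[edge_order]
        src_p = np.where(np.isnan(p), 0.0, p)
        num = stay[:, None] * src_p + M @ src_p
        den = stay + M @ np.ones(nc)
        with np.errstate(invalid="ignore", divide="ignore"):
            pool = num / den[:, None]

        N_now = hist.N_end[g].astype(float)
        occ = N_now > 0
        gam = np.maximum(1, np.rint(2.0 * N_now[occ]).astype(np.int64))
        pool_occ = np.clip(pool[occ], 0.0, 1.0)
        pool_occ = np.where(np.isnan(pool_occ), 0.0, pool_occ)
        draws = rng.binomial(gam[:, None], pool_occ)
        p[:] = np.nan
        p[occ] = draws / gam[:, None]
    return p


@dataclass
class SimOutput:
    scenario: ScenarioConfig
    history: DemeHistory
    cell_freqs: np.ndarray  # present-day per-cell frequencies (sampled SNPs)
    genotypes: GenotypeMatrix
    sites: SiteTable


def run_genetics(
    scenario: ScenarioConfig,
    hist: DemeHistory | None = None,
    seed: int | None = None,
    ancestral_freq=None,
) -> SimOutput:
    """Simulate SNPs on a completed demography and sample genotypes.

    SNPs start at an ancestral frequency drawn uniform(0.05, 0.95) in the
    origin deme (or ``ancestral_freq`` if given), drift by binomial gamete
    sampling from the migration-weighted parental pool each generation, and
    are ascertained at present so every reported SNP has pooled-sample
    MAF >= ``maf_min``; undersupplied batches are topped up by further
    passes.
    """
    scenario.validate()
    if hist is None:
        hist = run_demography(scenario)
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    w = scenario.world
    cells = np.asarray(scenario.sample_cells, dtype=int)
    if cells.size == 0:
        raise ValueError("scenario has no sample cells")
    dead = cells[hist.N_end[0][cells] <= 0]
    if dead.size:
        raise ValueError(f"sample cells extinct at present: {dead.tolist()}")

    n_per = scenario.samples_per_cell
    target = scenario.n_snps
    kept_freq: list[np.ndarray] = []
    kept_geno: list[np.ndarray] = []
    total = 0
    attempts = 0
    fixed_p0 = ancestral_freq is not None
    while total < target:
        batch = target if fixed_p0 else max(64, int(1.1 * (target - total)))
        p0 = None
        if fixed_p0:
            p0 = np.broadcast_to(np.asarray(ancestral_freq, dtype=float), (batch,))
        p = _genetics_pass(scenario, hist, batch, rng, p0=p0)
        freqs = p[cells]  # n_sample_cells x batch
        geno = rng.binomial(2, np.repeat(freqs, n_per, axis=0))
        if scenario.maf_min > 0:
            af = geno.sum(axis=0) / (2.0 * geno.shape[0])
            maf = np.minimum(af, 1 - af)
            ok = maf >= scenario.maf_min
        else:
            ok = np.ones(batch, dtype=bool)
        kept_freq.append(freqs[:, ok])
        kept_geno.append(geno[:, ok])
        total += int(ok.sum())
        attempts += 1
        if fixed_p0 or attempts > 50:
            break
    freqs = np.hstack(kept_freq)[:, :target]
    geno = np.hstack(kept_geno)[:, :target].astype(np.int8)

    S = geno.shape[1]
    mm = pd.DataFrame(
        {"id": [f"sim{i}" for i in range(S)], "chrom": "1",
         "pos": (np.arange(S) + 1) * 100_000}
    )
    codes = [f"C{c}" for c in cells]
    ids, assignment = [], {}
    for code in codes:
        for j in range(n_per):
            iid = f"{code}_{j:02d}"
            ids.append(iid)
            assignment[iid] = code
    gm = GenotypeMatrix(ids, mm, geno).validate()
    latlon = w.coords_of(cells)
    st = SiteTable(
        pd.DataFrame({"site": codes, "lat": latlon[:, 0], "lon": latlon[:, 1]}),
        assignment,
    ).validate()
    return SimOutput(scenario, hist, freqs, gm, st)


@dataclass
class ScenarioComparison:
    protest_geo: dict  # scenario label -> (r, p)
    protest_cross: tuple[float, float]
    bearing_r2: float
    bearing_r2_adj: float
    profiles: dict


def compare_scenarios(
    outA: SimOutput, outB: SimOutput, n_perm: int = 999, seed: int = 0,
    labels: tuple[str, str] = ("A", "B"),
) -> ScenarioComparison:
    """Compare two simulated scenarios through the genetic-geography lens.

    For each scenario: pairwise Fst (negatives clamped), classical MDS, and
    a Procrustes test of the first two MDS axes against the sample-cell
    coordinates. Across scenarios: a Procrustes test between the two MDS
    configurations and an OLS fit between the two bearing-correlogram
    profiles with its (adjusted) R^2.
    """
    if list(outA.sites.sites["site"]) != list(outB.sites.sites["site"]):
        raise ValueError("scenarios do not share sample-cell geometry")
    res = {}
    mds_coords = {}
    profiles = {}
    for label, out in zip(labels, (outA, outB)):
        fst = wc_fst(out.genotypes, out.sites, min_n=1)
        D = PairMatrix(fst.pairwise.labels, fst.pairwise.values, "distance")
        mds = classical_mds(D, k=2, correct=True)
        geo_xy = np.column_stack(
            [out.sites.sites["lon"].to_numpy(), out.sites.sites["lat"].to_numpy()]
        )
        pr = procrustes_protest(mds.coordinates, geo_xy, n_perm=n_perm, seed=seed)
        res[label] = (pr.r, pr.p_value)
        mds_coords[label] = mds.coordinates
        profiles[label] = bearing_correlogram(
            fst.pairwise, out.sites, n_perm=0, seed=seed
        )
    cross = procrustes_protest(
        mds_coords[labels[0]], mds_coords[labels[1]], n_perm=n_perm, seed=seed
    )
    rA, rB = profiles[labels[0]].r, profiles[labels[1]].r
    resid = rA - np.polyval(np.polyfit(rB, rA, 1), rB)
    ss_res = (resid**2).sum()
    ss_tot = ((rA - rA.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot
    n = len(rA)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return ScenarioComparison(
        protest_geo=res,
        protest_cross=(cross.r, cross.p_value),
        bearing_r2=float(r2),
        bearing_r2_adj=float(r2_adj),
        profiles=profiles,
    )


def toy_coastal_scenario(
    discontinuity: bool,
    n: int = 40,
    seed: int = 0,
    n_snps: int = 1000,
    samples_per_cell: int = 20,
) -> ScenarioConfig:
    """Preset: n x n habitable world with a western coastal strip.

    Both waves start in the southeast corner (Palaeolithic 220, Neolithic
    150 generations before present, scaled so the first front traverses the
    world before the 70-35 discontinuity window). 39 sample cells sit in a
    northwestern block of which 28 are coastal; the discontinuity empties
    exactly those 28 cells.
    """
    world = LatticeWorld(n_cols=n, n_rows=n)
    block_cols = range(0, 6)
    block_rows = range(n - 10, n - 3)
    cells = [world.flat(c, r) for r in block_rows for c in block_cols]
    coastal = [world.flat(c, r) for r in block_rows for c in block_cols if c < 4]
    inland = [x for x in cells if x not in coastal]
    sample = np.array(coastal + inland[:11])  # 28 coastal + 11 inland = 39
    pal = WaveConfig(origin=(n - 1, 0), start_gen=220, K=500.0,
                     growth_rate=0.5, migration_rate=0.4)
    neo = WaveConfig(origin=(n - 1, 0), start_gen=150, K=5000.0,
                     growth_rate=0.8, migration_rate=0.8)
    disc = Discontinuity(np.array(coastal), 70, 35) if discontinuity else None
    return ScenarioConfig(
        world=world, palaeolithic=pal, neolithic=neo, discontinuity=disc,
        sample_cells=sample, n_snps=n_snps, maf_min=0.03,
        samples_per_cell=samples_per_cell, seed=seed,
    )
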