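"""Post-fire seed release and the three dispersal channels.

When a dune burns, every cohort releases its canopy seed bank.  Dispersal
then proceeds per cohort in a fixed order: a fraction of the fertile cones
(7% calibrated) is carried off by cockatoos and dropped on suitable dune
cells within 1250 m of the source; a fraction of the remaining viable
seeds (15% calibrated) is lofted by post-fire wind vortices -- uniform
angle, log-normal distance (meanlog 6.79, sdlog 0.68, metres) -- and lands
anywhere, classified as resident (source dune), immigrant (another dune)
or lost (swale or off-grid); everything else is short-distance dispersal
(SDD) and stays in the source dune.

Seed accounting is exactly conservative: bird-removed seeds + wind seeds +
SDD seeds equals the released viable-seed total by construction.

For very large seed pools the per-seed wind loop is replaced by a
multinomial draw over a Monte-Carlo estimate of the per-dune landing
probabilities (same exchangeable-seed distribution, bounded cost); the
same capping applies to bird cones, with totals rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import Dune, Landscape

# Calibrated long-distance dispersal fractions and fitted kernel/cone models
DEFAULT_P_BIRD = 0.07
DEFAULT_P_WIND = 0.15
WIND_MEANLOG = 6.79
WIND_SDLOG = 0.68
BIRD_MAX_DIST_M = 1250.0
FOLLICLE_NBINOM_SIZE = 6.22  # baseline epoch
FOLLICLE_NBINOM_MU = 10.08
FOLLICLE_POISSON_LAMBDA = 7.33  # current epoch
OPEN_FOLLICLE_RANGE = (0.5, 1.0)


@dataclass(frozen=True)
class DispersalParams:
    p_bird: float = DEFAULT_P_BIRD
    p_wind: float = DEFAULT_P_WIND
    wind_meanlog: float = WIND_MEANLOG
    wind_sdlog: float = WIND_SDLOG
    bird_max_dist_m: float = BIRD_MAX_DIST_M
    follicle_size_baseline: float = FOLLICLE_NBINOM_SIZE
    follicle_mu_baseline: float = FOLLICLE_NBINOM_MU
    follicle_lambda_current: float = FOLLICLE_POISSON_LAMBDA
    open_follicle_low: float = OPEN_FOLLICLE_RANGE[0]
    open_follicle_high: float = OPEN_FOLLICLE_RANGE[1]
    max_simulated_units: int = 5000  # per-cohort cap before rescaling kicks in

    def __post_init__(self) -> None:
        for frac in (self.p_bird, self.p_wind):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("dispersal fractions must be in [0, 1]")
        if self.wind_sdlog <= 0:
            raise ValueError("wind kernel sdlog must be positive")

    def mean_follicles(self, epoch: str) -> float:
        if epoch == "baseline":
            return self.follicle_mu_baseline
        return self.follicle_lambda_current

    def sample_follicles(
        self, n: int, epoch: str, rng: np.random.Generator
    ) -> np.ndarray:
        if epoch == "baseline":
            size, mu = self.follicle_size_baseline, self.follicle_mu_baseline
            p = size / (size + mu)
            return rng.negative_binomial(size, p, n)
        return rng.poisson(self.follicle_lambda_current, n)


@dataclass
class SeedDeposit:
    """Seeds arriving at one destination from one source cohort."""

    dune_id: int  # -1 = lost (swale or off-grid)
    seeds: float
    source_dune: int
    initial_id: int  # lineage origin of the source cohort
    mechanism: str  # "bird" | "wind" | "SDD"

    def label(self) -> str:
        if self.dune_id < 0:
            return "lost"
        return "resident" if self.dune_id == self.source_dune else "immigrant"


def release_on_burn(
    cones_by_age: np.ndarray, viable_seed_vector: np.ndarray
) -> tuple[float, float]:
    """Total (fertile cones, viable seeds) released by a burned cohort,
    given its total cone counts per cone age 1..12 and V(a)."""
    cones_total = float(cones_by_age.sum())
    seeds_total = float((cones_by_age * viable_seed_vector).sum())
    return cones_total, seeds_total


def sample_wind_distances(
    n: int, rng: np.random.Generator, params: DispersalParams | None = None
) -> np.ndarray:
    params = params or DispersalParams()
    return rng.lognormal(params.wind_meanlog, params.wind_sdlog, n)


def classify_landing(
    point_xy: tuple[float, float], landscape: Landscape, source_dune: int
) -> str:
    """resident / immigrant / lost for a continuous landing point."""
    dune_id = _landing_dune(np.atleast_2d(np.asarray(point_xy, dtype=float)), landscape)[0]
    if dune_id < 0:
        return "lost"
    return "resident" if dune_id == source_dune else "immigrant"


def _landing_dune(xy: np.ndarray, landscape: Landscape) -> np.ndarray:
    """Vectorized map from continuous points to dune id (-1 = lost)."""
    g = landscape.grid
    col = np.floor(xy[:, 0] / g.cell_m).astype(int)
    row = np.floor(xy[:, 1] / g.cell_m).astype(int)
    inside = (col >= 0) & (col < g.n_cols) & (row >= 0) & (row < g.n_rows)
    out = np.full(len(xy), -1, dtype=int)
    out[inside] = landscape.cell_to_dune[row[inside], col[inside]]
    return out


def disperse_cones_birds(
    cones_total: float,
    source_dune: Dune,
    landscape: Landscape,
    params: DispersalParams,
    pollination_epoch: str,
    viable_seeds_cone1: float,
    rng: np.random.Generator,
) -> tuple[list[SeedDeposit], float, int]:
    """Bird-mediated cone dispersal for one burned cohort.

    round(p_bird * cones_total) cones are carried off.  Each cone's seed
    content is follicles (epoch cone model) times the per-follicle
    viability implied by a 1-year-old cone (V(1) / mean follicle count);
    the seeds released at the drop cell are that content times a uniform
    open-follicle proportion in [0.5, 1], rounded.  Drop cells are uniform
    over the source dune's precomputed suitable cells within 1250 m.

    Returns (deposits, seeds_removed_from_pool, cones_dispersed,
    drop_cells).  The removed-seed total is the full cone content, so pool
    accounting stays conservative whether or not every follicle opened.
    `drop_cells` holds the (row, col) drop cell of every simulated cone.
    """
    n_cones = int(np.floor(params.p_bird * cones_total + 0.5))
    if n_cones == 0:
        return [], 0.0, 0, np.empty((0, 2), dtype=int)
    targets = source_dune.bird_target_cells
    if targets is None or len(targets) == 0:
        raise ValueError("bird target cells were not precomputed")
    per_follicle = viable_seeds_cone1 / params.mean_follicles(pollination_epoch)

    n_sim = min(n_cones, params.max_simulated_units)
    scale = n_cones / n_sim
    follicles = params.sample_follicles(n_sim, pollination_epoch, rng)
    content = follicles * per_follicle
    open_frac = rng.uniform(params.open_follicle_low, params.open_follicle_high, n_sim)
    released = np.floor(content * open_frac + 0.5)
    cell_idx = rng.integers(len(targets), size=n_sim)
    cells = targets[cell_idx]
    dune_ids = landscape.cell_to_dune[cells[:, 0], cells[:, 1]]

    deposits: list[SeedDeposit] = []
    for d in np.unique(dune_ids):
        seeds = float(released[dune_ids == d].sum() * scale)
        if seeds > 0:
            deposits.append(SeedDeposit(int(d), seeds, source_dune.dune_id, 0, "bird"))
    seeds_removed = float(content.sum() * scale)
    return deposits, seeds_removed, n_cones, cells


def wind_landing_distribution(
    source_dune: Dune,
    landscape: Landscape,
    params: DispersalParams,
    rng: np.random.Generator,
    n_draws: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo estimate of the per-seed landing distribution over
    destination dunes (and -1 for lost) for wind LDD from one source dune.

    Wind seeds from the same dune are exchangeable (origin uniform over
    the dune, iid angle and distance), so one empirical distribution can
    serve every cohort released from that dune in the same fire."""
    n = n_draws or params.max_simulated_units
    g = landscape.grid
    cell_idx = rng.integers(len(source_dune.cells), size=n)
    cells = source_dune.cells[cell_idx]
    ox = (cells[:, 1] + rng.random(n)) * g.cell_m
    oy = (cells[:, 0] + rng.random(n)) * g.cell_m
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    dist = sample_wind_distances(n, rng, params)
    landing = np.column_stack([ox + dist * np.cos(theta), oy + dist * np.sin(theta)])
    dune_ids = _landing_dune(landing, landscape)
    cats, counts = np.unique(dune_ids, return_counts=True)
    return cats, counts / counts.sum()


def disperse_seeds_wind(
    seeds_remaining: float,
    source_dune: Dune,
    landscape: Landscape,
    params: DispersalParams,
    rng: np.random.Generator,
    landing_dist: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[list[SeedDeposit], int]:
    """Wind LDD for one burned cohort: round(p_wind * seeds_remaining)
    seeds fly.  Each seed starts at a uniform point inside the source
    dune, flies at a uniform angle for a log-normal distance, and is
    classified by its landing cell.  Above the per-cohort cap the per-seed
    trajectories are subsampled and a multinomial over the estimated
    landing distribution allocates the full seed count (conservation is
    exact either way).

    Returns (deposits including a lost-seed record, n_wind).
    """
    n_wind = int(np.floor(params.p_wind * seeds_remaining + 0.5))
    if n_wind == 0:
        return [], 0
    if landing_dist is None:
        n_sim = min(n_wind, params.max_simulated_units)
        g = landscape.grid
        cell_idx = rng.integers(len(source_dune.cells), size=n_sim)
        cells = source_dune.cells[cell_idx]
        ox = (cells[:, 1] + rng.random(n_sim)) * g.cell_m
        oy = (cells[:, 0] + rng.random(n_sim)) * g.cell_m
        theta = rng.uniform(0.0, 2.0 * np.pi, n_sim)
        dist = sample_wind_distances(n_sim, rng, params)
        landing = np.column_stack([ox + dist * np.cos(theta), oy + dist * np.sin(theta)])
        dune_ids = _landing_dune(landing, landscape)
        cats = np.unique(dune_ids)
        if n_sim == n_wind:
            counts = {int(d): int((dune_ids == d).sum()) for d in cats}
        else:
            probs = np.array([(dune_ids == d).mean() for d in cats])
            draw = rng.multinomial(n_wind, probs / probs.sum())
            counts = {int(d): int(k) for d, k in zip(cats, draw)}
    else:
        cats, probs = landing_dist
        draw = rng.multinomial(n_wind, probs)
        counts = {int(d): int(k) for d, k in zip(cats, draw)}

    deposits = [
        SeedDeposit(d, float(k), source_dune.dune_id, 0, "wind")
        for d, k in counts.items()
        if k > 0
    ]
    return deposits, n_wind


def disperse_cohort_release(
    cones_total: float,
    seeds_total: float,
    source_dune: Dune,
    landscape: Landscape,
    params: DispersalParams,
    pollination_epoch: str,
    viable_seeds_cone1: float,
    rng: np.random.Generator,
    wind_landing: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[SeedDeposit]:
    """Full dispersal pipeline for one burned cohort's release:
    birds first (cones), then wind (share of the remaining seeds), then
    the SDD remainder deposited in the source dune.  The three channels
    partition `seeds_total` exactly."""
    deposits, bird_seed_removal, _, _ = disperse_cones_birds(
        cones_total, source_dune, landscape, params, pollination_epoch,
        viable_seeds_cone1, rng,
    )
    remaining = max(0.0, seeds_total - bird_seed_removal)
    wind_deposits, n_wind = disperse_seeds_wind(
        remaining, source_dune, landscape, params, rng, wind_landing
    )
    deposits.extend(wind_deposits)
    sdd_seeds = remaining - n_wind
    if sdd_seeds > 0:
        deposits.append(
            SeedDeposit(source_dune.dune_id, sdd_seeds, source_dune.dune_id, 0, "SDD")
        )
    return deposits
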