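"""The yearly simulation loop.

Every run starts with a landscape-wide burn (the 1998-wildfire analogue):
the initial stands die, release the canopy seed bank built up during a
mortality-free production spin-up, and found the first post-fire cohorts.
Each subsequent year samples a climate row, checks the fire schedule and
then either processes a burn (release -> bird LDD -> wind LDD -> SDD ->
recruitment on burned dunes) or the between-fire sequence (mortality ->
aging -> density regulation -> cone production) per dune.  The run stops
at metapopulation extinction or after `max_years`.

All randomness flows from a single root seed through numpy SeedSequence
spawning, so identical configurations reproduce identical runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import climate as clim
from . import demography as demo
from . import dispersal as disp
from . import fire as fire_mod
from . import landscape as land
from .demography import Cohort, DemographyParams, GOOD, POOR
from .dispersal import DispersalParams, SeedDeposit
from .fire import FireRegime
from .landscape import DuneSpec, GridSpec, Landscape

STAGES = ("seed", "seedling", "adult", "source")


@dataclass
class SimConfig:
    climate_epoch: str = "baseline"
    pollination_epoch: str = "baseline"
    fire: FireRegime = field(default_factory=FireRegime)
    mortality_scenario: str = "i"
    production_mode: str = "cohort"  # "cohort" | "individual"
    demography: DemographyParams = field(default_factory=DemographyParams)
    dispersal: DispersalParams = field(default_factory=DispersalParams)
    dune_table: list[DuneSpec] | None = None  # None -> packaged default
    grid: GridSpec = field(default_factory=GridSpec)
    landscape: Landscape | None = None  # prebuilt replicate; overrides dune_table
    climate_table: clim.ClimateTable | None = None  # None -> synthetic epoch table
    climate_years: int = 15
    initial_density_per_ha: float = 7.0
    initial_stand_age: int = 21
    max_years: int = 500
    source_dune_ids: frozenset[int] | None = None  # sink-to-source designation
    seed: int = 0

    def resolve_climate(self, rng: np.random.Generator) -> clim.ClimateTable:
        if self.climate_table is not None:
            return self.climate_table
        return clim.synth_climate(self.climate_epoch, self.climate_years, rng)


@dataclass
class DuneState:
    dune: land.Dune
    tsf: int = 0
    cohorts: list[Cohort] = field(default_factory=list)
    ever_alive: bool = False
    last_year_alive: int = 0
    immigrant_stages: set[str] = field(default_factory=set)

    @property
    def n_plants(self) -> int:
        return sum(c.n_plants for c in self.cohorts)


@dataclass
class ChainRecord:
    """One (re)colonization attempt on an extinct or never-occupied dune."""

    dune_id: int
    year: int
    stages: set[str] = field(default_factory=lambda: {"seed"})


@dataclass
class SimState:
    year: int
    landscape: Landscape
    dunes: dict[int, DuneState]
    climate_table: clim.ClimateTable
    rng: np.random.Generator
    chains: dict[tuple[int, int], ChainRecord] = field(default_factory=dict)
    sink_to_source: int = 0
    occupied_fraction_sum: float = 0.0
    years_recorded: int = 0
    fire_log: list = field(default_factory=list)
    extinct: bool = False
    base_rates: np.ndarray | None = None  # (3, max_age) scenario mortality table

    @property
    def total_plants(self) -> int:
        return sum(d.n_plants for d in self.dunes.values())


@dataclass
class SimResult:
    persistence: int
    per_dune_persistence: dict[int, int]
    occupancy_pct: float
    chains: list[ChainRecord]
    immigrant_stages_by_dune: dict[int, set[str]]
    ever_alive_dunes: set[int]
    sink_to_source: int
    final_total_plants: int
    final_immigrant_plants: int
    initial_ids_by_occupied_dune: dict[int, set[int]]
    n_fires: int
    max_years: int

    @property
    def immigration_rate_pct(self) -> float:
        """Percentage of living plants in immigrant cohorts at the final
        census (NaN when no plant is alive)."""
        if self.final_total_plants == 0:
            return float("nan")
        return 100.0 * self.final_immigrant_plants / self.final_total_plants


def _spin_up_cone_bank(
    cohort: Cohort,
    config: SimConfig,
    quality_coefficient: float,
    climate_table: clim.ClimateTable,
    rng: np.random.Generator,
) -> None:
    """Mortality-free production history giving the initial stand a cone
    bank consistent with the production submodel: one production year per
    age from maturity to the initial stand age, with yearly cone aging."""
    params = config.demography
    saved_age = cohort.age
    for age in range(params.maturity_age, saved_age + 1):
        shifted = np.zeros_like(cohort.cones)
        shifted[:, 1:] = cohort.cones[:, :-1]
        cohort.cones = shifted
        cohort.age = age
        cy = clim.sample_year(climate_table, rng)
        demo.produce_and_store_cones(
            cohort, cy, params, config.production_mode, config.pollination_epoch,
            config.climate_epoch, quality_coefficient, rng,
        )
    cohort.age = saved_age


def initialize(config: SimConfig, rng: np.random.Generator | None = None) -> SimState:
    """Build the landscape, populate occupied dunes at the configured
    density and stand age, then run the year-1 landscape-wide burn."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ls = (
        config.landscape
        if config.landscape is not None
        else land.generate_landscape(config.dune_table, config.grid, rng)
    )
    climate_table = config.resolve_climate(rng)
    dunes: dict[int, DuneState] = {}
    for dune in ls.dunes:
        ds = DuneState(dune=dune, tsf=config.initial_stand_age)
        if dune.spec.initially_occupied:
            n0 = int(round(config.initial_density_per_ha * dune.spec.area_ha))
            n = np.zeros(2, dtype=int)
            if config.production_mode == "individual":
                n_good, n_poor = demo.assign_producer_class(
                    n0, rng, config.demography.good_fraction
                )
                n[GOOD], n[POOR] = n_good, n_poor
            else:
                n[POOR] = n0
            cohort = Cohort(
                age=config.initial_stand_age,
                n=n,
                dispersal_class="SDD",
                id_triple=(dune.dune_id, dune.dune_id, dune.dune_id),
                cones=Cohort.empty_bank(),
                founding_year=0,
            )
            _spin_up_cone_bank(
                cohort, config, dune.spec.quality_coefficient, climate_table, rng
            )
            ds.cohorts = [cohort]
            ds.ever_alive = True
        dunes[dune.dune_id] = ds
    state = SimState(
        year=0, landscape=ls, dunes=dunes, climate_table=climate_table, rng=rng,
        base_rates=demo.scenario_base_rates(
            config.demography, config.mortality_scenario
        ),
    )
    run_year(state, config)  # year 1: whole-landscape burn
    return state


def _process_burns(
    state: SimState, config: SimConfig, burned: set[int], climate_year: clim.ClimateYear
) -> None:
    """Seed release, dispersal, and cohort formation for this year's burns."""
    params = config.demography
    # dunes with no plants before the fire: deposits there start
    # (re)colonization chains
    empty_before = {i for i, d in state.dunes.items() if d.n_plants == 0}
    v = params.viable_seed_vector(config.pollination_epoch)
    v1 = params.viable_seeds_cone1[config.pollination_epoch]
    deposits: list[SeedDeposit] = []

    # release and dispersal, cohort by cohort
    for dune_id in sorted(burned):
        ds = state.dunes[dune_id]
        wind_landing = (
            disp.wind_landing_distribution(
                ds.dune, state.landscape, config.dispersal, state.rng
            )
            if ds.cohorts
            else None
        )
        for cohort in ds.cohorts:
            if cohort.n_plants == 0:
                continue
            # source-stage bookkeeping: adults with canopy seed banks that
            # reached this fire
            if cohort.age >= params.maturity_age and cohort.total_cones() > 0:
                if cohort.chain_key is not None and cohort.chain_key in state.chains:
                    state.chains[cohort.chain_key].stages.add("source")
                if cohort.is_immigrant:
                    ds.immigrant_stages.add("source")
                if (
                    config.source_dune_ids is not None
                    and dune_id in config.source_dune_ids
                    and cohort.is_immigrant
                    and cohort.id_triple[1] not in config.source_dune_ids
                ):
                    state.sink_to_source += cohort.n_plants
            cones_by_age = (cohort.cones * cohort.n[:, None]).sum(axis=0)
            cones_total, seeds_total = disp.release_on_burn(cones_by_age, v)
            if seeds_total <= 0:
                continue
            cohort_deposits = disp.disperse_cohort_release(
                cones_total, seeds_total, ds.dune, state.landscape,
                config.dispersal, config.pollination_epoch, v1, state.rng,
                wind_landing,
            )
            for dep in cohort_deposits:
                dep.initial_id = cohort.id_triple[0]
            deposits.extend(cohort_deposits)
        # fire kills every plant of the burned dune
        ds.cohorts = []
        ds.tsf = 0

    _settle_deposits(state, config, deposits, burned, empty_before, climate_year)


def _settle_deposits(
    state: SimState,
    config: SimConfig,
    deposits: list[SeedDeposit],
    burned: set[int],
    empty_before: set[int],
    climate_year: clim.ClimateYear,
) -> None:
    """Aggregate deposits per (target, source, lineage, mechanism) and run
    post-fire recruitment on dunes burned this year; all other seeds
    perish (no soil seed bank)."""
    params = config.demography
    # one cohort per (target x source x mechanism); lineage fragments from
    # the same source pool together, keeping the plurality lineage id
    pooled: dict[tuple[int, int, str], dict[int, float]] = {}
    for dep in deposits:
        if dep.dune_id < 0:
            continue  # lost
        target = state.dunes[dep.dune_id]
        # seed-stage bookkeeping happens for any seed on a suitable patch
        if dep.dune_id in empty_before:
            key = (dep.dune_id, state.year)
            if key not in state.chains:
                state.chains[key] = ChainRecord(dep.dune_id, state.year)
        if dep.label() == "immigrant":
            target.immigrant_stages.add("seed")
        k = (dep.dune_id, dep.source_dune, dep.mechanism)
        by_initial = pooled.setdefault(k, {})
        by_initial[dep.initial_id] = by_initial.get(dep.initial_id, 0.0) + dep.seeds

    for (target_id, source_id, mechanism), by_initial in sorted(pooled.items()):
        if target_id not in burned:
            continue  # seeds on unburned dunes perish
        seeds = sum(by_initial.values())
        initial_id = max(sorted(by_initial), key=lambda i: by_initial[i])
        n_seeds = int(np.floor(seeds + 0.5))
        recruits = demo.postfire_recruitment(n_seeds, climate_year, params, state.rng)
        if recruits == 0:
            continue
        target = state.dunes[target_id]
        n = np.zeros(2, dtype=int)
        if config.production_mode == "individual":
            n_good, n_poor = demo.assign_producer_class(
                recruits, state.rng, params.good_fraction
            )
            n[GOOD], n[POOR] = n_good, n_poor
        else:
            n[POOR] = recruits
        chain_key = (
            (target_id, state.year) if (target_id, state.year) in state.chains else None
        )
        cohort = Cohort(
            age=1,  # germination in the first rainy season after the fire
            n=n,
            dispersal_class="SDD" if mechanism == "SDD" else "LDD",
            id_triple=(initial_id, source_id, target_id),
            cones=Cohort.empty_bank(),
            founding_year=state.year,
            chain_key=chain_key,
        )
        target.cohorts.append(cohort)
        if chain_key is not None:
            state.chains[chain_key].stages.add("seedling")
        if cohort.is_immigrant:
            target.immigrant_stages.add("seedling")


def _process_interfire(
    state: SimState, config: SimConfig, ds: DuneState, climate_year: clim.ClimateYear
) -> None:
    """Between-fire sequence for one unburned dune: mortality, aging,
    density regulation, cone production.

    Mortality is applied to all cohorts of the dune in one vectorized
    binomial draw (statistically identical to per-cohort draws)."""
    params = config.demography
    ref = (
        params.mortality_ref_wsp
        if params.mortality_ref_wsp is not None
        else state.climate_table.mean_wsp
    )
    bonus = (
        params.good_survival_bonus if config.production_mode == "individual" else 0.0
    )
    base_rates = state.base_rates
    cohorts = ds.cohorts
    ages = np.fromiter((c.age for c in cohorts), int, len(cohorts))
    labels = np.fromiter((c.label_index for c in cohorts), int, len(cohorts))
    dev = climate_year.wsp_prev - ref
    rate = np.clip(
        base_rates[labels, np.minimum(ages, params.max_plant_age) - 1]
        - params.weather_beta * dev / 100.0,
        0.0, 1.0,
    )
    n = np.stack([c.n for c in cohorts])  # (k, 2)
    surv = np.column_stack([1.0 - rate, np.minimum(1.0, (1.0 - rate) * (1.0 + bonus))])
    n = state.rng.binomial(n, surv)
    for c, row in zip(cohorts, n):
        c.n = row
    ds.cohorts = [c for c in cohorts if c.n_plants > 0]
    ds.cohorts = demo.age_step(ds.cohorts, params.max_plant_age)
    ds.cohorts = demo.density_regulation(
        ds.cohorts, ds.dune.carrying_capacity, state.rng, params.maturity_age
    )
    ds.cohorts = [c for c in ds.cohorts if c.n_plants > 0]
    adults = [c for c in ds.cohorts if c.age >= params.maturity_age]
    if adults and config.production_mode == "cohort":
        # flowers depend only on age here: one vectorized pass
        w = demo._cohort_weather_factor(climate_year, config.climate_epoch, params)
        f_fert = params.f_fert[config.pollination_epoch]
        cq = ds.dune.spec.quality_coefficient
        for cohort in adults:
            cones1 = params.flowers_max * demo.age_ramp(cohort.age, params) * w * cq * f_fert
            cohort.cones[:, 0] = np.where(cohort.n > 0, cones1, 0.0)
    elif adults:
        for cohort in adults:
            demo.produce_and_store_cones(
                cohort, climate_year, params, "individual",
                config.pollination_epoch, config.climate_epoch,
                ds.dune.spec.quality_coefficient, state.rng,
            )
    # stage bookkeeping at first adulthood
    for cohort in ds.cohorts:
        if cohort.age == params.maturity_age:
            if cohort.chain_key is not None and cohort.chain_key in state.chains:
                state.chains[cohort.chain_key].stages.add("adult")
            if cohort.is_immigrant:
                ds.immigrant_stages.add("adult")


def run_year(state: SimState, config: SimConfig) -> SimState:
    """Advance the simulation by one year (exact per-year process order)."""
    state.year += 1
    climate_year = clim.sample_year(state.climate_table, state.rng)

    burned: set[int] = set()
    if fire_mod.fire_due(state.year, config.fire, state.rng):
        if state.year == 1:
            burned = {d.dune_id for d in state.landscape.dunes}
            event = None
        else:
            event = fire_mod.sample_fire_ellipse(
                config.fire, state.landscape.grid, state.rng
            )
            tsf = {i: d.tsf for i, d in state.dunes.items()}
            burned = fire_mod.resolve_burns(state.landscape, event, tsf, state.rng)
        state.fire_log.append((state.year, event, frozenset(burned)))

    if burned:
        _process_burns(state, config, burned, climate_year)
    for dune_id, ds in state.dunes.items():
        if dune_id in burned:
            continue
        if ds.cohorts:
            _process_interfire(state, config, ds, climate_year)
        ds.tsf += 1

    # year-end census
    n_occupied = 0
    for ds in state.dunes.values():
        if ds.n_plants > 0:
            n_occupied += 1
            ds.ever_alive = True
            ds.last_year_alive = state.year
    state.occupied_fraction_sum += n_occupied / len(state.dunes)
    state.years_recorded += 1
    if n_occupied == 0:
        state.extinct = True
    return state


def finalize(state: SimState, config: SimConfig) -> SimResult:
    occupied_spec = {
        d.dune_id for d in state.landscape.dunes if d.spec.initially_occupied
    }
    ids_by_dune = {
        i: {c.id_triple[0] for c in state.dunes[i].cohorts} for i in occupied_spec
    }
    total = state.total_plants
    immigrants = sum(
        c.n_plants for ds in state.dunes.values() for c in ds.cohorts if c.is_immigrant
    )
    persistence = max((d.last_year_alive for d in state.dunes.values()), default=0)
    return SimResult(
        persistence=persistence,
        per_dune_persistence={i: d.last_year_alive for i, d in state.dunes.items()},
        occupancy_pct=100.0 * state.occupied_fraction_sum / max(1, state.years_recorded),
        chains=list(state.chains.values()),
        immigrant_stages_by_dune={i: set(d.immigrant_stages) for i, d in state.dunes.items()},
        ever_alive_dunes={i for i, d in state.dunes.items() if d.ever_alive},
        sink_to_source=state.sink_to_source,
        final_total_plants=total,
        final_immigrant_plants=immigrants,
        initial_ids_by_occupied_dune=ids_by_dune,
        n_fires=len(state.fire_log),
        max_years=config.max_years,
    )


def run_simulation(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SimResult:
    """Run one full simulation until extinction or `max_years`."""
    state = initialize(config, rng)
    while state.year < config.max_years and not state.extinct:
        run_year(state, config)
    return finalize(state, config)
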