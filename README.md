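# dunefire

A spatially explicit, process-based metapopulation simulator for a
fire-killed, serotinous shrub (modelled on *Banksia hookeriana*) living on
a mosaic of sand-dune habitat patches. It is written for ecologists who
want to explore how fire size and frequency, long-distance seed dispersal
(LDD) and variation in plant performance interact to decide regional
persistence under a drying climate.

## The model in brief

The landscape is a 3 km x 5 km grid of 100 m cells holding 37 dunes
(habitat patches) grown by a random-walk algorithm with a 100 m minimum
swale gap; a dune of area *A* ha supports at most 2500 *A* adults (one
plant per 2 m x 2 m). Plants live in same-age cohorts, mature at 5 years,
die by 40, and hold their seeds in a canopy cone bank (serotiny): a cone
of age *a* holds *V(a)* viable seeds, with *V(1) ~ 10* under baseline
pollination and *~7* under current pollination, and nothing beyond 12
years.

Each simulated year:

1. a climate row (previous winter-spring rainfall, previous annual
   rainfall, 3-year winter-spring sum) is resampled from an epoch table;
2. on the deterministic fire schedule an elliptical patchy fire is placed
   at random (the 100% "baseline" size is the ellipse circumscribing the
   study area); an overlapped dune burns with probability 0 below 3 years
   since fire, 1 above 12, linear in between;
3. burned dunes release their seed banks: 7% of cones are carried off by
   cockatoos to suitable cells within 1250 m, 15% of the remaining seeds
   ride post-fire wind vortices with a log-normal distance kernel
   (meanlog 6.79, sdlog 0.68 m), and the rest stays put; seeds landing on
   dunes burned the same year recruit through a rainfall-dependent
   post-fire bottleneck;
4. unburned dunes undergo rainfall-adjusted mortality (six percentage
   points per 100 mm winter-spring deviation), aging, density regulation
   at carrying capacity, and flower-to-cone production.

Cohorts carry an (initial, previous, current) population-ID triple, so
immigration, recolonization chains (seed -> seedling -> adult -> source
plant) and sink-to-source flows can be scored per run.

## Worked example

```python
import dunefire as df

cfg = df.SimConfig(climate_epoch="baseline", pollination_epoch="baseline",
                   fire=df.FireRegime(interval=21, size_pct=100),
                   mortality_scenario="i", seed=1)
res = df.run_simulation(cfg)
print(f"persistence: {res.persistence} years")
print(f"final plants: {res.final_total_plants}")
print(f"immigrants at final census: {res.immigration_rate_pct:.1f}%")
```

prints

```
persistence: 500 years
final plants: 137361
immigrants at final census: 7.6%
```

i.e. under the wetter baseline epoch with the regional mean fire interval
(21 years) and full-size patchy fires, the metapopulation persists to the
500-year horizon, and about 8% of the standing plants descend from seeds
that immigrated from another dune. Switching both epochs to
`"current"` makes runs collapse early in most replicates — the
interval-squeeze signature the simulator is built to study.

The same machinery is scriptable from the shell:

```bash
dunefire simulate --seed 1 --landscapes 5 --replicates 5 --out out/
dunefire experiment --id 2 --landscapes 5 --replicates 5 --out out/
dunefire calibrate --step 5 --out out/
dunefire sensitivity --parameter demography.rec_upper_limit --landscapes 3 --replicates 3 --out out/
```

All outputs are tidy CSVs (one row per run, or per scenario x run).

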