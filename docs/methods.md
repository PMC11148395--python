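# Methods

This note documents the model as implemented, the parameters that matter,
what the synthetic inputs do and do not emulate, and the numerical and
design choices made where the design was genuinely open.

## Model structure

The simulator couples six components in a fixed yearly order: climate
resampling, fire scheduling and resolution, post-fire seed release and
dispersal, post-fire recruitment, between-fire demography, and metric
bookkeeping. State lives in per-dune cohort lists; a cohort is a same-age
group of plants with a dispersal class (SDD/LDD), an
(initial, previous, current) population-ID triple, per-producer-class
plant counts, and a canopy cone bank (mean fertile cones per plant by
cone age 1–12).

Key fixed biology: maturity at 5 years; longevity cap at 40 years (a
cohort aging to 41 dies deterministically — without inter-fire
recruitment this makes fire both the killer and the only renewer of
populations); cone viability V(a) = V(1)·0.95^(a−1) for cone ages 1–12,
zero after; V(1) = 10 (baseline pollination) or 7 (current); fertile-cone
fraction 0.90 / 0.65 by pollination epoch.

## Climate

A simulation year draws one whole row from an epoch climate table
(uniform, with replacement), preserving cross-predictor correlation; no
interannual autocorrelation is imposed beyond what rows encode, and the
3-year winter–spring sum is internally consistent within a row but not
across consecutively sampled years (rows are sampled, not series).

Because the station series is not packaged, a synthetic generator
produces epoch tables from independent log-normal latent series:
winter–spring rainfall mean 420 mm (CV 0.25) and non-winter rainfall mean
110 mm (CV 0.40) for the baseline epoch; the current epoch is 15% drier,
matching the reported regional drying. These parameters are synthetic:
they reproduce a plausible winter-rainfall Mediterranean climate, not the
real year list. Consequences for interpretation: epoch contrasts in the
package are driven by the configured 15% mean shift, not by observed
dry/wet sequencing, so absolute persistence times are not comparable to
the published values — only orderings and mechanism-level quantities are.

## Mortality

Two age-rate curves (spring-burn and autumn-burn experimental sites, ages
1–15, held constant beyond 15) underlie five scenarios: (i)/(ii) the mean
of the two curves for all cohorts, (iii) spring for LDD cohorts and
autumn for SDD, (iv) spring for immigrants and autumn for residents, (v)
the elementwise minimum for all (the lower-competition assumption). The
published regression coefficients are not reproducible from the main
text, so the packaged curves are surrogates with the documented
qualitative signature — autumn far above spring at ages 1–3 (0.45/0.35/0.25
vs 0.20/0.15/0.12), both declining with age. Their absolute level was
fixed once by the same pattern-oriented reasoning the original
calibration prescribes (see Calibration below).

The weather term subtracts β·(wsp − ref)/100 mm percentage points from
the base rate (wetter years lower mortality), with β = 0.06 and the
result clamped to [0, 1]. We apply the term as an absolute
percentage-point offset in every scenario; that is the natural reading of
a "six per cent per 100 mm" regression adjustment and keeps the term's
magnitude exactly testable. `ref` defaults to 420 mm — the mean of the
period the mortality data were collected in — rather than each epoch's
own mean, so the current epoch's 15% rainfall deficit translates into a
chronic ~3.8-point mortality surcharge. Setting
`DemographyParams.mortality_ref_wsp = None` switches to the running
table's own mean (no epoch penalty).

## Flower and cone production

Cohort mode is deterministic per plant: a convex age ramp (cubic in
relative age, saturating at 15 years — young stands hold very few cones,
consistent with production stabilizing only from 15 years post-fire)
times a rainfall factor times the habitat-quality coefficient
(1.00 / 1.38 / 2.23 for low / moderate / high). The rainfall factor is
anchored on baseline-epoch reference values (e.g. winter–spring 420 mm
with a 300 mm floor), shared across epochs, so drier years and the drier
epoch both produce fewer flowers; the baseline epoch uses the previous
winter–spring rainfall, the current epoch the mean of annual-rainfall and
3-year-sum terms, mirroring the different fitted predictor sets.

Individual mode classifies plants as poor (75%) or good (25%) producers.
Flower counts are drawn from per-(class x climate-class) discrete
distributions — Poisson for poor producers, negative binomial for good —
mixed by fuzzy climate-class weights (triangle/trapezoid memberships on
annual rainfall and the 3-year sum, nodes near the current epoch's
33rd/67th percentiles). The distributions describe mature plants under
current-epoch monitoring, so draws are thinned by the same age ramp as
cohort mode, and the surrogate means are pitched so the producer-class
mixture in a typical current-climate year matches cohort-mode
current-epoch production of a mature low-quality stand (good > poor and
wet > dry throughout). Good producers optionally survive better:
annual survival × (1 + s), capped at 1, with s = 0.06 by default (the
relative reading of the reported "6% higher survival"); s is the swept
variable of the intraspecific-variation experiment. Sums of per-plant
draws use the exact in-family identities (a sum of n Poisson or negative
binomial draws is again Poisson / negative binomial), so individual mode
costs O(1) per cohort-class regardless of cohort size.

## Fire

Deterministic schedule anchored at the year-1 landscape-wide burn (the
1998-wildfire analogue), then every `interval` years; an optional
stochastic mode (Bernoulli ignition at 1/interval per year) exists but is
off by default and excluded from all shipped analyses. The 100% fire is
the ellipse through the four corners of the study rectangle; size scales
area linearly via √(f/100) on both semi-axes; centre is uniform over cell
centres and orientation uniform on [0, π). Overlap is evaluated at cell
centres (exact at raster resolution). The fuel rule is
p(burn) = clamp((tsf − 3)/9, 0, 1): the ramp's left end p(3) = 0 is a
choice (the source leaves it open) and is configurable in spirit by
editing `burn_probability`.

## Dispersal and recruitment

Per burned cohort, in order: birds take round(7% of cones); each cone's
content is follicles (negative binomial size 6.22 / mean 10.08 under
baseline pollination, Poisson 7.33 under current) times the per-follicle
viability V(1)/mean-follicles, released at a uniform open-follicle
fraction in [0.5, 1] onto a uniform dune cell within 1250 m of the source
dune. Wind then takes round(15% of the remaining seeds): uniform origin
in the source dune, uniform angle, log-normal distance; landings are
classified resident / immigrant / lost. Everything else is SDD and stays
in the source dune. Accounting is conservative by construction:
bird-removed + wind + SDD equals the released total exactly.

Seeds recruit only on dunes burned the same year (no soil seed bank);
first-year mortality is upper·logistic((mean − rain)/slope) in the year's
winter–spring rainfall, defaults 0.995 / 620 mm / 45 mm — surrogates
placed so that typical baseline years recruit about two per cent of seeds
and current-epoch years less than half of that. Recruits form one cohort per
(target dune × source dune × mechanism), entering the census at age 1
(germination in the first post-fire rainy season); in individual mode
each recruit is a good producer with probability 0.25.

## Initialization

Occupied dunes start at 7 plants/ha at stand age 21 (the regional mean
fire interval; the source does not state an initial stand age). The
initial cone bank comes from a mortality-free production spin-up over
ages 5–21 under sampled climate — the calibrated quantity is the initial
plant density, and the spin-up keeps the year-1 seed release consistent
with the production submodel instead of inventing an independent bank
parameter.

## Calibration

The original study calibrates the two LDD fractions (bird cones 7%, wind
seeds 15%) by pattern-oriented modelling against two 8-year observations:
an immigration rate of 5.5–6.8% (±10% band: 4.95–7.48%) and at least two
population IDs in every initially occupied dune. `calibration_sweep`
reimplements this faithfully (0–20% × 0–20% in 1% steps, 8-year horizon,
feasibility = both patterns). The immigration rate is computed as the
percentage of living plants in immigrant cohorts at the 8-year census
(the reading consistent with genetic assignment of individuals); the
ID pattern is required to hold in a majority of replicate runs.

The same pattern-oriented logic fixes the levels of the surrogate
demography defaults (mortality curves, flower ramp and floors,
recruitment logistic): they were chosen once so the simulator sits in the
documented dynamical regime — the baseline epoch persists at the regional
mean fire interval, the current epoch collapses within a few fire cycles,
very short fire intervals are harmful, and high-quality large patches act
as sources. Within that regime all shipped comparisons are orderings, not
absolute times.

With the packaged surrogate dune map and mortality curves, the
calibrated point (7%, 15%) under scenario (iii) yields an 8-year
immigration rate around 14% — above the band's upper edge. The driver is
geometric: on a 15 km² grid holding 37 dunes, the 1250 m bird-drop disc
around a typical dune contains mostly other dunes' cells, so roughly
three quarters of bird-carried cones emigrate. The unpublished real dune
map is evidently sparser at bird range. The lower band edge and the
two-ID pattern are reproduced robustly and are what the shipped tests
assert; the surrogate map was chosen for realism of total habitat cover
(227 ha, 15%) and the printed constraints (37 dunes, 18 occupied, areas
1–54 ha), not tuned to the band's upper edge.

## Numerical choices

- All randomness flows from one root seed through `SeedSequence`
  spawning; landscape replicates get independent child streams and runs
  within a landscape are order-independent. Identical configurations are
  bit-reproducible.
- Per-seed and per-cone loops are capped at 5000 simulated units per
  cohort; beyond the cap, totals are allocated by a multinomial over the
  Monte-Carlo landing distribution (wind: one shared distribution per
  source dune per fire, since seeds from one dune are exchangeable), or
  rescaled (bird cone contents). Conservation stays exact; only
  higher-order sampling variance is approximated.
- Rounding of fractional cone/seed totals is half-up; the SDD remainder
  absorbs the slack so the partition stays exact.
- Mortality across all cohorts of a dune is one vectorized binomial
  draw; density-regulation overflow uses a multivariate hypergeometric
  draw (uniform establishment across candidate plants).
- Empty metric denominators (no colonization chains, no living
  populations) are reported as missing values, never as 0 or 100.

## Problem sizes in the shipped analyses

The test suite runs the qualitative-ordering comparisons (baseline vs
current epoch, 21- vs 5-year interval, large-first vs small-first
quality assignment) at 5 landscapes × 5 runs, and the calibration-band
check at reduced replication; `scripts/acceptance.py` recomputes the
8-year immigration rate at the full 30 × 30 design (900 runs) and the
sampling-moment checks at 100,000 draws. These sizes were chosen so the
whole reproduction runs in minutes on one CPU while keeping Monte-Carlo
error well inside the asserted margins.

## Known limitations

- Absolute persistence times depend on the surrogate mortality curves,
  flower models and recruitment parameters and should not be read as
  predictions; orderings and mechanism-level quantities are the robust
  outputs.
- The synthetic climate has no interannual autocorrelation or trend
  within an epoch.
- Fire is a single ellipse per ignition year; no spread dynamics,
  severity or season effects below dune resolution.
- No soil seed bank, inter-fire recruitment, pollination mechanics beyond
  the fertile-cone fraction, or genetics.
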