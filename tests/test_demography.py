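"""Cohort demography: seeds per cone, mortality scenarios, aging, density
regulation, fuzzy weights, flower/cone production, recruitment."""

import numpy as np
import pytest

from dunefire import (
    Cohort,
    DemographyParams,
    age_step,
    apply_interfire_mortality,
    assign_producer_class,
    density_regulation,
    flowers_per_plant,
    fuzzify_climate,
    interfire_mortality_rate,
    postfire_recruitment,
    produce_and_store_cones,
    viable_seeds_per_cone,
)
from dunefire.climate import ClimateYear
from dunefire.demography import (
    COHORT_LABELS,
    FuzzyClassConfig,
    GOOD,
    POOR,
    recruitment_mortality,
    scenario_base_rates,
)

CY = ClimateYear(wsp_prev=420.0, annual_prev=530.0, wsp_sum3=1260.0)


def make_cohort(age=10, n_poor=100, n_good=0, triple=(1, 1, 1), disp="SDD"):
    n = np.zeros(2, dtype=int)
    n[POOR], n[GOOD] = n_poor, n_good
    return Cohort(age=age, n=n, dispersal_class=disp, id_triple=triple,
                  cones=Cohort.empty_bank())


# ---------------------------------------------------------------------------
# viable seeds per cone

@pytest.mark.parametrize(
    "cone_age,scenario,expected",
    [(1, "baseline", 10.0), (1, "current", 7.0), (13, "baseline", 0.0),
     (13, "current", 0.0)],
)
def test_viable_seeds_anchor_values(cone_age, scenario, expected):
    assert viable_seeds_per_cone(cone_age, scenario) == pytest.approx(expected)


def test_viable_seeds_non_increasing_and_positive():
    v = [viable_seeds_per_cone(a, "baseline") for a in range(1, 13)]
    assert all(a >= b for a, b in zip(v, v[1:]))
    assert all(x > 0 for x in v)
    with pytest.raises(ValueError):
        viable_seeds_per_cone(0, "baseline")


# ---------------------------------------------------------------------------
# mortality

def test_weather_adjustment_is_six_points_per_100mm():
    """+100 mm wetter than the reference shifts the rate by exactly 6
    percentage points (downward)."""
    params = DemographyParams()
    wet = ClimateYear(520.0, 630.0, 1560.0)
    base = interfire_mortality_rate(1, CY, "i", "SDD-resident", 420.0, params)
    shifted = interfire_mortality_rate(1, wet, "i", "SDD-resident", 420.0, params)
    assert base - shifted == pytest.approx(0.06)


def test_zero_deviation_returns_base_curve():
    params = DemographyParams()
    for age in (1, 5, 15, 40):
        r = interfire_mortality_rate(age, CY, "ii", "SDD-resident", 420.0, params)
        expected = (params.m_spring[min(age, 15) - 1] + params.m_autumn[min(age, 15) - 1]) / 2
        assert r == pytest.approx(expected)


def test_scenario_v_is_elementwise_minimum():
    params = DemographyParams()
    for age in range(1, 16):
        r = interfire_mortality_rate(age, CY, "v", "LDD-immigrant", 420.0, params)
        assert r == pytest.approx(min(params.m_spring[age - 1], params.m_autumn[age - 1]))


def test_scenario_iii_splits_by_dispersal_class():
    params = DemographyParams()
    for age in (1, 2, 3):
        ldd = interfire_mortality_rate(age, CY, "iii", "LDD-resident", 420.0, params)
        imm = interfire_mortality_rate(age, CY, "iii", "LDD-immigrant", 420.0, params)
        sdd = interfire_mortality_rate(age, CY, "iii", "SDD-resident", 420.0, params)
        assert ldd == imm == pytest.approx(params.m_spring[age - 1])
        assert sdd == pytest.approx(params.m_autumn[age - 1])


def test_scenario_iv_splits_by_immigrant_status():
    params = DemographyParams()
    imm = interfire_mortality_rate(2, CY, "iv", "LDD-immigrant", 420.0, params)
    res = interfire_mortality_rate(2, CY, "iv", "LDD-resident", 420.0, params)
    assert imm == pytest.approx(params.m_spring[1])
    assert res == pytest.approx(params.m_autumn[1])


def test_scenario_v_never_exceeds_iii_rates():
    params = DemographyParams()
    table_v = scenario_base_rates(params, "v")
    table_iii = scenario_base_rates(params, "iii")
    assert (table_v <= table_iii + 1e-12).all()


def test_unknown_scenario_rejected():
    with pytest.raises(ValueError):
        interfire_mortality_rate(1, CY, "vi", "SDD-resident", 420.0)


def test_rate_clamped_to_unit_interval():
    params = DemographyParams()
    very_dry = ClimateYear(0.0, 0.0, 0.0)
    r = interfire_mortality_rate(1, very_dry, "i", "SDD-resident", 2000.0, params)
    assert r == 1.0


@pytest.mark.parametrize("rate,expected", [(0.0, 1000), (1.0, 0)])
def test_mortality_edge_rates(rate, expected, rng):
    c = make_cohort(n_poor=1000)
    apply_interfire_mortality(c, rate, rng)
    assert c.n_plants == expected


def test_mortality_binomial_moments(rng):
    n = 100000
    c = make_cohort(n_poor=n)
    apply_interfire_mortality(c, 0.3, rng)
    se = np.sqrt(n * 0.3 * 0.7)
    assert abs(c.n_plants - 0.7 * n) < 4 * se


def test_good_producer_bonus_neutral_at_zero(rng):
    a = make_cohort(n_poor=50000, n_good=50000)
    apply_interfire_mortality(a, 0.4, rng, good_survival_bonus=0.0)
    # both classes thinned with the same probability: shares stay close
    assert abs(a.n[POOR] - a.n[GOOD]) < 4 * np.sqrt(2 * 50000 * 0.4 * 0.6)


def test_good_producer_bonus_raises_survival(rng):
    c = make_cohort(n_poor=100000, n_good=100000)
    apply_interfire_mortality(c, 0.4, rng, good_survival_bonus=0.06)
    assert c.n[GOOD] > c.n[POOR]
    assert c.n[GOOD] / 100000 == pytest.approx(0.6 * 1.06, abs=0.01)


# ---------------------------------------------------------------------------
# aging

def test_age_step_shifts_cones_and_caps():
    c = make_cohort(age=4)
    c.cones[POOR, 0] = 5.0   # age-1 cones
    c.cones[POOR, 11] = 2.0  # age-12 cones, dropped on shift
    [c2] = age_step([c])
    assert c2.age == 5
    assert c2.cones[POOR, 1] == 5.0
    assert c2.cones[POOR, 0] == 0.0
    assert c2.cones[POOR, 11] == 0.0  # nothing aged into 12 this year


def test_longevity_cap_kills_at_41():
    c = make_cohort(age=40)
    assert age_step([c]) == []


# ---------------------------------------------------------------------------
# density regulation

def test_density_regulation_all_fit(rng):
    c = make_cohort(age=5, n_poor=10)
    out = density_regulation([c], 2500, rng)
    assert out[0].n_plants == 10


def test_density_regulation_exact_overflow(rng):
    adults = make_cohort(age=10, n_poor=2490)
    cand = make_cohort(age=5, n_poor=100)
    density_regulation([adults, cand], 2500, rng)
    assert cand.n_plants == 10
    assert adults.n_plants == 2490


def test_density_regulation_full_capacity(rng):
    adults = make_cohort(age=10, n_poor=2500)
    cand = make_cohort(age=5, n_poor=50)
    out = density_regulation([adults, cand], 2500, rng)
    assert sum(c.n_plants for c in out if c.age == 5) == 0


def test_density_regulation_hypergeometric_shares(rng):
    """Establishment shares across candidate cohorts are proportional to
    their candidate counts (multivariate hypergeometric oracle)."""
    trials, kept_a = 400, 0
    for _ in range(trials):
        adults = make_cohort(age=10, n_poor=2400)
        a = make_cohort(age=5, n_poor=300)
        b = make_cohort(age=5, n_poor=100)
        density_regulation([adults, a, b], 2500, rng)
        assert a.n_plants + b.n_plants == 100
        kept_a += a.n_plants
    mean_a = kept_a / trials
    # E[kept_a] = 100 * 300/400 = 75; hypergeometric SE per trial ~ 4.3
    assert abs(mean_a - 75.0) < 4 * 4.4 / np.sqrt(trials)


def test_capacity_never_exceeded_after_regulation(rng):
    cohorts = [make_cohort(age=10, n_poor=2000), make_cohort(age=5, n_poor=3000)]
    out = density_regulation(cohorts, 2500, rng)
    assert sum(c.n_plants for c in out) <= 2500


# ---------------------------------------------------------------------------
# fuzzy climate classes

TRI_A = FuzzyClassConfig("a", {"wsp_prev": (0.0, 100.0, 100.0, 200.0)})
TRI_B = FuzzyClassConfig("b", {"wsp_prev": (100.0, 200.0, 200.0, 300.0)})
TRAP = FuzzyClassConfig("t", {"wsp_prev": (0.0, 100.0, 200.0, 300.0)})


def cy_wsp(w):
    return ClimateYear(w, w + 100.0, 3 * w)


def test_trapezoid_plateau_gives_full_weight():
    weights = fuzzify_climate(cy_wsp(150.0), [TRAP])
    assert weights["t"] == pytest.approx(1.0)


def test_triangle_crossing_is_half_half():
    weights = fuzzify_climate(cy_wsp(150.0), [TRI_A, TRI_B])
    assert weights["a"] == pytest.approx(0.5)
    assert weights["b"] == pytest.approx(0.5)


@pytest.mark.parametrize("w", [10.0, 120.0, 260.0])
def test_weights_normalized(w):
    weights = fuzzify_climate(cy_wsp(w), [TRI_A, TRI_B, TRAP])
    assert sum(weights.values()) == pytest.approx(1.0)
    assert all(v >= 0 for v in weights.values())


def test_out_of_support_clamps_to_nearest():
    weights = fuzzify_climate(cy_wsp(1000.0), [TRI_A, TRI_B])
    assert weights["b"] == 1.0


def test_default_classes_cover_predictor_range():
    params = DemographyParams()
    for annual in (300.0, 450.0, 700.0):
        cy = ClimateYear(annual * 0.8, annual, annual * 2.4)
        weights = fuzzify_climate(cy, params.fuzzy_classes)
        assert sum(weights.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# flower and cone production

def test_no_flowers_before_maturity():
    params = DemographyParams()
    assert flowers_per_plant(3, CY, "cohort", params) == 0.0


def test_quality_coefficient_scales_flowers_exactly():
    params = DemographyParams()
    low = flowers_per_plant(20, CY, "cohort", params, quality_coefficient=1.0)
    high = flowers_per_plant(20, CY, "cohort", params, quality_coefficient=2.23)
    assert high / low == pytest.approx(2.23)


def test_age_ramp_saturates_at_15():
    params = DemographyParams()
    f15 = flowers_per_plant(15, CY, "cohort", params)
    f30 = flowers_per_plant(30, CY, "cohort", params)
    f10 = flowers_per_plant(10, CY, "cohort", params)
    assert f15 == pytest.approx(f30)
    assert f10 < f15


def test_individual_mode_good_exceeds_poor(rng):
    params = DemographyParams()
    n = 20000
    good = flowers_per_plant(20, CY, "individual", params, producer_class="good",
                             n_plants=n, rng=rng)
    poor = flowers_per_plant(20, CY, "individual", params, producer_class="poor",
                             n_plants=n, rng=rng)
    assert good > poor
    # check against the mixture's analytic mean
    from dunefire.demography import fuzzify_climate as fz

    weights = fz(CY, params.fuzzy_classes)
    for cls, sample in (("good", good), ("poor", poor)):
        mean = sum(
            weights[fc.name] * params.flower_dists[(cls, fc.name)].mean
            for fc in params.fuzzy_classes
        )
        assert sample == pytest.approx(mean, rel=0.05)


@pytest.mark.parametrize("epoch,frac", [("baseline", 0.90), ("current", 0.65)])
def test_flower_to_cone_conversion(epoch, frac, rng):
    """100 flowers yield 90 (baseline) / 65 (current) fertile cones in
    expectation mode."""
    params = DemographyParams()
    params.flowers_max = 100.0
    c = make_cohort(age=20, n_poor=10)
    produce_and_store_cones(c, CY, params, "cohort", epoch, "baseline", 1.0, rng)
    assert c.cones[POOR, 0] == pytest.approx(100.0 * frac)


def test_zero_flowers_leave_bank_unchanged(rng):
    params = DemographyParams()
    params.flowers_max = 0.0
    c = make_cohort(age=20, n_poor=10)
    c.cones[POOR, 3] = 7.0
    produce_and_store_cones(c, CY, params, "cohort", "baseline", "baseline", 1.0, rng)
    assert c.cones[POOR, 0] == 0.0
    assert c.cones[POOR, 3] == 7.0


# ---------------------------------------------------------------------------
# producer classes and recruitment

def test_producer_split_moments(rng):
    n = 400000
    n_good, n_poor = assign_producer_class(n, rng)
    assert n_good + n_poor == n
    se = np.sqrt(n * 0.25 * 0.75)
    assert abs(n_good - 0.25 * n) < 4 * se


def test_producer_split_edges(rng):
    assert assign_producer_class(0, rng) == (0, 0)
    assert assign_producer_class(1000, rng, good_fraction=0.0) == (0, 1000)


def test_recruitment_mortality_bounds_and_monotonicity():
    params = DemographyParams()
    rains = np.linspace(0, 1500, 40)
    m = [recruitment_mortality(r, params) for r in rains]
    assert all(0 <= x <= params.rec_upper_limit for x in m)
    assert all(a >= b for a, b in zip(m, m[1:]))  # wetter -> fewer deaths


def test_recruitment_edge_cases(rng):
    params = DemographyParams()
    params.rec_upper_limit = 0.0  # m_rec = 0 -> all seeds recruit
    assert postfire_recruitment(1000, CY, params, rng) == 1000
    assert postfire_recruitment(0, CY, params, rng) == 0


def test_recruitment_binomial_moments(rng):
    params = DemographyParams()
    m = recruitment_mortality(CY.wsp_prev, params)
    seeds = 100000
    got = postfire_recruitment(seeds, CY, params, rng)
    se = np.sqrt(seeds * m * (1 - m))
    assert abs(got - seeds * (1 - m)) < 4 * se


def test_cohort_labels():
    assert make_cohort(disp="SDD").label == "SDD-resident"
    assert make_cohort(disp="LDD", triple=(1, 2, 2)).label == "LDD-resident"
    c = make_cohort(disp="LDD", triple=(1, 1, 2))
    assert c.label == "LDD-immigrant"
    assert c.is_immigrant
    assert COHORT_LABELS.index(c.label) == c.label_index
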