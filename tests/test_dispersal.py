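"""Seed release and the three dispersal channels: conservation, kernels,
landing classification."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from dunefire import (
    DispersalParams,
    classify_landing,
    disperse_cones_birds,
    disperse_seeds_wind,
    release_on_burn,
    sample_wind_distances,
)
from dunefire.dispersal import disperse_cohort_release, wind_landing_distribution


PARAMS = DispersalParams()


def test_release_arithmetic():
    v = 10.0 * 0.95 ** np.arange(12)
    cones = np.zeros(12)
    cones[0] = 5  # five 1-year-old cones
    cones_total, seeds = release_on_burn(cones, v)
    assert cones_total == 5
    assert seeds == pytest.approx(50.0)


def test_release_empty_and_stale_banks():
    v = 10.0 * 0.95 ** np.arange(12)
    assert release_on_burn(np.zeros(12), v) == (0.0, 0.0)
    # cones only beyond the viability horizon contribute nothing: V(13)=0,
    # which the bank encodes by having no bin beyond age 12


def test_bird_fraction_of_cones(two_dune_landscape, rng):
    src = two_dune_landscape.dunes[0]
    _, _, n_cones, _ = disperse_cones_birds(
        100.0, src, two_dune_landscape, PARAMS, "baseline", 10.0, rng
    )
    assert n_cones == 7  # 7% of 100 cones


def test_bird_zero_cones(two_dune_landscape, rng):
    deposits, removed, n, cells = disperse_cones_birds(
        0.0, two_dune_landscape.dunes[0], two_dune_landscape, PARAMS,
        "baseline", 10.0, rng,
    )
    assert deposits == [] and removed == 0.0 and n == 0 and len(cells) == 0


def test_bird_drops_within_1250m(two_dune_landscape, rng):
    src = two_dune_landscape.dunes[0]
    g = two_dune_landscape.grid
    _, _, _, cells = disperse_cones_birds(
        10000 / PARAMS.p_bird, src, two_dune_landscape, PARAMS, "baseline",
        10.0, rng,
    )
    d = cdist(g.cell_centers(cells), g.cell_centers(src.cells)).min(axis=1)
    assert (d <= 1250.0).all()


def test_bird_drops_only_on_dune_cells(two_dune_landscape, rng):
    src = two_dune_landscape.dunes[0]
    _, _, _, cells = disperse_cones_birds(
        5000 / PARAMS.p_bird, src, two_dune_landscape, PARAMS, "baseline",
        10.0, rng,
    )
    ids = two_dune_landscape.cell_to_dune[cells[:, 0], cells[:, 1]]
    assert (ids >= 0).all()


@pytest.mark.parametrize(
    "epoch,mean",
    [("baseline", 10.08), ("current", 7.33)],
)
def test_follicle_model_means(epoch, mean, rng):
    draws = PARAMS.sample_follicles(100000, epoch, rng)
    se = draws.std(ddof=1) / np.sqrt(len(draws))
    assert abs(draws.mean() - mean) < 4 * se


def test_wind_kernel_log_moments(rng):
    d = sample_wind_distances(100000, rng)
    logs = np.log(d)
    se_mean = logs.std(ddof=1) / np.sqrt(len(logs))
    assert abs(logs.mean() - 6.79) < 4 * se_mean
    assert abs(logs.std(ddof=1) - 0.68) < 0.01


def test_wind_zero_seeds(two_dune_landscape, rng):
    deposits, n = disperse_seeds_wind(
        0.0, two_dune_landscape.dunes[0], two_dune_landscape, PARAMS, rng
    )
    assert deposits == [] and n == 0


def test_wind_partition_is_exact(two_dune_landscape, rng):
    """resident + immigrant + lost = n_wind, for direct and multinomial paths."""
    src = two_dune_landscape.dunes[0]
    for seeds_remaining in (500 / PARAMS.p_wind, 40000 / PARAMS.p_wind):
        deposits, n_wind = disperse_seeds_wind(
            seeds_remaining, src, two_dune_landscape, PARAMS, rng
        )
        assert sum(d.seeds for d in deposits) == n_wind
        labels = {d.label() for d in deposits}
        assert labels <= {"resident", "immigrant", "lost"}


def test_wind_shared_distribution_partition(two_dune_landscape, rng):
    src = two_dune_landscape.dunes[0]
    dist = wind_landing_distribution(src, two_dune_landscape, PARAMS, rng)
    deposits, n_wind = disperse_seeds_wind(
        9000 / PARAMS.p_wind, src, two_dune_landscape, PARAMS, rng, dist
    )
    assert sum(d.seeds for d in deposits) == n_wind


@pytest.mark.parametrize(
    "point,expected",
    [((-50.0, 100.0), "lost"), ((5000.0, 100.0), "lost")],
)
def test_classify_outside_grid_is_lost(two_dune_landscape, point, expected):
    assert classify_landing(point, two_dune_landscape, 1) == expected


def test_classify_resident_immigrant_swale(two_dune_landscape):
    ls = two_dune_landscape
    g = ls.grid
    for dune in ls.dunes:
        r, c = dune.cells[0]
        point = ((c + 0.5) * g.cell_m, (r + 0.5) * g.cell_m)
        assert classify_landing(point, ls, dune.dune_id) == "resident"
        other = [d for d in ls.dunes if d.dune_id != dune.dune_id][0]
        assert classify_landing(point, ls, other.dune_id) == "immigrant"
    swale = np.argwhere(ls.cell_to_dune < 0)[0]
    point = ((swale[1] + 0.5) * g.cell_m, (swale[0] + 0.5) * g.cell_m)
    assert classify_landing(point, ls, 1) == "lost"


def test_full_pipeline_seed_conservation_without_birds(two_dune_landscape, rng):
    """With the bird channel off, wind + SDD seeds partition the released
    total exactly."""
    params = DispersalParams(p_bird=0.0)
    src = two_dune_landscape.dunes[0]
    v = 10.0 * 0.95 ** np.arange(12)
    cones_total, seeds_total = release_on_burn(np.full(12, 20.0), v)
    deposits = disperse_cohort_release(
        cones_total, seeds_total, src, two_dune_landscape, params,
        "baseline", 10.0, rng,
    )
    wind = sum(d.seeds for d in deposits if d.mechanism == "wind")
    sdd = sum(d.seeds for d in deposits if d.mechanism == "SDD")
    assert wind + sdd == pytest.approx(seeds_total)
    assert wind == int(np.floor(params.p_wind * seeds_total + 0.5))


def test_full_pipeline_conservation_with_birds(two_dune_landscape, rng):
    """With birds on, the wind share is consistent with the post-bird
    remainder: wind = round(p_wind * (wind + SDD)), and deposited bird
    seeds never exceed the removed cone content."""
    src = two_dune_landscape.dunes[0]
    v = 10.0 * 0.95 ** np.arange(12)
    cones_total, seeds_total = release_on_burn(np.full(12, 20.0), v)
    deposits = disperse_cohort_release(
        cones_total, seeds_total, src, two_dune_landscape, PARAMS,
        "baseline", 10.0, rng,
    )
    wind = sum(d.seeds for d in deposits if d.mechanism == "wind")
    sdd = sum(d.seeds for d in deposits if d.mechanism == "SDD")
    bird = sum(d.seeds for d in deposits if d.mechanism == "bird")
    remaining = wind + sdd
    assert wind == int(np.floor(PARAMS.p_wind * remaining + 0.5))
    assert bird <= seeds_total - remaining + 1e-9  # deposited <= removed content
    assert remaining < seeds_total  # birds removed a positive share


def test_sdd_stays_in_source(two_dune_landscape, rng):
    src = two_dune_landscape.dunes[0]
    v = 10.0 * 0.95 ** np.arange(12)
    cones = np.full(12, 10.0)
    cones_total, seeds_total = release_on_burn(cones, v)
    deposits = disperse_cohort_release(
        cones_total, seeds_total, src, two_dune_landscape, PARAMS,
        "baseline", 10.0, rng,
    )
    for d in deposits:
        if d.mechanism == "SDD":
            assert d.dune_id == src.dune_id
            assert d.label() == "resident"


def test_no_ldd_reduces_to_isolated_populations(two_dune_landscape, rng):
    """p_bird = p_wind = 0: every seed is SDD in the source dune."""
    params = DispersalParams(p_bird=0.0, p_wind=0.0)
    src = two_dune_landscape.dunes[0]
    v = 10.0 * 0.95 ** np.arange(12)
    cones_total, seeds_total = release_on_burn(np.full(12, 50.0), v)
    deposits = disperse_cohort_release(
        cones_total, seeds_total, src, two_dune_landscape, params,
        "baseline", 10.0, rng,
    )
    assert {d.mechanism for d in deposits} == {"SDD"}
    assert sum(d.seeds for d in deposits) == pytest.approx(seeds_total)


def test_invalid_fractions_rejected():
    with pytest.raises(ValueError):
        DispersalParams(p_bird=1.5)
    with pytest.raises(ValueError):
        DispersalParams(p_wind=-0.1)
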