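"""Fire scheduling, elliptical patchy-fire geometry and burn resolution.

Fires follow a deterministic schedule anchored at the year-1
landscape-wide burn: subsequent ignitions occur every `interval` years.
Each ignition draws a random ellipse; the 100% "baseline" size is the
ellipse circumscribing the rectangular study area (it passes through all
four corners), and other sizes scale its area linearly.  A dune overlapped
by the ellipse -- at any cell centre, no matter how marginally -- is a burn
candidate, and actually burns with a probability set by its fuel load,
proxied by time since last fire: never under 3 years, always over 12, and
linearly in between.  A candidate that burns, burns entirely.

An optional stochastic mode replaces the fixed schedule with a yearly
Bernoulli ignition at rate 1/interval; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import GridSpec, Landscape


@dataclass(frozen=True)
class FireEvent:
    center_x: float
    center_y: float
    semi_axis_x: float
    semi_axis_y: float
    orientation: float  # radians

    def __post_init__(self) -> None:
        if self.semi_axis_x <= 0 or self.semi_axis_y <= 0:
            raise ValueError("fire ellipse semi-axes must be positive")

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask: which (x, y) points fall inside (or on) the ellipse."""
        xy = np.atleast_2d(xy)
        dx = xy[:, 0] - self.center_x
        dy = xy[:, 1] - self.center_y
        ct, st = np.cos(self.orientation), np.sin(self.orientation)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        return (u / self.semi_axis_x) ** 2 + (v / self.semi_axis_y) ** 2 <= 1.0 + 1e-12

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_axis_x * self.semi_axis_y)


@dataclass(frozen=True)
class FireRegime:
    interval: int = 21
    size_pct: float = 100.0
    stochastic: bool = False

    def __post_init__(self) -> None:
        if self.interval < 1:
            raise ValueError("fire interval must be >= 1 year")
        if self.size_pct <= 0:
            raise ValueError("fire size must be positive")


def fire_due(
    year: int, regime: FireRegime, rng: np.random.Generator | None = None
) -> bool:
    """True in years with an ignition: always in year 1 (landscape-wide
    burn), then at years 1 + k*interval on the deterministic schedule, or
    by a Bernoulli(1/interval) draw in stochastic mode."""
    if year < 1:
        raise ValueError("year must be >= 1")
    if year == 1:
        return True
    if regime.stochastic:
        if rng is None:
            raise ValueError("stochastic fire mode requires an rng")
        return bool(rng.random() < 1.0 / regime.interval)
    return (year - 1) % regime.interval == 0


def baseline_semi_axes(grid: GridSpec) -> tuple[float, float]:
    """Semi-axes of the ellipse circumscribing the study-area rectangle."""
    return (grid.width_m / 2 * np.sqrt(2.0), grid.height_m / 2 * np.sqrt(2.0))


def sample_fire_ellipse(
    regime: FireRegime, grid: GridSpec, rng: np.random.Generator
) -> FireEvent:
    """Random patchy-fire ellipse: centre uniform over cell centres,
    orientation uniform on [0, pi); both semi-axes scale by
    sqrt(size_pct/100) so the burnable area scales linearly with size."""
    a0, b0 = baseline_semi_axes(grid)
    scale = np.sqrt(regime.size_pct / 100.0)
    row = rng.integers(grid.n_rows)
    col = rng.integers(grid.n_cols)
    cx = (col + 0.5) * grid.cell_m
    cy = (row + 0.5) * grid.cell_m
    theta = rng.uniform(0.0, np.pi)
    return FireEvent(cx, cy, a0 * scale, b0 * scale, theta)


def burn_probability(tsf: int) -> float:
    """Fuel-load burn probability given integer time since fire (years):
    0 below 3 years, 1 above 12, linear ramp (tsf - 3)/9 in between."""
    if tsf < 0:
        raise ValueError("time since fire must be >= 0")
    if tsf < 3:
        return 0.0
    if tsf > 12:
        return 1.0
    return (tsf - 3) / 9.0


def resolve_burns(
    landscape: Landscape,
    fire_event: FireEvent,
    tsf: dict[int, int],
    rng: np.random.Generator,
) -> set[int]:
    """Dune ids burned by this fire.

    A dune is a candidate iff at least one of its cell centres lies inside
    the ellipse; each candidate burns independently with
    burn_probability(tsf), evaluated before any same-year update."""
    burned: set[int] = set()
    for dune in landscape.dunes:
        xy = landscape.grid.cell_centers(dune.cells)
        if not fire_event.contains(xy).any():
            continue
        if rng.random() < burn_probability(tsf[dune.dune_id]):
            burned.add(dune.dune_id)
    return burned
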