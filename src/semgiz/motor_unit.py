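"""Motor-unit population sampling: fiber counts, velocities and geometry.

Fiber counts follow the exponential motor-neuron size model

    N_mf(i) = a * exp(ln(R) * i / N_mu),        i = 0 .. N_mu - 1,

with the growth ratio R chosen so the pool totals a prescribed fiber count.
Mean conduction velocity rises linearly with the unit id (larger units are
faster); individual fibers scatter normally around their unit's mean.

Fiber geometry is sampled from a cylindrical innervation-zone region plus two
myotendinous-junction windows: the innervation point's axial coordinate is
uniform over a width ``iz_width`` about the zone center, its (y, z) uniform
over a disc of radius ``iz_radius``, and the two fiber ends are uniform over
windows of widths ``w_tl`` / ``w_tr`` centered ``l_left`` to the left and
``l_right`` to the right of the zone center.  All fibers run parallel to the
x axis through their innervation point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GeometrySet",
    "MuscleFiber",
    "MotorUnit",
    "PopulationModel",
    "n_fibers",
    "solve_range_ratio",
    "mu_conduction_velocity",
    "sample_fiber_cv",
    "sample_motor_unit",
]

#: Radius of a disc of area 10 cm^2, the default innervation-zone radius (m).
DEFAULT_IZ_RADIUS = math.sqrt(10e-4 / math.pi)


@dataclass(frozen=True)
class GeometrySet:
    """Regions from which one motor unit's fiber geometry is drawn (all m)."""

    iz_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    iz_radius: float = DEFAULT_IZ_RADIUS
    iz_width: float = 0.02
    l_left: float = 0.075
    l_right: float = 0.075
    w_tl: float = 0.005
    w_tr: float = 0.005

    def __post_init__(self) -> None:
        if min(self.iz_radius, self.iz_width, self.l_left, self.l_right, self.w_tl, self.w_tr) <= 0:
            raise ValueError("all geometry widths and radii must be > 0")
        if self.l_left + self.l_right <= self.iz_width:
            raise ValueError("fibers must extend beyond the innervation zone")

    @property
    def max_ip_to_junction(self) -> float:
        """Largest admissible innervation-point-to-junction distance (m)."""
        half_w = self.iz_width / 2.0
        left = self.l_left + self.w_tl / 2.0 + half_w
        right = self.l_right + self.w_tr / 2.0 + half_w
        return max(left, right)


@dataclass(frozen=True)
class MuscleFiber:
    """One fiber: reference point at the left junction, axis angles, extent.

    ``innervation_coord`` is the axial coordinate of the innervation point
    measured from ``ref_point``; ``cv`` is the conduction velocity (m/s).
    """

    ref_point: tuple[float, float, float]
    alpha: float
    beta: float
    length: float
    innervation_coord: float
    cv: float

    def __post_init__(self) -> None:
        if not 0 < self.innervation_coord < self.length:
            raise ValueError("innervation point must lie strictly inside the fiber")
        if not self.cv > 0:
            raise ValueError("conduction velocity must be > 0")


@dataclass(frozen=True)
class MotorUnit:
    mu_id: int
    fibers: tuple[MuscleFiber, ...]
    geometry: GeometrySet
    mean_cv: float

    @property
    def true_iz_center_x(self) -> float:
        """Ground-truth center: mean global innervation x over the fibers."""
        return float(np.mean([f.ref_point[0] + f.innervation_coord for f in self.fibers]))


@dataclass
class PopulationModel:
    """Pool-level parameters of the exponential fiber-count model."""

    n_mu: int = 774
    n_fibers_total: float = 580e3
    smallest_mu: float = 21.0
    range_ratio: float | None = None  # solved on demand
    v_min: float = 2.5
    v_max: float = 5.4
    cv_sigma: float = 0.22
    cv_floor: float = 0.5  # non-physical-draw guard, m/s

    def __post_init__(self) -> None:
        if self.smallest_mu < 1 or self.n_mu < 2 or not self.v_min < self.v_max or self.cv_sigma < 0:
            raise ValueError(f"invalid population model: {self}")

    def solved_range_ratio(self) -> float:
        if self.range_ratio is None:
            self.range_ratio = solve_range_ratio(self)
        return self.range_ratio


def solve_range_ratio(pop: PopulationModel) -> float:
    """Growth ratio R > 1 normalizing the pool to ``n_fibers_total`` fibers.

    Solves sum_{i=0}^{n_mu-1} a * exp(ln(R) i / n_mu) = total by monotone
    bracketing; the residual is below one fiber.
    """
    a, n, total = pop.smallest_mu, pop.n_mu, pop.n_fibers_total
    if not a * n < total:
        raise ValueError("total fiber count must exceed n_mu * smallest_mu")
    i = np.arange(n)

    def residual(r: float) -> float:
        return a * float(np.sum(np.exp(np.log(r) * i / n))) - total

    hi = 2.0
    while residual(hi) < 0:
        hi *= 10.0
        if hi > 1e12:  # pragma: no cover
            raise ValueError("no bracket for the range ratio")
    return float(brentq(residual, 1.0 + 1e-12, hi, xtol=1e-10, rtol=1e-14))


def n_fibers(i: int, pop: PopulationModel) -> int:
    """Fiber count of unit ``i``, rounded to the nearest integer."""
    if not 0 <= i <= pop.n_mu:
        raise ValueError(f"motor unit id {i} outside [0, {pop.n_mu}]")
    r = pop.solved_range_ratio()
    return int(np.round(pop.smallest_mu * math.exp(math.log(r) * i / pop.n_mu)))


def mu_conduction_velocity(i: int, pop: PopulationModel) -> float:
    """Mean conduction velocity of unit ``i`` (m/s), linear in the id."""
    if not 0 <= i <= pop.n_mu - 1:
        raise ValueError(f"motor unit id {i} outside [0, {pop.n_mu - 1}]")
    return (pop.v_max - pop.v_min) / (pop.n_mu - 1) * i + pop.v_min


def sample_fiber_cv(i: int, pop: PopulationModel, rng: np.random.Generator) -> float:
    """One fiber velocity ~ Normal(mu_conduction_velocity(i), cv_sigma)."""
    v = rng.normal(mu_conduction_velocity(i, pop), pop.cv_sigma)
    return float(max(v, pop.cv_floor))


def _uniform_disc(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Rejection sampling of n points uniform on a disc; exact, no angular bias."""
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        cand = rng.uniform(-radius, radius, size=(2 * (n - filled) + 8, 2))
        keep = cand[np.einsum("ij,ij->i", cand, cand) <= radius**2]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def sample_motor_unit(
    i: int,
    pop: PopulationModel,
    geom: GeometrySet,
    rng: np.random.Generator,
    scale: float = 1.0,
) -> MotorUnit:
    """Draw one motor unit's fiber population from a geometry set.

    ``scale`` uniformly reduces the fiber count (at least one fiber is kept)
    for reduced-size runs; the geometry and velocity statistics are untouched.
    """
    n = max(1, int(round(n_fibers(i, pop) * scale)))
    cx, cy, cz = geom.iz_center
    fibers = []
    while len(fibers) < n:
        m = n - len(fibers)
        ivx = rng.uniform(cx - geom.iz_width / 2, cx + geom.iz_width / 2, size=m)
        yz = _uniform_disc(m, geom.iz_radius, rng) + np.array([cy, cz])
        left = rng.uniform(
            cx - geom.l_left - geom.w_tl / 2, cx - geom.l_left + geom.w_tl / 2, size=m
        )
        right = rng.uniform(
            cx + geom.l_right - geom.w_tr / 2, cx + geom.l_right + geom.w_tr / 2, size=m
        )
        for k in range(m):
            if not left[k] < ivx[k] < right[k]:  # cannot occur with sane geometry
                continue
            fibers.append(
                MuscleFiber(
                    ref_point=(float(left[k]), float(yz[k, 0]), float(yz[k, 1])),
                    alpha=0.0,
                    beta=0.0,
                    length=float(right[k] - left[k]),
                    innervation_coord=float(ivx[k] - left[k]),
                    cv=sample_fiber_cv(i, pop, rng),
                )
            )
    return MotorUnit(
        mu_id=i,
        fibers=tuple(fibers),
        geometry=geom,
        mean_cv=mu_conduction_velocity(i, pop),
    )
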