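"""Point-source potentials in an unbounded, isotropic, resistive medium.

Under the quasi-static assumption the potential produced by the concentrated
sources of one fiber at an observation point P is

    phi(P, t) = 1 / (4 pi sigma_e) * sum_k  i_k(t) / r_k(t),

summed over the six concentrated currents (three per traveling side).  Time
enters only through the instantaneous source states, so every time sample is
an independent computation.  sigma_e is a pure scale factor of the potential
and cancels in every delay-based estimate downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .source_model import ActionPotentialShape, tripole_arrays

__all__ = [
    "Electrode",
    "Medium",
    "SingularConfigurationError",
    "fiber_direction",
    "source_to_electrode_distance",
    "fiber_potential",
    "motor_unit_potential",
    "motor_unit_potentials",
]


class SingularConfigurationError(ValueError):
    """Raised when an electrode coincides with a concentrated source."""


@dataclass(frozen=True)
class Electrode:
    """Ideal point electrode at ``position`` (m) in the global frame."""

    position: np.ndarray
    id: int = 0


@dataclass(frozen=True)
class Medium:
    """Homogeneous extracellular medium with conductivity ``sigma_e`` (S/m)."""

    sigma_e: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma_e > 0:
            raise ValueError("sigma_e must be > 0")


def fiber_direction(fiber) -> np.ndarray:
    """Unit vector of the fiber axis from its elevation/azimuth angles."""
    ca, sa = np.cos(fiber.alpha), np.sin(fiber.alpha)
    cb, sb = np.cos(fiber.beta), np.sin(fiber.beta)
    return np.array([cb * ca, sb * ca, -sa])


def source_to_electrode_distance(c, fiber, electrode: Electrode):
    """Distance (m) from an axial source coordinate ``c`` to an electrode.

    ``c`` is measured along the fiber axis from the fiber's reference point at
    the left myotendinous junction.
    """
    c = np.asarray(c, dtype=float)
    u = fiber_direction(fiber)
    ref = np.asarray(fiber.ref_point, dtype=float)
    pe = np.asarray(electrode.position, dtype=float)
    diff = c[..., None] * u + (ref - pe)
    r = np.linalg.norm(diff, axis=-1)
    if np.any(r == 0.0):
        raise SingularConfigurationError("electrode coincides with a source point")
    return r if r.ndim else float(r)


def fiber_potential(t, fiber, shape: ActionPotentialShape, medium: Medium, electrode: Electrode):
    """Potential (V) of one fiber's six concentrated sources at times ``t``."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    phi = np.zeros_like(t)
    for side in ("left", "right"):
        cur, pos = tripole_arrays(t, fiber, shape, side)  # (3, T)
        r = source_to_electrode_distance(pos.ravel(), fiber, electrode).reshape(pos.shape)
        phi += np.sum(cur / r, axis=0)
    phi /= 4.0 * np.pi * medium.sigma_e
    return phi if np.ndim(t) and t.size > 1 else float(phi[0])


def motor_unit_potential(t, motor_unit, shape: ActionPotentialShape, medium: Medium, electrode: Electrode):
    """Sum of ``fiber_potential`` over all fibers of the unit."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    phi = np.zeros_like(t)
    for fiber in motor_unit.fibers:
        phi += fiber_potential(t, fiber, shape, medium, electrode)
    return phi if t.size > 1 else float(phi[0])


def motor_unit_potentials(
    t: np.ndarray,
    motor_unit,
    shape: ActionPotentialShape,
    medium: Medium,
    electrode_positions: np.ndarray,
    chunk_elements: int = 8_000_000,
) -> np.ndarray:
    """Potentials of a whole unit at many electrodes: array (n_electrodes, T).

    Equivalent to looping ``fiber_potential`` over fibers and electrodes but
    vectorized; intended for parallel-fiber geometries of any size.  Work is
    chunked over electrodes to bound memory.
    """
    t = np.asarray(t, dtype=float)
    epos = np.asarray(electrode_positions, dtype=float)
    n_e = epos.shape[0]
    out = np.zeros((n_e, t.size))
    for fiber in motor_unit.fibers:
        u = fiber_direction(fiber)
        ref = np.asarray(fiber.ref_point, dtype=float)
        curs, poss = [], []
        for side in ("left", "right"):
            c, p = tripole_arrays(t, fiber, shape, side)
            curs.append(c)
            poss.append(p)
        cur = np.concatenate(curs, axis=0)  # (6, T)
        pos = np.concatenate(poss, axis=0)
        # Decompose electrode offsets into along-axis and perpendicular parts:
        # r^2 = (pos - d.u)^2 + (|d|^2 - (d.u)^2) with d = P_E - ref.
        d = epos - ref[None, :]
        du = d @ u
        dperp2 = np.einsum("ex,ex->e", d, d) - du**2
        chunk = max(1, chunk_elements // (6 * t.size))
        for j0 in range(0, n_e, chunk):
            sl = slice(j0, min(j0 + chunk, n_e))
            r2 = (pos[None, :, :] - du[sl, None, None]) ** 2 + dperp2[sl, None, None]
            if np.any(r2 == 0.0):
                raise SingularConfigurationError("electrode coincides with a source point")
            out[sl] += np.sum(cur[None, :, :] / np.sqrt(r2), axis=1)
    out /= 4.0 * np.pi * medium.sigma_e
    return out
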