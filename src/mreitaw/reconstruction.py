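"""Conductivity reconstruction by transversal J-substitution.

Two flux-density images measured under orthogonal current injections are
compared with those of a homogeneous reference model.  A single
differentiation of the data mismatch yields a pointwise conductivity
update

    sigma = sigma_H - (1/mu0) * sum_n rot_perp(Bz_n - Bz_n^H) . grad u_n^H
                              / sum_n |grad u_n^H|^2

with ``rot_perp f = (df/dy, -df/dx)``.  Because the update is local, noise
in one region does not propagate into its neighbors — the property that
makes a position-adaptive postprocessing filter effective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .forward_model import (
    MU0,
    FluxDensityImage,
    VoltageMap,
    bz_from_current,
    current_density,
    solve_voltage,
)
from .grid import Grid, check_same_grid, masked_gradient
from .grid import perp_gradient as _perp_gradient
from .phantom_sim import ConductivityImage, ElectrodeConfig

__all__ = [
    "HomogeneousReference",
    "homogeneous_reference",
    "perp_gradient",
    "transversal_j_substitution",
]


def perp_gradient(
    f: np.ndarray, grid: Grid, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rotated transverse gradient ``(df/dy, -df/dx)``, shared stencil."""
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    return _perp_gradient(f, mask, grid.pixel_size)


@dataclass
class HomogeneousReference:
    """Voltages and flux densities of the homogeneous model sigma_H.

    Computed on the identical grid, support and electrode setup as the
    measured data; ``u_grads`` caches ``grad u_n^H`` for the update.
    """

    sigma_h: float
    u: tuple[VoltageMap, ...]
    bz: tuple[FluxDensityImage, ...]
    u_grads: tuple[tuple[np.ndarray, np.ndarray], ...]
    grid: Grid
    support: np.ndarray
    electrodes: tuple[ElectrodeConfig, ...]


def homogeneous_reference(
    sigma_h: float,
    grid: Grid,
    electrodes: Sequence[ElectrodeConfig],
    support: np.ndarray,
    *,
    kernel: str = "tall",
) -> HomogeneousReference:
    """Solve the forward model with constant ``sigma_h`` per injection."""
    if not sigma_h > 0:
        raise ValueError("sigma_H must be positive")
    support = np.asarray(support, dtype=bool)
    sigma = ConductivityImage(
        np.where(support, sigma_h, 0.0), grid, support=support
    )
    us, bzs, grads = [], [], []
    for n, elec in enumerate(electrodes, start=1):
        u = solve_voltage(sigma, elec)
        j = current_density(sigma, u)
        bz = bz_from_current(j, elec.thickness, kernel=kernel, injection=n)
        us.append(u)
        bzs.append(bz)
        grads.append(masked_gradient(u.values, support, grid.pixel_size))
    return HomogeneousReference(
        sigma_h, tuple(us), tuple(bzs), tuple(grads), grid, support,
        tuple(electrodes),
    )


def transversal_j_substitution(
    bz_1: FluxDensityImage,
    bz_2: FluxDensityImage,
    ref: HomogeneousReference,
    eps_denominator: float = 1e-6,
) -> ConductivityImage:
    """Single-pass transversal J-substitution conductivity image.

    The denominator ``sum_n |grad u_n^H|^2`` is floored at
    ``eps_denominator`` times its maximum to guard pixels that carry
    almost no reference current (e.g. in the shadow of the electrodes);
    floored pixels are flagged in ``floored_mask`` of the result.
    """
    grid = check_same_grid(bz_1.grid, bz_2.grid, ref.grid)
    support = ref.support
    p = grid.pixel_size

    num = np.zeros(grid.shape)
    den = np.zeros(grid.shape)
    for bz_meas, bz_ref, (ux, uy) in zip((bz_1, bz_2), ref.bz, ref.u_grads):
        diff = np.where(support, bz_meas.values - bz_ref.values, 0.0)
        gx, gy = _perp_gradient(diff, support, p)
        num += gx * ux + gy * uy
        den += ux**2 + uy**2

    den_max = den[support].max() if support.any() else 0.0
    if den_max == 0.0:
        raise ValueError("reference model carries no current on the support")
    floor = eps_denominator * den_max
    floored = support & (den < floor)
    sigma = np.where(support, ref.sigma_h - num / (MU0 * np.maximum(den, floor)), 0.0)
    out = ConductivityImage(sigma, grid, support=support)
    out.floored_mask = floored
    return out
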