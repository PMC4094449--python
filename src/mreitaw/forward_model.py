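"""Forward physics and noisy acquisition.

Given a conductivity map and an electrode pair this module solves the
Neumann conductivity problem

    div(sigma grad u) = 0  in the support,   -sigma du/dn = g  on its boundary,

forms the current density ``J = -sigma grad u``, evaluates the induced
magnetic flux density ``Bz`` by a discrete Biot-Savart sum, and simulates
the complex MR acquisition with reversed current polarities from which
``Bz`` is extracted as a phase difference:

    Bz = arg(S+ conj(S-)) / (2 gamma Tc).

The flux-density noise model is the standard one for spin-echo phase
imaging: ``sd(Bz) = 1 / (2 gamma Tc Y)`` with ``Y`` the magnitude-image
SNR, valid for ``Y`` above about 2.8; below that threshold the map is
clamped and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.signal import fftconvolve

from .grid import Grid, check_same_grid, masked_gradient, shifted
from .phantom_sim import ConductivityImage, ElectrodeConfig, MagnitudeImage

#: gyromagnetic ratio of the proton, rad / (T s)
GAMMA = 26.75e7
#: magnetic permeability of free space, T m / A
MU0 = 4.0e-7 * np.pi

#: magnitude-SNR validity threshold of the flux-density noise model
SNR_VALIDITY_THRESHOLD = 2.8

__all__ = [
    "GAMMA",
    "MU0",
    "SNR_VALIDITY_THRESHOLD",
    "VoltageMap",
    "CurrentDensityMap",
    "FluxDensityImage",
    "ComplexImagePair",
    "NoiseStdMap",
    "solve_voltage",
    "current_density",
    "bz_from_current",
    "simulate_acquisition",
    "extract_bz",
    "noise_std_map",
    "measured_magnitude",
]


@dataclass
class VoltageMap:
    """Voltage u in volts, zero-mean over the support (gauge fixing)."""

    values: np.ndarray
    grid: Grid
    support: np.ndarray


@dataclass
class CurrentDensityMap:
    jx: np.ndarray  # A/m^2
    jy: np.ndarray
    grid: Grid
    support: np.ndarray


@dataclass
class FluxDensityImage:
    """z-component of the magnetic flux density, tesla."""

    values: np.ndarray
    grid: Grid
    injection: int | None = None  # 1 or 2 for the orthogonal injections
    tc: float | None = None  # current injection time, s
    invalid_mask: np.ndarray | None = None


@dataclass
class ComplexImagePair:
    """Complex images acquired with positive/negative current pulses."""

    s_plus: np.ndarray
    s_minus: np.ndarray
    tc: float
    grid: Grid
    gamma: float = GAMMA
    injection: int | None = None
    seed: int | None = None


@dataclass
class NoiseStdMap:
    """Per-pixel noise standard deviation of measured Bz, tesla."""

    values: np.ndarray
    low_snr_mask: np.ndarray
    grid: Grid
    tc: float
    snr_threshold: float = SNR_VALIDITY_THRESHOLD


# ---------------------------------------------------------------------------
# voltage / current density


def solve_voltage(sigma: ConductivityImage, electrodes: ElectrodeConfig) -> VoltageMap:
    """Solve the Neumann conductivity problem on the support.

    Finite-volume 5-point stencil with harmonic averaging of sigma on
    faces; the electrode current is lumped onto the boundary faces.  The
    rank-deficient system is closed with a zero-mean constraint (Lagrange
    multiplier), which also fixes the voltage gauge.
    """
    check_same_grid(sigma.grid, electrodes.grid)
    mask = sigma.support
    n = int(mask.sum())
    if n == 0:
        raise ValueError("conductivity support is empty")
    if np.any(sigma.values[mask] <= 0):
        raise ValueError("conductivity must be positive on the support")

    idx = np.full(sigma.grid.shape, -1)
    idx[mask] = np.arange(n)
    s = sigma.values
    t = electrodes.thickness

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for di, dj in ((0, 1), (1, 0)):
        m_nb = mask & shifted(mask, di, dj, fill=False)
        s_nb = shifted(s, di, dj)
        i_here = idx[m_nb]
        nb_idx = shifted(idx, di, dj)
        i_there = nb_idx[m_nb]
        g_face = 2.0 * s[m_nb] * s_nb[m_nb] / (s[m_nb] + s_nb[m_nb]) * t
        rows.extend([i_here, i_there])
        cols.extend([i_there, i_here])
        vals.extend([-g_face, -g_face])
        np.add.at(diag, i_here, g_face)
        np.add.at(diag, i_there, g_face)
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    lap = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()

    b_map = electrodes.injection_map()
    if not mask[tuple(np.argwhere(b_map != 0).T)].all():
        raise ValueError("electrode faces must be attached to support pixels")
    b = b_map[mask]
    if abs(b.sum()) > 1e-12 * electrodes.current:
        raise ValueError(
            "Neumann data incompatible: net injected current "
            f"{b.sum():.3e} A is not zero"
        )

    ones = np.ones((n, 1))
    aug = sp.bmat([[lap, ones], [ones.T, None]], format="csc")
    rhs = np.concatenate([b, [0.0]])
    sol = spla.spsolve(aug, rhs)
    u = np.zeros(sigma.grid.shape)
    u[mask] = sol[:n] - sol[:n].mean()

    residual = np.abs(lap @ u[mask] - b).max()
    if not np.isfinite(residual) or residual > 1e-8 * max(abs(b).max(), 1e-300):
        raise ValueError(f"voltage solve did not converge (residual {residual:.3e} A)")
    return VoltageMap(u, sigma.grid, mask)


def current_density(sigma: ConductivityImage, u: VoltageMap) -> CurrentDensityMap:
    """``J = -sigma grad u`` with the shared masked gradient stencil."""
    check_same_grid(sigma.grid, u.grid)
    ux, uy = masked_gradient(u.values, u.support, u.grid.pixel_size)
    jx = np.where(u.support, -sigma.values * ux, 0.0)
    jy = np.where(u.support, -sigma.values * uy, 0.0)
    return CurrentDensityMap(jx, jy, sigma.grid, u.support)


# ---------------------------------------------------------------------------
# Biot-Savart


def _kernels(grid: Grid, kernel: str, thickness: float):
    nr, nc = grid.shape
    p = grid.pixel_size
    dy = (np.arange(2 * nr - 1) - (nr - 1))[:, None] * p
    dx = (np.arange(2 * nc - 1) - (nc - 1))[None, :] * p
    rho2 = dx**2 + dy**2
    center = (nr - 1, nc - 1)
    rho2[center] = np.inf  # self-pixel excluded (odd integrand over the pixel)
    if kernel == "tall":
        # sources uniform along z over a tall object: 2-D line-integrated law
        kx = MU0 / (2.0 * np.pi) * p**2 * dy / rho2
        ky = MU0 / (2.0 * np.pi) * p**2 * dx / rho2
    elif kernel == "slab":
        # sources concentrated in the imaging slab, treated as point volumes
        rho3 = rho2**1.5
        vol = p**2 * thickness
        kx = MU0 / (4.0 * np.pi) * vol * dy / rho3
        ky = MU0 / (4.0 * np.pi) * vol * dx / rho3
    else:
        raise ValueError("kernel must be 'tall' or 'slab'")
    kx[center] = 0.0
    ky[center] = 0.0
    return kx, ky


def bz_from_current(
    j: CurrentDensityMap,
    thickness: float = 0.004,
    *,
    kernel: str = "tall",
    method: str = "fft",
    tc: float | None = None,
    injection: int | None = None,
) -> FluxDensityImage:
    """Discrete Biot-Savart evaluation of Bz at the pixel centers.

    ``kernel="tall"`` integrates each source column along z (current
    uniform in z, the usual idealization for an object much taller than
    the slice); with this kernel the in-plane curl identity
    ``rot_perp Bz = mu0 J`` holds at all wavelengths, which keeps the
    single-differentiation reconstruction quantitatively consistent.
    ``kernel="slab"`` instead treats each source pixel as a small volume
    ``pixel_area * thickness`` in the imaging slab.  The fast path uses
    FFT cross-correlations and agrees with the direct double sum to
    floating precision.
    """
    if not (np.all(np.isfinite(j.jx)) and np.all(np.isfinite(j.jy))):
        raise ValueError("current density must be finite")
    kx, ky = _kernels(j.grid, kernel, thickness)
    if method == "fft":
        bz = fftconvolve(j.jx, kx, mode="same") - fftconvolve(j.jy, ky, mode="same")
    elif method == "direct":
        nr, nc = j.grid.shape
        bz = np.zeros((nr, nc))
        for i in range(nr):
            for jj in range(nc):
                # kernel entries at offsets (i - i', j - j') for every source
                ki = kx[i : i + nr, jj : jj + nc][::-1, ::-1]
                kj = ky[i : i + nr, jj : jj + nc][::-1, ::-1]
                bz[i, jj] = np.sum(j.jx * ki) - np.sum(j.jy * kj)
    else:
        raise ValueError("method must be 'fft' or 'direct'")
    return FluxDensityImage(bz, j.grid, injection=injection, tc=tc)


# ---------------------------------------------------------------------------
# acquisition / extraction


def simulate_acquisition(
    magnitude: MagnitudeImage,
    delta: np.ndarray | float,
    bz: FluxDensityImage,
    tc: float,
    seed: int,
) -> ComplexImagePair:
    """Simulate the positive/negative current-pulse complex images.

    ``S+- = M exp(i delta) exp(+-i gamma Bz Tc)`` plus i.i.d. complex
    Gaussian noise per pixel and per polarity.  The per-channel noise
    scale is ``noise_std / sqrt(2)``, so that a magnitude SNR of
    ``Y = M / noise_std`` propagates to exactly
    ``sd(Bz) = 1 / (2 gamma Tc Y)`` through the phase-difference
    extraction (see :func:`noise_std_map`).
    """
    check_same_grid(magnitude.grid, bz.grid)
    if not tc > 0:
        raise ValueError("Tc must be positive")
    phase = GAMMA * bz.values * tc
    pmax = np.abs(phase).max()
    if pmax >= np.pi / 2:
        raise ValueError(
            f"phase-wrap precondition violated: max |gamma Bz Tc| = {pmax:.3f} rad "
            ">= pi/2; reduce Tc or the injected current"
        )
    delta = np.broadcast_to(np.asarray(delta, dtype=float), magnitude.grid.shape)
    clean = magnitude.values * np.exp(1j * delta)
    s_plus = clean * np.exp(1j * phase)
    s_minus = clean * np.exp(-1j * phase)

    rng = np.random.default_rng(seed)
    scale = magnitude.noise_std / np.sqrt(2.0)
    noise = rng.standard_normal((2, 2) + magnitude.grid.shape) * scale
    s_plus = s_plus + noise[0, 0] + 1j * noise[0, 1]
    s_minus = s_minus + noise[1, 0] + 1j * noise[1, 1]
    return ComplexImagePair(s_plus, s_minus, tc, magnitude.grid, seed=seed)


def extract_bz(pair: ComplexImagePair) -> FluxDensityImage:
    """Phase-difference extraction of Bz; systematic phase cancels.

    Zero-magnitude pixels (undefined phase) yield Bz = 0 and are flagged
    in ``invalid_mask``.
    """
    if not pair.tc > 0:
        raise ValueError("Tc must be positive")
    prod = pair.s_plus * np.conj(pair.s_minus)
    invalid = prod == 0
    bz = np.where(invalid, 0.0, np.angle(prod) / (2.0 * pair.gamma * pair.tc))
    return FluxDensityImage(
        bz, pair.grid, injection=pair.injection, tc=pair.tc, invalid_mask=invalid
    )


def measured_magnitude(
    pairs: list[ComplexImagePair], noise_std: float
) -> MagnitudeImage:
    """Magnitude estimate averaged over all acquired complex images.

    ``noise_std`` remains the per-acquisition magnitude noise level that
    defines the SNR entering the noise model; averaging only sharpens the
    estimate of M itself.
    """
    grid = check_same_grid(*[p.grid for p in pairs])
    stack = [np.abs(p.s_plus) for p in pairs] + [np.abs(p.s_minus) for p in pairs]
    return MagnitudeImage(np.mean(stack, axis=0), noise_std, grid)


def noise_std_map(
    magnitude: MagnitudeImage,
    tc: float,
    snr_threshold: float = SNR_VALIDITY_THRESHOLD,
) -> NoiseStdMap:
    """Per-pixel ``sd(Bz) = 1/(2 gamma Tc Y)``, clamped below the SNR bound.

    Where the magnitude SNR ``Y`` is at or below ``snr_threshold`` the
    model is no longer valid; those pixels get the threshold value and
    are flagged in ``low_snr_mask``.
    """
    if not tc > 0:
        raise ValueError("Tc must be positive")
    snr = magnitude.snr
    low = snr <= snr_threshold
    sd = 1.0 / (2.0 * GAMMA * tc * np.maximum(snr, snr_threshold))
    return NoiseStdMap(sd, low, magnitude.grid, tc, snr_threshold)
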