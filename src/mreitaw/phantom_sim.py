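"""Synthetic conductivity/magnitude phantoms and injection electrodes.

The default phantom emulates a saline-filled cylindrical tank scanned in a
conductivity-imaging experiment: a 0.4 S/m background disc containing
three inclusions — a 1.5 S/m disc (D1), a 0.1 S/m disc (D2), and a
1.5 S/m disc wrapped in a 0.3 S/m annulus (D3).  The inclusions have a
short T2, so their MR magnitude is far below the background level; this
is precisely the regime in which the flux-density noise, and hence the
reconstruction noise, concentrates inside the objects.

Geometry not dictated by the emulated experiment (disc radius, inclusion
radii and positions) is a stated package default and fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid, check_same_grid, shifted

__all__ = [
    "Inclusion",
    "ConductivityImage",
    "MagnitudeImage",
    "ROIMask",
    "ElectrodeConfig",
    "Phantom",
    "make_disc_phantom",
    "make_electrodes",
    "standard_phantom",
    "standard_rois",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Inclusion:
    """Cylindrical (disc) inclusion.

    A wrapped object (core inside an annulus) is expressed as two
    concentric inclusions; each pixel takes the innermost region whose
    boundary contains its center, so the smaller disc wins where they
    overlap.
    """

    label: str
    center: tuple[float, float]  # (x, y) in meters
    radius: float  # m
    conductivity: float  # S/m
    magnitude_level: float  # arbitrary units

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"inclusion {self.label}: radius must be positive")
        if not self.conductivity > 0:
            raise ValueError(f"inclusion {self.label}: conductivity must be positive")
        if self.magnitude_level < 0:
            raise ValueError(f"inclusion {self.label}: magnitude must be nonnegative")

    def contains(self, x, y):
        return (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2 <= self.radius**2


@dataclass
class ConductivityImage:
    """2-D conductivity field sigma in S/m with its support mask."""

    values: np.ndarray
    grid: Grid
    support: np.ndarray | None = None
    floored_mask: np.ndarray | None = None  # set by the reconstruction

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("conductivity shape does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("conductivity must be finite")
        if self.support is None:
            self.support = self.values > 0
        self.support = np.asarray(self.support, dtype=bool)


@dataclass
class MagnitudeImage:
    """Nonnegative MR magnitude image with its noise standard deviation.

    The per-pixel SNR is ``values / noise_std``; the flux-density noise
    model is driven by this ratio.
    """

    values: np.ndarray
    noise_std: float
    grid: Grid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("magnitude shape does not match grid")
        if not self.noise_std > 0:
            raise ValueError("noise_std must be positive")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("magnitude must be finite and nonnegative")

    @property
    def snr(self) -> np.ndarray:
        return self.values / self.noise_std


@dataclass
class ROIMask:
    label: str
    mask: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("ROI shape does not match grid")
        if not self.mask.any():
            raise ValueError(f"ROI {self.label!r} is empty")


@dataclass
class ElectrodeConfig:
    """Opposite boundary electrodes carrying the injection current.

    ``faces_pos``/``faces_neg`` list the support pixels owning boundary
    faces under the source/sink electrode (one entry per face).  The
    injected current is split equally across the faces of an electrode,
    so the Neumann data are compatible (net flux zero) by construction.
    """

    pair: str  # "horizontal" | "vertical"
    current: float  # A
    width: float  # electrode extent along the boundary, m
    thickness: float  # slab thickness converting current to flux, m
    faces_pos: np.ndarray  # (k, 2) int row/col indices
    faces_neg: np.ndarray
    grid: Grid

    @property
    def g(self) -> float:
        """Neumann flux magnitude per face, A/m^2."""
        face_area = self.grid.pixel_size * self.thickness
        return self.current / (len(self.faces_pos) * face_area)

    def injection_map(self) -> np.ndarray:
        """Per-pixel injected current (A); sums to zero."""
        b = np.zeros(self.grid.shape)
        for faces, sign in ((self.faces_pos, +1.0), (self.faces_neg, -1.0)):
            per_face = sign * self.current / len(faces)
            np.add.at(b, (faces[:, 0], faces[:, 1]), per_face)
        return b


@dataclass
class Phantom:
    """Bundle produced by :func:`make_disc_phantom`."""

    sigma: ConductivityImage
    magnitude: MagnitudeImage
    rois: list[ROIMask]
    support: np.ndarray
    disc_radius: float
    background_sigma: float

    def roi(self, label: str) -> ROIMask:
        for r in self.rois:
            if r.label == label:
                return r
        raise KeyError(label)


# ---------------------------------------------------------------------------
# operations


def make_disc_phantom(
    grid: Grid,
    background_sigma: float = 0.4,
    inclusions: tuple[Inclusion, ...] = (),
    seed: int = 0,
    *,
    disc_radius: float | None = None,
    magnitude_background: float = 30.0,
    noise_std: float = 1.0,
) -> Phantom:
    """Build a disc phantom with piecewise-constant conductivity/magnitude.

    Each pixel is assigned the innermost region containing its center
    (no anti-aliasing), so the truth stays piecewise constant and the
    ROI gradient-variance metric is meaningful.  ``seed`` is accepted for
    interface uniformity; the construction is fully deterministic.
    """
    del seed  # geometry is deterministic
    if not background_sigma > 0:
        raise ValueError("background conductivity must be positive")
    if disc_radius is None:
        disc_radius = 0.4 * min(grid.fov)
    X, Y = grid.coords()
    support = X**2 + Y**2 <= disc_radius**2

    for inc in inclusions:
        d = np.hypot(inc.center[0], inc.center[1])
        if d + inc.radius > disc_radius:
            raise ValueError(
                f"inclusion {inc.label!r} (center distance {d:.4g} m, radius "
                f"{inc.radius:.4g} m) does not fit inside the background disc "
                f"of radius {disc_radius:.4g} m"
            )

    sigma = np.where(support, background_sigma, 0.0)
    mag = np.where(support, float(magnitude_background), 0.0)

    # innermost region wins: paint large radii first
    order = sorted(range(len(inclusions)), key=lambda i: -inclusions[i].radius)
    owner = np.full(grid.shape, -1)
    for i in order:
        inside = inclusions[i].contains(X, Y) & support
        sigma[inside] = inclusions[i].conductivity
        mag[inside] = inclusions[i].magnitude_level
        owner[inside] = i

    rois: list[ROIMask] = []
    for i, inc in enumerate(inclusions):
        m = owner == i
        if not m.any():
            raise ValueError(f"inclusion {inc.label!r} covers no pixel center")
        rois.append(ROIMask(inc.label, m, grid))
    rois.append(ROIMask("background", support & (owner == -1), grid))

    return Phantom(
        sigma=ConductivityImage(sigma, grid, support=support),
        magnitude=MagnitudeImage(mag, noise_std, grid),
        rois=rois,
        support=support,
        disc_radius=disc_radius,
        background_sigma=background_sigma,
    )


def make_electrodes(
    grid: Grid,
    pair: str,
    current: float,
    support: np.ndarray | None = None,
    *,
    width: float = 0.08,
    thickness: float = 0.004,
) -> ElectrodeConfig:
    """Place two opposite boundary electrodes on the support boundary.

    ``pair="horizontal"`` drives current along +x (source on the west
    boundary, sink on the east), ``"vertical"`` along +y.  An electrode
    collects the boundary faces whose outward normal points along the
    injection axis and whose center lies within ``width/2`` of the
    support centroid measured along the transverse axis.
    """
    if pair not in ("horizontal", "vertical"):
        raise ValueError("pair must be 'horizontal' or 'vertical'")
    if not current > 0:
        raise ValueError("current must be positive")
    if support is None:
        support = np.ones(grid.shape, dtype=bool)
    support = np.asarray(support, dtype=bool)
    X, Y = grid.coords()
    cx = X[support].mean()
    cy = Y[support].mean()

    if pair == "horizontal":
        transverse, center, extent = Y, cy, Y[support].max() - Y[support].min()
        normals = ((0, -1), (0, 1))  # west (source), east (sink)
    else:
        transverse, center, extent = X, cx, X[support].max() - X[support].min()
        normals = ((-1, 0), (1, 0))  # north (source, low y), south (sink)
    if width > extent + grid.pixel_size:
        raise ValueError(
            f"electrode width {width:.4g} m exceeds the {extent:.4g} m support extent"
        )

    faces = []
    band = np.abs(transverse - center) <= width / 2.0
    for di, dj in normals:
        outside = ~shifted(support, di, dj, fill=False)
        sel = support & outside & band
        idx = np.argwhere(sel)
        if len(idx) == 0:
            raise ValueError(f"no boundary faces found for the {pair} electrode pair")
        faces.append(idx)

    return ElectrodeConfig(
        pair=pair,
        current=current,
        width=width,
        thickness=thickness,
        faces_pos=faces[0],
        faces_neg=faces[1],
        grid=grid,
    )


# ---------------------------------------------------------------------------
# the emulated three-inclusion experiment


def standard_phantom(
    n: int = 128,
    fov: float = 0.240,
    *,
    magnitude_background: float = 30.0,
    magnitude_inclusion: float = 4.0,
    noise_std: float = 1.0,
    background_sigma: float = 0.4,
) -> Phantom:
    """Three-inclusion disc phantom used throughout the package.

    Conductivities: background 0.4 S/m; D1 1.5 S/m; D2 0.1 S/m; D3 a
    1.5 S/m core wrapped in a 0.3 S/m annulus.  The inclusions share a
    low magnitude level (default SNR ~= 4 against ~= 30 in the
    background), mimicking the signal drop of short-T2 objects.
    """
    grid = Grid.from_fov(n, fov)
    r_d = 0.4 * fov  # background disc radius
    rho = 0.52 * r_d  # inclusion center distance from phantom center
    angles = {"D1": 90.0, "D2": 210.0, "D3": 330.0}

    def pos(label):
        a = np.deg2rad(angles[label])
        return (rho * np.cos(a), rho * np.sin(a))

    m_in = magnitude_inclusion
    inclusions = (
        Inclusion("D1", pos("D1"), 0.20 * r_d, 1.5, m_in),
        Inclusion("D3_annulus", pos("D3"), 0.22 * r_d, 0.3, m_in),
        Inclusion("D3", pos("D3"), 0.13 * r_d, 1.5, m_in),
        Inclusion("D2", pos("D2"), 0.20 * r_d, 0.1, m_in),
    )
    return make_disc_phantom(
        grid,
        background_sigma,
        inclusions,
        disc_radius=r_d,
        magnitude_background=magnitude_background,
        noise_std=noise_std,
    )


def standard_rois(phantom: Phantom) -> list[ROIMask]:
    """The three homogeneous inclusion ROIs (D1, D2, D3 core)."""
    return [phantom.roi(lbl) for lbl in ("D1", "D2", "D3")]
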