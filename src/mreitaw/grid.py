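"""Pixel grid geometry and shared finite-difference stencils.

Every module in the package works on 2-D scalar fields sampled at pixel
centers.  The conventions fixed here are used everywhere:

* arrays are indexed ``[row, col]``;
* physical ``x`` increases with the column index, ``y`` with the row index;
* the physical origin sits at the center of the field of view, so pixel
  ``(i, j)`` is located at ``x = (j - (n_cols - 1)/2) * pixel_size`` and
  ``y = (i - (n_rows - 1)/2) * pixel_size``;
* all geometry is in meters.

Gradients use central differences in the interior of a support mask and
fall back to one-sided differences on the support boundary, so the same
stencil serves the forward model, the reconstruction, and the evaluation
metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Grid:
    """Uniform pixel grid with physical spacing.

    Parameters
    ----------
    n_rows, n_cols:
        Matrix size; at least 8 per axis.
    pixel_size:
        Pixel edge length in meters (FOV / matrix size per axis).
    """

    n_rows: int
    n_cols: int
    pixel_size: float

    def __post_init__(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("grid must be at least 8x8")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @classmethod
    def from_fov(cls, n: int, fov: float) -> "Grid":
        """Square grid with ``n`` pixels covering a field of view ``fov`` (m)."""
        return cls(n, n, fov / n)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def fov(self) -> tuple[float, float]:
        """Physical extent (y, x) in meters."""
        return (self.n_rows * self.pixel_size, self.n_cols * self.pixel_size)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Y)`` pixel-center coordinate arrays in meters."""
        x = (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * self.pixel_size
        y = (np.arange(self.n_rows) - (self.n_rows - 1) / 2.0) * self.pixel_size
        return np.meshgrid(x, y)


def check_same_grid(*grids: Grid) -> Grid:
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise ValueError(f"grid mismatch: {g} != {first}")
    return first


def shifted(a: np.ndarray, di: int, dj: int, fill=0):
    """Array shifted so that ``out[i, j] = a[i + di, j + dj]`` (``fill`` outside)."""
    out = np.full_like(a, fill)
    src_i = slice(max(di, 0), a.shape[0] + min(di, 0))
    src_j = slice(max(dj, 0), a.shape[1] + min(dj, 0))
    dst_i = slice(max(-di, 0), a.shape[0] + min(-di, 0))
    dst_j = slice(max(-dj, 0), a.shape[1] + min(-dj, 0))
    out[dst_i, dst_j] = a[src_i, src_j]
    return out


def masked_gradient(
    f: np.ndarray, mask: np.ndarray, pixel_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient ``(df/dx, df/dy)`` restricted to a support mask.

    Central differences where both neighbors along an axis lie inside the
    mask, one-sided differences where only one does, zero where the pixel
    is isolated along that axis.  Pixels outside the mask get zero.
    """
    f = np.asarray(f, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    p = float(pixel_size)
    out = []
    for di, dj in ((0, 1), (1, 0)):  # x: columns, y: rows
        f_p = shifted(f, di, dj)
        f_m = shifted(f, -di, -dj)
        m_p = shifted(mask, di, dj, fill=False)
        m_m = shifted(mask, -di, -dj, fill=False)
        grad = np.zeros_like(f)
        both = m_p & m_m
        fwd = m_p & ~m_m
        bwd = m_m & ~m_p
        grad[both] = (f_p[both] - f_m[both]) / (2.0 * p)
        grad[fwd] = (f_p[fwd] - f[fwd]) / p
        grad[bwd] = (f[bwd] - f_m[bwd]) / p
        grad[~mask] = 0.0
        out.append(grad)
    return out[0], out[1]


def perp_gradient(
    f: np.ndarray, mask: np.ndarray, pixel_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rotated gradient ``(df/dy, -df/dx)`` with the shared stencil."""
    fx, fy = masked_gradient(f, mask, pixel_size)
    return fy, -fx
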