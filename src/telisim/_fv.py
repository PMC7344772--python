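"""Finite-volume assembly on structured tensor-product grids.

Shared by the substrate-transport and heat-conduction solvers. Cells are
axis-aligned boxes defined by per-axis edge arrays; face conductances use
the standard two-point series (harmonic-mean) formula, which is exact for
piecewise-constant coefficients on a tensor grid.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .errors import ConfigurationError

__all__ = [
    "geometric_partition",
    "cell_volumes",
    "assemble_diffusion",
]


def geometric_partition(total: float, n: int, ratio: float = 1.8) -> np.ndarray:
    """Split ``total`` into ``n`` widths in geometric progression.

    Returns widths in ascending order (smallest first), summing to
    ``total`` exactly. ``ratio`` is the factor between successive widths.
    """
    if total <= 0 or n < 1:
        raise ConfigurationError(f"cannot partition {total} into {n} cells")
    if n == 1:
        return np.array([float(total)])
    w = ratio ** np.arange(n)
    return total * w / w.sum()


def cell_volumes(dx: np.ndarray, dy: np.ndarray, dz: np.ndarray) -> np.ndarray:
    """Cell volumes (nx, ny, nz) from per-axis widths (metres)."""
    return dx[:, None, None] * dy[None, :, None] * dz[None, None, :]


def _face_terms(widths, coeff, areas, axis):
    """Conductances of interior faces along ``axis``.

    G = A / (0.5*d1/k1 + 0.5*d2/k2); zero-conductivity cells yield G = 0.
    """
    d = widths
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(None, -1)
    sl_hi[axis] = slice(1, None)
    k_lo = coeff[tuple(sl_lo)]
    k_hi = coeff[tuple(sl_hi)]
    shape = [1, 1, 1]
    shape[axis] = -1
    d_lo = d[:-1].reshape(shape)
    d_hi = d[1:].reshape(shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = 0.5 * d_lo / k_lo + 0.5 * d_hi / k_hi
        g = np.where(np.isfinite(res) & (res > 0), areas / res, 0.0)
    return g


def assemble_diffusion(
    dx: np.ndarray,
    dy: np.ndarray,
    dz: np.ndarray,
    coeff: np.ndarray,
    boundary: str = "neumann",
    film_h: float | None = None,
) -> sp.csc_matrix:
    """Assemble the discrete operator L such that V_i dU_i/dt = (L U)_i.

    Parameters
    ----------
    dx, dy, dz
        Per-axis cell widths in metres.
    coeff
        Per-cell diffusive coefficient (thermal conductivity W/(m K) or
        solute diffusivity m^2/s), shape (nx, ny, nz).
    boundary
        ``"neumann"``: no-flux exterior faces. ``"dirichlet"``: exterior
        faces held at the reference value (U = 0 in excursion form).
    film_h
        Optional film coefficient (W/(m^2 K)); when given with
        ``boundary="dirichlet"`` every exterior face couples to ambient
        through the series of half-cell conduction and the film.

    Row sums are zero for Neumann boundaries, so the operator conserves
    the volume integral of U exactly.
    """
    nx, ny, nz = coeff.shape
    if (len(dx), len(dy), len(dz)) != (nx, ny, nz):
        raise ConfigurationError("coefficient shape does not match axis widths")
    n = nx * ny * nz
    idx = np.arange(n).reshape(nx, ny, nz)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)

    area_x = dy[None, :, None] * dz[None, None, :]
    area_y = dx[:, None, None] * dz[None, None, :]
    area_z = dx[:, None, None] * dy[None, :, None]

    for axis, (widths, areas) in enumerate(
        [(dx, area_x), (dy, area_y), (dz, area_z)]
    ):
        g = _face_terms(widths, coeff, areas, axis)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        i_lo = idx[tuple(sl_lo)].ravel()
        i_hi = idx[tuple(sl_hi)].ravel()
        gf = g.ravel()
        rows.append(i_lo)
        cols.append(i_hi)
        vals.append(gf)
        rows.append(i_hi)
        cols.append(i_lo)
        vals.append(gf)
        np.add.at(diag, i_lo, -gf)
        np.add.at(diag, i_hi, -gf)

        if boundary == "dirichlet":
            for side, bcells in ((0, tuple_first(axis)), (-1, tuple_last(axis))):
                i_b = idx[bcells].ravel()
                k_b = coeff[bcells].ravel()
                d_b = widths[side]
                a_b = areas[_collapse(bcells, axis)].ravel()
                with np.errstate(divide="ignore", invalid="ignore"):
                    res = 0.5 * d_b / k_b
                    if film_h is not None:
                        res = res + 1.0 / film_h
                    gb = np.where(np.isfinite(res) & (res > 0) & (k_b > 0),
                                  a_b / res, 0.0)
                np.add.at(diag, i_b, -gb)

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    L = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return L


def tuple_first(axis):
    sl = [slice(None)] * 3
    sl[axis] = 0
    return tuple(sl)


def tuple_last(axis):
    sl = [slice(None)] * 3
    sl[axis] = -1
    return tuple(sl)


def _collapse(bcells, axis):
    # Areas arrays are broadcast along ``axis`` with size 1; index 0 there.
    sl = list(bcells)
    sl[axis] = 0
    return tuple(sl)
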