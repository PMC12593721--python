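"""Matérn correlation and the SPDE finite-element GMRF precision.

The spatial fields are Matérn with smoothness nu = 1 (the standard choice of
the SPDE framework in two dimensions, corresponding to SPDE order alpha = 2).
The range parameter rho follows the convention

    kappa = sqrt(8 * nu) / rho,

under which the correlation at distance rho is about 0.13.  On a triangulated
mesh the field is approximated by a Gaussian Markov random field whose sparse
precision is assembled from the P1 finite-element mass and stiffness
matrices:

    Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^-1 G),

with C the *lumped* (diagonal) mass matrix, G the stiffness matrix, and tau
chosen so the stationary marginal variance equals sigma^2:
sigma^2 = 1 / (4 pi kappa^2 tau^2).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.special import gamma as _gamma
from scipy.special import kv as _kv

__all__ = ["matern_correlation", "fem_matrices", "spde_precision", "SMOOTHNESS_NU"]

#: Matérn smoothness of the spatial fields; fixed, not a user knob.
SMOOTHNESS_NU = 1.0


def matern_correlation(distance_km, range_km: float, nu: float = SMOOTHNESS_NU):
    """Matérn correlation at the given distance(s).

    Parameters
    ----------
    distance_km : float or ndarray
        Non-negative separation distance(s) in km.
    range_km : float
        Spatial range rho > 0 (correlation ~0.13 at this distance).
    nu : float
        Smoothness; nu = 0.5 gives the exponential model exp(-2 d / rho).

    Returns
    -------
    Correlation value(s) in [0, 1]; exactly 1 at distance 0.
    """
    d = np.asarray(distance_km, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if range_km <= 0:
        raise ValueError("range_km must be positive")
    if nu <= 0:
        raise ValueError("nu must be positive")
    kappa = np.sqrt(8.0 * nu) / range_km
    scaled = kappa * d
    out = np.ones_like(d)
    pos = scaled > 0
    s = scaled[pos]
    out[pos] = (2.0 ** (1.0 - nu) / _gamma(nu)) * (s**nu) * _kv(nu, s)
    # Bessel underflow at large arguments -> correlation 0.
    out = np.where(np.isfinite(out), out, 0.0)
    return out if out.ndim else float(out)


def fem_matrices(vertices: np.ndarray, triangles: np.ndarray):
    """Assemble P1 finite-element matrices on a triangulation.

    Returns
    -------
    c_diag : ndarray
        Diagonal of the lumped mass matrix (vertex areas / 3 summed).
    g : csc_matrix
        Stiffness matrix (integrals of grad phi_i . grad phi_j).
    """
    vertices = np.asarray(vertices, dtype=float)
    triangles = np.asarray(triangles, dtype=int)
    n = len(vertices)
    c_diag = np.zeros(n)
    rows, cols, vals = [], [], []
    for tri in triangles:
        p = vertices[tri]
        e0 = p[2] - p[1]
        e1 = p[0] - p[2]
        e2 = p[1] - p[0]
        area = 0.5 * abs(e1[0] * e2[1] - e1[1] * e2[0])
        if area <= 0 or not np.isfinite(area):
            raise ValueError(f"degenerate triangle with vertices {tri.tolist()}")
        c_diag[tri] += area / 3.0
        edges = np.array([e0, e1, e2])
        local = (edges @ edges.T) / (4.0 * area)
        for a in range(3):
            for b in range(3):
                rows.append(tri[a])
                cols.append(tri[b])
                vals.append(local[a, b])
    g = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return c_diag, g


def spde_precision(
    mesh,
    range_km: float,
    marginal_sd: float,
    nu: float = SMOOTHNESS_NU,
) -> sp.csc_matrix:
    """Sparse GMRF precision over mesh vertices for a Matérn(nu=1) field.

    ``mesh`` is a :class:`psrr.mesh.Mesh` (or any object with ``vertices``,
    ``triangles`` and cached ``fem`` matrices).
    """
    if range_km <= 0 or marginal_sd <= 0:
        raise ValueError("range_km and marginal_sd must be positive")
    if nu != SMOOTHNESS_NU:
        raise NotImplementedError("precision assembly implements nu = 1 only")
    c_diag, g = mesh.fem()
    kappa = np.sqrt(8.0 * nu) / range_km
    tau = 1.0 / (np.sqrt(4.0 * np.pi) * kappa * marginal_sd)
    c = sp.diags(c_diag)
    c_inv = sp.diags(1.0 / c_diag)
    q = tau**2 * (kappa**4 * c + 2.0 * kappa**2 * g + g @ c_inv @ g)
    q = q.tocsc()
    if not np.all(np.isfinite(q.data)):
        bad = np.argwhere(~np.isfinite(q.toarray()))
        raise ValueError(f"non-finite precision entries at {bad[:5].tolist()}")
    return q
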