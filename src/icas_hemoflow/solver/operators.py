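"""Sparse finite-difference operators on a body-fitted structured grid.

The lumen (z in [0, L], y between the walls) is mapped onto a rectangular
computational grid (xi, eta) with ``y(xi, eta) = y_lower + eta * gap``.
Axisymmetric lumens use ``y_lower = 0`` so that ``y`` is the radius.  Chain
rule:

    d/dy  = (1/h) d/eta
    d/dz  = d/xi + b d/eta,            b = -(y_l' + eta h') / h
    d2/dz2 = d2/xi2 + 2 b d2/xi deta + b^2 d2/eta2 + (b_xi + b b_eta) d/eta

All operators are assembled once per geometry as scipy sparse matrices acting
on fields flattened in row-major (xi, eta) order.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def fd_weights(x: np.ndarray, x0: float, m: int) -> np.ndarray:
    """Fornberg weights for the m-th derivative at ``x0`` on nodes ``x``."""
    n = len(x)
    c = np.zeros((n, m + 1))
    c1, c4 = 1.0, x[0] - x0
    c[0, 0] = 1.0
    for i in range(1, n):
        mn = min(i, m)
        c2, c5, c4 = 1.0, c4, x[i] - x0
        for j in range(i):
            c3 = x[i] - x[j]
            c2 *= c3
            if j == i - 1:
                for k in range(mn, 0, -1):
                    c[i, k] = c1 * (k * c[i - 1, k - 1] - c5 * c[i - 1, k]) / c2
                c[i, 0] = -c1 * c5 * c[i - 1, 0] / c2
            for k in range(mn, 0, -1):
                c[j, k] = (c4 * c[j, k] - k * c[j, k - 1]) / c3
            c[j, 0] = c4 * c[j, 0] / c3
        c1 = c2
    return c[:, m]


def diff_matrix(x: np.ndarray, order: int) -> sp.csr_matrix:
    """1-D derivative matrix, 2nd-order accurate on an arbitrary grid.

    Interior rows use 3-point centred stencils; boundary rows use one-sided
    3-point (first derivative) or 4-point (second derivative) stencils.
    """
    n = len(x)
    width = 3 if order == 1 else 4
    rows, cols, vals = [], [], []
    for i in range(n):
        if 0 < i < n - 1:
            sten = [i - 1, i, i + 1]
        elif i == 0:
            sten = list(range(min(width, n)))
        else:
            sten = list(range(max(0, n - width), n))
        w = fd_weights(x[sten], x[i], order)
        rows.extend([i] * len(sten))
        cols.extend(sten)
        vals.extend(w)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def one_sided_matrices(x: np.ndarray) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """First-order backward/forward difference matrices (upwind building
    blocks); the rows without an upwind neighbour are left zero and must be
    overridden by boundary conditions."""
    n = len(x)
    hb = np.diff(x)
    back = sp.diags([np.concatenate([[0.0], 1.0 / hb]),
                     -1.0 / hb], [0, -1], shape=(n, n))
    fwd = sp.diags([np.concatenate([-1.0 / hb, [0.0]]),
                    1.0 / hb], [0, 1], shape=(n, n))
    return back.tocsr(), fwd.tocsr()


class MappedOperators:
    """Operator bundle for one lumen geometry.

    Parameters
    ----------
    z : (nz+1,) axial node positions.
    eta : (nr+1,) transverse computational nodes in [0, 1].
    y_lower, y_upper : (nz+1,) wall positions at the axial nodes.
    axisymmetric : if True, ``y`` is the radius and 1/r terms are provided.
    """

    def __init__(self, z: np.ndarray, eta: np.ndarray, y_lower: np.ndarray,
                 y_upper: np.ndarray, axisymmetric: bool):
        self.z, self.eta = np.asarray(z, float), np.asarray(eta, float)
        self.nz, self.nr = len(z) - 1, len(eta) - 1
        self.shape = (self.nz + 1, self.nr + 1)
        self.n = (self.nz + 1) * (self.nr + 1)
        self.axisymmetric = axisymmetric

        Dz1, Dz2 = diff_matrix(self.z, 1), diff_matrix(self.z, 2)
        De1, De2 = diff_matrix(self.eta, 1), diff_matrix(self.eta, 2)
        Iz = sp.identity(self.nz + 1, format="csr")
        Ie = sp.identity(self.nr + 1, format="csr")
        self.Axi1 = sp.kron(Dz1, Ie, format="csr")
        self.Axi2 = sp.kron(Dz2, Ie, format="csr")
        self.Aeta1 = sp.kron(Iz, De1, format="csr")
        self.Aeta2 = sp.kron(Iz, De2, format="csr")
        self.Across = sp.kron(Dz1, De1, format="csr")
        bz, fz = one_sided_matrices(self.z)
        be, fe = one_sided_matrices(self.eta)
        self.Bxi = sp.kron(bz, Ie, format="csr")
        self.Fxi = sp.kron(fz, Ie, format="csr")
        self.Beta = sp.kron(Iz, be, format="csr")
        self.Feta = sp.kron(Iz, fe, format="csr")
        # d/d(eta^2): for axisymmetric lumens u = (2/h^2) dpsi/d(eta^2),
        # which is regular at the axis (no 1/r amplification) and exact for
        # fully developed (quadratic-in-r^2) profiles.
        self.Dsq = sp.kron(Iz, diff_matrix(self.eta ** 2, 1), format="csr")

        yl, yu = np.asarray(y_lower, float), np.asarray(y_upper, float)
        h = yu - yl
        ylp, ylpp = Dz1 @ yl, Dz2 @ yl
        hp, hpp = Dz1 @ h, Dz2 @ h
        E = np.broadcast_to(self.eta[None, :], self.shape).copy()
        self.Y = yl[:, None] + E * h[:, None]
        self.h, self.hp = h, hp
        self.yl, self.yu, self.ylp = yl, yu, ylp
        self.yup = ylp + hp  # upper-wall slope

        hf = np.repeat(h, self.nr + 1)
        g = ylp[:, None] + E * hp[:, None]
        b = (-g / h[:, None]).ravel()
        b_xi = ((-(ylpp[:, None] + E * hpp[:, None]) / h[:, None]
                 + g * hp[:, None] / h[:, None] ** 2)).ravel()
        b_eta = np.repeat(-hp / h, self.nr + 1)
        self.b = b

        d = sp.diags
        self.Dy = d(1.0 / hf) @ self.Aeta1
        self.Dyy = d(1.0 / hf ** 2) @ self.Aeta2
        self.Dx = self.Axi1 + d(b) @ self.Aeta1
        self.Dxx = (self.Axi2 + d(2.0 * b) @ self.Across
                    + d(b ** 2) @ self.Aeta2
                    + d(b_xi + b * b_eta) @ self.Aeta1)
        for name in ("Dy", "Dyy", "Dx", "Dxx"):
            setattr(self, name, getattr(self, name).tocsr())

        yf = self.Y.ravel()
        # 1/y and 1/y^2 with the axis entries zeroed; axis rows are always
        # replaced by boundary/regularity conditions.
        self.inv_y = np.where(np.abs(yf) > 1e-300, 1.0 / np.where(yf == 0, 1.0, yf), 0.0)
        self.inv_y[yf == 0] = 0.0
        self.inv_y2 = self.inv_y ** 2

    def laplacian(self) -> sp.csr_matrix:
        """Scalar Laplacian (axisymmetric form includes the 1/r d/dr term)."""
        L = self.Dxx + self.Dyy
        if self.axisymmetric:
            L = L + sp.diags(self.inv_y) @ self.Dy
        return L.tocsr()

    def index(self, i, j):
        return i * (self.nr + 1) + j

    # Boundary node index arrays (flattened)
    def inlet_nodes(self):
        return self.index(0, np.arange(self.nr + 1))

    def outlet_nodes(self):
        return self.index(self.nz, np.arange(self.nr + 1))

    def lower_nodes(self):
        return self.index(np.arange(self.nz + 1), 0)

    def upper_nodes(self):
        return self.index(np.arange(self.nz + 1), self.nr)
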