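"""Reference shape functions and quadrature for quadratic simplices.

Quadratic Lagrange elements are used throughout: 6-node triangles in the 2D
plane-strain mode and 10-node tetrahedra in 3D. Node ordering follows the
VTK convention (corners first, then edge midside nodes). Quadrature rules
are degree 4 (triangle) and degree 5 (tetrahedron), sufficient for the
stiffness integrands of curved isoparametric quadratic elements.
"""

from __future__ import annotations

import numpy as np

# Local edges of a 6-node triangle: (corner, corner, midside)
TRI6_EDGES = ((0, 1, 3), (1, 2, 4), (2, 0, 5))

# Local faces of a 10-node tetrahedron as 6-node triangles (VTK ordering).
# Each face is (c0, c1, c2, m01, m12, m20).
TET10_FACES = (
    (0, 1, 3, 4, 8, 7),
    (1, 2, 3, 5, 9, 8),
    (2, 0, 3, 6, 7, 9),
    (0, 2, 1, 6, 5, 4),
)

# Corner pairs carrying each midside node.
TRI6_EDGE_PAIRS = ((0, 1), (1, 2), (2, 0))
TET10_EDGE_PAIRS = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))


def tri6_shape(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape functions and reference gradients of the 6-node triangle.

    ``points`` has shape (nq, 2) in reference coordinates (xi, eta); returns
    ``N`` (nq, 6) and ``dN`` (nq, 6, 2).
    """
    pts = np.asarray(points, dtype=float)
    xi, eta = pts[:, 0], pts[:, 1]
    l0 = 1.0 - xi - eta
    l1, l2 = xi, eta
    N = np.stack(
        [
            l0 * (2 * l0 - 1),
            l1 * (2 * l1 - 1),
            l2 * (2 * l2 - 1),
            4 * l0 * l1,
            4 * l1 * l2,
            4 * l2 * l0,
        ],
        axis=1,
    )
    # dL0 = (-1,-1), dL1 = (1,0), dL2 = (0,1)
    dN = np.empty((pts.shape[0], 6, 2))
    dN[:, 0, 0] = 1 - 4 * l0
    dN[:, 0, 1] = 1 - 4 * l0
    dN[:, 1, 0] = 4 * l1 - 1
    dN[:, 1, 1] = 0.0
    dN[:, 2, 0] = 0.0
    dN[:, 2, 1] = 4 * l2 - 1
    dN[:, 3, 0] = 4 * (l0 - l1)
    dN[:, 3, 1] = -4 * l1
    dN[:, 4, 0] = 4 * l2
    dN[:, 4, 1] = 4 * l1
    dN[:, 5, 0] = -4 * l2
    dN[:, 5, 1] = 4 * (l0 - l2)
    return N, dN


def tet10_shape(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape functions and reference gradients of the 10-node tetrahedron.

    ``points`` has shape (nq, 3); returns ``N`` (nq, 10) and ``dN`` (nq, 10, 3).
    """
    pts = np.asarray(points, dtype=float)
    xi, eta, zeta = pts[:, 0], pts[:, 1], pts[:, 2]
    l0 = 1.0 - xi - eta - zeta
    L = np.stack([l0, xi, eta, zeta], axis=1)  # (nq, 4)
    dL = np.array(
        [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )  # (4, 3)
    nq = pts.shape[0]
    N = np.empty((nq, 10))
    dN = np.empty((nq, 10, 3))
    for c in range(4):
        N[:, c] = L[:, c] * (2 * L[:, c] - 1)
        dN[:, c, :] = (4 * L[:, c, None] - 1) * dL[c]
    for m, (a, b) in enumerate(TET10_EDGE_PAIRS, start=4):
        N[:, m] = 4 * L[:, a] * L[:, b]
        dN[:, m, :] = 4 * (L[:, a, None] * dL[b] + L[:, b, None] * dL[a])
    return N, dN


def edge3_shape(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic edge (nodes at xi = 0, 1, 1/2); gradients w.r.t. xi."""
    xi = np.asarray(xi, dtype=float)
    N = np.stack(
        [(1 - xi) * (1 - 2 * xi), xi * (2 * xi - 1), 4 * xi * (1 - xi)], axis=1
    )
    dN = np.stack([4 * xi - 3, 4 * xi - 1, 4 - 8 * xi], axis=1)
    return N, dN


def tri_quadrature(degree: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric Gauss rule on the reference triangle (area 1/2)."""
    if degree <= 2:
        # 3-point degree-2 rule
        a = 1.0 / 6.0
        pts = np.array([[a, a], [2.0 / 3.0, a], [a, 2.0 / 3.0]])
        w = np.full(3, 1.0 / 3.0)
    else:
        # 6-point degree-4 rule (two symmetric orbits)
        a1, w1 = 0.445948490915965, 0.223381589678011
        a2, w2 = 0.091576213509771, 0.109951743655322
        pts = np.array(
            [
                [a1, a1], [1 - 2 * a1, a1], [a1, 1 - 2 * a1],
                [a2, a2], [1 - 2 * a2, a2], [a2, 1 - 2 * a2],
            ]
        )
        w = np.array([w1] * 3 + [w2] * 3)
    return pts, w * 0.5


def tet_quadrature(degree: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric rule on the reference tetrahedron (volume 1/6).

    Degree 5 uses the positive-weight 14-point Keast rule; degree <= 2 the
    classical 4-point rule.
    """
    if degree <= 2:
        a = (5.0 - np.sqrt(5.0)) / 20.0
        b = (5.0 + 3.0 * np.sqrt(5.0)) / 20.0
        bary = []
        for i in range(4):
            p = [a, a, a, a]
            p[i] = b
            bary.append(p)
        bary = np.array(bary)
        w = np.full(4, 0.25)
    else:
        g1, w1 = 0.3108859192633005, 0.1126879257180159
        g2, w2 = 0.0927352503108912, 0.0734930431163620
        g3, w3 = 0.0455037041256497, 0.0425460207770815
        orbits = []
        weights = []
        for g, w in ((g1, w1), (g2, w2)):
            for i in range(4):
                p = [g, g, g, g]
                p[i] = 1.0 - 3.0 * g
                orbits.append(p)
                weights.append(w)
        # six permutations of (g3, g3, d, d)
        d = 0.5 - g3
        import itertools

        seen = set()
        for perm in itertools.permutations((g3, g3, d, d)):
            if perm not in seen:
                seen.add(perm)
                orbits.append(list(perm))
                weights.append(w3)
        bary = np.array(orbits)
        w = np.array(weights)
    pts = bary[:, 1:]  # (xi, eta, zeta) with l0 = 1 - sum
    return pts, w / 6.0


def gauss1d(n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre rule mapped to [0, 1]."""
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w
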