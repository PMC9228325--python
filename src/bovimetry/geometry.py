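"""Low-level geometric primitives shared across the package.

Everything here operates in SI units (metres) with the body convention
x = body axis (muzzle to tail), y = lateral, z = up, ground at z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely.ops
import trimesh
from scipy.special import ellipe, ellipeinc, ellipkinc
from shapely.geometry import Polygon


@dataclass
class PointCloud:
    """Oriented point set sampled from (or acquired on) a body surface.

    points : (n, 3) float array, metres.
    normals : optional (n, 3) float array of unit outward normals.
    """

    points: np.ndarray
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float)
            if self.normals.shape != self.points.shape:
                raise ValueError("normals must match points in shape")
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normals must be unit length (|n| = 1 ± 1e-6)")

    def __len__(self) -> int:
        return len(self.points)


def ellipse_perimeter(a: float, b: float) -> float:
    """Exact perimeter of an ellipse with semi-axes a, b (complete E integral)."""
    a, b = float(a), float(b)
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    hi, lo = max(a, b), min(a, b)
    m = 1.0 - (lo / hi) ** 2
    return 4.0 * hi * ellipe(m)


def ellipsoid_area(a: float, b: float, c: float) -> float:
    """Exact surface area of an ellipsoid via the Legendre form.

    Valid for any positive semi-axes; degenerates gracefully to the sphere.
    """
    s = np.sort([float(a), float(b), float(c)])[::-1]
    a, b, c = s
    if c <= 0:
        raise ValueError("semi-axes must be positive")
    if (a - c) / a < 1e-12:
        return 4.0 * np.pi * a * a
    cos_phi = c / a
    phi = np.arccos(cos_phi)
    sin_phi = np.sin(phi)
    # prolate-like degenerate case b == c handled by the general formula too,
    # but guard k for b -> c where the modulus collapses to 0
    k2 = (a * a * (b * b - c * c)) / (b * b * (a * a - c * c))
    k2 = min(max(k2, 0.0), 1.0)
    F = ellipkinc(phi, k2)
    E = ellipeinc(phi, k2)
    return 2.0 * np.pi * c * c + (2.0 * np.pi * a * b / sin_phi) * (
        E * sin_phi**2 + F * cos_phi**2
    )


def _close_polygon(curve: np.ndarray) -> np.ndarray:
    if not np.allclose(curve[0], curve[-1]):
        curve = np.vstack([curve, curve[0]])
    return curve


def slice_polygons(
    mesh: trimesh.Trimesh,
    plane_origin: np.ndarray,
    plane_normal: np.ndarray,
    basis: tuple[np.ndarray, np.ndarray] | None = None,
    min_area: float = 1e-6,
) -> list[Polygon]:
    """Intersect a mesh with a plane and return merged closed polygons.

    Polygons are expressed in 2D plane coordinates given by ``basis``
    (two orthonormal in-plane vectors); overlapping or nested loops are
    resolved with a union so each returned polygon is one connected
    solid component of the section. Degenerate slivers below ``min_area``
    (m^2) are discarded.
    """
    plane_origin = np.asarray(plane_origin, dtype=float)
    plane_normal = np.asarray(plane_normal, dtype=float)
    plane_normal = plane_normal / np.linalg.norm(plane_normal)
    section = mesh.section(plane_origin=plane_origin, plane_normal=plane_normal)
    if section is None:
        return []
    if basis is None:
        # arbitrary orthonormal basis spanning the plane
        u = np.array([0.0, 1.0, 0.0])
        if abs(np.dot(u, plane_normal)) > 0.9:
            u = np.array([1.0, 0.0, 0.0])
        u = u - np.dot(u, plane_normal) * plane_normal
        u /= np.linalg.norm(u)
        v = np.cross(plane_normal, u)
        basis = (u, v)
    u, v = basis
    rings = []
    for curve in section.discrete:
        curve = _close_polygon(np.asarray(curve))
        rel = curve - plane_origin
        pts2 = np.column_stack([rel @ u, rel @ v])
        if len(pts2) < 4:
            continue
        poly = Polygon(pts2)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty:
            continue
        rings.append(poly)
    if not rings:
        return []
    # overlapping loops (e.g. membrane artifacts straddling legs) merge into
    # one solid component; disjoint loops stay separate
    merged = shapely.ops.unary_union(rings)
    if merged.geom_type == "Polygon":
        polys = [merged]
    else:
        polys = list(merged.geoms)
    return [p for p in polys if p.area >= min_area]


@dataclass
class Frame2D:
    """In-plane basis used when projecting body cross sections: (lateral, up)."""

    lateral: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    up: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
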