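"""Body measurements on triangulated meshes.

Re-implements the measurement stage of a 3D livestock scanner: body surface
area and volume of the watertight mesh, plus the classic linear traits —
heart girth (HG), withers height (WH), chest depth (CD), hip width (HW) and
buttock width (KW) — taken on cross-section planes at configurable landmark
stations along the body axis. The girth emulates a taut tape: it is the
convex-hull perimeter of the section, bridging concavities the way a
rule-tape does on a standing animal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely.ops
import trimesh

from .geometry import slice_polygons
from .records import TraitRecord
from .synthetic import DEFAULT_ANATOMY, Anatomy

log = logging.getLogger(__name__)


class FrameError(RuntimeError):
    """Body-axis fitting failed (e.g. near-isotropic vertex distribution)."""


class MeasurementError(RuntimeError):
    """A trait could not be measured on this mesh."""


@dataclass
class BodyFrame:
    """Body axis and landmark stations fitted to one mesh.

    axis_origin is the front end of the body on the axis at ground level;
    axis_direction points muzzle -> tail; stations map landmark names to
    fractional positions along the body length.
    """

    axis_origin: np.ndarray
    axis_direction: np.ndarray
    up_direction: np.ndarray
    body_length: float
    ground_z: float
    stations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(float(np.dot(self.axis_direction, self.up_direction))) > 1e-6:
            raise ValueError("axis must be perpendicular to the up direction")

    @property
    def lateral(self) -> np.ndarray:
        return np.cross(self.up_direction, self.axis_direction)

    def point_at(self, station: float) -> np.ndarray:
        return self.axis_origin + station * self.body_length * self.axis_direction

    def axial_coord(self, points: np.ndarray) -> np.ndarray:
        rel = np.asarray(points) - self.axis_origin
        return rel @ self.axis_direction


def fit_body_frame(mesh: trimesh.Trimesh, anatomy: Anatomy = DEFAULT_ANATOMY) -> BodyFrame:
    """Fit the body axis by planar PCA and orient it muzzle -> tail.

    The axis is the first principal direction of the vertices projected to
    the ground plane; up is +z (animals stand on the device floor). The
    front end is the one with the smaller cross-section area (head and neck
    are slimmer than the hindquarters).
    """
    verts = np.asarray(mesh.vertices)
    if len(verts) < 10:
        raise FrameError("not enough vertices to fit a body frame")
    xy = verts[:, :2] - verts[:, :2].mean(axis=0)
    cov = xy.T @ xy / len(xy)
    evals, evecs = np.linalg.eigh(cov)
    major, minor = evecs[:, 1], evecs[:, 0]
    ext_major = np.ptp(xy @ major)
    ext_minor = np.ptp(xy @ minor)
    if ext_minor <= 0 or ext_major / ext_minor < 1.1:
        raise FrameError(
            f"body axis is ambiguous (principal extent ratio "
            f"{ext_major / max(ext_minor, 1e-12):.3f} < 1.1)"
        )
    axis = np.array([major[0], major[1], 0.0])
    axis /= np.linalg.norm(axis)
    up = np.array([0.0, 0.0, 1.0])
    t = verts @ axis
    t0, t1 = t.min(), t.max()
    length = t1 - t0
    ground_z = verts[:, 2].min()

    def section_area(frac: float) -> float:
        origin = verts.mean(axis=0) + (t0 + frac * length - verts.mean(axis=0) @ axis) * axis
        polys = slice_polygons(mesh, origin, axis)
        return sum(p.area for p in polys)

    try:
        if section_area(0.12) > section_area(0.88):
            axis = -axis
            t0, t1 = -t1, -t0
    except Exception:  # orientation heuristic is best-effort
        log.warning("front/rear orientation heuristic failed; keeping PCA sign")
    centroid = verts.mean(axis=0)
    origin = centroid + (t0 - centroid @ axis) * axis
    origin[2] = ground_z
    stations = {
        "heart_girth": anatomy.heart_girth,
        "hip": anatomy.hip,
        "buttock": anatomy.buttock,
    }
    return BodyFrame(
        axis_origin=origin,
        axis_direction=axis,
        up_direction=up,
        body_length=float(length),
        ground_z=float(ground_z),
        stations=stations,
    )


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume by the divergence theorem; requires a watertight mesh."""
    if not mesh.is_watertight:
        raise MeasurementError("volume of a non-watertight mesh is undefined")
    v = float(mesh.volume)
    if v < 0:  # inward orientation; magnitude is still the enclosed volume
        v = -v
    if v <= 0:
        raise MeasurementError("mesh encloses no volume")
    return v


def mesh_surface_area(mesh: trimesh.Trimesh) -> float:
    """Total triangle area."""
    if len(mesh.faces) == 0:
        raise MeasurementError("empty mesh has no surface area")
    return float(mesh.area)


def cross_section(mesh: trimesh.Trimesh, frame: BodyFrame, station: float):
    """Closed planar polygons of the mesh cut normal to the body axis.

    Polygons are in (lateral, up) plane coordinates, merged so each is one
    solid component; slivers below 1e-6 m^2 are dropped.
    """
    if not 0.0 <= station <= 1.0:
        raise ValueError("station must lie in [0, 1]")
    polys = slice_polygons(
        mesh,
        frame.point_at(station),
        frame.axis_direction,
        basis=(frame.lateral, frame.up_direction),
    )
    if not polys:
        raise MeasurementError(f"empty cross section at station {station:.3f}")
    return polys


def girth(mesh: trimesh.Trimesh, frame: BodyFrame) -> float:
    """Heart girth: taut-tape (convex hull) perimeter of the chest section."""
    polys = cross_section(mesh, frame, frame.stations["heart_girth"])
    merged = shapely.ops.unary_union(polys)
    return float(merged.convex_hull.exterior.length)


def withers_height(mesh: trimesh.Trimesh, frame: BodyFrame, window: float = None) -> float:
    """Total height over the shoulders, referenced to the ground plane.

    Maximum surface height within an axial window around the heart-girth
    station (half-width ``window`` as a fraction of body length).
    """
    if window is None:
        window = DEFAULT_ANATOMY.wh_window
    t = frame.axial_coord(mesh.vertices)
    st = frame.stations["heart_girth"] * frame.body_length
    w = window * frame.body_length
    sel = (t >= st - w) & (t <= st + w)
    if not np.any(sel):
        raise MeasurementError("no surface in the withers window")
    return float(mesh.vertices[sel, 2].max() - frame.ground_z)


def _largest_polygon(polys):
    return max(polys, key=lambda p: p.area)


def chest_depth(mesh: trimesh.Trimesh, frame: BodyFrame) -> float:
    """Vertical extent of the trunk polygon at the heart-girth station."""
    poly = _largest_polygon(cross_section(mesh, frame, frame.stations["heart_girth"]))
    _, miny, _, maxy = poly.bounds
    return float(maxy - miny)


def body_width(mesh: trimesh.Trimesh, frame: BodyFrame, landmark: str) -> float:
    """Lateral extent of the trunk polygon at the hip or buttock station."""
    if landmark not in ("hip", "buttock"):
        raise ValueError("landmark must be 'hip' or 'buttock'")
    poly = _largest_polygon(cross_section(mesh, frame, frame.stations[landmark]))
    minx, _, maxx, _ = poly.bounds
    return float(maxx - minx)


def measure_all(
    mesh: trimesh.Trimesh,
    animal_id: str = "",
    age: float = 0.0,
    anatomy: Anatomy = DEFAULT_ANATOMY,
) -> TraitRecord:
    """Measure every trait, failing soft per trait.

    A trait whose measurement errors is recorded as missing — a partially
    digitized animal may still yield valid linear traits even when volume
    or surface area cannot be trusted. Surface area and volume are only
    reported on watertight meshes. The record carries the 1-4 usability
    score from the quality module.
    """
    from .quality import score_quality

    report = score_quality(mesh, anatomy=anatomy)
    vals: dict = {}
    try:
        frame = fit_body_frame(mesh, anatomy=anatomy)
    except FrameError:
        return TraitRecord(animal_id=animal_id, age=age, quality=1)

    def attempt(name, fn):
        try:
            vals[name] = fn()
        except Exception as err:
            log.info("trait %s unmeasurable: %s", name, err)
            vals[name] = None

    attempt("hg", lambda: girth(mesh, frame))
    attempt("wh", lambda: withers_height(mesh, frame, anatomy.wh_window))
    attempt("cd", lambda: chest_depth(mesh, frame))
    attempt("hw", lambda: body_width(mesh, frame, "hip"))
    attempt("kw", lambda: body_width(mesh, frame, "buttock"))
    if mesh.is_watertight:
        attempt("volume", lambda: mesh_volume(mesh))
        attempt("bsa", lambda: mesh_surface_area(mesh))
    else:
        vals["volume"] = None
        vals["bsa"] = None
    if vals.get("cd") is not None and vals.get("wh") is not None and vals["cd"] >= vals["wh"]:
        vals["cd"] = None  # a section polluted by artifacts is not a chest
    return TraitRecord(animal_id=animal_id, age=age, quality=report.score, **vals)
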