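"""Usability scoring of body meshes on the 1-4 scale used in practice.

4 = sufficient (closed surface, no artifacts), 3 = some defects (a mild
leg skirt), 2 = partially usable (exactly one serious defect — open
surface, a missing region, or a heavy skirt; linear traits may survive),
1 = not used (two or more serious defects, or no recognizable body axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import slice_polygons
from .synthetic import DEFAULT_ANATOMY, Anatomy


@dataclass
class QualityReport:
    score: int
    skirt_detected: bool = False
    skirt_severity: float = 0.0
    missing_regions: list = field(default_factory=list)
    watertight: bool = False
    leg_components_by_station: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.score not in (1, 2, 3, 4):
            raise ValueError("score must be 1-4")
        if self.score == 4 and (
            self.skirt_detected or self.missing_regions or not self.watertight
        ):
            raise ValueError("score 4 requires a defect-free watertight mesh")

    def as_dict(self) -> dict:
        return {
            "score": self.score,
            "skirt_detected": self.skirt_detected,
            "skirt_severity": self.skirt_severity,
            "missing_regions": list(self.missing_regions),
            "watertight": self.watertight,
            "leg_components_by_station": {
                f"{k:.3f}": v for k, v in self.leg_components_by_station.items()
            },
        }


def _leg_slice(mesh: trimesh.Trimesh, frame, z: float):
    basis = (frame.axis_direction, frame.lateral)  # (axial, lateral) in-plane
    origin = np.array([0.0, 0.0, z]) + frame.axis_origin * np.array([1.0, 1.0, 0.0])
    return slice_polygons(mesh, origin, frame.up_direction, basis=basis)


def detect_skirt(mesh: trimesh.Trimesh, frame, anatomy: Anatomy = DEFAULT_ANATOMY):
    """Detect membranes webbing the legs together.

    The leg zone (lowest ``anatomy.leg_zone`` fraction of the height) is
    sliced at 10 evenly spaced heights. A leg-like component is axially
    narrow (< 30% of the body length); legs come in well-separated pairs,
    so a slice where a leg-like component spans more than half the body
    width laterally — or where fewer than two remain — is webbed.
    Severity is the webbed fraction of slices; the flag trips above
    ``anatomy.skirt_flag_threshold``. If no slice shows any leg-like
    component, there is no leg region to assess and an error is raised.
    """
    zmin, zmax = mesh.bounds[0][2], mesh.bounds[1][2]
    height = zmax - zmin
    zone = anatomy.leg_zone * height
    heights = zmin + (np.arange(10) + 0.5) / 10.0 * zone
    body_width = float(np.ptp(np.asarray(mesh.vertices) @ frame.lateral))
    L = frame.body_length
    webbed = 0
    counts = {}
    leg_region = False
    for z in heights:
        st = float((z - zmin) / height)
        polys = _leg_slice(mesh, frame, z)
        counts[st] = len(polys)
        if len(polys) == 0:
            continue
        leg_like = [
            p for p in polys if (p.bounds[2] - p.bounds[0]) < 0.3 * L
        ]
        if not leg_like:
            continue  # trunk-only slice; says nothing about the legs
        merged = any(
            (p.bounds[3] - p.bounds[1]) > 0.5 * body_width for p in leg_like
        )
        # a genuine leg region shows separated leg pairs or a webbed pair;
        # a single narrow blob (e.g. a slice grazing the muzzle) is neither
        if len(leg_like) >= 2 or merged:
            leg_region = True
        if merged or len(leg_like) < 2:
            webbed += 1
    if not leg_region:
        raise ValueError("no leg region detected in the lowest "
                         f"{anatomy.leg_zone:.0%} of the body height")
    severity = webbed / 10.0
    flag = severity > anatomy.skirt_flag_threshold
    return flag, severity, counts


def detect_missing(mesh: trimesh.Trimesh, frame, anatomy: Anatomy = DEFAULT_ANATOMY):
    """Report absent body regions ('head', 'leg') against the body plan.

    Head: an intact body tapers to nothing at both axial ends (muzzle and
    tail); a cropped scan instead ends abruptly in a wide open section. If
    either end of the axis still shows at least
    ``anatomy.truncation_area_frac`` of the maximum section area, the
    forward anatomy (head/neck) was not digitized.
    Legs: the lowest part of the body must show at least two separate
    axially-narrow cross-section components at some height; a single blob
    (or nothing) means the legs were not digitized.
    """
    missing = []
    fracs = np.linspace(0.02, 0.98, 33)
    areas = []
    for f in fracs:
        polys = slice_polygons(
            mesh, frame.point_at(f), frame.axis_direction,
            basis=(frame.lateral, frame.up_direction),
        )
        areas.append(sum(p.area for p in polys))
    areas = np.array(areas)
    amax = areas.max()
    if amax <= 0:
        return ["torso"]
    if max(areas[0], areas[-1]) >= anatomy.truncation_area_frac * amax:
        missing.append("head")
    zmin, zmax = mesh.bounds[0][2], mesh.bounds[1][2]
    height = zmax - zmin
    L = frame.body_length
    has_legs = False
    for f in (0.08, 0.16, 0.24, 0.32):
        polys = _leg_slice(mesh, frame, zmin + f * height)
        narrow = [p for p in polys if (p.bounds[2] - p.bounds[0]) < 0.3 * L]
        if len(narrow) >= 2:
            has_legs = True
            break
    if not has_legs:
        missing.append("leg")
    return missing


def score_quality(mesh: trimesh.Trimesh, anatomy: Anatomy = DEFAULT_ANATOMY) -> QualityReport:
    """Score a mesh 1-4 and report the defects found."""
    from .morphometrics import FrameError, fit_body_frame

    watertight = bool(mesh.is_watertight)
    try:
        frame = fit_body_frame(mesh, anatomy=anatomy)
    except FrameError:
        return QualityReport(score=1, watertight=watertight)
    try:
        skirt_flag, severity, counts = detect_skirt(mesh, frame, anatomy)
    except ValueError:
        skirt_flag, severity, counts = False, 0.0, {}
    missing = detect_missing(mesh, frame, anatomy)
    # an open surface that is open *because* a region is missing is one
    # physical defect, not two; such scans stay partially usable (score 2)
    open_alone = (not watertight) and not missing
    serious = int(open_alone) + int(bool(missing)) + int(
        severity > anatomy.skirt_partial_threshold
    )
    if serious == 0:
        score = 3 if skirt_flag else 4
    elif serious == 1:
        score = 2
    else:
        score = 1
    return QualityReport(
        score=score,
        skirt_detected=skirt_flag,
        skirt_severity=severity,
        missing_regions=missing,
        watertight=watertight,
        leg_components_by_station=counts,
    )
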