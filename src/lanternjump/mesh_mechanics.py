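"""Rigid-body mechanical properties of insect body meshes.

Computes mass properties (volume, center of mass, inertia tensor, principal
axes) of closed triangular surface meshes by exact polyhedral integrals,
builds parametric synthetic nymph meshes for the two stereotyped mid-air
postures (legs tucked / legs extended), and measures anatomical-plane
cross-sectional areas used as drag reference areas.

Internal units: mm (length), mg (mass), mg*mm^2 (inertia).  Density in
mg/mm^3 is numerically identical to g/cm^3.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import trimesh
import yaml
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

__all__ = [
    "RigidBodyProperties",
    "PostureGeometry",
    "LegGeometry",
    "CrossSections",
    "WatertightError",
    "compute_rigid_body_properties",
    "principal_decomposition",
    "build_nymph_mesh",
    "leg_inertia_fraction",
    "cross_section_areas",
    "load_mesh",
    "save_mesh",
]

# Anatomical frame used throughout: +x cranial (toward head), +y transverse
# (toward the animal's left), +z dorsal (up).  Roll is rotation about the
# cranial-caudal axis (moment I1), pitch about the transverse axis (I2),
# yaw about the dorsal-ventral axis (I3).
ANATOMICAL_AXES = np.eye(3)

PlaneName = Literal["frontal", "sagittal", "transverse"]

#: projection plane -> indices of the two coordinates spanning the silhouette
_PLANE_COORDS: dict[str, tuple[int, int]] = {
    # frontal (a.k.a. dorsal) plane: view along z, silhouette in x-y
    "frontal": (0, 1),
    # sagittal plane: view along y, silhouette in x-z
    "sagittal": (0, 2),
    # transverse plane: view along x, silhouette in y-z
    "transverse": (1, 2),
}


class WatertightError(ValueError):
    """Raised when a mesh is not a closed surface."""


# ---------------------------------------------------------------------------
# mass properties
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidBodyProperties:
    """Mass properties of one posture model.

    Attributes
    ----------
    mass : float
        Body mass in mg.
    volume : float
        Enclosed volume in mm^3.
    com : ndarray, shape (3,)
        Center of mass (mm).
    inertia_tensor : ndarray, shape (3, 3)
        Inertia tensor about the COM, mg*mm^2, in the mesh frame.
    principal_moments : ndarray, shape (3,)
        (I1, I2, I3) = (roll, pitch, yaw) moments, mg*mm^2, named by
        anatomical proximity (see :func:`principal_decomposition`).
    principal_axes : ndarray, shape (3, 3)
        Columns are the unit principal axes (u1, u2, u3); right-handed.
    density : float
        mass/volume in mg/mm^3 (== g/cm^3).
    """

    mass: float
    volume: float
    com: np.ndarray
    inertia_tensor: np.ndarray
    principal_moments: np.ndarray
    principal_axes: np.ndarray
    density: float

    def to_dict(self) -> dict:
        return {
            "mass_mg": self.mass,
            "volume_mm3": self.volume,
            "com_mm": self.com.tolist(),
            "inertia_tensor_mg_mm2": self.inertia_tensor.tolist(),
            "principal_moments_mg_mm2": self.principal_moments.tolist(),
            "principal_axes": self.principal_axes.tolist(),
            "density_g_cm3": self.density,
        }


def _polyhedron_integrals(vertices: np.ndarray, faces: np.ndarray):
    """Signed volume, first moment and second-moment matrix of a closed mesh.

    Divergence-theorem accumulation over signed origin tetrahedra, exact for
    polyhedra: each face (v0, v1, v2) contributes the tetrahedron
    (0, v0, v1, v2) with signed volume det/6.  The second moment uses the
    closed form  C = (V_t/20) * (sum_i p_i p_i^T + s s^T)  with s = sum of
    the tetrahedron's vertices (the origin contributing nothing).

    Returns (volume, integral of x dV, integral of x x^T dV), unsigned
    density (multiply by rho afterwards).
    """
    v0 = vertices[faces[:, 0]]
    v1 = vertices[faces[:, 1]]
    v2 = vertices[faces[:, 2]]
    # signed tetra volumes
    vols = np.einsum("ij,ij->i", v0, np.cross(v1, v2)) / 6.0
    volume = vols.sum()
    # first moment: centroid of tetra (v0+v1+v2+0)/4
    first = (vols[:, None] * (v0 + v1 + v2)).sum(axis=0) / 4.0
    # second moment
    s = v0 + v1 + v2
    outer = (
        np.einsum("ij,ik->ijk", v0, v0)
        + np.einsum("ij,ik->ijk", v1, v1)
        + np.einsum("ij,ik->ijk", v2, v2)
        + np.einsum("ij,ik->ijk", s, s)
    )
    second = np.einsum("i,ijk->jk", vols / 20.0, outer)
    return volume, first, second


def _as_trimesh(mesh) -> trimesh.Trimesh:
    if isinstance(mesh, trimesh.Trimesh):
        return mesh
    vertices, faces = mesh
    return trimesh.Trimesh(vertices=np.asarray(vertices, dtype=float),
                           faces=np.asarray(faces, dtype=int), process=False)


def _require_watertight(mesh: trimesh.Trimesh) -> None:
    if mesh.is_watertight:
        return
    # name the open edges to make the failure actionable
    edges = mesh.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    bad = unique[counts != 2]
    raise WatertightError(
        f"mesh is not watertight: {len(bad)} edge(s) not shared by exactly "
        f"two faces, e.g. {bad[:5].tolist()}"
    )


def compute_rigid_body_properties(mesh, mass: float) -> RigidBodyProperties:
    """Exact uniform-density mass properties of a closed triangular mesh.

    Parameters
    ----------
    mesh : trimesh.Trimesh or (vertices, faces)
        Closed surface with consistent outward winding.  Inverted winding
        (negative enclosed volume) is auto-corrected with a warning.
    mass : float
        Total mass in mg, distributed uniformly over the enclosed volume.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    tm = _as_trimesh(mesh)
    _require_watertight(tm)
    volume, first, second = _polyhedron_integrals(
        np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=int)
    )
    if volume < 0:
        warnings.warn("mesh winding is inverted (negative volume); flipping")
        volume, first, second = -volume, -first, -second
    if volume == 0:
        raise ValueError("mesh encloses zero volume")
    rho = mass / volume
    com = first / volume
    # inertia about origin: J = rho * (tr(C) I - C); then parallel-axis to COM
    c = rho * second
    j_origin = np.trace(c) * np.eye(3) - c
    r2 = com @ com
    j_com = j_origin - mass * (r2 * np.eye(3) - np.outer(com, com))
    j_com = 0.5 * (j_com + j_com.T)  # enforce exact symmetry
    moments, axes = principal_decomposition(j_com)
    return RigidBodyProperties(
        mass=float(mass),
        volume=float(volume),
        com=com,
        inertia_tensor=j_com,
        principal_moments=moments,
        principal_axes=axes,
        density=float(rho),
    )


def principal_decomposition(
    inertia_tensor: np.ndarray,
    anatomical_axes: np.ndarray = ANATOMICAL_AXES,
    degenerate_rtol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decompose an inertia tensor and name axes anatomically.

    The three principal axes are assigned roles by proximity to the
    anatomical directions: pitch = the axis closest to the transverse
    direction (I2); of the remaining two, roll = closest to cranial-caudal
    (I1) and yaw = the other (I3).  Signs are chosen so each axis points
    along (not against) its anatomical direction, and the triad is made
    right-handed via u3 = u1 x u2.

    For a fully degenerate (spherical) tensor the anatomical triad itself
    is returned.  Near-degenerate pairs fall back to the same
    proximity-then-smallest-index rule, which is deterministic.

    Returns
    -------
    (moments, axes)
        moments = (I1, I2, I3); axes columns are (u1, u2, u3).
    """
    it = np.asarray(inertia_tensor, dtype=float)
    if not np.allclose(it, it.T, rtol=0, atol=1e-9 * max(1.0, np.abs(it).max())):
        raise ValueError("inertia tensor must be symmetric")
    evals, evecs = np.linalg.eigh(it)
    if np.any(evals <= 0):
        raise ValueError("inertia tensor must be positive-definite")
    if np.ptp(evals) <= degenerate_rtol * evals.mean():
        # spherical tensor: any triad diagonalizes; use the anatomical one
        return evals.copy(), np.asarray(anatomical_axes, dtype=float).copy()

    cos = np.abs(evecs.T @ anatomical_axes)  # cos[i, k]: eigvec i vs axis k
    # pitch first (transverse, column 1), then roll (column 0), then yaw
    order = [-1, -1, -1]  # order[role] = eigenvector index; roles (roll,pitch,yaw)
    i_pitch = int(np.argmax(cos[:, 1]))
    order[1] = i_pitch
    remaining = [i for i in range(3) if i != i_pitch]
    i_roll = remaining[int(np.argmax(cos[remaining, 0]))]
    order[0] = i_roll
    order[2] = [i for i in remaining if i != i_roll][0]

    moments = evals[order]
    axes = evecs[:, order].copy()
    for k in range(2):  # orient roll and pitch along anatomy
        if axes[:, k] @ anatomical_axes[:, k] < 0:
            axes[:, k] *= -1
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])  # right-handed
    return moments, axes


# ---------------------------------------------------------------------------
# parametric synthetic nymph builder
# ---------------------------------------------------------------------------


@dataclass
class LegGeometry:
    """One leg: two capsule segments (femur, tibia+tarsus) hinged at a knee.

    Angles are in degrees, in the anatomical frame of the body:
    ``azimuth`` of the femur in the horizontal plane measured from +x
    (cranial), positive toward the leg's own side; ``elevation`` from the
    horizontal (positive up); ``knee`` the interior angle between femur and
    tibia (180 = straight).
    """

    femur_length: float
    tibia_length: float
    radius: float
    azimuth: float
    elevation: float
    knee: float
    attach_x: float  # attachment longitudinal station, fraction of semi-axis a
    side: int = 1  # +1 left (+y), -1 right


def _default_legs(posture_label: str) -> list[LegGeometry]:
    """Stereotyped third-instar leg poses for the two mid-air postures.

    legs_tucked: all legs folded close alongside the body.
    legs_extended: fore/mid legs extended laterally in the transverse plane,
    hindlegs extended rearward and crossed.
    """
    tucked = posture_label == "legs_tucked"
    legs = []
    # (femur, tibia, radius, attach_x) for fore, mid, hind
    dims = [(2.2, 2.6, 0.16, 0.45), (2.5, 3.0, 0.16, 0.10), (3.4, 4.4, 0.20, -0.30)]
    for i, (fl, tl, r, ax) in enumerate(dims):
        for side in (+1, -1):
            if tucked:
                # femur runs rearward close alongside the body, tibia folds
                # back on it (small interior knee angle)
                az, el, knee = (150.0, -12.0, 25.0)
                if i == 2:
                    az, el, knee = (165.0, -10.0, 20.0)
            else:
                if i < 2:  # fore/mid laterally extended, nearly straight
                    az, el, knee = (80.0 + 10.0 * i, 5.0, 160.0)
                else:  # hind rearward, crossed over the midline
                    az, el, knee = (168.0, 10.0, 170.0)
            legs.append(
                LegGeometry(
                    femur_length=fl, tibia_length=tl, radius=r,
                    azimuth=az, elevation=el, knee=knee,
                    attach_x=ax, side=side,
                )
            )
    return legs


@dataclass
class PostureGeometry:
    """Parametric geometry of a synthetic nymph in one posture.

    Defaults emulate a third-instar specimen: body length 8.9 mm, total
    mass 28.4 mg, calibrated so the uniform-density builder lands near an
    effective density of 1.0 g/cm^3.
    """

    body_length: float = 8.9  # L_b, mm (cranial-caudal extent of the body)
    body_semi_axes: tuple[float, float, float] = (4.45, 1.30, 1.00)
    legs: list[LegGeometry] | None = None
    hindleg_crossed: bool = True

    def __post_init__(self):
        a = self.body_length / 2.0
        if abs(self.body_semi_axes[0] - a) > 1e-9:
            self.body_semi_axes = (a, self.body_semi_axes[1], self.body_semi_axes[2])
        if any(s <= 0 for s in self.body_semi_axes) or self.body_length <= 0:
            raise ValueError("all lengths must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PostureGeometry":
        data = yaml.safe_load(Path(path).read_text())
        legs = data.pop("legs", None)
        if legs is not None:
            legs = [LegGeometry(**leg) for leg in legs]
        geo = cls(**{k: v for k, v in data.items() if k != "legs"})
        geo.legs = legs
        return geo

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["body_semi_axes"] = list(self.body_semi_axes)
        Path(path).write_text(yaml.safe_dump(data))


def _rotate_z(az_deg):
    a = np.deg2rad(az_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _capsule_between(p0: np.ndarray, p1: np.ndarray, radius: float) -> trimesh.Trimesh:
    """Closed capsule mesh from p0 to p1."""
    vec = p1 - p0
    length = np.linalg.norm(vec)
    cap = trimesh.creation.capsule(height=max(length, 1e-6), radius=radius, count=(12, 12))
    # trimesh capsule axis is +z spanning [0, height] plus hemispherical caps
    z = np.array([0.0, 0.0, 1.0])
    direction = vec / length if length > 0 else z
    rot = trimesh.geometry.align_vectors(z, direction)
    cap.apply_transform(rot)
    cap.apply_translation(p0)
    return cap


def build_nymph_mesh(geometry: PostureGeometry, posture_label: str) -> trimesh.Trimesh:
    """Build a synthetic nymph surface mesh for one posture.

    The mesh is a composition of closed parts: an ellipsoidal body (semi-axes
    a, b, c along the anatomical x, y, z) plus capsule femur and tibia
    segments per leg, posed at the configured joint angles.  Leg roots are
    inset slightly into the body so the parts join without gaps; every part
    is individually closed so the combined surface passes the watertightness
    invariant (each edge shared by exactly two faces).  Deterministic for a
    fixed geometry.
    """
    if posture_label not in ("legs_tucked", "legs_extended"):
        raise ValueError(f"unknown posture label {posture_label!r}")
    a, b, c = geometry.body_semi_axes
    body = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    body.apply_scale([a, b, c])
    parts = [body]
    legs = geometry.legs if geometry.legs is not None else _default_legs(posture_label)
    inset = 0.1  # mm, leg root buried into the body surface
    for leg in legs:
        if leg.femur_length <= 0 and leg.tibia_length <= 0:
            continue
        az = leg.azimuth * leg.side  # mirror across the sagittal plane
        el = np.deg2rad(leg.elevation)
        u_femur = _rotate_z(az) @ np.array([np.cos(el), 0.0, np.sin(el)])
        # attachment point on the body surface at station attach_x
        x0 = leg.attach_x * a
        # lateral/ventral point on the ellipse cross-section at x0
        scale = np.sqrt(max(1.0 - (x0 / a) ** 2, 1e-6))
        root = np.array([x0, leg.side * 0.8 * b * scale, -0.5 * c * scale])
        p0 = root - inset * u_femur
        p1 = p0 + leg.femur_length * u_femur
        if leg.femur_length > 0:
            parts.append(_capsule_between(p0, p1, leg.radius))
        # tibia bends by (180 - knee) degrees downward in the femur's vertical plane
        bend = np.deg2rad(180.0 - leg.knee)
        lateral = _rotate_z(az) @ np.array([np.cos(el + np.pi / 2), 0.0, np.sin(el + np.pi / 2)])
        u_tibia = np.cos(bend) * u_femur - np.sin(bend) * lateral
        if posture_label == "legs_extended" and geometry.hindleg_crossed and leg.attach_x < 0:
            # cross the hindlegs: tibia deflects across the midline
            u_tibia = u_tibia - np.array([0.0, leg.side * 0.35, 0.0])
            u_tibia /= np.linalg.norm(u_tibia)
        if leg.tibia_length > 0:
            parts.append(_capsule_between(p1, p1 + leg.tibia_length * u_tibia, leg.radius))
    mesh = trimesh.util.concatenate(parts)
    if not mesh.is_watertight:
        raise ValueError(
            "posed mesh is not watertight (self-intersecting pose?); "
            "adjust joint angles"
        )
    return mesh


def build_body_mesh(geometry: PostureGeometry) -> trimesh.Trimesh:
    """The legless body ellipsoid of the same geometry (for leg-contribution
    analyses)."""
    a, b, c = geometry.body_semi_axes
    body = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    body.apply_scale([a, b, c])
    return body


def leg_inertia_fraction(body_mesh, full_mesh, mass: float) -> np.ndarray:
    """Per-principal-axis fraction of the moment of inertia due to the legs.

    Both meshes are assigned the same uniform density (set by ``mass`` over
    the full mesh's volume); the legless body's inertia is evaluated about
    the full model's COM and principal axes, and the fraction is
    1 - I_body / I_full per axis.
    """
    full = compute_rigid_body_properties(full_mesh, mass)
    body_tm = _as_trimesh(body_mesh)
    _require_watertight(body_tm)
    vol_body = float(body_tm.volume)
    if vol_body >= full.volume * (1 + 1e-12) and vol_body > full.volume:
        raise ValueError("body volume exceeds full-model volume")
    body = compute_rigid_body_properties(body_tm, full.density * vol_body)
    # body inertia about the full model's COM, projected on its principal axes
    d = body.com - full.com
    shift = body.mass * ((d @ d) * np.eye(3) - np.outer(d, d))
    j_body = body.inertia_tensor + shift
    axes = full.principal_axes
    i_body = np.einsum("ki,kl,li->i", axes, j_body, axes)
    frac = 1.0 - i_body / full.principal_moments
    return np.clip(frac, 0.0, None)


# ---------------------------------------------------------------------------
# cross-sectional areas
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossSections:
    """Projected silhouette areas for one anatomical plane (mm^2)."""

    plane: str
    silhouette_area: float
    min_polygon_area: float  # area of the minimum enclosing convex polygon

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def cross_section_areas(mesh, plane: PlaneName) -> CrossSections:
    """Silhouette and minimum-enclosing-convex-polygon areas of a projection.

    The silhouette is the exact union of all triangles projected onto the
    requested anatomical plane; the minimum polygon is its convex hull.
    """
    if plane not in _PLANE_COORDS:
        raise ValueError(f"plane must be one of {sorted(_PLANE_COORDS)}")
    tm = _as_trimesh(mesh)
    i, j = _PLANE_COORDS[plane]
    pts2 = np.asarray(tm.vertices, dtype=float)[:, [i, j]]
    tris = []
    for f in tm.faces:
        t = pts2[f]
        # skip edge-on (degenerate) projected triangles
        e1, e2 = t[1] - t[0], t[2] - t[0]
        area2 = abs(e1[0] * e2[1] - e1[1] * e2[0])
        if area2 > 1e-12:
            tris.append(Polygon(t).buffer(0))
    if not tris:
        raise ValueError("projection is empty (degenerate mesh/plane)")
    union = unary_union(tris)
    silhouette = float(union.area)
    if silhouette <= 0:
        raise ValueError("projection has zero area")
    if isinstance(union, MultiPolygon):
        hull = union.convex_hull
    else:
        hull = union.convex_hull
    return CrossSections(plane=plane, silhouette_area=silhouette,
                         min_polygon_area=float(hull.area))


def area_increase_percent(area_tucked: float, area_extended: float) -> float:
    """Percent increase of a reference area due to leg extension."""
    if area_tucked <= 0:
        raise ValueError("reference area must be positive")
    return 100.0 * (area_extended - area_tucked) / area_tucked


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_mesh(path) -> trimesh.Trimesh:
    """Read an STL (binary or ASCII) surface mesh."""
    mesh = trimesh.load_mesh(str(path))
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path} did not contain a single triangular mesh")
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path) -> None:
    mesh.export(str(path))


def properties_report(props: RigidBodyProperties,
                      sections: list[CrossSections] | None = None) -> str:
    """JSON report of rigid-body properties (and optional cross-sections)."""
    out = {"rigid_body": props.to_dict()}
    if sections:
        out["cross_sections"] = [s.to_dict() for s in sections]
    return json.dumps(out, indent=2)
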