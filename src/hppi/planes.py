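"""Pi-plane frames of peptide-bond units and donor->acceptor contact geometry.

The N, C, O atoms of a peptide-bond unit define its pi-plane.  A donor
unit's amide hydrogen is described relative to an acceptor unit's plane by
per-site distances (to the N, C, O nuclei and to the plane centroid), the
approach angle of the N-H bond to the plane normal (folded to [0, 90]
degrees so the normal's sign is irrelevant), the perpendicular height of H
above the plane, and the in-plane offsets of its projection.  Distances in
Angstrom, angles in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import PeptideUnit

__all__ = [
    "SITES",
    "PlaneFrame",
    "ContactGeometry",
    "CollinearPlaneError",
    "NoDonorHydrogenError",
    "plane_frame",
    "contact_descriptors",
]

#: Acceptor sites on a peptide-bond unit's pi-plane.
SITES = ("N", "C", "O", "center")


class CollinearPlaneError(ValueError):
    """Plane atoms are (numerically) collinear; no plane is defined."""


class NoDonorHydrogenError(ValueError):
    """The putative donor unit carries no amide hydrogen."""


@dataclass
class PlaneFrame:
    """Orthonormal frame of a pi-plane: centroid origin, unit normal, two
    in-plane axes (u along the projected N->O direction, v = normal x u)."""

    origin: np.ndarray
    normal: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray

    def to_plane_coords(self, p: np.ndarray) -> tuple[float, float, float]:
        """(u, v, signed height) of a point in this frame."""
        d = np.asarray(p, float) - self.origin
        return float(d @ self.u_axis), float(d @ self.v_axis), float(d @ self.normal)


@dataclass
class ContactGeometry:
    """Descriptors of one donor-H -> acceptor-plane contact."""

    donor_index: int
    acceptor_index: int
    r: dict[str, float]          # 3D H -> site-point distance per site, A
    theta: float                 # N-H bond vs plane normal, folded to [0, 90] deg
    approach: dict[str, float]   # site->H direction vs plane normal, [0, 90] deg
    d_perp: float                # unsigned H -> plane distance, A
    u: float                     # in-plane offsets of H's projection
    v: float
    best_site: str               # argmin_s r_s
    angle_nho: float             # N-H...O angle at H, deg (H-bond geometry)
    elevation_o: float           # elevation of H over the plane seen from O, deg

    @property
    def r_best(self) -> float:
        return self.r[self.best_site]


def plane_frame(unit: PeptideUnit) -> PlaneFrame:
    """Exact plane through the unit's N, C, O atoms.

    The normal is the unit cross product (C-N) x (O-N); its sign never
    matters downstream because approach angles are folded to [0, 90].
    """
    n, c, o = unit.n, unit.c, unit.o
    cross = np.cross(c - n, o - n)
    norm = np.linalg.norm(cross)
    if norm <= 1e-9:
        raise CollinearPlaneError(f"unit {unit.label}: plane atoms are collinear")
    normal = cross / norm
    origin = (n + c + o) / 3.0
    u = o - n
    u = u - (u @ normal) * normal
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return PlaneFrame(origin=origin, normal=normal, u_axis=u, v_axis=v)


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    cosang = float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def contact_descriptors(donor: PeptideUnit, acceptor: PeptideUnit) -> ContactGeometry:
    """Geometry of the donor's amide H relative to the acceptor's pi-plane."""
    if donor.h is None:
        raise NoDonorHydrogenError(f"unit {donor.label} has no donor hydrogen")
    frame = plane_frame(acceptor)
    h = donor.h
    sites = {
        "N": acceptor.n,
        "C": acceptor.c,
        "O": acceptor.o,
        "center": frame.origin,
    }
    r = {s: float(np.linalg.norm(h - p)) for s, p in sites.items()}
    best_site = min(SITES, key=lambda s: r[s])

    nh = h - donor.n
    cosang = abs(float(nh @ frame.normal)) / np.linalg.norm(nh)
    theta = math.degrees(math.acos(min(1.0, cosang)))

    u, v, height = frame.to_plane_coords(h)
    d_perp = abs(height)
    # site points lie in the plane, so cos(approach angle) = d_perp / r_s
    approach = {
        s: math.degrees(math.acos(min(1.0, d_perp / r[s]))) if r[s] > 0 else 0.0
        for s in SITES
    }

    angle_nho = _angle_deg(donor.n - h, acceptor.o - h)
    elevation_o = math.degrees(math.asin(min(1.0, d_perp / r["O"]))) if r["O"] > 0 else 90.0

    return ContactGeometry(
        donor_index=donor.index,
        acceptor_index=acceptor.index,
        r=r,
        theta=theta,
        approach=approach,
        d_perp=d_perp,
        u=u,
        v=v,
        best_site=best_site,
        angle_nho=angle_nho,
        elevation_o=elevation_o,
    )
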