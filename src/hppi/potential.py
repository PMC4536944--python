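"""Anchored empirical potential for Hp-pi contacts, plus an H-bond comparator.

The model is a site potential over the four acceptor points of a peptide
pi-plane (the N, C, O nuclei and the plane centroid).  Each site carries an
anchor: a well depth epsilon (kJ/mol, negative) at an anchor distance
r_anchor (A) for perpendicular approach, taken from coupled-cluster
interaction energies of the NMA-NMA (n-methyl-acetamide) dimer in vacuum
and in water.  Around each anchor the radial profile is an (a, b) n-m well

    f(x) = (b x^-a - a x^-b) / (b - a),   x = r / r_anchor,

which satisfies f(1) = 1 exactly (so every anchor is reproduced to
machine precision), decays to zero at long range and diverges repulsively
at short range; repulsion is capped at ``e_max``.  Orientation enters as
cos^2(theta) of the N-H bond against the plane normal, vanishing for
in-plane approach — where the canonical hydrogen bond, modelled with the
same radial family around its own anchor, takes over.

Energies are interaction energies relative to separated monomers:
negative values are attractive.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .planes import SITES, ContactGeometry

__all__ = [
    "SiteAnchor",
    "AnchorTable",
    "PotentialModel",
    "EnergyGrid",
    "default_anchor_table",
    "load_anchor_table",
    "calibrate",
]

MEDIA = ("vacuum", "water")


@dataclass(frozen=True)
class SiteAnchor:
    """One calibration point: well depth at anchor distance for one site."""

    site: str
    medium: str
    epsilon: float  # kJ/mol, negative
    r_anchor: float  # Angstrom

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.medium not in MEDIA:
            raise ValueError(f"unknown medium {self.medium!r}")
        if not self.epsilon < 0:
            raise ValueError(f"anchor {self.site}/{self.medium}: epsilon must be negative")
        if not 1.5 <= self.r_anchor <= 4.0:
            raise ValueError(f"anchor {self.site}/{self.medium}: r_anchor outside [1.5, 4] A")


# Coupled-cluster NMA-NMA anchors (kJ/mol, Angstrom): perpendicular Hp-pi
# approach to each site, plus the coplanar NMA-NMA hydrogen bond.
_VACUUM = {
    "N": (-17.329, 2.310),
    "C": (-16.464, 2.514),
    "O": (-24.252, 2.368),
    "center": (-16.001, 2.550),
}
_WATER = {
    "N": (-12.207, 2.654),
    "C": (-8.276, 3.110),
    "O": (-15.759, 2.319),
}
_HBOND = (-24.391, 2.019)


@dataclass
class AnchorTable:
    """Per-site, per-medium anchors plus the H-bond comparator anchor."""

    anchors: dict[tuple[str, str], SiteAnchor]
    hbond_epsilon: float = _HBOND[0]
    hbond_r: float = _HBOND[1]
    synthesized: tuple[tuple[str, str], ...] = ()

    def get(self, site: str, medium: str) -> SiteAnchor:
        try:
            return self.anchors[(site, medium)]
        except KeyError:
            raise KeyError(f"no anchor for site {site!r} in medium {medium!r}") from None

    def vacuum_complete(self) -> bool:
        return all((s, "vacuum") in self.anchors for s in SITES)


def default_anchor_table() -> AnchorTable:
    """The calibration table, with the missing water 'center' anchor synthesized.

    No water-phase center-site energy was computed in the source
    calibration; it is synthesized as the vacuum center depth scaled by the
    mean water/vacuum depth ratio over the N, C, O sites, at the vacuum
    anchor distance, and flagged in ``synthesized``.
    """
    anchors: dict[tuple[str, str], SiteAnchor] = {}
    for site, (eps, r) in _VACUUM.items():
        anchors[(site, "vacuum")] = SiteAnchor(site, "vacuum", eps, r)
    for site, (eps, r) in _WATER.items():
        anchors[(site, "water")] = SiteAnchor(site, "water", eps, r)
    ratio = float(np.mean([_WATER[s][0] / _VACUUM[s][0] for s in ("N", "C", "O")]))
    anchors[("center", "water")] = SiteAnchor(
        "center", "water", _VACUUM["center"][0] * ratio, _VACUUM["center"][1]
    )
    return AnchorTable(anchors=anchors, synthesized=(("center", "water"),))


def load_anchor_table(path: str | Path) -> AnchorTable:
    """Read anchor overrides from a TOML file.

    Expected layout::

        [vacuum]
        N = [-17.329, 2.310]
        ...
        [water]
        ...
        [hbond]
        anchor = [-24.391, 2.019]

    Sites not listed fall back to the defaults.
    """
    data = tomllib.loads(Path(path).read_text())
    table = default_anchor_table()
    anchors = dict(table.anchors)
    synthesized = set(table.synthesized)
    for medium in MEDIA:
        for site, pair in data.get(medium, {}).items():
            eps, r = float(pair[0]), float(pair[1])
            anchors[(site, medium)] = SiteAnchor(site, medium, eps, r)
            synthesized.discard((site, medium))
    hb_eps, hb_r = table.hbond_epsilon, table.hbond_r
    if "hbond" in data:
        hb_eps, hb_r = (float(x) for x in data["hbond"]["anchor"])
    return AnchorTable(
        anchors=anchors,
        hbond_epsilon=hb_eps,
        hbond_r=hb_r,
        synthesized=tuple(sorted(synthesized)),
    )


@dataclass
class PotentialModel:
    """Calibrated site potential; build with :func:`calibrate`."""

    anchors: AnchorTable = field(default_factory=default_anchor_table)
    a: float = 6.0
    b: float = 10.0
    e_max: float = 50.0  # kJ/mol clash cap (finite stand-in for a hard wall)

    # -- radial / angular laws -------------------------------------------

    def radial(self, x: float | np.ndarray) -> float | np.ndarray:
        """(a, b) well profile with f(1) = 1, f(inf) = 0, f(0+) = -inf."""
        a, b = self.a, self.b
        x = np.asarray(x, float)
        f = (b * x ** (-a) - a * x ** (-b)) / (b - a)
        return float(f) if f.ndim == 0 else f

    @staticmethod
    def angular(theta_deg: float) -> float:
        """cos^2 approach-angle weight; 1 for perpendicular, 0 for in-plane."""
        if theta_deg >= 90.0:
            return 0.0
        return math.cos(math.radians(theta_deg)) ** 2

    # -- energies --------------------------------------------------------

    def site_energy(self, site: str, r: float, theta: float, medium: str = "vacuum") -> float:
        """Energy (kJ/mol) of an H at 3D distance r from one acceptor site."""
        if r <= 0:
            raise ValueError("r must be positive")
        if not 0.0 <= theta <= 90.0:
            raise ValueError("theta must lie in [0, 90] degrees")
        anchor = self.anchors.get(site, medium)
        e = anchor.epsilon * self.radial(r / anchor.r_anchor) * self.angular(theta)
        return min(e, self.e_max)

    def contact_energy(
        self,
        geom: ContactGeometry,
        medium: str = "vacuum",
        orientation: str = "approach",
    ) -> tuple[float, str]:
        """Lowest site energy over {N, C, O, center} and the winning site.

        ``orientation`` selects the angle fed to the cos^2 law:
        ``"approach"`` (default) uses the per-site elevation of the H over
        the plane — the positional geometry that governs overlap with the
        pi cloud, and zero exactly at every anchor pose; ``"bond"`` uses
        the donor N-H bond angle against the plane normal for all sites.
        """
        if orientation == "approach":
            angles = geom.approach
        elif orientation == "bond":
            angles = {s: geom.theta for s in SITES}
        else:
            raise ValueError(f"unknown orientation {orientation!r}")
        best = min(
            ((self.site_energy(s, geom.r[s], angles[s], medium), s) for s in SITES),
            key=lambda t: t[0],
        )
        return best

    def hbond_energy(self, r_ho: float, angle_nho: float) -> float:
        """Canonical N-H...O hydrogen-bond comparator (kJ/mol).

        Same radial family around the H-bond anchor; the angular weight is
        cos^2(180 - angle) for N-H...O angles >= 120 degrees and zero below
        (a bent geometry is no hydrogen bond).
        """
        if r_ho <= 0:
            raise ValueError("r_ho must be positive")
        if angle_nho < 120.0:
            return 0.0
        h = math.cos(math.radians(180.0 - angle_nho)) ** 2
        e = self.anchors.hbond_epsilon * self.radial(r_ho / self.anchors.hbond_r) * h
        return min(e, self.e_max)

    def plane_scan(
        self,
        extent: tuple[float, float] = (4.0, 8.0),
        step: float = 0.1,
        height: float = 2.5,
    ) -> "EnergyGrid":
        """Scan a probe amide H over a rectangle parallel to the pi-plane.

        The probe is held at fixed height above the plane with its N-H bond
        perpendicular (theta = 0).  The grid is inclusive of both extent
        endpoints, centred on the site centroid, with the long axis along
        the in-plane N->O direction so all three atom-site projections fall
        inside the scanned area.  Energy at each node is the best
        (lowest) site energy.
        """
        if step <= 0:
            raise ValueError("step must be positive")
        if height <= 0:
            raise ValueError("height must be positive")
        short, long_ = extent
        nu = round(short / step) + 1
        nv = round(long_ / step) + 1
        u = -short / 2 + step * np.arange(nu)
        v = -long_ / 2 + step * np.arange(nv)

        site_uv = _reference_site_frame()
        energy = np.empty((nu, nv))
        for i, ui in enumerate(u):
            for j, vj in enumerate(v):
                e_best = math.inf
                for s in SITES:
                    su, sv = site_uv[s]
                    r = math.sqrt(height**2 + (ui - su) ** 2 + (vj - sv) ** 2)
                    e = self.site_energy(s, r, 0.0, "vacuum")
                    e_best = min(e_best, e)
                energy[i, j] = e_best
        return EnergyGrid(u=u, v=v, energy=energy, height=height, sites=site_uv)


def _reference_site_frame() -> dict[str, tuple[float, float]]:
    """In-plane (u, v) coordinates of the N, C, O sites and centroid.

    Built from ideal peptide-plane internal coordinates (C-N 1.329 A,
    C=O 1.231 A, N-C-O 123 deg), centred on the centroid with the v (long)
    axis along the N->O direction.
    """
    n = np.array([0.0, 0.0])
    c = np.array([1.329, 0.0])
    ang = math.radians(180.0 - 123.0)
    o = c + 1.231 * np.array([math.cos(ang), math.sin(ang)])
    center = (n + c + o) / 3.0
    long_axis = o - n
    long_axis /= np.linalg.norm(long_axis)
    short_axis = np.array([-long_axis[1], long_axis[0]])
    out = {}
    for name, p in (("N", n), ("C", c), ("O", o), ("center", center)):
        d = p - center
        out[name] = (float(d @ short_axis), float(d @ long_axis))
    return out


@dataclass
class EnergyGrid:
    """Rectangular in-plane energy map from :meth:`PotentialModel.plane_scan`."""

    u: np.ndarray
    v: np.ndarray
    energy: np.ndarray  # shape (len(u), len(v)), kJ/mol
    height: float
    sites: dict[str, tuple[float, float]]

    @property
    def n_nodes(self) -> int:
        return int(self.energy.size)

    def argmin(self) -> tuple[float, float]:
        """(u, v) of the deepest grid node."""
        i, j = np.unravel_index(int(np.argmin(self.energy)), self.energy.shape)
        return float(self.u[i]), float(self.v[j])

    def min(self) -> float:
        return float(self.energy.min())

    def to_dataframe(self) -> pd.DataFrame:
        uu, vv = np.meshgrid(self.u, self.v, indexing="ij")
        return pd.DataFrame(
            {
                "u": uu.ravel(),
                "v": vv.ravel(),
                "energy_kJ_mol": self.energy.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def calibrate(
    anchors: AnchorTable | None = None,
    a: float = 6.0,
    b: float = 10.0,
    e_max: float = 50.0,
) -> PotentialModel:
    """Build a :class:`PotentialModel` around an anchor table.

    The radial exponents must satisfy ``a < b``; all four vacuum anchors
    must be present.  By construction the model reproduces every anchor
    exactly: E(site, r_anchor, theta=0, medium) = epsilon.
    """
    if a >= b:
        raise ValueError(f"radial exponents need a < b, got a={a}, b={b}")
    table = anchors if anchors is not None else default_anchor_table()
    for site in SITES:
        if (site, "vacuum") not in table.anchors:
            raise ValueError(f"missing vacuum anchor for site {site!r}")
    return PotentialModel(anchors=table, a=a, b=b, e_max=e_max)
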