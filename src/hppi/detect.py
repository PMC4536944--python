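"""Classification of unit pairs as Hp-pi contacts or canonical H-bonds.

An Hp-pi bond is a perpendicular approach of an amide hydrogen to a
neighbouring peptide unit's pi-plane; a canonical backbone hydrogen bond
is the complementary in-plane, near-linear N-H...O=C geometry.  The two
regimes are geometrically exclusive, so a pair passing both gate sets is
recorded once, as an H-bond (precedence rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd

from .planes import ContactGeometry, contact_descriptors
from .potential import PotentialModel, calibrate
from .structure_io import (
    PeptideUnit,
    Structure,
    build_peptide_units,
    compute_backbone_torsions,
    place_amide_hydrogens,
)

__all__ = [
    "DetectionParams",
    "HpPiContact",
    "SummaryStats",
    "classify_pair",
    "detect_hp_pi",
    "summarize_contacts",
    "analyze_loop",
    "contacts_to_dataframe",
]


@dataclass(frozen=True)
class DetectionParams:
    """Geometric gates for contact classification (A / degrees).

    The Hp-pi gates bracket the calibration geometries (anchor distances
    2.3-2.6 A, perpendicular approach): best-site distance at most
    ``r_max``, approach angle at most ``theta_max``, hydrogen at least
    ``d_perp_min`` above the plane, and the in-plane projection either
    within ``inplane_tol`` of a site point or inside the N-C-O triangle.
    The H-bond gates demand a short in-plane, near-linear N-H...O
    geometry.  Both orders of every unit pair with sequence separation at
    least ``min_separation`` are evaluated; a unit never contacts itself.
    """

    r_max: float = 3.2
    theta_max: float = 35.0
    d_perp_min: float = 1.5
    inplane_tol: float = 1.2
    hb_r_max: float = 2.5
    hb_angle_min: float = 120.0
    hb_elevation_max: float = 30.0
    min_separation: int = 1

    def __post_init__(self) -> None:
        for name in ("r_max", "theta_max", "d_perp_min", "inplane_tol",
                     "hb_r_max", "hb_angle_min", "hb_elevation_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.theta_max > 90.0:
            raise ValueError("theta_max cannot exceed 90 degrees")


@dataclass
class HpPiContact:
    """One detected, scored contact between two peptide-bond units."""

    donor: PeptideUnit
    acceptor: PeptideUnit
    kind: str                    # "hp_pi" | "h_bond"
    site: str                    # best acceptor site ("O" for h_bond)
    geometry: ContactGeometry
    energy_vacuum: float
    energy_water: float

    @property
    def donor_residue(self):
        """Residue carrying the donor amide hydrogen."""
        return self.donor.res_next

    @property
    def acceptor_residue(self):
        """Residue owning the acceptor carbonyl."""
        return self.acceptor.res_prev


@dataclass
class SummaryStats:
    residues_analyzed: int
    n_hp_pi: int
    n_h_bond: int
    supported_residues: list[str]
    multiplicity: dict[str, int] = field(default_factory=dict)

    @property
    def n_supported(self) -> int:
        return len(self.supported_residues)


def _inside_triangle(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> bool:
    """Barycentric point-in-triangle test in the plane (2D inputs)."""
    v0, v1, v2 = c - a, b - a, p - a
    d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
    d20, d21 = v2 @ v0, v2 @ v1
    den = d00 * d11 - d01 * d01
    if abs(den) < 1e-12:
        return False
    u = (d11 * d20 - d01 * d21) / den
    v = (d00 * d21 - d01 * d20) / den
    return u >= -1e-9 and v >= -1e-9 and u + v <= 1.0 + 1e-9


def _inplane_gate(g: ContactGeometry, acceptor: PeptideUnit, tol: float) -> bool:
    from .planes import plane_frame

    frame = plane_frame(acceptor)
    p = np.array([g.u, g.v])
    pts = {}
    for name, pos in (("N", acceptor.n), ("C", acceptor.c), ("O", acceptor.o),
                      ("center", frame.origin)):
        u, v, _ = frame.to_plane_coords(pos)
        pts[name] = np.array([u, v])
    if any(np.linalg.norm(p - q) <= tol for q in pts.values()):
        return True
    return _inside_triangle(p, pts["N"], pts["C"], pts["O"])


def classify_pair(
    g: ContactGeometry,
    params: DetectionParams | None = None,
    acceptor: PeptideUnit | None = None,
) -> str:
    """Label a donor->acceptor geometry: ``"h_bond"``, ``"hp_pi"`` or ``"none"``.

    H-bond gates take precedence.  The in-plane projection gate needs the
    acceptor unit; when it is not supplied that gate is evaluated from the
    stored (u, v) offsets against the site projections implied by the
    geometry record's distances, so prefer passing ``acceptor``.
    """
    p = params or DetectionParams()
    if (
        g.r["O"] <= p.hb_r_max
        and g.angle_nho >= p.hb_angle_min
        and g.elevation_o <= p.hb_elevation_max
    ):
        return "h_bond"
    if (
        g.r[g.best_site] <= p.r_max
        and g.theta <= p.theta_max
        and g.d_perp >= p.d_perp_min
        and (acceptor is None or _inplane_gate(g, acceptor, p.inplane_tol))
    ):
        return "hp_pi"
    return "none"


def detect_hp_pi(
    s: Structure,
    params: DetectionParams | None = None,
    model: PotentialModel | None = None,
    add_hydrogens: bool = True,
) -> list[HpPiContact]:
    """Detect and score all Hp-pi and H-bond contacts in a structure.

    Every ordered (donor, acceptor) unit pair with sequence separation of
    at least ``params.min_separation`` is evaluated; output is sorted by
    donor then acceptor unit index.  Each record carries the full contact
    geometry and energies in both media (H-bond records use the H-bond
    comparator energy for both).
    """
    p = params or DetectionParams()
    m = model or calibrate()
    if add_hydrogens:
        place_amide_hydrogens(s)
    units = build_peptide_units(s)
    out: list[HpPiContact] = []
    for donor in units:
        if not donor.has_donor_h:
            continue
        for acceptor in units:
            if abs(donor.index - acceptor.index) < p.min_separation:
                continue
            g = contact_descriptors(donor, acceptor)
            kind = classify_pair(g, p, acceptor)
            if kind == "none":
                continue
            if kind == "h_bond":
                e = m.hbond_energy(g.r["O"], g.angle_nho)
                e_vac = e_wat = e
                site = "O"
            else:
                e_vac, site = m.contact_energy(g, "vacuum")
                e_wat, _ = m.contact_energy(g, "water")
            out.append(
                HpPiContact(
                    donor=donor,
                    acceptor=acceptor,
                    kind=kind,
                    site=site,
                    geometry=g,
                    energy_vacuum=e_vac,
                    energy_water=e_wat,
                )
            )
    out.sort(key=lambda c: (c.donor.index, c.acceptor.index))
    return out


def summarize_contacts(s: Structure, contacts: list[HpPiContact]) -> SummaryStats:
    """Per-structure support statistics.

    A residue is *supported* when it is the donor residue (amide-H owner)
    or the acceptor residue (carbonyl owner) of at least one Hp-pi
    contact.
    """
    mult: dict[str, int] = {}
    supported: set[str] = set()
    n_hp = n_hb = 0
    for c in contacts:
        if c.kind == "hp_pi":
            n_hp += 1
            for res in (c.donor_residue, c.acceptor_residue):
                supported.add(res.label)
                mult[res.label] = mult.get(res.label, 0) + 1
        else:
            n_hb += 1
    order = {r.label: i for i, r in enumerate(s.residues)}
    return SummaryStats(
        residues_analyzed=len(s.residues),
        n_hp_pi=n_hp,
        n_h_bond=n_hb,
        supported_residues=sorted(supported, key=lambda x: order.get(x, 1 << 30)),
        multiplicity=mult,
    )


def contacts_to_dataframe(contacts: list[HpPiContact]) -> pd.DataFrame:
    rows = []
    for c in contacts:
        g = c.geometry
        rows.append(
            {
                "donor_res": c.donor_residue.label,
                "acceptor_res": c.acceptor_residue.label,
                "class": c.kind,
                "site": c.site,
                "r": round(g.r[c.site] if c.kind == "hp_pi" else g.r["O"], 3),
                "theta": round(g.theta, 2),
                "d_perp": round(g.d_perp, 3),
                "E_vac": round(c.energy_vacuum, 3),
                "E_water": round(c.energy_water, 3),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["donor_res", "acceptor_res", "class", "site",
                 "r", "theta", "d_perp", "E_vac", "E_water"],
    )


def analyze_loop(
    s: Structure,
    chain_id: str,
    first: int,
    last: int,
    params: DetectionParams | None = None,
    model: PotentialModel | None = None,
) -> dict:
    """End-to-end loop analysis: slice, protonate, detect, summarise.

    Returns a dict with the sliced structure, contacts, summary statistics
    and backbone torsions of the slice.
    """
    loop = s.slice_residues(chain_id, first, last)
    contacts = detect_hp_pi(loop, params=params, model=model)
    summary = summarize_contacts(loop, contacts)
    torsions = compute_backbone_torsions(loop)
    return {
        "structure": loop,
        "contacts": contacts,
        "summary": summary,
        "torsions": torsions,
    }
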