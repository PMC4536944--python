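"""Rigid dipeptide builder, Phi-Psi conformational scan and region labels.

A blocked alanine dipeptide CH3-CO-NH-CaH(CH3)-CO-NH-CH3 contains exactly
two peptide-bond units (p1: acetyl C=O with the alanine N-H; p2: alanine
C=O with the N-methyl N-H), so its (Phi, Psi) torsions place the donor
hydrogen of one unit against the pi-plane of the other.  The builder uses
a fixed standard-restraint internal-coordinate set and natural-extension
(NeRF) placement, so requested torsions are reproduced exactly.

The scan evaluates the calibrated empirical contact potential over an
inclusive (Phi, Psi) grid, with a hard-sphere clash penalty standing in
for sterically impossible conformations.  It reproduces the basin
*topology and geometry* of the torsion map — not quantum-chemical energy
values, which depend on a reference-state convention this package does
not compute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .potential import PotentialModel, calibrate
from .structure_io import (
    AtomRecord,
    Chain,
    PeptideUnit,
    Residue,
    Structure,
    build_peptide_units,
)
from .planes import contact_descriptors

__all__ = [
    "GeometryParams",
    "RegionLabel",
    "TorsionMap",
    "REGION_CENTERS",
    "place_atom",
    "build_dipeptide",
    "torsion_scan",
    "classify_conformation",
    "find_basins",
    "toroidal_distance",
]


@dataclass(frozen=True)
class GeometryParams:
    """Standard-restraint internal coordinates for backbone construction.

    Bond lengths in Angstrom, angles in degrees; the peptide bond is held
    planar trans (omega = 180) unless overridden per call.
    """

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    n_h: float = 1.010
    ca_cb: float = 1.521
    c_ch3: float = 1.505          # cap methyl carbon to carbonyl carbon
    ang_n_ca_c: float = 111.0
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8
    ang_c_n_h: float = 119.2
    ang_n_ca_cb: float = 110.4
    cb_torsion_offset: float = -122.6  # branch of Cb off the Phi torsion (L config)
    omega: float = 180.0

    def __post_init__(self) -> None:
        for name in ("n_ca", "ca_c", "c_n", "c_o", "n_h", "ca_cb", "c_ch3"):
            v = getattr(self, name)
            if not 0.9 <= v <= 1.8:
                raise ValueError(f"bond length {name}={v} outside [0.9, 1.8] A")
        for name in (
            "ang_n_ca_c", "ang_ca_c_n", "ang_c_n_ca",
            "ang_ca_c_o", "ang_c_n_h", "ang_n_ca_cb",
        ):
            v = getattr(self, name)
            if not 90.0 < v < 135.0:
                raise ValueError(f"angle {name}={v} outside (90, 135) degrees")

    @property
    def ang_n_c_o(self) -> float:
        """In-plane sp2 closure: N-C=O angle."""
        return 360.0 - self.ang_ca_c_n - self.ang_ca_c_o


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place atom D so |C-D| = bond, angle(B,C,D) = angle, torsion(A,B,C,D) = torsion.

    Natural extension of reference frames (NeRF); torsion follows the
    IUPAC sign convention.
    """
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def _residue(
    chain_id: str, name: str, seq: int, atoms: dict[str, np.ndarray]
) -> Residue:
    res = Residue(name, seq, chain_id)
    for atom_name, pos in atoms.items():
        element = "H" if atom_name.startswith("H") else atom_name[0]
        res.add(AtomRecord(atom_name, name, chain_id, seq, pos, element))
    return res


def build_dipeptide(
    phi: float,
    psi: float,
    params: GeometryParams | None = None,
    omega: float | None = None,
) -> Structure:
    """Blocked alanine dipeptide at exact (Phi, Psi), both omegas trans.

    Residues: ACE (CH3, C, O) - ALA (N, H, CA, CB, C, O) - NME (N, H, CH3).
    Recomputing backbone torsions on the result returns the inputs to
    numerical precision.
    """
    g = params or GeometryParams()
    om = g.omega if omega is None else omega
    phi = _wrap_angle(phi)
    psi = _wrap_angle(psi)

    ch3a = np.zeros(3)
    ca_ = ch3a + np.array([g.c_ch3, 0.0, 0.0])
    ang = math.radians(180.0 - g.ang_ca_c_n)
    na = ca_ + g.c_n * np.array([math.cos(ang), math.sin(ang), 0.0])

    caa = place_atom(ch3a, ca_, na, g.n_ca, g.ang_c_n_ca, om)
    cala = place_atom(ca_, na, caa, g.ca_c, g.ang_n_ca_c, phi)
    nn = place_atom(na, caa, cala, g.c_n, g.ang_ca_c_n, psi)
    ch3n = place_atom(caa, cala, nn, g.n_ca, g.ang_c_n_ca, om)

    oa = place_atom(caa, na, ca_, g.c_o, g.ang_n_c_o, 0.0)
    ha = place_atom(ch3a, ca_, na, g.n_h, g.ang_c_n_h, 0.0)
    cb = place_atom(ca_, na, caa, g.ca_cb, g.ang_n_ca_cb, phi + g.cb_torsion_offset)
    on = place_atom(ch3n, nn, cala, g.c_o, g.ang_n_c_o, 0.0)
    hn = place_atom(caa, cala, nn, g.n_h, g.ang_c_n_h, 0.0)

    chain = Chain("A")
    chain.residues = [
        _residue("A", "ACE", 1, {"CH3": ch3a, "C": ca_, "O": oa}),
        _residue("A", "ALA", 2, {"N": na, "H": ha, "CA": caa, "CB": cb, "C": cala, "O": on}),
        _residue("A", "NME", 3, {"N": nn, "H": hn, "CH3": ch3n}),
    ]
    return Structure(
        chains=[chain], provenance=f"dipeptide phi={phi:g} psi={psi:g}"
    )


def _wrap_angle(x: float) -> float:
    """Wrap into (-180, 180]."""
    x = math.fmod(x, 360.0)
    if x <= -180.0:
        x += 360.0
    elif x > 180.0:
        x -= 360.0
    return x


# ---------------------------------------------------------------------------
# region classification

#: Fixed label order (also the tie-break order), centers in degrees.
REGION_CENTERS: tuple[tuple[str, tuple[float, float]], ...] = (
    ("alpha", (-65.0, -40.0)),
    ("beta", (-165.0, 165.0)),
    ("hpi1", (-90.0, 70.0)),
    ("hpi2", (60.0, 40.0)),
    ("hpi3", (80.0, -65.0)),
    ("hpi4", (-140.0, -70.0)),
    ("barrier_center", (0.0, 0.0)),
    ("barrier_NS", (0.0, 180.0)),
    ("barrier_EW", (180.0, 0.0)),
    ("reference", (90.0, 180.0)),
)


@dataclass(frozen=True)
class RegionLabel:
    """Torsion-space region assignment by nearest center on the torus."""

    name: str
    center: tuple[float, float]
    distance: float               # toroidal degrees to the center
    second: str | None = None     # next-nearest region (basins overlap)


def toroidal_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Euclidean distance on the (Phi, Psi) torus with 360-degree wrap."""
    dphi = abs(a[0] - b[0]) % 360.0
    dpsi = abs(a[1] - b[1]) % 360.0
    dphi = min(dphi, 360.0 - dphi)
    dpsi = min(dpsi, 360.0 - dpsi)
    return math.hypot(dphi, dpsi)


def classify_conformation(phi: float, psi: float) -> RegionLabel:
    """Nearest region center under the toroidal metric; ties break by the
    fixed order of ``REGION_CENTERS``."""
    p = (phi, psi)
    dists = [(toroidal_distance(p, ctr), i) for i, (_, ctr) in enumerate(REGION_CENTERS)]
    dists.sort(key=lambda t: (t[0], t[1]))
    (d0, i0), (_, i1) = dists[0], dists[1]
    name, center = REGION_CENTERS[i0]
    return RegionLabel(name=name, center=center, distance=d0, second=REGION_CENTERS[i1][0])


# ---------------------------------------------------------------------------
# torsion scan

# Covalent bond graph of the blocked dipeptide, by (residue seq, atom name).
_BONDS = [
    ((1, "CH3"), (1, "C")),
    ((1, "C"), (1, "O")),
    ((1, "C"), (2, "N")),
    ((2, "N"), (2, "H")),
    ((2, "N"), (2, "CA")),
    ((2, "CA"), (2, "CB")),
    ((2, "CA"), (2, "C")),
    ((2, "C"), (2, "O")),
    ((2, "C"), (3, "N")),
    ((3, "N"), (3, "H")),
    ((3, "N"), (3, "CH3")),
]


def _excluded_pairs() -> frozenset[frozenset]:
    """Atom pairs within two bonds (1-2 and 1-3) — not checked for clashes."""
    adj: dict = {}
    for x, y in _BONDS:
        adj.setdefault(x, set()).add(y)
        adj.setdefault(y, set()).add(x)
    excluded = set()
    for x, y in _BONDS:
        excluded.add(frozenset((x, y)))
    for center, nbrs in adj.items():
        for p in nbrs:
            for q in nbrs:
                if p != q:
                    excluded.add(frozenset((p, q)))
    return frozenset(excluded)


_EXCLUDED = _excluded_pairs()

HEAVY_CLASH = 2.4   # A, nonbonded heavy-heavy closer than this is a clash
H_CLASH = 1.6       # A, nonbonded H-heavy


def _is_clashed(s: Structure) -> bool:
    atoms = [
        ((res.seq, a.name), a.name.startswith("H"), a.position)
        for res in s.residues
        for a in res.atoms.values()
    ]
    for i in range(len(atoms)):
        key_i, is_h_i, p_i = atoms[i]
        for j in range(i + 1, len(atoms)):
            key_j, is_h_j, p_j = atoms[j]
            if is_h_i and is_h_j:
                continue
            if frozenset((key_i, key_j)) in _EXCLUDED:
                continue
            cutoff = H_CLASH if (is_h_i or is_h_j) else HEAVY_CLASH
            if np.linalg.norm(p_i - p_j) < cutoff:
                return True
    return False


@dataclass
class TorsionMap:
    """Inclusive (Phi, Psi) grid of surrogate contact energies.

    Both -180 and +180 nodes are present (the seam is duplicated), so a
    step of s degrees yields (360/s + 1)^2 nodes.
    """

    phi: np.ndarray
    psi: np.ndarray
    energy: np.ndarray          # (n_phi, n_psi), kJ/mol
    d_ho: np.ndarray            # H(p2)...O(p1), A
    d_hn: np.ndarray            # H(p2)...N(p1), A
    d_hc: np.ndarray            # H(p1)...C(p2), A
    region: np.ndarray          # region names, dtype object
    e_max: float

    @property
    def n_nodes(self) -> int:
        return int(self.energy.size)

    def to_dataframe(self):
        import pandas as pd

        pp, ss = np.meshgrid(self.phi, self.psi, indexing="ij")
        return pd.DataFrame(
            {
                "phi": pp.ravel(),
                "psi": ss.ravel(),
                "energy": self.energy.ravel(),
                "d_HO": self.d_ho.ravel(),
                "d_HN": self.d_hn.ravel(),
                "d_HC": self.d_hc.ravel(),
                "region": self.region.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def torsion_scan(
    step: float = 5.0,
    params: GeometryParams | None = None,
    model: PotentialModel | None = None,
) -> TorsionMap:
    """Scan the dipeptide over an inclusive (Phi, Psi) grid.

    Surrogate energy per node: the lowest directed unit-pair contact
    energy (both donor->acceptor orders, all four sites, vacuum), with a
    hard-sphere clash penalty — any nonbonded heavy-heavy pair under
    2.4 A or H-heavy pair under 1.6 A caps the node at ``model.e_max``.
    """
    if step <= 0 or abs(360.0 / step - round(360.0 / step)) > 1e-9:
        raise ValueError(f"step must divide 360, got {step}")
    g = params or GeometryParams()
    m = model or calibrate()
    n = int(round(360.0 / step)) + 1
    phis = -180.0 + step * np.arange(n)
    psis = -180.0 + step * np.arange(n)

    energy = np.empty((n, n))
    d_ho = np.empty((n, n))
    d_hn = np.empty((n, n))
    d_hc = np.empty((n, n))
    region = np.empty((n, n), dtype=object)

    for i, phi in enumerate(phis):
        for j, psi in enumerate(psis):
            s = build_dipeptide(phi, psi, g)
            p1, p2 = build_peptide_units(s)
            d_ho[i, j] = np.linalg.norm(p2.h - p1.o)
            d_hn[i, j] = np.linalg.norm(p2.h - p1.n)
            d_hc[i, j] = np.linalg.norm(p1.h - p2.c)
            if _is_clashed(s):
                e = m.e_max
            else:
                e = min(
                    m.contact_energy(contact_descriptors(p2, p1))[0],
                    m.contact_energy(contact_descriptors(p1, p2))[0],
                )
                e = min(e, m.e_max)
            energy[i, j] = e
            region[i, j] = classify_conformation(phi, psi).name
    return TorsionMap(
        phi=phis, psi=psis, energy=energy,
        d_ho=d_ho, d_hn=d_hn, d_hc=d_hc,
        region=region, e_max=m.e_max,
    )


def find_basins(tmap: TorsionMap) -> list[tuple[float, float, float]]:
    """Toroidal 8-neighbour local minima below 0 kJ/mol, deepest first.

    The duplicated +180 seam row/column is dropped before wrap-around
    comparison so seam nodes are not counted twice.
    """
    e = tmap.energy[:-1, :-1]
    is_min = np.ones_like(e, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            is_min &= e < np.roll(np.roll(e, di, axis=0), dj, axis=1)
    is_min &= e < 0.0
    out = [
        (float(tmap.phi[i]), float(tmap.psi[j]), float(e[i, j]))
        for i, j in zip(*np.nonzero(is_min))
    ]
    out.sort(key=lambda t: t[2])
    return out
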