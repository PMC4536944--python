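"""Synthetic test structures: ideal segments, posed unit pairs, random decoys.

Everything a test needs is generated here from internal coordinates — no
structure files, no network.  Segments are poly-alanine chains built at
prescribed per-residue (Phi, Psi); pair fixtures are two blocked
single-peptide-unit molecules (the NMA model of a peptide bond) posed at
an exact contact geometry; decoys are seeded uniform-torsion chains with
clash rejection, the least-informative null for property tests.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .structure_io import (
    AtomRecord,
    Chain,
    Residue,
    Structure,
    build_peptide_units,
    transform,
    write_pdb,
)
from .planes import SITES, plane_frame
from .torsion import GeometryParams, place_atom, _residue

__all__ = [
    "make_ideal_segment",
    "make_nma_unit",
    "make_hp_pi_pair",
    "make_hbond_pair",
    "make_beta_pair",
    "make_decoy",
    "write_fixture_suite",
]


def make_ideal_segment(
    torsions: list[tuple[float, float]],
    params: GeometryParams | None = None,
    chain_id: str = "A",
    start_seq: int = 1,
) -> Structure:
    """Poly-alanine chain with exact per-residue (Phi, Psi), omega = 180.

    ``torsions[i]`` gives (Phi, Psi) of residue i+1.  Phi of the first
    residue only orients its side chain; amide hydrogens are present from
    residue 2 on (the chain start has no preceding carbonyl).
    """
    if len(torsions) < 2:
        raise ValueError("segment needs at least 2 residues")
    g = params or GeometryParams()
    n_res = len(torsions)

    n = [None] * n_res
    ca = [None] * n_res
    c = [None] * n_res
    n[0] = np.zeros(3)
    ca[0] = np.array([g.n_ca, 0.0, 0.0])
    ang = math.radians(180.0 - g.ang_n_ca_c)
    c[0] = ca[0] + g.ca_c * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(n_res - 1):
        psi_i = torsions[i][1]
        n[i + 1] = place_atom(n[i], ca[i], c[i], g.c_n, g.ang_ca_c_n, psi_i)
        ca[i + 1] = place_atom(ca[i], c[i], n[i + 1], g.n_ca, g.ang_c_n_ca, g.omega)
        c[i + 1] = place_atom(c[i], n[i + 1], ca[i + 1], g.ca_c, g.ang_n_ca_c,
                              torsions[i + 1][0])

    chain = Chain(chain_id)
    for i in range(n_res):
        atoms: dict[str, np.ndarray] = {"N": n[i], "CA": ca[i], "C": c[i]}
        atoms["O"] = place_atom(n[i], ca[i], c[i], g.c_o, g.ang_ca_c_o,
                                torsions[i][1] + 180.0)
        if i > 0:
            atoms["H"] = place_atom(ca[i - 1], c[i - 1], n[i], g.n_h, g.ang_c_n_h, 0.0)
            cb_frame = (c[i - 1], n[i], ca[i])
        else:
            # virtual preceding carbonyl so Phi of residue 1 orients the Cb
            c_virtual = place_atom(c[0], ca[0], n[0], g.c_n, g.ang_c_n_ca,
                                   torsions[0][0])
            cb_frame = (c_virtual, n[0], ca[0])
        atoms["CB"] = place_atom(*cb_frame, g.ca_cb, g.ang_n_ca_cb,
                                 torsions[i][0] + g.cb_torsion_offset)
        chain.residues.append(
            _residue(chain_id, "ALA", start_seq + i, atoms)
        )
    return Structure(chains=[chain], provenance=f"ideal segment n={n_res}")


def make_nma_unit(params: GeometryParams | None = None, chain_id: str = "A",
                  start_seq: int = 1) -> Structure:
    """One blocked peptide-bond unit CH3-CO-NH-CH3 (the NMA model system)."""
    g = params or GeometryParams()
    ch3a = np.zeros(3)
    c = ch3a + np.array([g.c_ch3, 0.0, 0.0])
    ang = math.radians(180.0 - g.ang_ca_c_n)
    n = c + g.c_n * np.array([math.cos(ang), math.sin(ang), 0.0])
    ch3n = place_atom(ch3a, c, n, g.n_ca, g.ang_c_n_ca, g.omega)
    o = place_atom(ch3n, n, c, g.c_o, g.ang_n_c_o, 0.0)
    h = place_atom(ch3a, c, n, g.n_h, g.ang_c_n_h, 0.0)
    chain = Chain(chain_id)
    chain.residues = [
        _residue(chain_id, "ACE", start_seq, {"CH3": ch3a, "C": c, "O": o}),
        _residue(chain_id, "NME", start_seq + 1, {"N": n, "H": h, "CH3": ch3n}),
    ]
    return Structure(chains=[chain], provenance="NMA unit")


def _merge(a: Structure, b: Structure) -> Structure:
    out = Structure(provenance=f"{a.provenance} + {b.provenance}")
    out.chains = [*a.chains, *b.chains]
    return out


def _orthonormal_to(d: np.ndarray) -> np.ndarray:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    t = helper - (helper @ d) * d
    return t / np.linalg.norm(t)


def _rotation_between_frames(
    x_from: np.ndarray, y_from: np.ndarray, x_to: np.ndarray, y_to: np.ndarray
) -> np.ndarray:
    """Rotation mapping one right-handed orthonormal pair onto another."""

    def frame(x, y):
        z = np.cross(x, y)
        return np.column_stack([x, y, z])

    return frame(x_to, y_to) @ frame(x_from, y_from).T


def _posed_donor(
    h_target: np.ndarray,
    nh_dir: np.ndarray,
    spin_ref: np.ndarray,
    params: GeometryParams | None,
) -> Structure:
    """A donor NMA unit rigidly moved so its amide H sits at ``h_target``
    with the N->H bond along ``nh_dir``; the spin about the bond axis is
    fixed by ``spin_ref``."""
    donor = make_nma_unit(params, chain_id="B", start_seq=3)
    unit = build_peptide_units(donor)[0]
    nh = unit.h - unit.n
    nh_u = nh / np.linalg.norm(nh)
    # spin reference: the donor's own plane normal, mapped toward spin_ref
    ref_from = _perp_component(plane_frame(unit).normal, nh_u)
    ref_to = spin_ref - (spin_ref @ nh_dir) * nh_dir
    nrm = np.linalg.norm(ref_to)
    ref_to = _orthonormal_to(nh_dir) if nrm < 1e-9 else ref_to / nrm
    rot = _rotation_between_frames(nh_u, ref_from, nh_dir, ref_to)
    shift = h_target - rot @ unit.h
    return transform(donor, rot, shift)


def make_hp_pi_pair(
    site: str,
    r: float,
    theta: float = 0.0,
    params: GeometryParams | None = None,
) -> Structure:
    """Two NMA units posed at an exact Hp-pi geometry.

    The donor amide hydrogen is placed directly above the requested
    acceptor site at 3D distance ``r``, with the N-H bond tilted ``theta``
    degrees off the acceptor plane normal.  Contact descriptors computed
    on the result echo (site, r, theta) to numerical precision.
    """
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}")
    if r <= 0:
        raise ValueError("r must be positive")
    if not 0.0 <= theta <= 90.0:
        raise ValueError("theta must lie in [0, 90] degrees")
    acceptor = make_nma_unit(params, chain_id="A", start_seq=1)
    unit = build_peptide_units(acceptor)[0]
    frame = plane_frame(unit)
    site_point = {
        "N": unit.n, "C": unit.c, "O": unit.o, "center": frame.origin
    }[site]
    h_target = site_point + r * frame.normal
    th = math.radians(theta)
    nh_dir = math.cos(th) * frame.normal + math.sin(th) * frame.u_axis
    donor = _posed_donor(h_target, nh_dir, frame.normal, params)
    return _merge(acceptor, donor)


def make_hbond_pair(
    r_ho: float = 2.019,
    angle_nho: float = 180.0,
    params: GeometryParams | None = None,
) -> Structure:
    """Two NMA units in a coplanar, near-linear N-H...O=C hydrogen bond.

    The donor H sits in the acceptor plane, ``r_ho`` from the carbonyl O
    along the C=O direction, with the requested N-H...O angle (180 =
    linear).  Both pi-planes are parallel, the canonical H-bond geometry.
    """
    acceptor = make_nma_unit(params, chain_id="A", start_seq=1)
    unit = build_peptide_units(acceptor)[0]
    frame = plane_frame(unit)
    co = unit.o - unit.c
    co_u = co / np.linalg.norm(co)
    h_target = unit.o + r_ho * co_u
    # N-H...O angle at H: rotate the H->N direction away from H->O by
    # (180 - angle) within the acceptor plane.
    bend = math.radians(180.0 - angle_nho)
    in_plane = np.cross(frame.normal, co_u)
    hn_dir = math.cos(bend) * co_u + math.sin(bend) * in_plane
    nh_dir = -hn_dir  # bond vector N->H points at the oxygen when linear
    donor = _posed_donor(h_target, nh_dir, frame.normal, params)
    return _merge(acceptor, donor)


def make_beta_pair(
    n_residues: int = 6,
    params: GeometryParams | None = None,
) -> Structure:
    """Two extended beta strands joined by one canonical inter-strand H-bond.

    Both strands are ideal (-165, 165) poly-alanine; the second is rigidly
    posed so one of its amide hydrogens donates a coplanar, linear
    N-H...O=C bond (2.0 A) to the middle of the first strand, with the two
    peptide planes parallel — the sheet-like geometry in which hydrogen
    bonds, not Hp-pi bonds, hold the backbone together.
    """
    tors = [(-165.0, 165.0)] * n_residues
    strand_a = make_ideal_segment(tors, params, chain_id="A", start_seq=1)
    strand_b = make_ideal_segment(tors, params, chain_id="B", start_seq=101)
    units_a = build_peptide_units(strand_a)
    unit_a = units_a[len(units_a) // 2]
    frame = plane_frame(unit_a)
    co_u = unit_a.o - unit_a.c
    co_u /= np.linalg.norm(co_u)
    h_target = unit_a.o + 2.0 * co_u
    nh_dir = -co_u  # N->H bond vector aimed at the oxygen (linear N-H...O)

    units_b = build_peptide_units(strand_b)
    unit_b = units_b[len(units_b) // 2]
    nh = unit_b.h - unit_b.n
    nh_u = nh / np.linalg.norm(nh)
    frame_b = plane_frame(unit_b)
    rot = _rotation_between_frames(
        nh_u, _perp_component(frame_b.normal, nh_u),
        nh_dir, _perp_component(frame.normal, nh_dir),
    )
    shift = h_target - rot @ unit_b.h
    strand_b = transform(strand_b, rot, shift)
    return _merge(strand_a, strand_b)


def _perp_component(v: np.ndarray, d: np.ndarray) -> np.ndarray:
    w = v - (v @ d) * d
    n = np.linalg.norm(w)
    return _orthonormal_to(d) if n < 1e-9 else w / n


class DecoyError(RuntimeError):
    """Clash-free decoy could not be built within the retry budget."""


def make_decoy(
    length: int,
    seed: int,
    params: GeometryParams | None = None,
    max_retries: int = 60,
) -> Structure:
    """Random-torsion poly-alanine decoy chain, clash-rejected, seeded.

    (Phi, Psi) are drawn uniformly on the torus residue by residue; a
    residue whose placement clashes with atoms two or more residues back
    (any heavy-heavy pair under 2.4 A) is redrawn, up to ``max_retries``
    times.  Identical seeds give identical structures.
    """
    if length < 3:
        raise ValueError("decoy needs at least 3 residues")
    rng = np.random.default_rng(seed)

    def draw() -> tuple[float, float]:
        phi, psi = rng.uniform(-180.0, 180.0, 2)
        return (float(phi), float(psi))

    # Grow residue by residue; a clash at residue k may be baked in by the
    # torsions of earlier residues (their atoms only become constrained
    # once the chain extends past them), so on retry exhaustion we
    # backtrack one residue and redraw.
    tors: list[tuple[float, float]] = [draw()]
    backtracks = 0
    while len(tors) < length:
        for _ in range(max_retries):
            cand = draw()
            trial = make_ideal_segment(tors + [cand], params)
            if not _tail_clash(trial):
                tors.append(cand)
                break
        else:
            backtracks += 1
            if backtracks > 20 * length:
                raise DecoyError(
                    f"retry budget exhausted at residue {len(tors) + 1} "
                    f"(seed {seed})"
                )
            if len(tors) > 1:
                tors.pop()
            else:
                tors = [draw()]
    s = make_ideal_segment(tors, params)
    s.provenance = f"decoy length={length} seed={seed}"
    return s


def _tail_clash(s: Structure, cutoff: float = 2.4) -> bool:
    """True when any heavy atom of the last residue sits under ``cutoff``
    from a heavy atom two or more residues back."""
    residues = s.residues
    tail = [a.position for a in residues[-1].atoms.values() if a.element != "H"]
    for res in residues[:-2]:
        for atom in res.atoms.values():
            if atom.element == "H":
                continue
            for p in tail:
                if np.linalg.norm(atom.position - p) < cutoff:
                    return True
    return False


def write_fixture_suite(out_dir: str | Path, seed: int = 17) -> dict:
    """Write the standard fixture set as PDB files plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixtures = {
        "helix_10.pdb": make_ideal_segment([(-65.0, -40.0)] * 10),
        "strand_8.pdb": make_ideal_segment([(-165.0, 165.0)] * 8),
        "beta_pair.pdb": make_beta_pair(),
        "hp_pi_O.pdb": make_hp_pi_pair("O", 2.368, 0.0),
        "hp_pi_N.pdb": make_hp_pi_pair("N", 2.310, 0.0),
        "hbond_pair.pdb": make_hbond_pair(),
        "decoy_12.pdb": make_decoy(12, seed),
    }
    manifest = {"seed": seed, "files": {}}
    for name, s in fixtures.items():
        (out / name).write_text(write_pdb(s))
        manifest["files"][name] = {
            "provenance": s.provenance,
            "residues": len(s.residues),
            "atoms": s.atom_count(),
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
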