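"""Structure reading/writing, peptide-bond units, amide hydrogens, backbone torsions.

The in-memory model is deliberately small: ordered chains of residues of
named atoms, carrying only what backbone geometry needs (names, residue
identity with insertion codes, Cartesian coordinates).  Parsing and PDB
serialisation are delegated to :mod:`gemmi`; this module adds the
domain-level assembly on top: peptide-bond units (the planar C(=O)-N(H)
group linking consecutive residues), planar amide-hydrogen reconstruction,
and IUPAC backbone torsions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "Structure",
    "PeptideUnit",
    "TorsionTriple",
    "ParseError",
    "parse_pdb",
    "write_pdb",
    "build_peptide_units",
    "place_amide_hydrogens",
    "compute_backbone_torsions",
    "dihedral",
    "transform",
]

#: Nominal N-H bond length used when reconstructing amide hydrogens, Angstrom.
N_H_BOND_LENGTH = 1.010

#: C(i)-N(i+1) distances above this are treated as chain breaks, Angstrom.
CHAIN_BREAK_CN = 1.8

# Accepted covalent ranges for the peptide-plane bonds (Angstrom).
C_O_RANGE = (1.1, 1.4)
C_N_RANGE = (1.2, 1.5)


class ParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


@dataclass
class AtomRecord:
    """A single atom: label, residue identity and Cartesian position (A)."""

    name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    position: np.ndarray
    element: str = ""
    icode: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class Residue:
    name: str
    seq: int
    chain_id: str
    icode: str = ""
    atoms: dict[str, AtomRecord] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq, self.icode)

    @property
    def label(self) -> str:
        return f"{self.name}{self.seq}{self.icode}".strip()

    def get(self, *names: str) -> np.ndarray | None:
        """Position of the first present atom among ``names`` (or None)."""
        for n in names:
            if n in self.atoms:
                return self.atoms[n].position
        return None

    def add(self, atom: AtomRecord, overwrite: bool = False) -> None:
        if atom.name in self.atoms and not overwrite:
            return  # first occurrence wins (altloc policy)
        self.atoms[atom.name] = atom


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)


@dataclass
class Structure:
    """Ordered chains of residues; the container all operations work on."""

    chains: list[Chain] = field(default_factory=list)
    provenance: str = ""

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    @property
    def residues(self) -> list[Residue]:
        return [r for c in self.chains for r in c.residues]

    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def slice_residues(self, chain_id: str, first: int, last: int) -> "Structure":
        """Sub-structure with residues ``first``..``last`` (inclusive) of a chain."""
        src = self.chain(chain_id)
        kept = [r for r in src.residues if first <= r.seq <= last]
        out = Structure(provenance=f"{self.provenance} [{chain_id}:{first}-{last}]")
        out.chains.append(Chain(chain_id, kept))
        return out


@dataclass
class PeptideUnit:
    """One peptide-bond unit: C(=O) of residue k bonded to N(-H) of residue k+1.

    The pi-plane of the unit is spanned by atoms N, C, O.  The amide
    hydrogen (when present) makes the unit a donor; the plane makes every
    unit an acceptor.
    """

    index: int
    res_prev: Residue   # residue k, owner of C=O
    res_next: Residue   # residue k+1, owner of N-H (the donor residue)
    c: np.ndarray
    o: np.ndarray
    n: np.ndarray
    ca_prev: np.ndarray
    ca_next: np.ndarray
    h: np.ndarray | None = None

    @property
    def has_donor_h(self) -> bool:
        return self.h is not None

    @property
    def label(self) -> str:
        return f"{self.res_prev.label}-{self.res_next.label}"


@dataclass
class TorsionTriple:
    """Backbone torsions of one residue, degrees in (-180, 180].

    Entries are ``None`` where a defining atom is missing (chain termini)
    or the defining atoms are numerically collinear.
    """

    phi: float | None
    psi: float | None
    omega: float | None


# ---------------------------------------------------------------------------
# geometry primitives


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float | None:
    """IUPAC-sign dihedral angle p1-p2-p3-p4 in degrees, range (-180, 180].

    Returns ``None`` when either atom triple is collinear (cross-product
    norm below 1e-9), where the angle is undefined.
    """
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) <= 1e-9 or np.linalg.norm(n2) <= 1e-9:
        return None
    ang = math.degrees(
        gemmi.calculate_dihedral(
            gemmi.Position(*np.asarray(p1, float)),
            gemmi.Position(*np.asarray(p2, float)),
            gemmi.Position(*np.asarray(p3, float)),
            gemmi.Position(*np.asarray(p4, float)),
        )
    )
    if ang <= -180.0:
        ang += 360.0
    return ang


def transform(s: Structure, rotation: np.ndarray, translation: np.ndarray) -> Structure:
    """Apply the rigid motion ``x -> R x + t`` to every atom (new Structure)."""
    R = np.asarray(rotation, float)
    t = np.asarray(translation, float)
    out = Structure(provenance=s.provenance)
    for chain in s.chains:
        new_chain = Chain(chain.id)
        for res in chain.residues:
            new_res = Residue(res.name, res.seq, res.chain_id, res.icode)
            for atom in res.atoms.values():
                new_res.add(
                    AtomRecord(
                        atom.name,
                        atom.residue_name,
                        atom.chain_id,
                        atom.residue_seq,
                        R @ atom.position + t,
                        atom.element,
                        atom.icode,
                    )
                )
            new_chain.residues.append(new_res)
        out.chains.append(new_chain)
    return out


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)

_WATER_NAMES = {"HOH", "WAT", "DOD"}

# Backbone blocking groups are kept even when a writer emits them as HETATM.
_CAP_NAMES = {"ACE", "NME", "NMA"}


def _validate_atom_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fld = line[lo:hi]
                try:
                    float(fld)
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: malformed coordinate field {fld!r}"
                    ) from None


def parse_pdb(text: str, provenance: str = "") -> Structure:
    """Parse fixed-column PDB text into a :class:`Structure`.

    ATOM records are kept; HETATM records and waters are dropped, as are
    alternate locations other than the first/highest-occupancy conformer.
    Insertion codes are preserved in residue identity.
    """
    if not text.strip():
        raise ParseError("empty input")
    _validate_atom_lines(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise ParseError(str(exc)) from exc
    if len(st) == 0:
        raise ParseError("no ATOM records found")
    st.remove_alternative_conformations()

    out = Structure(provenance=provenance or st.name)
    n_in = n_kept = 0
    model = st[0]
    for gchain in model:
        chain = Chain(gchain.name)
        for gres in gchain:
            n_in += len(gres)
            if gres.name in _WATER_NAMES or (
                gres.het_flag == "H" and gres.name not in _CAP_NAMES
            ):
                continue
            res = Residue(gres.name, gres.seqid.num, gchain.name, gres.seqid.icode.strip())
            for ga in gres:
                res.add(
                    AtomRecord(
                        ga.name,
                        gres.name,
                        gchain.name,
                        gres.seqid.num,
                        np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        ga.element.name.strip(),
                        gres.seqid.icode.strip(),
                    )
                )
            n_kept += len(res.atoms)
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            chain.residues.sort(key=lambda r: (r.seq, r.icode))
            out.chains.append(chain)
    if not out.chains:
        raise ParseError("no ATOM records found")
    logger.info("parsed %d atoms, kept %d, dropped %d", n_in, n_kept, n_in - n_kept)
    return out


def write_pdb(s: Structure) -> str:
    """Serialise to standard 80-column PDB ATOM records."""
    st = gemmi.Structure()
    st.name = s.provenance or "hppi"
    model = gemmi.Model("1")
    for chain in s.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq, res.icode or " ")
            for atom in res.atoms.values():
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = 1.0
                ga.b_iso = 0.0
                ga.element = gemmi.Element(atom.element or atom.name[0])
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


# ---------------------------------------------------------------------------
# peptide units


def _flanking_carbon(res: Residue) -> np.ndarray | None:
    # Capping groups (acetyl / N-methyl) stand in with their methyl carbon.
    return res.get("CA", "CH3", "CAY", "CAT")


def build_peptide_units(s: Structure) -> list[PeptideUnit]:
    """Assemble one peptide-bond unit per bonded consecutive residue pair.

    Pairs with a C(i)-N(i+1) distance above 1.8 A (chain break) or with a
    missing plane atom are skipped silently (logged).  Units are indexed in
    sequence order across the structure.
    """
    units: list[PeptideUnit] = []
    k = 0
    for chain in s.chains:
        for prev, nxt in zip(chain.residues, chain.residues[1:]):
            c = prev.get("C")
            o = prev.get("O")
            n = nxt.get("N")
            ca_prev = _flanking_carbon(prev)
            ca_next = _flanking_carbon(nxt)
            if c is None or o is None or n is None or ca_prev is None or ca_next is None:
                logger.debug("unit %s-%s skipped: missing backbone atom", prev.label, nxt.label)
                continue
            d_cn = float(np.linalg.norm(n - c))
            if d_cn > CHAIN_BREAK_CN:
                logger.debug("chain break %s-%s: C-N %.2f A", prev.label, nxt.label, d_cn)
                continue
            d_co = float(np.linalg.norm(o - c))
            if not (C_O_RANGE[0] <= d_co <= C_O_RANGE[1]) or not (
                C_N_RANGE[0] <= d_cn <= C_N_RANGE[1]
            ):
                logger.debug(
                    "unit %s-%s rejected: C-O %.2f / C-N %.2f outside covalent range",
                    prev.label, nxt.label, d_co, d_cn,
                )
                continue
            units.append(
                PeptideUnit(
                    index=k,
                    res_prev=prev,
                    res_next=nxt,
                    c=c,
                    o=o,
                    n=n,
                    ca_prev=ca_prev,
                    ca_next=ca_next,
                    h=nxt.get("H"),
                )
            )
            k += 1
    return units


def place_amide_hydrogens(s: Structure) -> Structure:
    """Reconstruct missing backbone amide hydrogens in place (returns ``s``).

    The hydrogen is set 1.010 A from N, in the plane of (C_prev, N, CA),
    opposite the bisector of the C_prev->N and CA->N directions — the
    standard planar (sp2) amide reconstruction.  Prolines and chain-start
    residues get no hydrogen; hydrogens already present are kept.
    """
    for chain in s.chains:
        for prev, res in zip(chain.residues, chain.residues[1:]):
            if res.name == "PRO" or "H" in res.atoms:
                continue
            n = res.get("N")
            ca = _flanking_carbon(res)
            c_prev = prev.get("C")
            if n is None or ca is None or c_prev is None:
                logger.debug("no H for %s: missing N/CA/C_prev", res.label)
                continue
            if np.linalg.norm(c_prev - n) > CHAIN_BREAK_CN:
                continue
            u1 = (c_prev - n) / np.linalg.norm(c_prev - n)
            u2 = (ca - n) / np.linalg.norm(ca - n)
            bis = u1 + u2
            nrm = np.linalg.norm(bis)
            if nrm < 1e-9:   # pathological straight C-N-CA
                logger.debug("no H for %s: collinear C_prev,N,CA", res.label)
                continue
            h = n - N_H_BOND_LENGTH * bis / nrm
            res.add(
                AtomRecord("H", res.name, res.chain_id, res.seq, h, "H", res.icode)
            )
    return s


def compute_backbone_torsions(
    s: Structure,
) -> Mapping[tuple[str, int, str], TorsionTriple]:
    """Phi/psi/omega per residue, keyed by (chain id, residue seq, icode).

    phi(i) = C(i-1)-N-CA-C, psi(i) = N-CA-C-N(i+1),
    omega(i) = CA(i-1)-C(i-1)-N-CA; IUPAC sign, degrees in (-180, 180].
    Torsions across a chain break, at termini, or with collinear defining
    atoms are ``None``.
    """
    out: dict[tuple[str, int, str], TorsionTriple] = {}
    for chain in s.chains:
        rs = chain.residues
        for i, res in enumerate(rs):
            n, ca, c = res.get("N"), res.get("CA"), res.get("C")
            phi = psi = omega = None
            prev = rs[i - 1] if i > 0 else None
            nxt = rs[i + 1] if i + 1 < len(rs) else None

            def bonded(a: np.ndarray | None, b: np.ndarray | None) -> bool:
                return (
                    a is not None and b is not None
                    and np.linalg.norm(a - b) <= CHAIN_BREAK_CN
                )

            if prev is not None and n is not None and bonded(prev.get("C"), n):
                c_prev = prev.get("C")
                if ca is not None and c is not None:
                    phi = dihedral(c_prev, n, ca, c)
                ca_prev = prev.get("CA", "CH3", "CAY", "CAT")
                if ca_prev is not None and ca is not None:
                    omega = dihedral(ca_prev, c_prev, n, ca)
            if nxt is not None and c is not None and bonded(c, nxt.get("N")):
                if n is not None and ca is not None:
                    psi = dihedral(n, ca, c, nxt.get("N"))
            out[res.key] = TorsionTriple(phi, psi, omega)
    return out
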