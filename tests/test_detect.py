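import math

import numpy as np
import pytest

from hppi.detect import (
    DetectionParams,
    classify_pair,
    contacts_to_dataframe,
    detect_hp_pi,
    summarize_contacts,
)
from hppi.fixtures import (
    make_beta_pair,
    make_decoy,
    make_hbond_pair,
    make_hp_pi_pair,
    make_ideal_segment,
)
from hppi.planes import contact_descriptors
from hppi.structure_io import build_peptide_units, write_pdb


def brute_force_classes(s, params):
    """Exhaustive all-pairs re-derivation of contact classes from raw
    coordinates, independent of the detector's code path."""
    units = build_peptide_units(s)
    found = {}
    for don in units:
        if don.h is None:
            continue
        for acc in units:
            if don.index == acc.index:
                continue
            h = don.h
            normal = np.cross(acc.c - acc.n, acc.o - acc.n)
            normal /= np.linalg.norm(normal)
            origin = (acc.n + acc.c + acc.o) / 3.0
            sites = {"N": acc.n, "C": acc.c, "O": acc.o, "center": origin}
            r = {k: float(np.linalg.norm(h - p)) for k, p in sites.items()}
            d_perp = abs(float((h - origin) @ normal))
            nh = h - don.n
            theta = math.degrees(
                math.acos(min(1.0, abs(nh @ normal) / np.linalg.norm(nh)))
            )
            hn = don.n - h
            ho = acc.o - h
            angle_nho = math.degrees(
                math.acos(
                    np.clip(hn @ ho / np.linalg.norm(hn) / np.linalg.norm(ho), -1, 1)
                )
            )
            elev = math.degrees(math.asin(min(1.0, d_perp / r["O"])))
            if r["O"] <= params.hb_r_max and angle_nho >= params.hb_angle_min and elev <= params.hb_elevation_max:
                found[(don.index, acc.index)] = "h_bond"
                continue
            best = min(r, key=r.get)
            proj = h - ((h - origin) @ normal) * normal
            near_site = any(
                np.linalg.norm(proj - p) <= params.inplane_tol
                for p in sites.values()
            )
            # inside-triangle via signed areas
            def side(p, a, b):
                return np.cross(b - a, p - a) @ normal

            inside = (
                side(proj, acc.n, acc.c) >= -1e-9
                and side(proj, acc.c, acc.o) >= -1e-9
                and side(proj, acc.o, acc.n) >= -1e-9
            ) or (
                side(proj, acc.n, acc.c) <= 1e-9
                and side(proj, acc.c, acc.o) <= 1e-9
                and side(proj, acc.o, acc.n) <= 1e-9
            )
            if (
                r[best] <= params.r_max
                and theta <= params.theta_max
                and d_perp >= params.d_perp_min
                and (near_site or inside)
            ):
                found[(don.index, acc.index)] = "hp_pi"
    return found


class TestClassifyPair:
    def test_perpendicular_anchor_pose_is_hp_pi(self):
        acc, don = build_peptide_units(make_hp_pi_pair("O", 2.368, 0.0))
        g = contact_descriptors(don, acc)
        assert classify_pair(g, acceptor=acc) == "hp_pi"
        assert g.best_site == "O"

    def test_coplanar_linear_pose_is_h_bond(self):
        acc, don = build_peptide_units(make_hbond_pair(2.019, 180.0))
        g = contact_descriptors(don, acc)
        assert classify_pair(g, acceptor=acc) == "h_bond"

    def test_bad_pose_is_none(self):
        acc, don = build_peptide_units(make_hp_pi_pair("center", 4.5, 80.0))
        g = contact_descriptors(don, acc)
        assert classify_pair(g, acceptor=acc) == "none"


class TestDetect:
    def test_constructed_positive_yields_one_contact(self, model):
        contacts = detect_hp_pi(make_hp_pi_pair("O", 2.368, 0.0), model=model)
        assert len(contacts) == 1
        c = contacts[0]
        assert c.kind == "hp_pi" and c.site == "O"
        assert abs(c.energy_vacuum - (-24.252)) < 1e-9

    def test_hbond_fixture_scored_at_comparator_anchor(self, model):
        contacts = detect_hp_pi(make_hbond_pair(2.019, 180.0), model=model)
        kinds = [c.kind for c in contacts]
        assert kinds.count("h_bond") == 1
        hb = contacts[kinds.index("h_bond")]
        assert abs(hb.energy_vacuum - (-24.391)) < 1e-9

    def test_beta_pair_has_hbonds_but_no_hp_pi(self, model):
        contacts = detect_hp_pi(make_beta_pair(), model=model)
        kinds = {c.kind for c in contacts}
        assert sum(c.kind == "h_bond" for c in contacts) >= 1
        assert "hp_pi" not in kinds

    def test_single_unit_structure_gives_nothing(self, model):
        assert detect_hp_pi(make_ideal_segment([(-65, -40)] * 2), model=model) == []

    def test_deterministic_ordering(self, model):
        s1 = make_decoy(10, seed=5)
        s2 = make_decoy(10, seed=5)
        c1 = contacts_to_dataframe(detect_hp_pi(s1, model=model))
        c2 = contacts_to_dataframe(detect_hp_pi(s2, model=model))
        assert c1.to_csv() == c2.to_csv()

    def test_no_pair_reported_twice(self, model):
        for seed in range(5):
            contacts = detect_hp_pi(make_decoy(8, seed=seed), model=model)
            keys = [(c.donor.index, c.acceptor.index) for c in contacts]
            assert len(keys) == len(set(keys))

    def test_emitted_contacts_pass_gate_self_audit(self, model):
        p = DetectionParams()
        for seed in range(30):
            s = make_decoy(12, seed=seed)
            for c in detect_hp_pi(s, params=p, model=model):
                g = c.geometry
                if c.kind == "hp_pi":
                    assert g.r[g.best_site] <= p.r_max
                    assert g.theta <= p.theta_max
                    assert g.d_perp >= p.d_perp_min
                else:
                    assert g.r["O"] <= p.hb_r_max
                    assert g.angle_nho >= p.hb_angle_min
                    assert g.elevation_o <= p.hb_elevation_max

    def test_matches_brute_force_oracle_on_short_chains(self, model):
        p = DetectionParams()
        for seed in range(12):
            s = make_decoy(6, seed=100 + seed)
            got = {
                (c.donor.index, c.acceptor.index): c.kind
                for c in detect_hp_pi(s, params=p, model=model)
            }
            assert got == brute_force_classes(s, p)

    def test_proline_cannot_donate(self, model):
        s = make_hp_pi_pair("O", 2.368, 0.0)
        # donor unit's amide-H residue relabelled proline: H removed, no contact
        donor_chain = s.chains[1]
        donor_chain.residues[1].name = "PRO"
        donor_chain.residues[1].atoms.pop("H")
        assert detect_hp_pi(s, model=model) == []

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(r_max=-1.0)
        with pytest.raises(ValueError):
            DetectionParams(theta_max=120.0)


class TestSummary:
    def test_empty_contacts(self, model):
        s = make_ideal_segment([(-65, -40)] * 4)
        stats = summarize_contacts(s, [])
        assert stats.n_supported == 0
        assert stats.residues_analyzed == 4

    def test_single_contact_supports_two_residues(self, model):
        s = make_hp_pi_pair("N", 2.310, 0.0)
        contacts = detect_hp_pi(s, model=model)
        stats = summarize_contacts(s, contacts)
        assert stats.n_hp_pi == 1
        assert stats.n_supported == 2
        assert stats.n_supported <= stats.residues_analyzed

    def test_dataframe_columns(self, model):
        df = contacts_to_dataframe(detect_hp_pi(make_beta_pair(), model=model))
        assert list(df.columns) == [
            "donor_res", "acceptor_res", "class", "site",
            "r", "theta", "d_perp", "E_vac", "E_water",
        ]
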