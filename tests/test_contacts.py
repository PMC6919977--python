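import numpy as np
import pytest

from dbdscreen.contacts import (
    BindingSiteDefinition,
    ContactParams,
    HotspotGrid,
    consensus_site,
    hotspot_grid,
    perceive_contacts,
)
from dbdscreen.errors import DomainError, EmptySiteError
from dbdscreen.structio import Atom, ComplexStructure, Residue
from dbdscreen.synthetic import gen_toy_complex, rng_for


def _res(chain, number, name, atom_spec):
    key = (chain, number, name)
    atoms = [
        Atom(i + 1, aname, el, np.array(xyz, float), key)
        for i, (aname, el, xyz) in enumerate(atom_spec)
    ]
    return Residue(chain, number, name, atoms)


def _hbond_fixture(n_to_o=2.9, angle_deg=160.0):
    """Backbone N-H (protein) pointing at a DNA phosphate oxygen."""
    theta = np.radians(180.0 - angle_deg)
    # place the acceptor so that |N-A| = n_to_o and the D-H...A angle is angle_deg
    direction = np.array([np.sin(theta), np.cos(theta), 0.0])
    h = np.array([0.0, 1.0, 0.0])
    # solve |h + d*direction| = n_to_o for d >= 0
    b = 2.0 * float(h @ direction)
    c = float(h @ h) - n_to_o**2
    d = (-b + np.sqrt(b * b - 4 * c)) / 2.0
    acceptor = h + d * direction
    prot = _res("A", 211, "GLY", [("N", "N", (0, 0, 0)), ("H", "H", tuple(h)), ("CA", "C", (1.4, -0.6, 0))])
    dna = _res("B", 1, "DA", [("P", "P", tuple(acceptor + [0, 1.6, 0])), ("OP1", "O", tuple(acceptor))])
    return ComplexStructure(residues=[prot, dna])


class TestPerceiveContacts:
    def test_distant_chains_have_no_contacts(self):
        prot = _res("A", 1, "GLY", [("N", "N", (0, 0, 0)), ("H", "H", (0, 1, 0)), ("CA", "C", (1.4, 0, 0))])
        dna = _res("B", 1, "DA", [("OP1", "O", (50, 50, 50)), ("C1'", "C", (52, 50, 50))])
        assert perceive_contacts(ComplexStructure(residues=[prot, dna]), "A", "B") == []

    def test_geometric_hbond_perceived(self):
        recs = perceive_contacts(_hbond_fixture(2.9, 160.0), "A", "B")
        hbonds = [r for r in recs if r.kind == "hbond"]
        assert len(hbonds) == 1
        rec = hbonds[0]
        assert rec.protein_atom.name == "N" and rec.partner_atom.name == "OP1"
        assert rec.distance == pytest.approx(2.9, abs=1e-6)
        assert rec.angle == pytest.approx(160.0, abs=1e-6)
        assert rec.protein_is_donor is True

    def test_stretched_hbond_rejected_at_default_threshold(self):
        recs = perceive_contacts(_hbond_fixture(4.0, 160.0), "A", "B")
        assert [r for r in recs if r.kind == "hbond"] == []

    def test_bent_hbond_rejected(self):
        recs = perceive_contacts(_hbond_fixture(2.9, 100.0), "A", "B")
        assert [r for r in recs if r.kind == "hbond"] == []

    def test_donor_without_hydrogen_warns_and_skips(self):
        prot = _res("A", 1, "GLY", [("N", "N", (0, 0, 0)), ("CA", "C", (1.4, 0, 0))])
        dna = _res("B", 1, "DA", [("OP1", "O", (0, 2.9, 0))])
        with pytest.warns(UserWarning, match="no explicit hydrogens"):
            recs = perceive_contacts(ComplexStructure(residues=[prot, dna]), "A", "B")
        assert recs == []

    def test_ionic_pair_between_guanidinium_and_phosphate(self):
        prot = _res(
            "A", 222, "ARG",
            [("CA", "C", (0, -3, 0)), ("NE", "N", (0, 0, 0)), ("HE", "H", (-0.5, 0.8, 0)),
             ("CZ", "C", (1.2, 0, 0)),
             ("NH1", "N", (2.0, 1.0, 0)), ("NH2", "N", (2.0, -1.0, 0))],
        )
        dna = _res(
            "B", 1, "DT",
            [("P", "P", (1.3, 4.5, 0)), ("OP1", "O", (0.4, 5.4, 0)), ("OP2", "O", (2.2, 5.4, 0))],
        )
        recs = perceive_contacts(ComplexStructure(residues=[prot, dna]), "A", "B")
        ionic = [r for r in recs if r.kind == "ionic"]
        assert len(ionic) == 1
        assert ionic[0].protein_charge == +1

    def test_records_sorted_by_residue_then_distance(self):
        cx, _ = gen_toy_complex(seed=3, n_hbonds=3, n_hydrophobic=2)
        recs = perceive_contacts(cx, "A", "B")
        keys = [(r.protein_atom.residue_key[1], r.distance) for r in recs]
        assert keys == sorted(keys)

    def test_matches_brute_force_pair_scan(self):
        """Record count equals an all-pairs scan with the same thresholds."""
        cx, _ = gen_toy_complex(seed=7, n_hbonds=2, n_hydrophobic=2)
        p = ContactParams()
        prot = [a for r in cx.chain_residues("A") for a in r.atoms]
        part = [a for r in cx.chain_residues("B") for a in r.atoms]

        def dist(a, b):
            return float(np.linalg.norm(a.coords - b.coords))

        n_hb = 0
        for donor in prot:
            if donor.element not in ("N", "O"):
                continue
            for h in prot:
                if h.element != "H" or dist(donor, h) > 1.3 or h is donor:
                    continue
                for acc in part:
                    if acc.element not in ("N", "O") or dist(donor, acc) > p.d_hb:
                        continue
                    v1, v2 = donor.coords - h.coords, acc.coords - h.coords
                    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= p.theta_hb:
                        n_hb += 1
        recs = perceive_contacts(cx, "A", "B")
        assert sum(1 for r in recs if r.kind == "hbond") == n_hb


class TestHotspotGrid:
    def test_empty_structure_all_zero(self):
        grid = hotspot_grid(ComplexStructure(), "DRY")
        assert np.all(grid.energies == 0) and not grid.favorable.any()

    def test_dry_minimum_near_lj_optimum(self):
        carbon = _res("X", 1, "LIG", [("C1", "C", (0.0, 0.0, 0.0))])
        s = ComplexStructure(residues=[carbon])
        grid = hotspot_grid(s, "DRY", spacing=0.25, padding=6.0)
        pts = grid.points()
        best = pts[int(np.argmin(grid.energies.ravel()))]
        r_best = np.linalg.norm(best)
        r_min = 2 ** (1 / 6) * 3.40  # sigma_pair for a carbon-DRY pair
        assert abs(r_best - r_min) <= 0.25 * np.sqrt(3)

    def test_default_dry_cutoff_recorded(self):
        carbon = _res("X", 1, "LIG", [("C1", "C", (0.0, 0.0, 0.0))])
        grid = hotspot_grid(ComplexStructure(residues=[carbon]), "DRY")
        assert grid.cutoff == -2.5

    def test_translation_invariance(self):
        cx, _ = gen_toy_complex(seed=1, n_hbonds=1, n_hydrophobic=1)
        g1 = hotspot_grid(cx, "N1", spacing=1.5)
        shift = np.array([7.0, -3.0, 11.0])
        moved = ComplexStructure(
            residues=[
                Residue(
                    r.chain, r.number, r.name,
                    [Atom(a.serial, a.name, a.element, a.coords + shift, a.residue_key) for a in r.atoms],
                )
                for r in cx.residues
            ]
        )
        g2 = hotspot_grid(moved, "N1", spacing=1.5, origin=g1.origin + shift,
                          shape=g1.energies.shape)
        np.testing.assert_allclose(g2.energies, g1.energies, atol=1e-9)

    def test_unknown_probe_rejected(self):
        with pytest.raises(DomainError):
            hotspot_grid(ComplexStructure(), "XX")

    def test_positive_cutoff_rejected(self):
        with pytest.raises(DomainError):
            HotspotGrid(np.zeros(3), 1.0, "DRY", np.zeros((2, 2, 2)), cutoff=1.0)


class TestConsensusSite:
    def test_unanimity_returns_same_set(self):
        sets = [{"a", "b"}] * 4
        site = consensus_site(sets, min_votes=4)
        assert site.residues == {"a", "b"}
        assert all(v == 4 for v in site.votes.values())

    def test_vote_enumeration_with_experimental_addition(self):
        sets = [{"A", "B"}, {"B", "C"}, {"B"}, {"C"}]
        assert consensus_site(sets, min_votes=2).residues == {"B", "C"}
        assert consensus_site(sets, {"D"}, min_votes=2).residues == {"B", "C", "D"}

    def test_min_votes_one_is_union(self):
        sets = [{"A"}, {"B"}, {"C"}]
        assert consensus_site(sets, min_votes=1).residues == {"A", "B", "C"}

    def test_all_empty_raises(self):
        with pytest.raises(EmptySiteError):
            consensus_site([set(), set()], min_votes=1)

    def test_monotone_in_min_votes(self):
        rng = rng_for(11, "consensus_property")
        universe = [f"r{i}" for i in range(12)]
        for _ in range(20):
            sets = [
                set(rng.choice(universe, size=rng.integers(1, 8), replace=False))
                for _ in range(4)
            ]
            prev = None
            for mv in range(4, 0, -1):
                cur = consensus_site(sets, min_votes=mv).residues
                if prev is not None:
                    assert prev <= cur
                prev = cur

    def test_center_and_radius_from_structure(self):
        res1 = _res("A", 1, "ALA", [("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0))])
        res2 = _res("A", 2, "ALA", [("CA", "C", (4, 0, 0)), ("CB", "C", (5.5, 0, 0))])
        s = ComplexStructure(residues=[res1, res2])
        site = consensus_site([{res1.key}, {res2.key}], min_votes=1, structure=s)
        np.testing.assert_allclose(site.center, [2.0, 0.0, 0.0])
        assert site.radius == pytest.approx(3.5)
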