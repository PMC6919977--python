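import numpy as np
import pytest

from dbdscreen.contacts import perceive_contacts
from dbdscreen.errors import DomainError
from dbdscreen.pharmacophore import (
    ConformerFeatureSet,
    Feature,
    FeaturePoint,
    PharmacophoreModel,
    build_model,
    features_from_contacts,
    kabsch,
    match_conformer,
    read_conformer_tsv,
    screen_library,
    write_conformer_tsv,
)
from dbdscreen.synthetic import gen_conformer_library, gen_toy_complex, rng_for
from helpers import brute_force_match


def _conf(points, cid="c", conf_id=0):
    return ConformerFeatureSet(
        compound_id=cid,
        conformer_id=conf_id,
        points=[FeaturePoint(kind=k, position=np.asarray(p, float)) for k, p in points],
    )


def _rigid(points, angle_deg=90.0, shift=(5.0, 5.0, 5.0)):
    t = np.radians(angle_deg)
    R = np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]])
    return [(k, R @ np.asarray(p, float) + np.asarray(shift)) for k, p in points]


class TestFeaturesFromContacts:
    def test_empty_contacts_give_no_features(self):
        assert features_from_contacts([]) == []

    def test_protein_donor_hbond_becomes_directed_acceptor_feature(self):
        cx, manifest = gen_toy_complex(seed=5, n_hbonds=1, n_hydrophobic=0, jitter_sd=0.0)
        recs = perceive_contacts(cx, "A", "B")
        feats = features_from_contacts(recs)
        assert len(feats) == 1 and feats[0].kind == "HBA"
        rec = recs[0]
        donor = rec.protein_atom
        h = next(a for a in cx.residue(*donor.residue_key[:2]).atoms if a.name == "H")
        h_to_a = rec.partner_atom.coords - h.coords
        h_to_a /= np.linalg.norm(h_to_a)
        assert float(np.dot(feats[0].direction, h_to_a)) == pytest.approx(-1.0, abs=1e-6)
        np.testing.assert_allclose(feats[0].centroid, rec.partner_atom.coords)

    def test_close_hydrophobic_contacts_merge_to_midpoint(self):
        cx, _ = gen_toy_complex(seed=5, n_hbonds=0, n_hydrophobic=1)
        recs = perceive_contacts(cx, "A", "B")
        # duplicate the record with the partner shifted by 1 Å
        import copy

        rec2 = copy.deepcopy(recs[0])
        moved = rec2.partner_atom
        object.__setattr__(moved, "coords", moved.coords + np.array([1.0, 0.0, 0.0]))
        feats = features_from_contacts(recs + [rec2], merge_radius=2.0)
        assert len(feats) == 1
        np.testing.assert_allclose(
            feats[0].centroid,
            (recs[0].partner_atom.coords + moved.coords) / 2.0,
        )

    def test_distant_same_kind_features_not_merged(self):
        cx, _ = gen_toy_complex(seed=5, n_hbonds=0, n_hydrophobic=2)
        feats = features_from_contacts(perceive_contacts(cx, "A", "B"), merge_radius=1.5)
        assert len(feats) == 2


class TestBuildModel:
    def _features(self):
        return [
            Feature("H", np.zeros(3), source_residue=("A", 211, "ARG")),
            Feature("H", np.array([3.0, 0, 0]), source_residue=("A", 212, "HIS")),
            Feature("HBD", np.array([0, 3.0, 0]), source_residue=("A", 212, "HIS")),
            Feature("HBA", np.array([3.0, 3.0, 0]), source_residue=("A", 208, "ASN")),
            Feature("HBA", np.array([1.5, 1.5, 3.0]), source_residue=("A", 166, "SER")),
        ]

    def test_anchor_features_become_required(self):
        model = build_model(self._features(), {("A", 211), ("A", 212)})
        assert model.required_ids == {0, 1, 2}

    def test_no_anchors_means_no_required(self):
        assert build_model(self._features(), set()).required_ids == set()

    def test_anchored_model_composition(self):
        """Hydrophobics at Arg211/His212 plus H-bond features at His212/Asn208."""
        model = build_model(self._features(), {("A", 211), ("A", 212), ("A", 208)})
        by_res = {
            (f.kind, f.source_residue[1]) for i, f in enumerate(model.features)
            if i in model.required_ids
        }
        assert {("H", 211), ("H", 212), ("HBD", 212), ("HBA", 208)} <= by_res

    def test_unmatched_anchor_warns(self):
        with pytest.warns(UserWarning, match="anchor"):
            model = build_model(self._features(), {("A", 999)})
        assert model.required_ids == set()

    def test_json_round_trip(self):
        model = build_model(self._features(), {("A", 211)}, name="m1")
        again = PharmacophoreModel.from_json(model.to_json())
        assert again.required_ids == model.required_ids
        assert [f.kind for f in again.features] == [f.kind for f in model.features]
        np.testing.assert_allclose(
            np.stack([f.centroid for f in again.features]),
            np.stack([f.centroid for f in model.features]),
        )


class TestKabsch:
    def test_proper_rotation_only(self):
        rng = rng_for(2, "kabsch_test")
        P = rng.normal(size=(5, 3))
        mirrored = P * np.array([1.0, 1.0, -1.0])
        R, t, rmsd = kabsch(mirrored, P)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1  # a reflection would fit exactly; proper rotation cannot

    def test_recovers_known_transform(self):
        rng = rng_for(3, "kabsch_test")
        P = rng.normal(size=(6, 3))
        t_true = np.array([1.0, -2.0, 3.0])
        theta = 0.7
        R_true = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        Q = P @ R_true.T + t_true
        _, _, rmsd = kabsch(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-9)


class TestMatchConformer:
    def test_identity_points_full_match(self, five_feature_model):
        model = five_feature_model
        conf = _conf([(f.kind, f.centroid) for f in model.features])
        res = match_conformer(model, conf)
        assert res is not None and res.n_matched == 5
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.matched_required

    def test_rigid_transform_removed_by_superposition(self, five_feature_model):
        model = five_feature_model
        conf = _conf(_rigid([(f.kind, f.centroid) for f in model.features]))
        res = match_conformer(model, conf)
        assert res is not None and res.n_matched == 5
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_incompatible_kinds_never_match(self, five_feature_model):
        swap = {"H": "PI", "HBA": "NI", "HBD": "AR"}
        conf = _conf([(swap[f.kind], f.centroid) for f in five_feature_model.features])
        assert match_conformer(five_feature_model, conf) is None

    def test_mirror_image_rejected(self, five_feature_model):
        model = five_feature_model
        pts = [(f.kind, f.centroid * np.array([1.0, 1.0, -1.0])) for f in model.features]
        res = match_conformer(model, _conf(pts))
        # planar sub-sets of the enantiomer can still superpose, but the full
        # five-point chiral geometry must not fit at near-zero rmsd
        assert res is None or not (res.n_matched == 5 and res.rmsd < 1e-3)

    def test_under_determined_model_rejected(self):
        model = PharmacophoreModel(
            features=[Feature("H", np.zeros(3)), Feature("H", np.array([3.0, 0, 0]))]
        )
        with pytest.raises(DomainError):
            match_conformer(model, _conf([("H", (0, 0, 0))]))

    def test_missing_required_feature_means_no_match(self, five_feature_model):
        model = five_feature_model  # feature 2 (HBA) required
        pts = [(f.kind, f.centroid) for i, f in enumerate(model.features) if i != 2]
        pts = [(k if k != "HBA" else "H", p) for k, p in pts]
        assert match_conformer(model, _conf(pts)) is None


class TestOracleEquivalence:
    def test_matches_exhaustive_search_on_random_instances(self):
        """Backtracking with distance pruning equals the itertools oracle."""
        rng = rng_for(17, "match_oracle")
        kinds = ["H", "HBA", "HBD", "AR"]
        n_checked = 0
        for trial in range(200):
            n_feats = int(rng.integers(3, 7))
            feats = [
                Feature(
                    kind=kinds[int(rng.integers(0, len(kinds)))],
                    centroid=rng.uniform(-4, 4, 3),
                    tolerance=float(rng.uniform(1.0, 2.0)),
                )
                for _ in range(n_feats)
            ]
            required = set(
                int(i) for i in rng.choice(n_feats, size=int(rng.integers(0, 3)), replace=False)
            )
            model = PharmacophoreModel(features=feats, required_ids=required)
            n_pts = int(rng.integers(3, 8))
            pts = []
            for j in range(n_pts):
                if j < n_feats and rng.random() < 0.6:
                    pts.append(
                        (feats[j].kind, feats[j].centroid + rng.normal(0, 0.8, 3))
                    )
                else:
                    pts.append(
                        (kinds[int(rng.integers(0, len(kinds)))], rng.uniform(-5, 5, 3))
                    )
            conf = _conf(pts)
            got = match_conformer(model, conf)
            want = brute_force_match(model, conf)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert got.mapping == want.mapping
                assert got.rmsd == pytest.approx(want.rmsd, abs=1e-12)
                n_checked += 1
        assert n_checked > 20  # the ensemble exercises real matches, not only rejections

    def test_match_invariant_under_random_rigid_transforms(self, five_feature_model):
        model = five_feature_model
        base = [(f.kind, f.centroid + 0.3) for f in model.features]
        ref = match_conformer(model, _conf(base))
        rng = rng_for(23, "rigid_invariance")
        for _ in range(10):
            angle = float(rng.uniform(0, 360))
            shift = rng.uniform(-30, 30, 3)
            res = match_conformer(model, _conf(_rigid(base, angle, shift)))
            assert res is not None
            assert res.mapping == ref.mapping
            assert res.rmsd == pytest.approx(ref.rmsd, abs=1e-6)


class TestScreenLibrary:
    def test_empty_library(self, five_feature_model):
        assert screen_library(five_feature_model, []) == []

    def test_planted_actives_recovered_decoys_absent(self, five_feature_model):
        library, labels = gen_conformer_library(
            five_feature_model, n_actives=5, n_decoys=50, noise_sd=0.3, seed=31
        )
        hits = screen_library(five_feature_model, library)
        assert {cid for cid, _ in hits} == {cid for cid, act in labels.items() if act}

    def test_rank_order_breaks_ties_by_rmsd(self, five_feature_model):
        model = five_feature_model
        exact = _conf([(f.kind, f.centroid) for f in model.features], cid="exact")
        rng = rng_for(41, "rank_order")
        jitter = _conf(
            [(f.kind, f.centroid + rng.normal(0, 0.15, 3)) for f in model.features],
            cid="jitter",
        )
        hits = screen_library(model, [jitter, exact])
        assert [cid for cid, _ in hits] == ["exact", "jitter"]
        assert hits[0][1].rmsd < hits[1][1].rmsd

    def test_result_independent_of_library_order(self, five_feature_model):
        library, _ = gen_conformer_library(
            five_feature_model, n_actives=4, n_decoys=10, seed=13
        )
        forward = screen_library(five_feature_model, library)
        backward = screen_library(five_feature_model, library[::-1])
        assert [(c, r.n_matched, r.rmsd) for c, r in forward] == [
            (c, r.n_matched, r.rmsd) for c, r in backward
        ]


def test_conformer_tsv_round_trip(tmp_path, five_feature_model):
    library, _ = gen_conformer_library(five_feature_model, n_actives=2, n_decoys=2, seed=3)
    path = tmp_path / "lib.tsv"
    write_conformer_tsv(library, path)
    again = read_conformer_tsv(path)
    assert {c.compound_id for c in again} == {c.compound_id for c in library}
    orig = {c.compound_id: c for c in library}
    for c in again:
        np.testing.assert_allclose(
            np.stack([p.position for p in c.points]),
            np.stack([p.position for p in orig[c.compound_id].points]),
            atol=1e-3,
        )
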