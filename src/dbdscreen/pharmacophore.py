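"""Pharmacophore models: construction from contacts, anchored refinement, and
geometric screening of conformer libraries.

A pharmacophore model is a set of typed, positioned, toleranced features
(H-bond donor/acceptor, hydrophobic, aromatic, ionizable).  A conformer
"maps" to the model when an injective, type-compatible assignment of its
feature points to model features exists such that, after an optimal
rigid-body superposition (Kabsch, proper rotations only — enantiomers do
not match), every mapped point lies within its feature's tolerance sphere,
every required (anchor) feature is mapped, and any directional constraints
agree within the angular tolerance.

The assignment search is exact: backtracking over type buckets with
pairwise-distance pruning (two points can only map to two features if their
distance agrees with the feature-feature distance within the sum of the two
tolerances — a necessary condition under any rigid motion).  Among accepted
assignments the best is the one with most matched features, ties broken by
lower RMSD, then by lexicographically smallest mapping, which makes
screening fully deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from dbdscreen.contacts import ContactRecord
from dbdscreen.errors import DomainError
from dbdscreen.structio import ResidueKey

FEATURE_KINDS = ("HBD", "HBA", "H", "AR", "PI", "NI")

#: default tolerance radius (Å) per feature kind
DEFAULT_TOLERANCE = {k: 1.5 for k in FEATURE_KINDS}
DEFAULT_ANGLE_TOL = 45.0  # degrees, direction constraint
DEFAULT_MERGE_RADIUS = 1.5  # Å, duplicate-feature coalescing


@dataclass
class Feature:
    """A typed interaction feature with a tolerance sphere and optional direction."""

    kind: str
    centroid: np.ndarray
    tolerance: float = 1.5
    direction: np.ndarray | None = None
    source_residue: ResidueKey | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise DomainError(f"unknown feature kind {self.kind!r}")
        if self.tolerance <= 0:
            raise DomainError("feature tolerance must be > 0")
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.direction is not None:
            self.direction = np.asarray(self.direction, dtype=float)
            norm = np.linalg.norm(self.direction)
            if abs(norm - 1.0) > 1e-6:
                raise DomainError("feature direction must be a unit vector")


@dataclass
class PharmacophoreModel:
    features: list[Feature]
    required_ids: set[int] = field(default_factory=set)
    name: str = "model"

    def __post_init__(self) -> None:
        if not self.required_ids <= set(range(len(self.features))):
            raise DomainError("required_ids must be a subset of feature indices")

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "features": [
                    {
                        "kind": f.kind,
                        "centroid": f.centroid.tolist(),
                        "tolerance": f.tolerance,
                        "direction": None if f.direction is None else f.direction.tolist(),
                        "source_residue": f.source_residue,
                        "required": i in self.required_ids,
                    }
                    for i, f in enumerate(self.features)
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PharmacophoreModel":
        obj = json.loads(text)
        features, required = [], set()
        for i, fo in enumerate(obj["features"]):
            src = fo.get("source_residue")
            features.append(
                Feature(
                    kind=fo["kind"],
                    centroid=np.array(fo["centroid"], float),
                    tolerance=fo["tolerance"],
                    direction=None if fo.get("direction") is None else np.array(fo["direction"], float),
                    source_residue=tuple(src) if src is not None else None,
                )
            )
            if fo.get("required"):
                required.add(i)
        return cls(features=features, required_ids=required, name=obj.get("name", "model"))


@dataclass
class FeaturePoint:
    kind: str
    position: np.ndarray
    direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise DomainError("feature point position must be finite")


@dataclass
class ConformerFeatureSet:
    compound_id: str
    conformer_id: int
    points: list[FeaturePoint]

    def __post_init__(self) -> None:
        if self.conformer_id < 0:
            raise DomainError("conformer_id must be >= 0")


@dataclass
class MatchResult:
    mapping: dict[int, int]  # feature index -> point index, injective
    rmsd: float
    n_matched: int
    matched_required: bool

    def __post_init__(self) -> None:
        if self.rmsd < 0 or self.n_matched != len(self.mapping):
            raise DomainError("inconsistent match result")


# ---------------------------------------------------------------------------
# feature derivation

def features_from_contacts(
    contacts: list[ContactRecord],
    side: str = "protein-complement",
    merge_radius: float = DEFAULT_MERGE_RADIUS,
    tolerances: dict[str, float] | None = None,
) -> list[Feature]:
    """Translate perceived contacts into pharmacophore features.

    On the default protein-complement side the features describe what a
    ligand must present: a protein-donated hydrogen bond becomes an acceptor
    (HBA) feature at the partner acceptor position, directed along the
    acceptor->donor axis (anti-parallel to the donor's H->A vector); a
    protein-accepted bond becomes an HBD feature analogously; hydrophobic
    contacts become H features at the partner atom; ionic contacts become
    the charge complement of the protein group.  Same-kind features closer
    than ``merge_radius`` are coalesced to their centroid.
    """
    if side not in ("protein-complement", "protein-surface"):
        raise DomainError(f"unknown side {side!r}")
    tol = dict(DEFAULT_TOLERANCE)
    if tolerances:
        tol.update(tolerances)
    complement = side == "protein-complement"

    raw: list[Feature] = []
    for c in contacts:
        anchor = c.partner_atom if complement else c.protein_atom
        res = c.protein_atom.residue_key
        if c.kind == "hbond":
            if c.protein_is_donor:
                kind = "HBA" if complement else "HBD"
            else:
                kind = "HBD" if complement else "HBA"
            raw.append(
                Feature(
                    kind=kind,
                    centroid=anchor.coords,
                    tolerance=tol[kind],
                    direction=c.direction if complement else (
                        None if c.direction is None else -c.direction
                    ),
                    source_residue=res,
                )
            )
        elif c.kind == "hydrophobic":
            raw.append(
                Feature(kind="H", centroid=anchor.coords, tolerance=tol["H"], source_residue=res)
            )
        elif c.kind == "ionic":
            if c.protein_charge is None:
                raise DomainError("ionic contact lacks protein charge sign")
            kind = ("NI" if c.protein_charge > 0 else "PI") if complement else (
                "PI" if c.protein_charge > 0 else "NI"
            )
            raw.append(
                Feature(kind=kind, centroid=anchor.coords, tolerance=tol[kind], source_residue=res)
            )
        else:
            raise DomainError(f"unknown contact kind {c.kind!r}")
    return _merge_features(raw, merge_radius)


def _merge_features(features: list[Feature], merge_radius: float) -> list[Feature]:
    """Coalesce same-kind features within merge_radius (union-find clusters -> centroid)."""
    n = len(features)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if features[i].kind != features[j].kind:
                continue
            if np.linalg.norm(features[i].centroid - features[j].centroid) <= merge_radius:
                parent[find(j)] = find(i)

    clusters: dict[int, list[Feature]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(features[i])

    merged = []
    for root in sorted(clusters):
        members = clusters[root]
        if len(members) == 1:
            merged.append(members[0])
            continue
        centroid = np.mean([m.centroid for m in members], axis=0)
        dirs = [m.direction for m in members if m.direction is not None]
        direction = None
        if dirs:
            d = np.sum(dirs, axis=0)
            if np.linalg.norm(d) > 1e-9:
                direction = d / np.linalg.norm(d)
        merged.append(
            Feature(
                kind=members[0].kind,
                centroid=centroid,
                tolerance=max(m.tolerance for m in members),
                direction=direction,
                source_residue=members[0].source_residue,
            )
        )
    return merged


def build_model(
    features: list[Feature],
    anchors: set[ResidueKey] | set[tuple] = frozenset(),
    name: str = "model",
) -> PharmacophoreModel:
    """Assemble a model; features sourced from anchor residues become required.

    Anchor keys may be full residue keys (chain, number, name) or
    (chain, number) pairs; the paper-style refinement pins the model to the
    functionally critical residues so only compounds satisfying those
    interactions can match.
    """
    if not features:
        raise DomainError("cannot build a model from zero features")
    anchors = set(anchors)
    short = {a[:2] for a in anchors if isinstance(a, tuple) and len(a) >= 2}
    required = set()
    for i, f in enumerate(features):
        if f.source_residue is None:
            continue
        if f.source_residue in anchors or f.source_residue[:2] in short:
            required.add(i)
    if anchors and not required:
        warnings.warn("no feature is sourced from any anchor residue; required set is empty")
    return PharmacophoreModel(features=features, required_ids=required, name=name)


# ---------------------------------------------------------------------------
# rigid superposition

def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of P onto Q, proper rotations only.

    Returns (R, t, rmsd) with R a rotation matrix (det +1; reflections are
    rejected by flipping the smallest singular direction, so chirality is
    preserved) such that P @ R.T + t best fits Q.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# matching

def _mapping_key(m: dict[int, int]) -> tuple:
    return tuple(sorted(m.items()))


def _evaluate_assignment(
    model: PharmacophoreModel,
    conf: ConformerFeatureSet,
    mapping: dict[int, int],
    angle_tol: float,
) -> MatchResult | None:
    """Superpose the mapped points onto the feature centroids and check acceptance."""
    fidx = sorted(mapping)
    P = np.stack([conf.points[mapping[i]].position for i in fidx])
    Q = np.stack([model.features[i].centroid for i in fidx])
    R, t, rmsd = kabsch(P, Q)
    moved = P @ R.T + t
    for row, i in enumerate(fidx):
        if np.linalg.norm(moved[row] - model.features[i].centroid) > model.features[i].tolerance + 1e-9:
            return None
        fdir = model.features[i].direction
        pdir = conf.points[mapping[i]].direction
        if fdir is not None and pdir is not None:
            moved_dir = R @ pdir
            cosang = float(np.clip(np.dot(moved_dir, fdir), -1.0, 1.0))
            if np.degrees(np.arccos(cosang)) > angle_tol + 1e-9:
                return None
    return MatchResult(
        mapping=dict(mapping),
        rmsd=rmsd,
        n_matched=len(mapping),
        matched_required=model.required_ids <= set(mapping),
    )


def _result_rank(r: MatchResult) -> tuple:
    return (-r.n_matched, r.rmsd, _mapping_key(r.mapping))


def match_conformer(
    model: PharmacophoreModel,
    conf: ConformerFeatureSet,
    angle_tol: float = DEFAULT_ANGLE_TOL,
) -> MatchResult | None:
    """Best accepted assignment of conformer points to model features, or None.

    The search is exhaustive over injective type-compatible assignments that
    cover all required features and at least three features total (a rigid
    alignment with fewer pairs is under-determined).  Pairwise-distance
    pruning only discards assignments that no rigid motion could accept.
    """
    if len(model.features) < 3:
        raise DomainError("a well-posed model needs at least 3 features")
    feats = model.features
    pts = conf.points
    # candidate points per feature, by kind
    candidates = [
        [j for j, p in enumerate(pts) if p.kind == f.kind] for f in feats
    ]
    if any(not candidates[i] for i in model.required_ids):
        return None

    # order features: required first, then by fewest candidates (fail fast)
    order = sorted(
        range(len(feats)),
        key=lambda i: (i not in model.required_ids, len(candidates[i]), i),
    )
    feat_d = {
        (i, j): float(np.linalg.norm(feats[i].centroid - feats[j].centroid))
        for i in range(len(feats))
        for j in range(len(feats))
        if i < j
    }
    pt_d = {
        (a, b): float(np.linalg.norm(pts[a].position - pts[b].position))
        for a in range(len(pts))
        for b in range(len(pts))
        if a < b
    }

    best: MatchResult | None = None

    def compatible(i: int, pi: int, mapping: dict[int, int]) -> bool:
        for j, pj in mapping.items():
            dij = feat_d[(min(i, j), max(i, j))]
            dpq = pt_d[(min(pi, pj), max(pi, pj))] if pi != pj else 0.0
            if abs(dij - dpq) > feats[i].tolerance + feats[j].tolerance + 1e-9:
                return False
        return True

    def backtrack(pos: int, mapping: dict[int, int], used: set[int]) -> None:
        nonlocal best
        if pos == len(order):
            if len(mapping) < 3 or not model.required_ids <= set(mapping):
                return
            res = _evaluate_assignment(model, conf, mapping, angle_tol)
            if res is not None and (best is None or _result_rank(res) < _result_rank(best)):
                best = res
            return
        i = order[pos]
        # upper-bound prune: even mapping everything left cannot beat best
        remaining = len(order) - pos
        if best is not None and len(mapping) + remaining < best.n_matched:
            return
        for pi in candidates[i]:
            if pi in used or not compatible(i, pi, mapping):
                continue
            mapping[i] = pi
            used.add(pi)
            backtrack(pos + 1, mapping, used)
            del mapping[i]
            used.remove(pi)
        if i not in model.required_ids:
            backtrack(pos + 1, mapping, used)

    backtrack(0, {}, set())
    return best


def screen_library(
    model: PharmacophoreModel,
    library: list[ConformerFeatureSet],
    angle_tol: float = DEFAULT_ANGLE_TOL,
) -> list[tuple[str, MatchResult]]:
    """Best match per compound over its conformers, ranked deterministically.

    Compounds with any accepted match are returned sorted by
    (n_matched desc, rmsd asc, compound_id asc); decoys simply drop out.
    """
    per_compound: dict[str, MatchResult] = {}
    for conf in library:
        res = match_conformer(model, conf, angle_tol=angle_tol)
        if res is None:
            continue
        prev = per_compound.get(conf.compound_id)
        if prev is None or _result_rank(res) < _result_rank(prev):
            per_compound[conf.compound_id] = res
    return sorted(
        per_compound.items(), key=lambda kv: (-kv[1].n_matched, kv[1].rmsd, kv[0])
    )


# ---------------------------------------------------------------------------
# conformer-library I/O (plain TSV dialect)

def read_conformer_tsv(path_or_buf) -> list[ConformerFeatureSet]:
    """Read the tabular conformer dialect: compound_id conformer_id kind x y z."""
    import pandas as pd

    df = pd.read_csv(path_or_buf, sep="\t", comment="#")
    expected = {"compound_id", "conformer_id", "kind", "x", "y", "z"}
    if not expected <= set(df.columns):
        raise DomainError(f"conformer TSV must have columns {sorted(expected)}")
    out = []
    for (cid, conf_id), grp in df.groupby(["compound_id", "conformer_id"], sort=True):
        pts = [
            FeaturePoint(kind=row.kind, position=np.array([row.x, row.y, row.z]))
            for row in grp.itertuples()
        ]
        out.append(ConformerFeatureSet(compound_id=str(cid), conformer_id=int(conf_id), points=pts))
    return out


def write_conformer_tsv(library: list[ConformerFeatureSet], path_or_buf) -> None:
    import pandas as pd

    rows = [
        {
            "compound_id": c.compound_id,
            "conformer_id": c.conformer_id,
            "kind": p.kind,
            "x": p.position[0],
            "y": p.position[1],
            "z": p.position[2],
        }
        for c in library
        for p in c.points
    ]
    pd.DataFrame(rows).to_csv(path_or_buf, sep="\t", index=False, float_format="%.4f")
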