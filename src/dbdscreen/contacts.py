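"""Protein-DNA (and protein-ligand) interaction perception and binding-site tools.

Three stages live here:

* :func:`perceive_contacts` — geometric perception of hydrogen bonds,
  hydrophobic contacts and ionic pairs between two chains, using explicit
  distance/angle thresholds (LigandScout-like defaults, all overridable);
* :func:`hotspot_grid` — simplified probe interaction maps (a 6-12
  Lennard-Jones term plus a distance-and-angle-gated hydrogen-bond well for
  the polar probes), with the conventional favourability cut-offs
  N1 -4.0, O -3.5, DRY -2.5 kcal/mol;
* :func:`consensus_site` — residue-vote consensus over several pocket
  predictions, optionally forced to include experimentally implicated
  residues.

The hotspot energy model is an explicit simplification: no electrostatics
and no force-field fitting; its parameters ship as a visible table below so
every number entering a map is inspectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from dbdscreen.errors import DomainError, EmptySiteError
from dbdscreen.structio import Atom, ComplexStructure, Residue, ResidueKey

# ---------------------------------------------------------------------------
# contact perception

#: covalent-bond distance cutoffs (Å) used when CONECT records are absent
BOND_CUTOFF_H = 1.3     # X-H bond
BOND_CUTOFF_HEAVY = 1.8  # heavy-heavy bond

#: formal-charge-bearing groups, by (residue name, atom names), sign
CHARGED_GROUPS: dict[str, tuple[tuple[str, ...], int]] = {
    "ARG": (("NE", "CZ", "NH1", "NH2"), +1),
    "LYS": (("NZ",), +1),
    "HIS": (("ND1", "NE2"), +1),
    "ASP": (("OD1", "OD2"), -1),
    "GLU": (("OE1", "OE2"), -1),
    # nucleic-acid backbone phosphate
    "DA": (("P", "OP1", "OP2"), -1),
    "DT": (("P", "OP1", "OP2"), -1),
    "DG": (("P", "OP1", "OP2"), -1),
    "DC": (("P", "OP1", "OP2"), -1),
}


@dataclass
class ContactParams:
    """Geometric thresholds for contact perception.

    d_hb: donor-acceptor heavy-atom distance ceiling (Å);
    theta_hb: donor-H...acceptor angle floor (degrees);
    d_phob: apolar carbon pair distance ceiling (Å);
    d_ion: charged-group centroid distance ceiling (Å).
    """

    d_hb: float = 3.5
    theta_hb: float = 130.0
    d_phob: float = 4.5
    d_ion: float = 5.5


@dataclass
class ContactRecord:
    kind: str  # hbond | hydrophobic | ionic
    protein_atom: Atom
    partner_atom: Atom
    distance: float
    angle: float | None = None  # donor-H...acceptor, hbond only
    direction: np.ndarray | None = None  # unit vector partner -> protein atom
    protein_is_donor: bool | None = None  # hbond only
    protein_charge: int | None = None  # ionic only

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise DomainError("contact distance must be > 0")
        if self.kind == "hbond" and not (0.0 <= (self.angle or 0.0) <= 180.0):
            raise DomainError("hbond angle must be within [0, 180] degrees")


def _bonded(atom: Atom, others: list[Atom], cutoff: float) -> list[Atom]:
    return [
        o
        for o in others
        if o is not atom and np.linalg.norm(o.coords - atom.coords) <= cutoff
    ]


def _chain_atoms(s: ComplexStructure, chain: str) -> list[Atom]:
    return [a for r in s.chain_residues(chain) for a in r.atoms]


def _donors_with_h(atoms: list[Atom]) -> list[tuple[Atom, Atom]]:
    """(heavy donor, hydrogen) pairs; donors lacking an explicit H are skipped with a warning."""
    hydrogens = [a for a in atoms if a.element == "H"]
    pairs: list[tuple[Atom, Atom]] = []
    for a in atoms:
        if a.element not in ("N", "O"):
            continue
        hs = _bonded(a, hydrogens, BOND_CUTOFF_H)
        if not hs:
            # a polar heavy atom with no attached H cannot be evaluated as donor
            continue
        pairs.extend((a, h) for h in hs)
    return pairs


def _warn_missing_hydrogens(atoms: list[Atom], label: str) -> None:
    hydrogens = [a for a in atoms if a.element == "H"]
    if any(a.element == "N" for a in atoms) and not hydrogens:
        warnings.warn(
            f"{label}: nitrogen donors present but no explicit hydrogens; "
            "donors skipped in hbond perception",
            stacklevel=3,
        )


def _acceptors(atoms: list[Atom]) -> list[Atom]:
    return [a for a in atoms if a.element in ("N", "O")]


def _apolar_carbons(atoms: list[Atom]) -> list[Atom]:
    """Carbons with no bonded N/O/S within one bond (covalent-radius inference)."""
    polar = [a for a in atoms if a.element in ("N", "O", "S")]
    return [
        a
        for a in atoms
        if a.element == "C" and not _bonded(a, polar, BOND_CUTOFF_HEAVY)
    ]


def _charged_groups(residues: list[Residue]) -> list[tuple[Residue, np.ndarray, int, Atom]]:
    out = []
    for r in residues:
        entry = CHARGED_GROUPS.get(r.name)
        if entry is None:
            continue
        names, sign = entry
        members = [a for a in r.atoms if a.name in names]
        if not members:
            continue
        centroid = np.mean([a.coords for a in members], axis=0)
        out.append((r, centroid, sign, members[0]))
    return out


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def perceive_contacts(
    complex_: ComplexStructure,
    protein_chain: str,
    partner_chain: str,
    params: ContactParams | None = None,
) -> list[ContactRecord]:
    """Perceive hbond / hydrophobic / ionic contacts between two chains.

    A hydrogen bond requires donor-acceptor heavy-atom distance <= d_hb and
    a donor-H...acceptor angle >= theta_hb; hydrogens must be explicit on the
    donor side (a side with N donors but no hydrogens raises a warning and is
    skipped rather than silently ignored).  Records are sorted by
    (protein residue number, distance).
    """
    p = params or ContactParams()
    prot_atoms = _chain_atoms(complex_, protein_chain)
    part_atoms = _chain_atoms(complex_, partner_chain)
    records: list[ContactRecord] = []

    _warn_missing_hydrogens(prot_atoms, f"chain {protein_chain}")
    _warn_missing_hydrogens(part_atoms, f"chain {partner_chain}")

    # hydrogen bonds: protein donates
    part_acc = _acceptors(part_atoms)
    for donor, h in _donors_with_h(prot_atoms):
        for acc in part_acc:
            d = float(np.linalg.norm(acc.coords - donor.coords))
            if d > p.d_hb:
                continue
            ang = _angle_deg(donor.coords, h.coords, acc.coords)
            if ang < p.theta_hb:
                continue
            records.append(
                ContactRecord(
                    kind="hbond",
                    protein_atom=donor,
                    partner_atom=acc,
                    distance=d,
                    angle=ang,
                    direction=_unit(donor.coords - acc.coords),
                    protein_is_donor=True,
                )
            )
    # hydrogen bonds: partner donates, protein accepts
    prot_acc = _acceptors(prot_atoms)
    for donor, h in _donors_with_h(part_atoms):
        for acc in prot_acc:
            d = float(np.linalg.norm(acc.coords - donor.coords))
            if d > p.d_hb:
                continue
            ang = _angle_deg(donor.coords, h.coords, acc.coords)
            if ang < p.theta_hb:
                continue
            records.append(
                ContactRecord(
                    kind="hbond",
                    protein_atom=acc,
                    partner_atom=donor,
                    distance=d,
                    angle=ang,
                    direction=_unit(acc.coords - donor.coords),
                    protein_is_donor=False,
                )
            )
    # hydrophobic
    for pc in _apolar_carbons(prot_atoms):
        for qc in _apolar_carbons(part_atoms):
            d = float(np.linalg.norm(qc.coords - pc.coords))
            if d <= p.d_phob:
                records.append(
                    ContactRecord(
                        kind="hydrophobic",
                        protein_atom=pc,
                        partner_atom=qc,
                        distance=d,
                        direction=_unit(pc.coords - qc.coords),
                    )
                )
    # ionic: opposite formal charges within d_ion (group centroids)
    prot_groups = _charged_groups(complex_.chain_residues(protein_chain))
    part_groups = _charged_groups(complex_.chain_residues(partner_chain))
    for _, pcen, psign, patom in prot_groups:
        for _, qcen, qsign, qatom in part_groups:
            if psign * qsign >= 0:
                continue
            d = float(np.linalg.norm(qcen - pcen))
            if d <= p.d_ion:
                records.append(
                    ContactRecord(
                        kind="ionic",
                        protein_atom=patom,
                        partner_atom=qatom,
                        distance=d,
                        direction=_unit(pcen - qcen),
                        protein_charge=psign,
                    )
                )
    records.sort(key=lambda r: (r.protein_atom.residue_key[1], r.distance))
    return records


def contacts_to_rows(records: list[ContactRecord]) -> list[dict]:
    """Tabular form used for TSV export."""
    rows = []
    for r in records:
        ca, cb = r.protein_atom.residue_key, r.partner_atom.residue_key
        rows.append(
            {
                "kind": r.kind,
                "chainA": ca[0],
                "resA": f"{ca[2]}{ca[1]}",
                "atomA": r.protein_atom.name,
                "chainB": cb[0],
                "resB": f"{cb[2]}{cb[1]}",
                "atomB": r.partner_atom.name,
                "distance": round(r.distance, 3),
                "angle": round(r.angle, 1) if r.angle is not None else "",
            }
        )
    return rows


# ---------------------------------------------------------------------------
# hotspot probe maps

#: default favourability cut-offs per probe (kcal/mol)
PROBE_CUTOFFS = {"N1": -4.0, "O": -3.5, "DRY": -2.5}

#: probe LJ parameters: sigma (Å), epsilon (kcal/mol), hbond well depth (kcal/mol)
PROBE_PARAMS = {
    "N1": {"sigma": 3.25, "eps": 0.17, "hb_depth": 4.5},   # sp3 NH donor probe
    "O": {"sigma": 2.96, "eps": 0.21, "hb_depth": 4.0},    # carbonyl oxygen probe
    "DRY": {"sigma": 3.40, "eps": 0.80, "hb_depth": 0.0},  # hydrophobic probe
}

#: per-element LJ parameters for protein heavy atoms
ELEMENT_PARAMS = {
    "C": {"sigma": 3.40, "eps": 0.09},
    "N": {"sigma": 3.25, "eps": 0.17},
    "O": {"sigma": 2.96, "eps": 0.21},
    "S": {"sigma": 3.56, "eps": 0.25},
    "P": {"sigma": 3.74, "eps": 0.20},
}
DEFAULT_ELEMENT = {"sigma": 3.40, "eps": 0.09}

HB_R0 = 2.9   # Å, optimal probe-partner heavy distance of the hbond well
HB_WIDTH = 0.35  # Å, Gaussian width of the well


@dataclass
class HotspotGrid:
    origin: np.ndarray
    spacing: float
    probe: str
    energies: np.ndarray  # 3-D array, kcal/mol
    cutoff: float

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise DomainError("grid spacing must be > 0")
        if self.cutoff > 0:
            raise DomainError("favourability cutoff must be <= 0")

    @property
    def favorable(self) -> np.ndarray:
        return self.energies <= self.cutoff

    def points(self) -> np.ndarray:
        nx, ny, nz = self.energies.shape
        ax = [self.origin[i] + self.spacing * np.arange(n) for i, n in enumerate((nx, ny, nz))]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


def hotspot_grid(
    structure: ComplexStructure,
    probe: str,
    spacing: float = 1.0,
    cutoff: float | None = None,
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
    padding: float = 4.0,
) -> HotspotGrid:
    """Simplified probe interaction map over a regular grid.

    Energy at each point is a sum of 6-12 Lennard-Jones terms over protein
    heavy atoms (Lorentz-Berthelot combination of the probe and element
    parameters above), plus, for the polar N1/O probes, a distance- and
    angle-gated hydrogen-bond well toward complementary polar atoms.
    Points with energy <= cutoff are flagged favourable.
    """
    if probe not in PROBE_PARAMS:
        raise DomainError(f"unknown probe {probe!r}; choose from {sorted(PROBE_PARAMS)}")
    if not (0.2 < spacing <= 2.0):
        raise DomainError("spacing must lie in (0.2, 2.0] Å")
    pp = PROBE_PARAMS[probe]
    if cutoff is None:
        cutoff = PROBE_CUTOFFS[probe]

    heavy = [a for r in structure.residues for a in r.heavy_atoms()]
    if not heavy:
        grid_shape = shape or (1, 1, 1)
        return HotspotGrid(
            origin=np.zeros(3) if origin is None else np.asarray(origin, float),
            spacing=spacing,
            probe=probe,
            energies=np.zeros(grid_shape),
            cutoff=cutoff,
        )
    coords = np.stack([a.coords for a in heavy])
    if origin is None:
        origin = coords.min(axis=0) - padding
    origin = np.asarray(origin, dtype=float)
    if shape is None:
        extent = coords.max(axis=0) + padding - origin
        shape = tuple(int(np.floor(e / spacing)) + 1 for e in extent)

    pts = np.stack(
        np.meshgrid(
            *[origin[i] + spacing * np.arange(shape[i]) for i in range(3)], indexing="ij"
        ),
        axis=-1,
    ).reshape(-1, 3)
    dists = cdist(pts, coords)
    np.clip(dists, 0.5, None, out=dists)  # avoid singularity exactly on an atom

    energies = np.zeros(len(pts))
    for j, atom in enumerate(heavy):
        ep = ELEMENT_PARAMS.get(atom.element, DEFAULT_ELEMENT)
        sig = 0.5 * (pp["sigma"] + ep["sigma"])
        eps = float(np.sqrt(pp["eps"] * ep["eps"]))
        sr6 = (sig / dists[:, j]) ** 6
        energies += 4.0 * eps * (sr6 * sr6 - sr6)

    if pp["hb_depth"] > 0:
        # N1 probe donates -> partner acceptors (N/O); O probe accepts -> partner donor heavies
        partners = [a for a in heavy if a.element in ("N", "O")]
        for atom in partners:
            j = heavy.index(atom)
            d = dists[:, j]
            gate = np.exp(-((d - HB_R0) ** 2) / (2.0 * HB_WIDTH**2))
            # angle gate: continuous ramp favouring approach from outside the
            # residue body (full weight opposite the residue centroid, zero
            # from inside); a smooth gate keeps the map translation-invariant
            res_atoms = [b for b in heavy if b.residue_key == atom.residue_key]
            centroid = np.mean([b.coords for b in res_atoms], axis=0)
            v_out = pts - atom.coords
            v_in = centroid - atom.coords
            if np.linalg.norm(v_in) < 1e-9:
                angle_gate = np.ones(len(pts))
            else:
                cosang = (v_out @ v_in) / (
                    np.linalg.norm(v_out, axis=1) * np.linalg.norm(v_in) + 1e-12
                )
                angle_gate = np.clip(-cosang, 0.0, 1.0)
            energies -= pp["hb_depth"] * gate * angle_gate

    return HotspotGrid(
        origin=origin,
        spacing=spacing,
        probe=probe,
        energies=energies.reshape(shape),
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# consensus binding site

@dataclass
class BindingSiteDefinition:
    residues: set[ResidueKey]
    votes: dict[ResidueKey, int]
    center: np.ndarray | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.votes.values()):
            raise DomainError("every residue must have at least one vote")
        if self.radius is not None and self.radius <= 0:
            raise DomainError("site radius must be > 0")


def consensus_site(
    predictions: list[set],
    experimental_residues: set | None = None,
    min_votes: int = 2,
    structure: ComplexStructure | None = None,
) -> BindingSiteDefinition:
    """Residue-vote consensus over pocket predictions.

    A residue is included iff it gathers >= min_votes across the predictions
    or it belongs to the experimentally implicated set.  When a structure is
    supplied, the site center is the centroid of included residues' Cα/C1'
    atoms and the radius the maximum center-to-included-atom distance.
    """
    if not predictions or min_votes < 1:
        raise DomainError("predictions must be non-empty and min_votes >= 1")
    experimental = set(experimental_residues or ())
    votes: dict = {}
    for pred in predictions:
        for res in pred:
            votes[res] = votes.get(res, 0) + 1
    if not votes and not experimental:
        raise EmptySiteError("all predictions and the experimental set are empty")
    included = {r for r, v in votes.items() if v >= min_votes} | experimental
    kept_votes = {r: votes.get(r, 0) or 1 for r in included}

    center = radius = None
    if structure is not None and included:
        anchor_pts, all_pts = [], []
        for r in structure.residues:
            if r.key not in included and (r.chain, r.number) not in included:
                continue
            names = {a.name: a for a in r.atoms}
            anchor = names.get("CA") or names.get("C1'") or r.atoms[0]
            anchor_pts.append(anchor.coords)
            all_pts.extend(a.coords for a in r.heavy_atoms())
        if anchor_pts:
            center = np.mean(anchor_pts, axis=0)
            radius = float(max(np.linalg.norm(p - center) for p in all_pts))
            radius = max(radius, 1e-6)
    return BindingSiteDefinition(residues=included, votes=kept_votes, center=center, radius=radius)
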