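"""Docking-pose loading and NMR-restraint-gated final-pose selection.

Poses are produced by external docking engines and consumed here.  The
selection rule mirrors the restraint-driven protocol: among the n_keep
lowest-energy solutions, take the lowest-energy pose whose geometry is
consistent with both the chemical-shift-perturbation map (the ligand must
touch the perturbed residues, weighted by significance tier) and the STD
epitope (protons with stronger STD signal should be more buried against
the protein, measured by Spearman rank correlation of burial counts with
relative STD percentages).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from dbdscreen.errors import DomainError, PoseFormatError
from dbdscreen.structio import ComplexStructure, ResidueKey


@dataclass
class Pose:
    pose_id: str
    ligand_atoms: list[tuple[str, str, np.ndarray]]  # (element, name, coords Å)
    energy: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy):
            raise DomainError(f"pose {self.pose_id}: energy must be finite")
        if not self.ligand_atoms:
            raise DomainError(f"pose {self.pose_id}: at least one atom required")
        self.ligand_atoms = [
            (el, name, np.asarray(xyz, dtype=float)) for el, name, xyz in self.ligand_atoms
        ]

    def heavy_coords(self) -> np.ndarray:
        pts = [xyz for el, _, xyz in self.ligand_atoms if el != "H"]
        return np.stack(pts) if pts else np.zeros((0, 3))

    def proton(self, label: str) -> np.ndarray | None:
        for el, name, xyz in self.ligand_atoms:
            if name == label:
                return xyz
        return None


@dataclass
class RestraintSet:
    """Experimental restraints a pose must satisfy.

    csp_residues maps residue key -> tier weight (2 for the most-affected,
    >2σ residues; 1 for the >1σ tier); epitope maps proton label ->
    relative STD percentage.
    """

    csp_residues: dict[ResidueKey, float]
    epitope: dict[str, float] = field(default_factory=dict)
    contact_cutoff: float = 4.0
    burial_cutoff: float = 5.0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.csp_residues.values()):
            raise DomainError("restraint weights must be > 0")
        if self.contact_cutoff <= 0 or self.burial_cutoff <= 0:
            raise DomainError("cutoffs must be > 0")


@dataclass
class ConsistencyReport:
    pose_id: str
    contact_fraction: float
    epitope_score: float | None
    consistent: bool
    contacted: dict[ResidueKey, bool]
    burials: dict[str, int] = field(default_factory=dict)
    epitope_undefined: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.contact_fraction <= 1.0):
            raise DomainError("contact_fraction must lie in [0, 1]")
        if self.epitope_score is not None and not (-1.0 - 1e-9 <= self.epitope_score <= 1.0 + 1e-9):
            raise DomainError("epitope_score must lie in [-1, 1]")


def consistency_score(
    pose: Pose,
    protein: ComplexStructure,
    restraints: RestraintSet,
    f_min: float = 0.6,
    rho_min: float = 0.3,
) -> ConsistencyReport:
    """Score one pose against CSP contacts and the STD epitope.

    A restraint residue is contacted when any of its heavy atoms lies
    within contact_cutoff of any ligand heavy atom; contact_fraction is the
    weight-fraction of contacted residues.  Proton burial counts protein
    heavy atoms within burial_cutoff; the epitope score is the Spearman
    correlation of burial with relative STD percentage.  With fewer than 3
    labeled protons the epitope score is undefined and consistency is
    decided on the contact fraction alone (flagged in the report).
    """
    lig = pose.heavy_coords()
    contacted: dict[ResidueKey, bool] = {}
    res_by_key = {r.key: r for r in protein.residues}
    shortkey = {(r.chain, r.number): r for r in protein.residues}
    total_w = hit_w = 0.0
    for key, w in restraints.csp_residues.items():
        res = res_by_key.get(key) or (shortkey.get(key[:2]) if isinstance(key, tuple) else None)
        if res is None:
            raise DomainError(f"restraint residue {key} absent from protein")
        pc = np.stack([a.coords for a in res.heavy_atoms()])
        hit = bool(
            lig.size
            and np.min(np.linalg.norm(lig[:, None, :] - pc[None, :, :], axis=2))
            <= restraints.contact_cutoff
        )
        contacted[key] = hit
        total_w += w
        hit_w += w if hit else 0.0
    contact_fraction = hit_w / total_w if total_w else 0.0

    prot_heavy = protein.coords(heavy_only=True)
    burials: dict[str, int] = {}
    pcts = []
    for label, pct in sorted(restraints.epitope.items()):
        xyz = pose.proton(label)
        if xyz is None:
            continue
        burials[label] = int(
            np.sum(np.linalg.norm(prot_heavy - xyz, axis=1) <= restraints.burial_cutoff)
        )
        pcts.append(pct)

    epitope_score: float | None = None
    undefined = len(burials) < 3
    if not undefined:
        b = np.array([burials[k] for k in sorted(burials)])
        p = np.array([restraints.epitope[k] for k in sorted(burials)])
        if np.ptp(b) == 0 or np.ptp(p) == 0:
            epitope_score = 0.0  # constant vector: no rank information
        else:
            epitope_score = float(spearmanr(b, p).statistic)

    if undefined:
        warnings.warn(
            f"pose {pose.pose_id}: fewer than 3 labeled protons; "
            "consistency decided on contact fraction alone"
        )
        consistent = contact_fraction >= f_min
    else:
        consistent = contact_fraction >= f_min and epitope_score >= rho_min
    return ConsistencyReport(
        pose_id=pose.pose_id,
        contact_fraction=contact_fraction,
        epitope_score=epitope_score,
        consistent=consistent,
        contacted=contacted,
        burials=burials,
        epitope_undefined=undefined,
    )


@dataclass
class SelectionResult:
    pose: Pose | None
    report: ConsistencyReport | None
    all_reports: list[ConsistencyReport]

    @property
    def selected(self) -> bool:
        return self.pose is not None


def select_final_pose(
    poses: list[Pose],
    protein: ComplexStructure,
    restraints: RestraintSet,
    n_keep: int = 20,
    f_min: float = 0.6,
    rho_min: float = 0.3,
) -> SelectionResult:
    """Restraint-gated energy selection: the lowest-energy consistent pose.

    The n_keep lowest-energy poses are scored in ascending energy order and
    the first consistent one returned; when all fail, a no-selection result
    carries every report for inspection.  The outcome depends only on the
    pose set, not on input ordering (ties in energy broken by pose id).
    """
    if not poses:
        raise DomainError("pose list must be non-empty")
    if n_keep < 1:
        raise DomainError("n_keep must be >= 1")
    window = sorted(poses, key=lambda p: (p.energy, p.pose_id))[:n_keep]
    reports = []
    for pose in window:
        rep = consistency_score(pose, protein, restraints, f_min=f_min, rho_min=rho_min)
        reports.append(rep)
        if rep.consistent:
            return SelectionResult(pose=pose, report=rep, all_reports=reports)
    return SelectionResult(pose=None, report=None, all_reports=reports)


# ---------------------------------------------------------------------------
# pose I/O

def load_poses(path_or_buf) -> list[Pose]:
    """Load poses from the tab-separated pose dialect (or SDF via rdkit).

    Dialect: a ``POSE <id> <energy>`` header line starts each record,
    followed by atom rows ``element name x y z``; ``#`` lines are comments.
    Records without a parseable energy are rejected with a warning;
    duplicate pose ids are an error.  Returned poses are sorted ascending
    by energy.
    """
    if not hasattr(path_or_buf, "read"):
        path = str(path_or_buf)
        if path.lower().endswith(".sdf"):
            return _load_poses_sdf(path)
        with open(path) as fh:
            text = fh.read()
    else:
        text = path_or_buf.read()

    poses: list[Pose] = []
    seen: set[str] = set()
    current_id: str | None = None
    current_energy: float | None = None
    atoms: list[tuple[str, str, np.ndarray]] = []

    def flush() -> None:
        nonlocal current_id, current_energy, atoms
        if current_id is None:
            return
        if current_energy is None:
            warnings.warn(f"pose {current_id}: missing energy; record rejected")
        elif not atoms:
            warnings.warn(f"pose {current_id}: no atoms; record rejected")
        else:
            if current_id in seen:
                raise PoseFormatError(f"duplicate pose id {current_id!r}")
            seen.add(current_id)
            poses.append(Pose(pose_id=current_id, ligand_atoms=atoms, energy=current_energy))
        current_id, current_energy, atoms = None, None, []

    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if parts[0] == "POSE":
            flush()
            if len(parts) < 2:
                raise PoseFormatError(f"line {lineno}: POSE header needs an id")
            current_id = parts[1]
            try:
                current_energy = float(parts[2]) if len(parts) > 2 else None
            except ValueError:
                current_energy = None
        else:
            if current_id is None:
                raise PoseFormatError(f"line {lineno}: atom row before any POSE header")
            if len(parts) != 5:
                raise PoseFormatError(f"line {lineno}: atom rows are 'element name x y z'")
            el, name, x, y, z = parts
            try:
                xyz = np.array([float(x), float(y), float(z)])
            except ValueError:
                raise PoseFormatError(f"line {lineno}: malformed coordinate") from None
            atoms.append((el.capitalize(), name, xyz))
    flush()
    poses.sort(key=lambda p: (p.energy, p.pose_id))
    return poses


def _load_poses_sdf(path: str) -> list[Pose]:
    from rdkit import Chem

    poses: list[Pose] = []
    seen: set[str] = set()
    for i, mol in enumerate(Chem.SDMolSupplier(path, removeHs=False, sanitize=False)):
        if mol is None:
            warnings.warn(f"SDF record {i}: unreadable; skipped")
            continue
        pid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"pose_{i}"
        if not mol.HasProp("energy"):
            warnings.warn(f"pose {pid}: missing energy property; record rejected")
            continue
        if pid in seen:
            raise PoseFormatError(f"duplicate pose id {pid!r}")
        seen.add(pid)
        conf = mol.GetConformer()
        atoms = []
        for a in mol.GetAtoms():
            p = conf.GetAtomPosition(a.GetIdx())
            atoms.append(
                (a.GetSymbol(), f"{a.GetSymbol()}{a.GetIdx() + 1}", np.array([p.x, p.y, p.z]))
            )
        poses.append(Pose(pose_id=pid, ligand_atoms=atoms, energy=float(mol.GetProp("energy"))))
    poses.sort(key=lambda p: (p.energy, p.pose_id))
    return poses


def write_poses(poses: list[Pose], path_or_buf) -> None:
    lines = []
    for p in poses:
        lines.append(f"POSE\t{p.pose_id}\t{p.energy:.4f}")
        for el, name, xyz in p.ligand_atoms:
            lines.append(f"{el}\t{name}\t{xyz[0]:.4f}\t{xyz[1]:.4f}\t{xyz[2]:.4f}")
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)
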