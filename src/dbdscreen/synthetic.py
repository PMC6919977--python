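"""Seeded generators with planted ground truth for every pipeline stage.

Each generator is a pure function of (seed, configuration): the random
stream is derived from the seed and the generator's name, so independent
generators never share state and reruns are byte-identical.  Every
generator emits a machine-readable truth manifest describing exactly what
was planted, and the matching pipeline stage is expected to recover it —
that recovery is the backbone of the test suite.

Defaults emulate the study conditions: a 114-residue construct span
(156-269) with 99 assigned backbone amides and 8 strongly perturbed
residues; an STD epitope with four pronounced protons out of seven;
20-pose docking decks; differential-expression tables with 1262 induced
probesets of which 193 reverse significantly and 779 as a trend, against a
second contrast with 208 up-regulated probesets sharing 35 with the first.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dbdscreen import contacts as contacts_mod
from dbdscreen import nmr, poses as poses_mod, structio
from dbdscreen.errors import DomainError, PlacementError
from dbdscreen.pharmacophore import (
    ConformerFeatureSet,
    FeaturePoint,
    PharmacophoreModel,
    match_conformer,
)
from dbdscreen.structio import Atom, ComplexStructure, Residue

#: the labelled insulin-responsive-element oligo used as the FP probe
IRE_OLIGO = "CTATCAAAACAACGC"

#: backbone-amide chemical-shift windows (ppm) for synthetic peak lists
H_RANGE = (6.5, 10.5)
N_RANGE = (105.0, 135.0)


def rng_for(seed: int, name: str) -> np.random.Generator:
    """One pseudo-random stream per (seed, generator name)."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# toy protein-DNA complex with planted contacts

def _peptide_residue(chain: str, number: int, x0: float, serial0: int) -> Residue:
    """Idealized alanine-like residue with an explicit amide hydrogen."""
    key = (chain, number, "ALA")
    mk = lambda i, name, el, xyz: Atom(serial0 + i, name, el, np.array(xyz), key)
    atoms = [
        mk(0, "N", "N", (x0, 0.0, 0.0)),
        mk(1, "H", "H", (x0, 1.0, 0.0)),
        mk(2, "CA", "C", (x0 + 1.2, -0.8, 0.0)),
        mk(3, "CB", "C", (x0 + 1.2, -0.8, 1.53)),
        mk(4, "C", "C", (x0 + 2.4, 0.0, 0.0)),
        mk(5, "O", "O", (x0 + 2.4, -1.2, -0.5)),
    ]
    return Residue(chain, number, "ALA", atoms)


def gen_toy_complex(
    seed: int,
    n_hbonds: int = 2,
    n_hydrophobic: int = 1,
    jitter_sd: float = 0.01,
) -> tuple[ComplexStructure, list[dict]]:
    """A short idealized peptide facing a 3-bp DNA fragment with planted contacts.

    The peptide (chain A, alanine-like residues with explicit amide
    hydrogens) runs along x; the DNA fragment (chain B, bases drawn from the
    IRE oligo) is parked out of contact range, and exactly the requested
    number of hydrogen bonds (backbone N-H to a phosphate oxygen at 2.9 Å,
    near-linear) and hydrophobic contacts (CB to an isolated DNA carbon at
    3.8 Å) are planted.  Returns the structure and a manifest listing the
    planted contacts; generation self-checks the manifest against
    :func:`dbdscreen.contacts.perceive_contacts` and raises
    :class:`PlacementError` on any mismatch.
    """
    if n_hbonds < 0 or n_hydrophobic < 0:
        raise DomainError("contact counts must be >= 0")
    rng = rng_for(seed, "toy_complex")
    n_res = max(4, 2 * (n_hbonds + n_hydrophobic) + 2)
    spacing = 6.0
    residues = [
        _peptide_residue("A", 201 + i, spacing * i, 1 + 6 * i) for i in range(n_res)
    ]

    # DNA residues parked 18 Å away; planted atoms are appended to them
    bases = {"C": "DC", "T": "DT", "A": "DA", "G": "DG"}
    dna_names = [bases[b] for b in IRE_OLIGO[:3]]
    serial = 1000
    dna_residues = []
    for j, name in enumerate(dna_names):
        key = ("B", j + 1, name)
        x0 = 10.0 * j
        atoms = [
            Atom(serial, "P", "P", np.array([x0, -18.0, 0.0]), key),
            Atom(serial + 1, "OP1", "O", np.array([x0 + 1.2, -18.8, 0.0]), key),
            Atom(serial + 2, "OP2", "O", np.array([x0 - 1.2, -18.8, 0.0]), key),
            Atom(serial + 3, "C1'", "C", np.array([x0, -15.0, 0.0]), key),
        ]
        dna_residues.append([key, atoms])
        serial += 10

    manifest: list[dict] = []
    # planted hydrogen bonds: acceptor O on the N->H axis, 2.9 Å from N
    for k in range(n_hbonds):
        ridx = 2 * k
        res = residues[ridx]
        n_atom = res.atom("N")
        jit = rng.normal(0.0, jitter_sd, size=3)
        pos = n_atom.coords + np.array([0.0, 2.9, 0.0]) + jit
        dres = dna_residues[k % 3]
        acc = Atom(serial, "OXT", "O", pos, dres[0])
        serial += 1
        dres[1].append(acc)
        manifest.append(
            {
                "kind": "hbond",
                "protein_residue": res.key,
                "protein_atom": "N",
                "partner_residue": dres[0],
                "partner_atom": "OXT",
            }
        )
    # planted hydrophobic contacts: isolated carbon 3.8 Å from CB
    for m in range(n_hydrophobic):
        ridx = 2 * (n_hbonds + m)
        res = residues[ridx]
        cb = res.atom("CB")
        jit = rng.normal(0.0, jitter_sd, size=3)
        pos = cb.coords + np.array([0.0, 3.8, 2.0]) + jit
        dres = dna_residues[m % 3]
        carb = Atom(serial, "CM", "C", pos, dres[0])
        serial += 1
        dres[1].append(carb)
        manifest.append(
            {
                "kind": "hydrophobic",
                "protein_residue": res.key,
                "protein_atom": "CB",
                "partner_residue": dres[0],
                "partner_atom": "CM",
            }
        )

    residues += [Residue(k[0], k[1], k[2], atoms) for (k, atoms) in dna_residues]
    cx = ComplexStructure(residues=residues)

    perceived = contacts_mod.perceive_contacts(cx, "A", "B")
    got = {
        (r.kind, r.protein_atom.residue_key, r.protein_atom.name, r.partner_atom.name)
        for r in perceived
    }
    want = {
        (m["kind"], m["protein_residue"], m["protein_atom"], m["partner_atom"])
        for m in manifest
    }
    if got != want:
        raise PlacementError(
            f"planted contacts not realized: expected {sorted(want)}, perceived {sorted(got)}"
        )
    return cx, manifest


def toy_complex_pdb(seed: int, n_hbonds: int = 2, n_hydrophobic: int = 1) -> tuple[str, list[dict]]:
    """The toy complex serialized as PDB text, plus its manifest."""
    cx, manifest = gen_toy_complex(seed, n_hbonds, n_hydrophobic)
    buf = io.StringIO()
    structio.write_structure(cx, buf)
    return buf.getvalue(), manifest


# ---------------------------------------------------------------------------
# conformer libraries with planted actives

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def gen_conformer_library(
    model: PharmacophoreModel,
    n_actives: int = 5,
    n_decoys: int = 50,
    noise_sd: float = 0.3,
    seed: int = 0,
    max_retries: int = 50,
) -> tuple[list[ConformerFeatureSet], dict[str, bool]]:
    """A screening library of planted actives and guaranteed-failing decoys.

    Actives copy the model geometry, jitter it isotropically (σ = noise_sd,
    which must stay below the smallest feature tolerance) and apply a random
    proper rigid transform — the matcher must undo the transform and accept.
    Decoys shuffle feature kinds and distort pairwise distances; each decoy
    is verified to produce no match (resampled up to ``max_retries`` times),
    so truth labels are exact, not merely probable.
    """
    min_tol = min(f.tolerance for f in model.features)
    if noise_sd >= min_tol:
        raise DomainError("noise_sd must stay below the smallest feature tolerance")
    rng = rng_for(seed, "conformer_library")
    centroids = np.stack([f.centroid for f in model.features])
    kinds = [f.kind for f in model.features]
    library: list[ConformerFeatureSet] = []
    labels: dict[str, bool] = {}

    for i in range(n_actives):
        cid = f"ACT-{i + 1:04d}"
        for attempt in range(max_retries):
            pts = centroids + rng.normal(0.0, noise_sd, size=centroids.shape)
            R = _random_rotation(rng)
            t = rng.uniform(-20.0, 20.0, size=3)
            moved = pts @ R.T + t
            conf = ConformerFeatureSet(
                compound_id=cid,
                conformer_id=0,
                points=[FeaturePoint(kind=k, position=p) for k, p in zip(kinds, moved)],
            )
            res = match_conformer(model, conf)
            if res is not None and res.matched_required:
                break
        else:
            raise PlacementError(f"could not realize active {cid} within retry budget")
        library.append(conf)
        labels[cid] = True

    distinct_kinds = sorted(set(kinds))
    for i in range(n_decoys):
        cid = f"DEC-{i + 1:04d}"
        for attempt in range(max_retries):
            # distance distortion plus kind shuffling defeats both the
            # pruning geometry and the type gate
            scale = rng.uniform(2.5, 4.0)
            pts = centroids * scale + rng.normal(0.0, 1.0, size=centroids.shape)
            shuffled = list(kinds)
            rng.shuffle(shuffled)
            if len(distinct_kinds) > 1 and shuffled == kinds:
                continue
            conf = ConformerFeatureSet(
                compound_id=cid,
                conformer_id=0,
                points=[FeaturePoint(kind=k, position=p) for k, p in zip(shuffled, pts)],
            )
            if match_conformer(model, conf) is None:
                break
        else:
            raise PlacementError(f"could not realize decoy {cid} within retry budget")
        library.append(conf)
        labels[cid] = False
    return library, labels


# ---------------------------------------------------------------------------
# NMR peak lists with a planted hot set

#: the most-affected residues of the study: helix H1 (167), helix H3
#: (211-216), wing W2 (220, 237)
DEFAULT_HOT_RESIDUES = (167, 211, 212, 213, 215, 216, 220, 237)


def gen_peaklists(
    residue_span: tuple[int, int] = (156, 269),
    n_assigned: int = 99,
    hot_residues: tuple[int, ...] = DEFAULT_HOT_RESIDUES,
    effect_ppm: float = 0.08,
    noise_sd: float = 0.002,
    seed: int = 0,
    weight: float = nmr.DEFAULT_CSP_WEIGHT,
) -> tuple[nmr.PeakList, nmr.PeakList, dict]:
    """Free and bound peak lists with a planted perturbed hot set.

    ``n_assigned`` residues of the span carry peaks (hot residues always
    included); the bound list shifts each hot residue by a random-direction
    (Δδ_H, Δδ_N) pair whose weighted CSP equals ``effect_ppm`` exactly,
    then adds Gaussian noise (σ = noise_sd on the ¹H axis, scaled by the
    inverse weight on the ¹⁵N axis) everywhere.
    """
    lo, hi = residue_span
    span = list(range(lo, hi + 1))
    hot = sorted(set(hot_residues))
    if not set(hot) <= set(span):
        raise DomainError("hot residues must lie inside the span")
    if n_assigned > len(span):
        raise DomainError("cannot assign more residues than the span holds")
    if effect_ppm <= 3 * noise_sd:
        import warnings

        warnings.warn("planted effect is close to the noise floor; recovery not guaranteed")
    rng = rng_for(seed, "peaklists")
    cold = [r for r in span if r not in hot]
    extra = rng.choice(cold, size=n_assigned - len(hot), replace=False)
    assigned = sorted(set(hot) | set(int(r) for r in extra))

    free = {
        r: (float(rng.uniform(*H_RANGE)), float(rng.uniform(*N_RANGE))) for r in assigned
    }
    bound = {}
    for r in assigned:
        dh = rng.normal(0.0, noise_sd)
        dn = rng.normal(0.0, noise_sd / weight)
        if r in hot:
            # random direction scaled so the weighted CSP equals effect_ppm
            theta = rng.uniform(0.0, 2.0 * np.pi)
            dh += effect_ppm * np.cos(theta)
            dn += effect_ppm * np.sin(theta) / weight
        bound[r] = (free[r][0] + dh, free[r][1] + dn)
    truth = {"hot_residues": hot, "assigned": assigned, "effect_ppm": effect_ppm}
    return (
        nmr.PeakList(entries=free, label="free"),
        nmr.PeakList(entries=bound, label="bound"),
        truth,
    )


def gen_titration_series(
    concentrations: tuple[float, ...] = (1.5, 3.0, 5.0, 7.0),
    kd_mm: float = 2.0,
    residue_span: tuple[int, int] = (156, 269),
    n_assigned: int = 99,
    hot_residues: tuple[int, ...] = DEFAULT_HOT_RESIDUES,
    effect_ppm: float = 0.08,
    noise_sd: float = 1e-4,
    seed: int = 0,
    weight: float = nmr.DEFAULT_CSP_WEIGHT,
) -> tuple[nmr.PeakList, list[nmr.PeakList], dict]:
    """Fast-exchange titration: CSPs follow a saturation curve c/(K+c).

    Returns the reference (free) list, one bound list per concentration
    (mM), and the truth manifest.
    """
    if len(concentrations) < 2:
        raise DomainError("a titration needs at least 2 concentrations")
    free, bound_full, truth = gen_peaklists(
        residue_span, n_assigned, hot_residues, effect_ppm, 0.0, seed, weight
    )
    rng = rng_for(seed, "titration_noise")
    series = []
    for c in concentrations:
        frac = c / (kd_mm + c)
        entries = {}
        for r in free.entries:
            dh = (bound_full.entries[r][0] - free.entries[r][0]) * frac
            dn = (bound_full.entries[r][1] - free.entries[r][1]) * frac
            entries[r] = (
                free.entries[r][0] + dh + rng.normal(0.0, noise_sd),
                free.entries[r][1] + dn + rng.normal(0.0, noise_sd / weight),
            )
        series.append(nmr.PeakList(entries=entries, label=f"+{c:g} mM"))
    truth = dict(truth, concentrations=list(concentrations), kd_mm=kd_mm)
    return free, series, truth


#: qualitative STD pattern of the oxalate-salt ligand: four pronounced
#: protons, two weak, one silent
S9OX_STD_PATTERN = {
    "H1": 0.95,
    "H2": 0.0,
    "H3": 1.0,
    "H4": 0.30,
    "H5": 0.90,
    "H6": 0.28,
    "H7": 0.85,
}


def gen_std_table(
    pattern: dict[str, float] | None = None,
    i0: float = 1.0,
    max_astd: float = 0.4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, float, float]], dict]:
    """STD intensity records realizing a relative amplification pattern.

    ``pattern`` maps proton label to its relative amplification (1.0 = the
    strongest proton, which receives A_STD = max_astd).
    """
    pattern = dict(S9OX_STD_PATTERN if pattern is None else pattern)
    rng = rng_for(seed, "std_table")
    records = []
    for proton in sorted(pattern):
        a = max_astd * pattern[proton] + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
        records.append((proton, i0, i0 * (1.0 - a)))
    truth = {
        "pronounced": sorted(p for p, rel in pattern.items() if rel >= 0.5),
        "absent": sorted(p for p, rel in pattern.items() if rel <= 0.0),
    }
    return records, truth


# ---------------------------------------------------------------------------
# FP plates

def gen_fp_plate(
    mu_p: float = 60.0,
    mu_n: float = 180.0,
    cv: float = 0.025,
    n_per_group: int = 16,
    doses: tuple[float, ...] = (),
    ec50: float = 10.0,
    seed: int = 0,
) -> tuple[list, dict]:
    """A synthetic FP plate: control wells plus a planted displacement curve.

    Positive controls (free oligo) scatter around ``mu_p`` and negative
    controls (bound DBD + oligo) around ``mu_n``, both with relative SD
    ``cv``.  Sample wells at the given doses (µM) follow the noiseless
    monotone curve mP(d) = μ_n + (μ_p − μ_n)·d/(d + ec50), so displacement
    increases strictly with dose.
    """
    from dbdscreen.assays import Well

    if mu_p == mu_n:
        raise DomainError("control means must differ")
    if cv < 0:
        raise DomainError("cv must be >= 0")
    rng = rng_for(seed, "fp_plate")
    wells = []
    for i in range(n_per_group):
        wells.append(
            Well(f"P{i + 1:02d}", "positive_ctrl", mp=float(mu_p + rng.normal(0, cv * abs(mu_p))))
        )
    for i in range(n_per_group):
        wells.append(
            Well(f"N{i + 1:02d}", "negative_ctrl", mp=float(mu_n + rng.normal(0, cv * abs(mu_n))))
        )
    curve = {}
    for i, d in enumerate(doses):
        mp = mu_n + (mu_p - mu_n) * d / (d + ec50)
        curve[d] = mp
        wells.append(Well(f"S{i + 1:02d}", "sample", dose=d, mp=float(mp)))
    truth = {
        "mu_p": mu_p,
        "mu_n": mu_n,
        "cv": cv,
        "zprime_closed_form": 1.0 - 3.0 * cv * (abs(mu_p) + abs(mu_n)) / abs(mu_p - mu_n),
        "curve": curve,
    }
    return wells, truth


def plate_tsv(wells) -> str:
    rows = ["well\trole\tdose_uM\tmP"]
    for w in wells:
        dose = "" if w.dose is None else f"{w.dose:g}"
        rows.append(f"{w.plate_pos}\t{w.role}\t{dose}\t{w.mp:.4f}")
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# differential-expression contrasts

def gen_de_tables(
    n_universe: int = 10_000,
    n_induced_a: int = 1262,
    n_reversed_sig: int = 193,
    n_reversed_ns: int = 779,
    n_up_b_total: int = 208,
    n_common: int = 35,
    alpha: float = 0.05,
    seed: int = 0,
    n_repressed_a: int = 889,
) -> tuple["pd.DataFrame", "pd.DataFrame", dict]:
    """Two DE contrasts with planted category sizes (margins guaranteed).

    Category sizes default to the study's printed counts: 1262 probesets
    induced (889 repressed) by activation alone; among the induced, 193
    reverse significantly and 779 as a non-significant trend under the
    inhibitor; the inhibitor contrast has 208 significantly up-regulated
    probesets of which 35 are shared with the induced set.  All defining
    inequalities are satisfied with margin, so classification recovers the
    counts exactly.  Returns contrast A, contrast B (as DataFrames with
    columns probeset/log2fc/padj) and the truth manifest.
    """
    from dbdscreen.transcription import reversal_percentages

    if n_reversed_sig + n_reversed_ns + n_common > n_induced_a:
        raise DomainError("reversal categories plus the common set exceed the induced count")
    needed = n_induced_a + n_repressed_a + (n_up_b_total - n_common)
    if needed > n_universe:
        raise DomainError("universe too small for the requested categories")
    if not (0 < alpha < 1):
        raise DomainError("alpha must lie in (0, 1)")
    rng = rng_for(seed, "de_tables")

    ids = np.array([f"PS{i + 1:06d}" for i in range(n_universe)])
    perm = rng.permutation(n_universe)
    induced = perm[:n_induced_a]
    repressed = perm[n_induced_a : n_induced_a + n_repressed_a]
    only_b = perm[n_induced_a + n_repressed_a : needed]

    sig = lambda n: rng.uniform(1e-8, 0.8 * alpha, size=n)
    nonsig = lambda n: rng.uniform(1.5 * alpha, 1.0, size=n)
    up = lambda n: rng.uniform(0.5, 3.0, size=n)
    down = lambda n: -rng.uniform(0.5, 3.0, size=n)

    a_lfc = rng.normal(0.0, 0.1, size=n_universe)
    a_padj = nonsig(n_universe)
    a_lfc[induced] = up(n_induced_a)
    a_padj[induced] = sig(n_induced_a)
    a_lfc[repressed] = down(n_repressed_a)
    a_padj[repressed] = sig(n_repressed_a)

    b_lfc = rng.normal(0.0, 0.1, size=n_universe)
    b_padj = nonsig(n_universe)
    rev_sig = induced[:n_reversed_sig]
    rev_ns = induced[n_reversed_sig : n_reversed_sig + n_reversed_ns]
    common = induced[n_reversed_sig + n_reversed_ns : n_reversed_sig + n_reversed_ns + n_common]
    rest = induced[n_reversed_sig + n_reversed_ns + n_common :]
    b_lfc[rev_sig] = down(len(rev_sig))
    b_padj[rev_sig] = sig(len(rev_sig))
    b_lfc[rev_ns] = down(len(rev_ns))
    b_padj[rev_ns] = nonsig(len(rev_ns))
    b_lfc[common] = up(len(common))
    b_padj[common] = sig(len(common))
    b_lfc[rest] = np.abs(rng.normal(0.2, 0.05, size=len(rest))) + 0.01  # up, not significant
    b_padj[rest] = nonsig(len(rest))
    b_lfc[only_b] = up(len(only_b))
    b_padj[only_b] = sig(len(only_b))

    contrast_a = pd.DataFrame({"probeset": ids, "log2fc": a_lfc, "padj": a_padj})
    contrast_b = pd.DataFrame({"probeset": ids, "log2fc": b_lfc, "padj": b_padj})
    pct_overall, pct_sig = reversal_percentages(n_induced_a, n_reversed_sig, n_reversed_ns)
    truth = {
        "n_induced": n_induced_a,
        "n_repressed": n_repressed_a,
        "n_reversed_sig": n_reversed_sig,
        "n_reversed_ns": n_reversed_ns,
        "n_up_b": n_up_b_total,
        "n_common": n_common,
        "pct_overall": pct_overall,
        "pct_sig": pct_sig,
        "induced_ids": sorted(ids[induced]),
        "up_b_ids": sorted(np.concatenate([ids[common], ids[only_b]])),
    }
    return contrast_a, contrast_b, truth


# ---------------------------------------------------------------------------
# docking decks with one planted consistent pose

def gen_poses(
    protein: ComplexStructure,
    restraints: poses_mod.RestraintSet,
    n_poses: int = 20,
    planted_rank: int = 1,
    seed: int = 0,
) -> tuple[list[poses_mod.Pose], dict]:
    """A docking deck where exactly one pose satisfies the restraints.

    The planted pose places one heavy atom 3 Å from each restraint residue
    and arranges its labelled protons so burial tracks the STD epitope; it
    occupies energy rank ``planted_rank`` (1 = lowest).  Decoys are the
    same ligand displaced far from the site, so their contact fraction is
    zero.  Energies are strictly ordered; truth records the planted id.
    """
    if not (1 <= planted_rank <= n_poses):
        raise DomainError("planted_rank must lie in [1, n_poses]")
    rng = rng_for(seed, "poses")
    res_by_short = {(r.chain, r.number): r for r in protein.residues}
    res_by_key = {r.key: r for r in protein.residues}

    atoms: list[tuple[str, str, np.ndarray]] = []
    i = 0
    for key in sorted(restraints.csp_residues, key=str):
        res = res_by_key.get(key) or res_by_short.get(tuple(key)[:2])
        if res is None:
            raise PlacementError(f"restraint residue {key} not in protein")
        anchor = res.heavy_atoms()[0]
        offset = rng.normal(0.0, 0.1, size=3) + np.array([0.0, 3.0, 0.0])
        atoms.append(("C", f"C{i + 1}", anchor.coords + offset))
        i += 1
    # labelled protons: stronger STD -> placed nearer the protein body
    prot_heavy = protein.coords(heavy_only=True)
    center = prot_heavy.mean(axis=0)
    anchor0 = atoms[0][2]
    direction = anchor0 - center
    direction /= np.linalg.norm(direction) + 1e-12
    ordered = sorted(restraints.epitope.items(), key=lambda kv: -kv[1])
    for j, (label, pct) in enumerate(ordered):
        # distance from the protein grows as the STD percentage falls
        dist = 1.0 + 2.5 * j
        atoms.append(("H", label, anchor0 + direction * dist + rng.normal(0, 0.05, 3)))

    energies = sorted(rng.uniform(-9.5, -5.0, size=n_poses))
    planted_energy = energies[planted_rank - 1]
    deck: list[poses_mod.Pose] = []
    planted = poses_mod.Pose(
        pose_id=f"pose_{planted_rank:03d}", ligand_atoms=list(atoms), energy=float(planted_energy)
    )
    deck.append(planted)
    far = np.array([120.0, 120.0, 120.0])
    rank = 0
    for e in energies:
        if e == planted_energy:
            continue
        rank += 1
        displaced = [
            (el, name, xyz + far + rng.normal(0, 1.0, 3)) for el, name, xyz in atoms
        ]
        deck.append(
            poses_mod.Pose(pose_id=f"decoy_{rank:03d}", ligand_atoms=displaced, energy=float(e))
        )

    report = poses_mod.consistency_score(planted, protein, restraints)
    if not report.consistent:
        raise PlacementError(
            f"planted pose failed its own consistency check "
            f"(contact_fraction={report.contact_fraction:.2f}, "
            f"epitope_score={report.epitope_score})"
        )
    truth = {"planted_id": planted.pose_id, "planted_rank": planted_rank}
    return deck, truth


def gen_pose_scenario(
    seed: int = 0, n_poses: int = 20, planted_rank: int = 1
) -> tuple[ComplexStructure, poses_mod.RestraintSet, list[poses_mod.Pose], dict]:
    """Convenience bundle: toy protein, tiered restraints, epitope, pose deck."""
    cx, _ = gen_toy_complex(seed, n_hbonds=2, n_hydrophobic=1)
    protein_res = [r for r in cx.residues if r.chain == "A"]
    tier2 = protein_res[: min(4, len(protein_res))]
    tier1 = protein_res[min(4, len(protein_res)) : min(6, len(protein_res))]
    csp_residues = {r.key: 2.0 for r in tier2}
    csp_residues.update({r.key: 1.0 for r in tier1})
    epitope = {
        rec.proton: rec.relative_pct
        for rec in nmr.std_epitope(gen_std_table(seed=seed)[0])
    }
    restraints = poses_mod.RestraintSet(csp_residues=csp_residues, epitope=epitope)
    protein = ComplexStructure(residues=protein_res)
    deck, truth = gen_poses(protein, restraints, n_poses, planted_rank, seed)
    return protein, restraints, deck, truth
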