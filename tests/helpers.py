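"""Independent brute-force oracles used by the oracle-equivalence tests.

These deliberately avoid the production search/classification code paths:
the matcher oracle enumerates every injective type-compatible assignment
with itertools, and the classification oracles re-scan rows one by one.
"""

from __future__ import annotations

import itertools

import numpy as np

from dbdscreen.pharmacophore import (
    ConformerFeatureSet,
    MatchResult,
    PharmacophoreModel,
    kabsch,
)


def brute_force_match(
    model: PharmacophoreModel, conf: ConformerFeatureSet, angle_tol: float = 45.0
) -> MatchResult | None:
    """Exhaustive assignment search: all subsets x all injective placements."""
    feats = model.features
    pts = conf.points
    n = len(feats)
    best = None
    best_key = None
    for size in range(3, n + 1):
        for fsub in itertools.combinations(range(n), size):
            if not model.required_ids <= set(fsub):
                continue
            compat = [
                [j for j, p in enumerate(pts) if p.kind == feats[i].kind] for i in fsub
            ]
            for assignment in itertools.product(*compat):
                if len(set(assignment)) != size:
                    continue
                P = np.stack([pts[j].position for j in assignment])
                Q = np.stack([feats[i].centroid for i in fsub])
                R, t, rmsd = kabsch(P, Q)
                moved = P @ R.T + t
                ok = all(
                    np.linalg.norm(moved[r] - feats[i].centroid) <= feats[i].tolerance + 1e-9
                    for r, i in enumerate(fsub)
                )
                if not ok:
                    continue
                dir_ok = True
                for r, i in enumerate(fsub):
                    fdir = feats[i].direction
                    pdir = pts[assignment[r]].direction
                    if fdir is not None and pdir is not None:
                        cosang = float(np.clip(np.dot(R @ pdir, fdir), -1.0, 1.0))
                        if np.degrees(np.arccos(cosang)) > angle_tol + 1e-9:
                            dir_ok = False
                            break
                if not dir_ok:
                    continue
                mapping = dict(zip(fsub, assignment))
                key = (-size, rmsd, tuple(sorted(mapping.items())))
                if best_key is None or key < best_key:
                    best_key = key
                    best = MatchResult(
                        mapping=mapping,
                        rmsd=rmsd,
                        n_matched=size,
                        matched_required=True,
                    )
    return best


def rescan_csp_classes(csps: dict[int, float], mean: float, sigma: float) -> dict[int, str]:
    """Row-by-row threshold classification (strict inequalities)."""
    out = {}
    for res, v in csps.items():
        if v > mean + 2 * sigma:
            out[res] = "above_2sigma"
        elif v > mean + sigma:
            out[res] = "above_1sigma"
        elif v > mean:
            out[res] = "above_mean"
        else:
            out[res] = "below_mean"
    return out


def rescan_reversal(rows_a, rows_b, alpha: float):
    """Row-by-row reversal classification over the shared probeset universe.

    rows_* are dicts probeset -> (log2fc, padj).
    """
    shared = set(rows_a) & set(rows_b)
    n_induced = n_repressed = n_sig = n_ns = 0
    up_a, up_b = set(), set()
    for ps in shared:
        lfc_a, p_a = rows_a[ps]
        lfc_b, p_b = rows_b[ps]
        if p_a < alpha and lfc_a > 0:
            n_induced += 1
            up_a.add(ps)
            if lfc_b < 0:
                if p_b < alpha:
                    n_sig += 1
                else:
                    n_ns += 1
        if p_a < alpha and lfc_a < 0:
            n_repressed += 1
        if p_b < alpha and lfc_b > 0:
            up_b.add(ps)
    return n_induced, n_repressed, n_sig, n_ns, up_a, up_b
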