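"""Chemical-shift perturbation (CSP) quantification and STD epitope ranking.

The CSP of a backbone amide between free and ligand-bound ¹H-¹⁵N HSQC
spectra is the weighted Euclidean combination

    CSP = sqrt(Δδ_H² + (w · Δδ_N)²),   default w = 1/5,

which rescales the wider ¹⁵N ppm axis onto the ¹H scale.  Residues are
classified against distribution thresholds — mean, mean + 1σ, mean + 2σ —
where σ is either the plain standard deviation of the whole CSP set
(default) or a 3σ-trimmed variant (σ⁰_corr with iterative outlier
exclusion), and relative CSPs are obtained by dividing the absolute values
by that standard deviation.

STD (saturation transfer difference) amplification factors
A_STD = (I0 − Isat)/I0 rank ligand protons by proximity to the protein:
protons above the relative threshold form the "pronounced" binding epitope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dbdscreen.errors import DomainError, EmptyResultError

DEFAULT_CSP_WEIGHT = 0.2  # 1/5 nitrogen weighting

CLASS_LEVELS = ("below_mean", "above_mean", "above_1sigma", "above_2sigma", "unassigned")


@dataclass
class PeakList:
    """Assigned ¹H-¹⁵N peak positions: residue number -> (δH, δN) in ppm."""

    entries: dict[int, tuple[float, float]]
    label: str = ""

    def __post_init__(self) -> None:
        for res, (dh, dn) in self.entries.items():
            if not (np.isfinite(dh) and np.isfinite(dn)):
                raise DomainError(f"residue {res}: non-finite chemical shift")

    @classmethod
    def read_tsv(cls, path_or_buf, label: str = "") -> "PeakList":
        df = pd.read_csv(path_or_buf, sep="\t", comment="#")
        cols = {c.lower(): c for c in df.columns}
        res_c = cols.get("residue") or cols.get("res")
        h_c = cols.get("dh_ppm") or cols.get("dh")
        n_c = cols.get("dn_ppm") or cols.get("dn")
        if not (res_c and h_c and n_c):
            raise DomainError("peak list TSV needs columns residue, dH_ppm, dN_ppm")
        if df[res_c].duplicated().any():
            raise DomainError("duplicate residue numbers in peak list")
        return cls(
            entries={
                int(r): (float(h), float(n))
                for r, h, n in zip(df[res_c], df[h_c], df[n_c])
            },
            label=label,
        )

    def write_tsv(self, path_or_buf) -> None:
        pd.DataFrame(
            [
                {"residue": r, "dH_ppm": h, "dN_ppm": n}
                for r, (h, n) in sorted(self.entries.items())
            ]
        ).to_csv(path_or_buf, sep="\t", index=False, float_format="%.4f")


@dataclass
class CSPResult:
    residue: int
    delta_h: float | None
    delta_n: float | None
    csp: float | None
    relative_csp: float | None = None
    cls: str = "unassigned"

    def __post_init__(self) -> None:
        if self.csp is not None and self.csp < 0:
            raise DomainError("csp must be >= 0")
        if self.cls not in CLASS_LEVELS:
            raise DomainError(f"unknown class {self.cls!r}")


@dataclass
class CSPSummary:
    mean: float
    sigma0_corr: float
    thresholds: tuple[float, float, float]  # mean, mean+1σ, mean+2σ
    n_above_1sigma: int
    n_above_2sigma: int
    trimmed: bool = False
    n_assigned: int = 0

    def __post_init__(self) -> None:
        if self.sigma0_corr < 0:
            raise DomainError("sigma0_corr must be >= 0")
        t = self.thresholds
        if not (t[0] <= t[1] <= t[2]):
            raise DomainError("thresholds must ascend")


def compute_csp(
    free: PeakList, bound: PeakList, weight: float = DEFAULT_CSP_WEIGHT
) -> list[CSPResult]:
    """Per-residue weighted CSP between two assigned peak lists.

    Residues present in both lists get Δδ_H = δH_bound − δH_free (and the
    ¹⁵N analogue) and csp = sqrt(Δδ_H² + (weight·Δδ_N)²); residues present
    in only one list are reported with class "unassigned".  The relative
    CSP divides each value by the plain standard deviation of the set.
    """
    if weight <= 0:
        raise DomainError("weight must be > 0")
    shared = sorted(set(free.entries) & set(bound.entries))
    if not shared:
        raise EmptyResultError("no residues shared between the free and bound lists")
    results: list[CSPResult] = []
    csps = []
    for res in shared:
        dh = bound.entries[res][0] - free.entries[res][0]
        dn = bound.entries[res][1] - free.entries[res][1]
        csp = float(np.hypot(dh, weight * dn))
        csps.append(csp)
        results.append(CSPResult(residue=res, delta_h=dh, delta_n=dn, csp=csp, cls="below_mean"))
    sigma = float(np.std(csps, ddof=1)) if len(csps) > 1 else 0.0
    for r in results:
        r.relative_csp = r.csp / sigma if sigma > 0 else None
    only = sorted((set(free.entries) ^ set(bound.entries)))
    for res in only:
        results.append(CSPResult(residue=res, delta_h=None, delta_n=None, csp=None))
    results.sort(key=lambda r: r.residue)
    return results


def _trimmed_sigma(values: np.ndarray) -> tuple[float, float]:
    """Iteratively exclude values above mean + 3σ until stable; return (mean, σ)."""
    vals = np.asarray(values, float)
    while True:
        mean = float(vals.mean())
        sigma = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        keep = vals <= mean + 3.0 * sigma
        if keep.all():
            return mean, sigma
        vals = vals[keep]


def summarize_csp(results: list[CSPResult], trim: bool = False) -> CSPSummary:
    """Distribution statistics plus threshold classification of the CSP set.

    Classes use strict inequalities against mean, mean + 1·σ⁰_corr and
    mean + 2·σ⁰_corr; ``trim`` selects the iteratively 3σ-trimmed σ⁰_corr,
    otherwise the plain standard deviation of the whole set is used.  The
    mean used for the thresholds is the one paired with the chosen σ (the
    trimmed mean when trimming).
    """
    assigned = [r for r in results if r.csp is not None]
    if len(assigned) < 2:
        raise DomainError("need at least 2 assigned residues to summarize")
    values = np.array([r.csp for r in assigned])
    if trim:
        mean, sigma = _trimmed_sigma(values)
        if sigma == 0.0:
            warnings.warn("degenerate CSP distribution: all values identical after trimming")
    else:
        mean = float(values.mean())
        sigma = float(values.std(ddof=1))
    thresholds = (mean, mean + sigma, mean + 2.0 * sigma)
    n1 = n2 = 0
    for r in assigned:
        if r.csp > thresholds[2]:
            r.cls = "above_2sigma"
            n2 += 1
            n1 += 1
        elif r.csp > thresholds[1]:
            r.cls = "above_1sigma"
            n1 += 1
        elif r.csp > thresholds[0]:
            r.cls = "above_mean"
        else:
            r.cls = "below_mean"
    return CSPSummary(
        mean=mean,
        sigma0_corr=sigma,
        thresholds=thresholds,
        n_above_1sigma=n1,
        n_above_2sigma=n2,
        trimmed=trim,
        n_assigned=len(assigned),
    )


@dataclass
class TitrationRecord:
    residue: int
    csps: list[float]
    monotone_nondecreasing: bool


def csp_titration(
    series: list[PeakList],
    reference: PeakList,
    weight: float = DEFAULT_CSP_WEIGHT,
    eps: float = 1e-3,
) -> dict[int, TitrationRecord]:
    """Per-residue CSP trajectory along a titration, with a monotonicity flag.

    Fast-exchange binding shows resonances shifting gradually toward the
    bound position, so the CSP of a binding-site residue grows with ligand
    concentration.  A residue is flagged monotone when no step decreases by
    more than the noise tolerance ``eps`` (ppm).
    """
    if len(series) < 2:
        raise DomainError("a titration needs at least 2 points")
    residues = set(reference.entries)
    for pl in series:
        residues &= set(pl.entries)
    out: dict[int, TitrationRecord] = {}
    for res in sorted(residues):
        csps = []
        for pl in series:
            dh = pl.entries[res][0] - reference.entries[res][0]
            dn = pl.entries[res][1] - reference.entries[res][1]
            csps.append(float(np.hypot(dh, weight * dn)))
        monotone = all(b >= a - eps for a, b in zip(csps, csps[1:]))
        out[res] = TitrationRecord(residue=res, csps=csps, monotone_nondecreasing=monotone)
    return out


# ---------------------------------------------------------------------------
# STD epitope

@dataclass
class STDRecord:
    proton: str
    i0: float
    isat: float
    a_std: float
    relative_pct: float
    category: str  # pronounced | weak | absent

    def __post_init__(self) -> None:
        if self.i0 <= 0:
            raise DomainError("reference intensity I0 must be > 0")
        if not (0.0 <= self.relative_pct <= 100.0):
            raise DomainError("relative_pct must lie in [0, 100]")


def std_epitope(
    records: list[tuple[str, float, float]],
    pronounced_threshold: float = 50.0,
) -> list[STDRecord]:
    """Rank ligand protons by STD amplification, categorizing the epitope.

    A_STD = (I0 − Isat)/I0 per proton; relative percentages are scaled to
    the strongest signal.  Protons at or above ``pronounced_threshold`` %
    of the maximum are "pronounced" (the direct binding epitope), protons
    with A_STD <= 0 are "absent", the rest "weak".  Output is sorted by
    relative percentage, descending (ties by proton label).
    """
    if not records:
        return []
    astds = []
    for proton, i0, isat in records:
        if i0 <= 0:
            raise DomainError(f"proton {proton}: I0 must be > 0")
        astds.append((proton, i0, isat, (i0 - isat) / i0))
    max_a = max(a for *_, a in astds)
    if max_a <= 0:
        warnings.warn("no positive STD amplification: all protons categorized absent")
    out = []
    for proton, i0, isat, a in astds:
        rel = 100.0 * a / max_a if max_a > 0 else 0.0
        rel = float(np.clip(rel, 0.0, 100.0))
        if a <= 0:
            cat = "absent"
        elif rel >= pronounced_threshold:
            cat = "pronounced"
        else:
            cat = "weak"
        out.append(
            STDRecord(proton=proton, i0=i0, isat=isat, a_std=a, relative_pct=rel, category=cat)
        )
    out.sort(key=lambda r: (-r.relative_pct, r.proton))
    return out


def read_std_tsv(path_or_buf) -> list[tuple[str, float, float]]:
    df = pd.read_csv(path_or_buf, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    p, i0, isat = cols.get("proton"), cols.get("i0"), cols.get("isat")
    if not (p and i0 and isat):
        raise DomainError("STD TSV needs columns proton, I0, Isat")
    return [(str(a), float(b), float(c)) for a, b, c in zip(df[p], df[i0], df[isat])]


def csp_table(results: list[CSPResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "residue": r.residue,
                "dDeltaH_ppm": r.delta_h,
                "dDeltaN_ppm": r.delta_n,
                "csp_ppm": r.csp,
                "relative_csp": r.relative_csp,
                "class": r.cls,
            }
            for r in results
        ]
    )
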