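"""Fluorescence-polarization assay arithmetic: mP, Z' and displacement.

A small fluorophore-labelled oligonucleotide tumbles fast when free (low
polarization) and slowly when protein-bound (high polarization), so
displacement of the oligo by a competing ligand lowers the measured
millipolarization.  The Z' factor, 1 − 3(σ_p + σ_n)/|μ_p − μ_n|, scores
how well the free-oligo (positive) and bound (negative) control
distributions separate; Z' > 0.5 marks an excellent screening window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dbdscreen.errors import DomainError

ROLES = ("positive_ctrl", "negative_ctrl", "sample")


@dataclass
class Well:
    """One plate well: either raw intensities (I_par, I_perp) or a direct mP value."""

    plate_pos: str
    role: str
    dose: float | None = None  # µM, samples only
    i_par: float | None = None
    i_perp: float | None = None
    mp: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DomainError(f"unknown well role {self.role!r}")
        has_pair = self.i_par is not None and self.i_perp is not None
        if has_pair == (self.mp is not None):
            raise DomainError("provide exactly one of (I_par, I_perp) or mP")
        if has_pair and (self.i_par <= 0 or self.i_perp < 0):
            raise DomainError("intensities must be positive")

    def millipolarization(self, g: float = 1.0) -> float:
        if self.mp is not None:
            return self.mp
        return mp_from_intensities(self.i_par, self.i_perp, g)


@dataclass
class PlateSummary:
    mu_p: float
    sigma_p: float
    mu_n: float
    sigma_n: float
    zprime: float

    def __post_init__(self) -> None:
        if self.zprime > 1:
            raise DomainError("Z' cannot exceed 1")


def mp_from_intensities(i_par: float, i_perp: float, g: float = 1.0) -> float:
    """Millipolarization: 1000·(I∥ − G·I⊥)/(I∥ + G·I⊥)."""
    if g <= 0:
        raise DomainError("grating factor G must be > 0")
    denom = i_par + g * i_perp
    if denom <= 0:
        raise DomainError("I_par + G*I_perp must be > 0")
    return 1000.0 * (i_par - g * i_perp) / denom


def zprime(pos_mp, neg_mp) -> PlateSummary:
    """Z' factor from positive- and negative-control mP values (sample SD, n−1)."""
    pos = np.asarray(pos_mp, float)
    neg = np.asarray(neg_mp, float)
    if len(pos) < 2 or len(neg) < 2:
        raise DomainError("need at least 2 wells per control group")
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    if mu_p == mu_n:
        raise DomainError("control means are identical; Z' undefined")
    sigma_p = float(pos.std(ddof=1))
    sigma_n = float(neg.std(ddof=1))
    z = 1.0 - 3.0 * (sigma_p + sigma_n) / abs(mu_p - mu_n)
    return PlateSummary(mu_p=mu_p, sigma_p=sigma_p, mu_n=mu_n, sigma_n=sigma_n, zprime=z)


def displacement(sample_mp: float, mu_bound: float, mu_free: float) -> tuple[float, bool]:
    """Percent displacement of the labelled oligo; flags out-of-range values.

    100·(μ_bound − mP)/(μ_bound − μ_free): 0% at the bound control, 100% at
    the free control.  The value is reported as computed; the second return
    flags results outside [−10, 110] (pipetting or compound-fluorescence
    artefacts).
    """
    if mu_bound == mu_free:
        raise DomainError("degenerate controls: bound and free means coincide")
    pct = 100.0 * (mu_bound - sample_mp) / (mu_bound - mu_free)
    return pct, not (-10.0 <= pct <= 110.0)


def read_plate_tsv(path_or_buf) -> list[Well]:
    """Read the plate dialect: well, role, dose_uM, then I_par/I_perp or mP columns."""
    df = pd.read_csv(path_or_buf, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    wells = []
    for row in df.itertuples(index=False):
        rec = {c.lower(): v for c, v in zip(df.columns, row)}

        def num(key):
            v = rec.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

        wells.append(
            Well(
                plate_pos=str(rec["well"]),
                role=str(rec["role"]),
                dose=num("dose_um"),
                i_par=num("i_par"),
                i_perp=num("i_perp"),
                mp=num("mp"),
            )
        )
    return wells


def summarize_plate(wells: list[Well], g: float = 1.0) -> PlateSummary:
    pos = [w.millipolarization(g) for w in wells if w.role == "positive_ctrl"]
    neg = [w.millipolarization(g) for w in wells if w.role == "negative_ctrl"]
    return zprime(pos, neg)
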