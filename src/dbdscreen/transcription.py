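"""Reversal classification of differential-expression contrasts.

Two contrasts are compared: contrast A (transcription-factor activation vs
control) defines the induced and repressed probeset universes; contrast B
(activation + inhibitor vs activation alone) asks whether the inhibitor
reverses the induction.  Among the probesets induced in A, those moving
down in B are counted as reversed — significantly when B's adjusted p
clears alpha, otherwise as a non-significant trend — and the report
carries the two headline percentages plus the Venn partition of the two
up-regulated sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from dbdscreen.errors import DomainError, EmptyResultError


@dataclass
class DEContrast:
    """A named differential-expression contrast: probeset -> (log2fc, padj)."""

    name: str
    rows: pd.DataFrame  # columns: probeset, log2fc, padj

    def __post_init__(self) -> None:
        required = {"probeset", "log2fc", "padj"}
        if not required <= set(self.rows.columns):
            raise DomainError(f"contrast needs columns {sorted(required)}")
        if self.rows["probeset"].duplicated().any():
            raise DomainError(f"contrast {self.name}: duplicate probeset ids")
        bad = ~self.rows["padj"].between(0.0, 1.0)
        if bad.any():
            raise DomainError(f"contrast {self.name}: padj outside [0, 1]")

    @classmethod
    def read_tsv(cls, path_or_buf, name: str = "") -> "DEContrast":
        df = pd.read_csv(path_or_buf, sep="\t", comment="#")
        df.columns = [c.lower() for c in df.columns]
        return cls(name=name or "contrast", rows=df[["probeset", "log2fc", "padj"]])

    def write_tsv(self, path_or_buf) -> None:
        self.rows.to_csv(path_or_buf, sep="\t", index=False, float_format="%.6g")


@dataclass
class ReversalReport:
    n_induced: int
    n_repressed: int
    n_reversed_sig: int
    n_reversed_ns: int
    pct_overall: int | None
    pct_sig: int | None
    venn: tuple[int, int, int]  # (onlyA, onlyB, common) of the up-regulated sets

    def __post_init__(self) -> None:
        if self.n_reversed_sig + self.n_reversed_ns > self.n_induced:
            raise DomainError("reversed counts exceed the induced universe")
        for pct in (self.pct_overall, self.pct_sig):
            if pct is not None and not (0 <= pct <= 100):
                raise DomainError("percentages must lie in [0, 100]")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def reversal_percentages(
    n_induced: int, n_reversed_sig: int, n_reversed_ns: int
) -> tuple[int | None, int | None]:
    """The two headline percentages from raw category counts.

    pct_overall = round(100·(sig + ns)/induced); pct_sig = round(100·sig/induced);
    both None when nothing was induced (undefined, not 0).
    """
    if n_induced == 0:
        return None, None
    return (
        round_half_away(100.0 * (n_reversed_sig + n_reversed_ns) / n_induced),
        round_half_away(100.0 * n_reversed_sig / n_induced),
    )


def classify_reversal(
    contrast_a: DEContrast,
    contrast_b: DEContrast,
    alpha: float = 0.05,
    lfc_min: float = 0.0,
) -> ReversalReport:
    """Classify probesets by induction in A and reversal in B.

    induced: A.padj < alpha and A.log2fc >= lfc_min (> when lfc_min is 0,
    so an exactly unchanged probeset never counts); repressed analogously
    downward.  Among induced probesets: reversed_sig requires B.padj <
    alpha and B.log2fc < 0; reversed_ns requires B.log2fc < 0 without
    significance.  Evaluated on the shared probeset universe.
    """
    if not (0.0 < alpha < 1.0):
        raise DomainError("alpha must lie in (0, 1)")
    a = contrast_a.rows.set_index("probeset")
    b = contrast_b.rows.set_index("probeset")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise EmptyResultError("contrasts share no probesets")
    a, b = a.loc[shared], b.loc[shared]

    up_gate = a["log2fc"] > lfc_min if lfc_min == 0 else a["log2fc"] >= lfc_min
    down_gate = a["log2fc"] < -lfc_min if lfc_min == 0 else a["log2fc"] <= -lfc_min
    induced = (a["padj"] < alpha) & up_gate
    repressed = (a["padj"] < alpha) & down_gate

    b_down = b["log2fc"] < 0
    b_sig = b["padj"] < alpha
    reversed_sig = induced & b_down & b_sig
    reversed_ns = induced & b_down & ~b_sig

    up_b_gate = b["log2fc"] > lfc_min if lfc_min == 0 else b["log2fc"] >= lfc_min
    up_a = set(shared[induced])
    up_b = set(shared[b_sig & up_b_gate])
    venn = venn_up(up_a, up_b)

    n_induced = int(induced.sum())
    pct_overall, pct_sig = reversal_percentages(
        n_induced, int(reversed_sig.sum()), int(reversed_ns.sum())
    )
    return ReversalReport(
        n_induced=n_induced,
        n_repressed=int(repressed.sum()),
        n_reversed_sig=int(reversed_sig.sum()),
        n_reversed_ns=int(reversed_ns.sum()),
        pct_overall=pct_overall,
        pct_sig=pct_sig,
        venn=venn,
    )


def venn_up(set_a: set, set_b: set) -> tuple[int, int, int]:
    """Partition counts (onlyA, onlyB, common) of two probeset sets."""
    common = set_a & set_b
    return (len(set_a) - len(common), len(set_b) - len(common), len(common))


def report_text(r: ReversalReport) -> str:
    lines = [
        f"induced (contrast A):          {r.n_induced}",
        f"repressed (contrast A):        {r.n_repressed}",
        f"reversed, significant (B):     {r.n_reversed_sig}",
        f"reversed, not significant (B): {r.n_reversed_ns}",
        f"reversal overall:              "
        + (f"{r.pct_overall}%" if r.pct_overall is not None else "undefined"),
        f"reversal significant:          "
        + (f"{r.pct_sig}%" if r.pct_sig is not None else "undefined"),
        f"venn up-regulated (onlyA, onlyB, common): {r.venn}",
    ]
    return "\n".join(lines)
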