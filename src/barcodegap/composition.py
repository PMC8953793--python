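"""Nucleotide composition and site-class counts by codon position.

Columns of the alignment are classified as conserved (one state across all
records) or variable; variable columns are parsimony-informative (at least
two states each present in at least two records) or singleton sites. Counts
and pooled base frequencies are reported for each codon position and for
the whole alignment.

Codon position 1 is anchored by the reading frame returned by
translate_check on the first record; for the standard 658 bp COI-5'
barcode (frame 2) this yields the familiar 219/219/220 split of sites
across positions 1/2/3.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .qc import translate_check
from .records import Dataset

POSITION_LABELS = ("1st", "2nd", "3rd", "all")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed composition
    tables), unlike Python's banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CompositionRow:
    position: str
    base_count: int
    conserved: int
    variable: int
    parsimony_informative: int
    singleton: int
    pct_T: float
    pct_C: float
    pct_A: float
    pct_G: float

    @property
    def pct_AT(self) -> float:
        # printed-table convention: AT/CG are sums of the rounded components
        return round_half_up(self.pct_A + self.pct_T, 1)

    @property
    def pct_CG(self) -> float:
        return round_half_up(self.pct_C + self.pct_G, 1)


@dataclass
class CompositionTable:
    rows: dict[str, CompositionRow]

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for label in POSITION_LABELS:
            r = self.rows[label]
            recs.append(
                {
                    "position": label,
                    "base_count": r.base_count,
                    "conserved": r.conserved,
                    "variable": r.variable,
                    "parsimony_informative": r.parsimony_informative,
                    "singleton": r.singleton,
                    "pct_T": r.pct_T,
                    "pct_C": r.pct_C,
                    "pct_A": r.pct_A,
                    "pct_G": r.pct_G,
                    "pct_AT": r.pct_AT,
                    "pct_CG": r.pct_CG,
                }
            )
        return pd.DataFrame(recs)

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def infer_frame(ds: Dataset) -> int:
    """Reading frame shared by the amplicon, from the first record."""
    if not ds.records:
        raise ValueError("empty dataset")
    passes, frame = translate_check(ds.records[0].sequence)
    if not passes:
        raise ValueError("first record has stop codons in every frame")
    return frame


def _matrix(ds: Dataset) -> np.ndarray:
    if len(ds.records) < 2:
        raise ValueError("site classification needs at least 2 records")
    arr = np.array([list(r.sequence) for r in ds.records])
    if len({len(r.sequence) for r in ds.records}) != 1:
        raise ValueError("records are not aligned to a single length")
    return arr

def _codon_positions(length: int, frame: int) -> np.ndarray:
    """1-based codon position of each 0-based column for a 1-based frame."""
    cols = np.arange(length)
    return ((cols - (frame - 1)) % 3) + 1


def _site_classes(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column flags: (variable, parsimony_informative)."""
    n_cols = arr.shape[1]
    variable = np.zeros(n_cols, dtype=bool)
    informative = np.zeros(n_cols, dtype=bool)
    for j in range(n_cols):
        _, counts = np.unique(arr[:, j], return_counts=True)
        variable[j] = counts.size > 1
        informative[j] = (counts >= 2).sum() >= 2
    return variable, informative


def compute_composition(ds: Dataset, frame: int | None = None) -> CompositionTable:
    """Site classes plus pooled base frequencies per codon position.

    Percentages are rounded half-up to 1 decimal; frequencies are pooled
    over all records and all columns of each position class.
    """
    arr = _matrix(ds)
    if frame is None:
        frame = infer_frame(ds)
    positions = _codon_positions(arr.shape[1], frame)
    variable, informative = _site_classes(arr)

    rows: dict[str, CompositionRow] = {}
    for label, mask in (
        ("1st", positions == 1),
        ("2nd", positions == 2),
        ("3rd", positions == 3),
        ("all", np.ones_like(positions, dtype=bool)),
    ):
        var = variable[mask]
        inf = informative[mask]
        sub = arr[:, mask]
        total = sub.size
        pct = {
            base: round_half_up(100.0 * (sub == base).sum() / total, 1)
            for base in "TCAG"
        }
        rows[label] = CompositionRow(
            position=label,
            base_count=int(mask.sum()),
            conserved=int((~var).sum()),
            variable=int(var.sum()),
            parsimony_informative=int(inf.sum()),
            singleton=int((var & ~inf).sum()),
            pct_T=pct["T"],
            pct_C=pct["C"],
            pct_A=pct["A"],
            pct_G=pct["G"],
        )
    return CompositionTable(rows=rows)


def classify_sites(ds: Dataset, frame: int | None = None) -> CompositionTable:
    """Site-class counts (conserved/variable/PI/singleton) by codon position."""
    return compute_composition(ds, frame=frame)


def base_composition(ds: Dataset, frame: int | None = None) -> CompositionTable:
    """Pooled nucleotide frequencies by codon position."""
    return compute_composition(ds, frame=frame)
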