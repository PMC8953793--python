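"""Kimura two-parameter (K2P) distances and barcode-gap summaries.

The K2P model corrects observed divergence separately for transitions
(A<->G, C<->T) and transversions:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with P and Q the proportions of sites differing by a transition and a
transversion. The estimate is undefined (saturated) when either logarithm's
argument is non-positive; such pairs are recorded and excluded from
summaries with a warning rather than aborting the run.

Distances are stored as proportions; reports render percent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import Dataset

_NT = {"A": 0, "G": 1, "C": 2, "T": 3}  # purines 0/1, pyrimidines 2/3


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_NT[c] for c in seq), dtype=np.uint8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-ACGT letter {exc.args[0]!r} in sequence") from None


def _k2p_from_counts(p: float, q: float) -> float:
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_distance(a: str, b: str) -> float:
    """K2P distance between two equal-length A/C/G/T sequences.

    Returns NaN when the formula is undefined (saturation).
    """
    if len(a) != len(b):
        raise ValueError(f"unequal sequence lengths: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("empty sequences")
    xa, xb = _encode(a), _encode(b)
    diff = xa != xb
    transitions = diff & ((xa >> 1) == (xb >> 1))  # same purine/pyrimidine class
    p = float(transitions.sum()) / len(a)
    q = float(diff.sum() - transitions.sum()) / len(a)
    return _k2p_from_counts(p, q)


def p_distance(a: str, b: str) -> float:
    """Raw mismatch proportion; internal oracle helper, not a reported model."""
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("sequences must be equal-length and non-empty")
    return sum(x != y for x, y in zip(a, b)) / len(a)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distances over an ordered set of records.

    Saturated (undefined) entries are NaN and their id pairs are listed in
    ``undefined_pairs``.
    """

    ids: list[str]
    values: np.ndarray
    undefined_pairs: set[tuple[str, str]]

    def __post_init__(self) -> None:
        self._index = {rid: i for i, rid in enumerate(self.ids)}

    def loc(self, id1: str, id2: str) -> float:
        return float(self.values[self._index[id1], self._index[id2]])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def pairwise_matrix(ds: Dataset) -> DistanceMatrix:
    """All-pairs K2P distance matrix for a post-QC dataset."""
    ids = [r.record_id for r in ds.records]
    n = len(ids)
    enc = np.stack([_encode(r.sequence) for r in ds.records]) if n else np.empty((0, 0))
    length = enc.shape[1] if n else 0
    values = np.zeros((n, n))
    undefined: set[tuple[str, str]] = set()
    cls = enc >> 1  # 0 = purine, 1 = pyrimidine
    for i in range(n):
        diff = enc[i] != enc[i + 1 :]
        ts = (diff & (cls[i] == cls[i + 1 :])).sum(axis=1)
        total = diff.sum(axis=1)
        p = ts / length
        q = (total - ts) / length
        with np.errstate(invalid="ignore", divide="ignore"):
            d = -0.5 * np.log(1 - 2 * p - q) - 0.25 * np.log(1 - 2 * q)
        bad = ((1 - 2 * p - q) <= 0) | ((1 - 2 * q) <= 0)
        d[bad] = np.nan
        values[i, i + 1 :] = d
        values[i + 1 :, i] = d
        for j in np.nonzero(bad)[0]:
            undefined.add((ids[i], ids[i + 1 + int(j)]))
    if undefined:
        warnings.warn(
            f"{len(undefined)} saturated pair(s) with undefined K2P distance "
            "excluded from summaries",
            stacklevel=2,
        )
    return DistanceMatrix(ids=ids, values=values, undefined_pairs=undefined)


@dataclass
class SpeciesGapSummary:
    """Per-species barcode-gap summary.

    ``has_gap`` is True when the maximum intraspecific distance is strictly
    smaller than the minimum interspecific distance; it is None when
    max_intra is undefined (all conspecific pairs saturated).
    """

    species: str
    n_records: int
    max_intra: float | None
    min_inter: float | None
    has_gap: bool | None


@dataclass
class DatasetDistanceSummary:
    """Whole-dataset intra/inter distance ranges and pair-level means."""

    intra_min: float
    intra_max: float
    intra_mean: float
    inter_min: float
    inter_max: float
    inter_mean: float
    n_intra_pairs: int
    n_inter_pairs: int

    @property
    def overlap_interval(self) -> tuple[float, float] | None:
        if self.inter_min < self.intra_max:
            return (self.inter_min, self.intra_max)
        return None


def _pair_class_masks(ds: Dataset) -> tuple[np.ndarray, np.ndarray]:
    species = np.array([r.species for r in ds.records])
    same = species[:, None] == species[None, :]
    upper = np.triu(np.ones_like(same, dtype=bool), k=1)
    return same & upper, (~same) & upper


def intra_inter_vectors(
    dm: DistanceMatrix, ds: Dataset
) -> tuple[np.ndarray, np.ndarray]:
    """Defined intra- and interspecific distances as flat vectors."""
    intra_mask, inter_mask = _pair_class_masks(ds)
    intra = dm.values[intra_mask]
    inter = dm.values[inter_mask]
    return intra[~np.isnan(intra)], inter[~np.isnan(inter)]


def species_summaries(
    dm: DistanceMatrix, ds: Dataset, scope: str = "dataset"
) -> list[SpeciesGapSummary]:
    """Max intra-GD, min inter-GD and the gap flag for every species.

    With ``scope="genus"`` the minimum interspecific distance is taken over
    congeners only, and species in monotypic genera (no congeneric records
    from another species) are excluded.
    """
    if scope not in ("dataset", "genus"):
        raise ValueError(f"unknown scope {scope!r}")
    species = np.array([r.species for r in ds.records])
    genus = np.array([r.genus for r in ds.records])
    out: list[SpeciesGapSummary] = []
    for sp in ds.species_names:
        members = species == sp
        n = int(members.sum())
        if n < 2:
            continue
        sub = dm.values[np.ix_(members, members)]
        iu = np.triu_indices(n, k=1)
        intra = sub[iu]
        intra = intra[~np.isnan(intra)]
        max_intra = float(intra.max()) if intra.size else None
        if max_intra is None:
            warnings.warn(
                f"species {sp!r}: all conspecific pairs saturated; "
                "excluded from gap counting",
                stacklevel=2,
            )
        others = ~members
        if scope == "genus":
            g = genus[members][0]
            others = others & (genus == g)
        if not others.any():
            continue  # monotypic genus under scope="genus"
        cross = dm.values[np.ix_(members, others)].ravel()
        cross = cross[~np.isnan(cross)]
        min_inter = float(cross.min()) if cross.size else None
        has_gap = (
            (max_intra < min_inter)
            if (max_intra is not None and min_inter is not None)
            else None
        )
        out.append(SpeciesGapSummary(sp, n, max_intra, min_inter, has_gap))
    return out


def summaries_to_dataframe(summaries: list[SpeciesGapSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": s.species,
                "n": s.n_records,
                "max_intra_pct": None if s.max_intra is None else round(s.max_intra * 100, 2),
                "min_inter_pct": None if s.min_inter is None else round(s.min_inter * 100, 2),
                "has_gap": s.has_gap,
            }
            for s in summaries
        ],
        columns=["species", "n", "max_intra_pct", "min_inter_pct", "has_gap"],
    )


def dataset_summary(dm: DistanceMatrix, ds: Dataset) -> DatasetDistanceSummary:
    """Overall min/max/mean of intra- and interspecific distances.

    Means are arithmetic means over all defined pairs of each class
    (pair-level, not per-species averages).
    """
    intra, inter = intra_inter_vectors(dm, ds)
    if intra.size == 0:
        raise ValueError("no intraspecific pairs (all species are singletons)")
    if inter.size == 0:
        raise ValueError("no interspecific pairs (single species)")
    return DatasetDistanceSummary(
        intra_min=float(intra.min()),
        intra_max=float(intra.max()),
        intra_mean=float(intra.mean()),
        inter_min=float(inter.min()),
        inter_max=float(inter.max()),
        inter_mean=float(inter.mean()),
        n_intra_pairs=int(intra.size),
        n_inter_pairs=int(inter.size),
    )


def long_format(dm: DistanceMatrix, ds: Dataset) -> pd.DataFrame:
    """Long-format pair table: id1, id2, distance, class in {intra, inter}."""
    species = {r.record_id: r.species for r in ds.records}
    rows = []
    for i, id1 in enumerate(dm.ids):
        for j in range(i + 1, len(dm.ids)):
            id2 = dm.ids[j]
            d = dm.values[i, j]
            rows.append(
                {
                    "id1": id1,
                    "id2": id2,
                    "distance": None if np.isnan(d) else float(d),
                    "class": "intra" if species[id1] == species[id2] else "inter",
                }
            )
    return pd.DataFrame(rows, columns=["id1", "id2", "distance", "class"])
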