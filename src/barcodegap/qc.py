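"""Quality-control filtering of barcode datasets.

The filter chain mirrors standard practice for curating COI-5' reference
barcodes: drop records not identified to species level, enforce the full
658 bp barcode length, reject degenerate bases, collapse exact duplicates
within a species, reject sequences whose translation contains a stop codon
in every forward frame, and finally drop species left with a single record
(intraspecific distances are inaccessible for singletons).

Stages run in a fixed order. Length and alphabet checks precede translation
(translation needs a clean sequence); duplicate collapse precedes singleton
removal (collapsing can create new singletons, which must then go).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .records import BarcodeRecord, Dataset

# invertebrate mitochondrial genetic code (NCBI translation table 5)
INVERT_MITO_TABLE = 5

#: frames tried in order; frame 2 is the canonical reading frame of the
#: 658 bp COI-5' amplicon (the first base is the 3rd position of the
#: preceding codon), so it is tested first.
FRAME_ORDER = (2, 1, 3)


@dataclass
class QCRemoval:
    record_id: str
    stage: str
    reason: str


@dataclass
class QCReport:
    """Every record removed by qc_filter, with the stage and reason."""

    removals: list[QCRemoval] = field(default_factory=list)

    def add(self, record_id: str, stage: str, reason: str) -> None:
        self.removals.append(QCRemoval(record_id, stage, reason))

    def __len__(self) -> int:
        return len(self.removals)

    @property
    def removed_ids(self) -> list[str]:
        return [r.record_id for r in self.removals]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"record_id": r.record_id, "stage": r.stage, "reason": r.reason}
                for r in self.removals
            ],
            columns=["record_id", "stage", "reason"],
        )

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def translate_check(
    sequence: str, genetic_code: int = INVERT_MITO_TABLE
) -> tuple[bool, int | None]:
    """Check a barcode for stop codons in the three forward frames.

    Translates under the invertebrate mitochondrial code, ignoring any
    trailing partial codon. Passes if at least one frame is stop-free;
    the reported frame is the first passing one in the order 2, 1, 3.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("translate_check requires an A/C/G/T sequence")
    for frame in FRAME_ORDER:
        sub = seq[frame - 1 :]
        sub = sub[: len(sub) - len(sub) % 3]
        protein = str(Seq(sub).translate(table=genetic_code))
        if "*" not in protein:
            return True, frame
    return False, None


_SP_LABEL = re.compile(r"^\S+(\s+sp\.?)?$")  # bare genus or "Genus sp."


def _unidentified(species: str) -> bool:
    """True for labels lacking a species epithet ('Gymnopholus sp.', bare genus)."""
    return bool(_SP_LABEL.match(species.strip()))


def qc_filter(
    ds: Dataset,
    min_len: int = 658,
    genetic_code: int = INVERT_MITO_TABLE,
    keep_morphospecies: bool = False,
    translation_check: bool = True,
) -> tuple[Dataset, QCReport]:
    """Apply the QC filter chain; return the clean dataset and a report.

    Stages, in order:

    1. ``unidentified`` — species label lacks an epithet or is "Genus sp.".
       Applies only to ``source="public"`` records: morphologically
       vouchered in-house material keeps its morphospecies labels.
       ``keep_morphospecies=True`` disables the stage entirely.
    2. ``short`` — sequence shorter than ``min_len``; longer sequences are
       truncated from the 3' end to ``min_len`` (the 5' barcode anchor is
       preserved), not removed.
    3. ``degenerate`` — any letter outside A/C/G/T (N, IUPAC ambiguity
       codes, X, gaps ...).
    4. ``duplicate`` — within each species, exact duplicate sequences are
       collapsed to the first record in input order.
    5. ``stop_codon`` — no forward frame is stop-free (see translate_check);
       skipped when ``translation_check=False``.
    6. ``singleton_species`` — species left with fewer than two records.

    Every input record ends up either in the returned dataset or in the
    QCReport, never both; running the filter on its own output yields the
    same dataset and an empty report.
    """
    report = QCReport()
    current: list[BarcodeRecord] = list(ds.records)

    def remove(rec: BarcodeRecord, stage: str, reason: str) -> BarcodeRecord:
        report.add(rec.record_id, stage, reason)
        return rec.copy(qc_status="removed", qc_reason=reason)

    # 1. unidentified-to-species-level (public records only)
    kept: list[BarcodeRecord] = []
    for rec in current:
        if (
            not keep_morphospecies
            and rec.source == "public"
            and _unidentified(rec.species)
        ):
            remove(rec, "1-species-level", "unidentified")
        else:
            kept.append(rec)
    current = kept

    # 2. length: remove short, truncate long
    kept = []
    for rec in current:
        if len(rec.sequence) < min_len:
            remove(rec, "2-length", "short")
        elif len(rec.sequence) > min_len:
            kept.append(rec.copy(sequence=rec.sequence[:min_len]))
        else:
            kept.append(rec)
    current = kept

    # 3. degenerate bases
    kept = []
    for rec in current:
        if set(rec.sequence) - set("ACGT"):
            remove(rec, "3-degenerate", "degenerate")
        else:
            kept.append(rec)
    current = kept

    # 4. duplicate collapse within species (keep first by input order)
    seen: dict[tuple[str, str], str] = {}
    kept = []
    for rec in current:
        key = (rec.species, rec.sequence)
        if key in seen:
            remove(rec, "4-duplicate", f"duplicate of {seen[key]}")
        else:
            seen[key] = rec.record_id
            kept.append(rec)
    current = kept

    # 5. stop-codon translation check
    if translation_check:
        kept = []
        for rec in current:
            passes, _ = translate_check(rec.sequence, genetic_code)
            if passes:
                kept.append(rec)
            else:
                remove(rec, "5-translation", "stop_codon")
        current = kept

    # 6. singleton species
    counts: dict[str, int] = {}
    for rec in current:
        counts[rec.species] = counts.get(rec.species, 0) + 1
    kept = []
    for rec in current:
        if counts[rec.species] < 2:
            remove(rec, "6-singleton", "singleton_species")
        else:
            kept.append(rec)
    current = kept

    if not current:
        raise ValueError("no analyzable species remain after QC")

    out = Dataset(records=current, alignment_length=min_len, label=ds.label)
    out.validate()
    return out, report


def apply_synonyms(ds: Dataset, mapping: dict[str, str]) -> Dataset:
    """Rewrite species labels via a synonym table (old name -> valid name).

    The genus is recomputed from the new label; records are otherwise
    unchanged. Malformed replacement names (not "Genus epithet") raise.
    """
    for old, new in mapping.items():
        if len(new.split()) != 2:
            raise ValueError(
                f"synonym target {new!r} (for {old!r}) is not 'Genus epithet'"
            )
    records = [
        rec.copy(species=mapping[rec.species]) if rec.species in mapping else rec
        for rec in ds.records
    ]
    return Dataset(records=records, alignment_length=ds.alignment_length, label=ds.label)
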