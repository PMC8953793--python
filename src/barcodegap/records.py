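"""Core domain containers: a single barcode record and an aligned dataset.

A record carries its taxon labels and QC provenance; a dataset is an ordered
collection of records sharing one alignment length (the standard COI-5'
barcode is 658 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

SOURCES = ("public", "generated", "synthetic")


@dataclass
class BarcodeRecord:
    """One barcode sequence with taxon labels and QC provenance.

    ``species`` is a binomial label ("Genus epithet"); the genus is always
    the first whitespace token of the species label. ``qc_status`` is "pass"
    until a QC stage removes the record, in which case ``qc_reason`` names
    the rule that fired.
    """

    record_id: str
    species: str
    sequence: str
    source: str = "public"
    qc_status: str = "pass"
    qc_reason: str | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(
                f"record {self.record_id!r}: unknown source {self.source!r}"
            )
        self.sequence = self.sequence.upper()

    @property
    def genus(self) -> str:
        return self.species.split()[0]

    def copy(self, **changes) -> "BarcodeRecord":
        return replace(self, **changes)


@dataclass
class Dataset:
    """An ordered collection of aligned barcode records.

    ``alignment_length`` is the shared post-QC sequence length; before QC it
    is informational only (raw records may differ in length).
    """

    records: list[BarcodeRecord] = field(default_factory=list)
    alignment_length: int | None = None
    label: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def species_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.species, None)
        return list(seen)

    @property
    def genera(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.genus, None)
        return list(seen)

    def by_species(self) -> dict[str, list[BarcodeRecord]]:
        out: dict[str, list[BarcodeRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.species, []).append(rec)
        return out

    def validate(self, require_min_two: bool = True) -> None:
        """Assert the post-QC invariants: equal lengths, ACGT alphabet,
        and (optionally) at least two records per species."""
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.alignment_length is not None and lengths and (
            lengths != {self.alignment_length}
        ):
            raise ValueError(
                f"sequence length {lengths} != alignment_length "
                f"{self.alignment_length}"
            )
        for rec in self.records:
            if set(rec.sequence) - set("ACGT"):
                raise ValueError(
                    f"record {rec.record_id!r} contains non-ACGT letters"
                )
        if require_min_two:
            for sp, recs in self.by_species().items():
                if len(recs) < 2:
                    raise ValueError(f"species {sp!r} has fewer than 2 records")
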