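"""Reading and writing barcode datasets.

Input is FASTA (wrapped or single-line). Species labels come either from a
pipe-delimited header convention (``>id|Genus species``) or from a TSV
sidecar with columns ``record_id`` and ``species`` (optional ``genus``,
``source``); sidecar entries override header labels.
"""

from __future__ import annotations

import os

import pandas as pd
from Bio import SeqIO

from .records import BarcodeRecord, Dataset


def _read_sidecar(path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"record_id", "species"}
    if not required.issubset(meta.columns):
        raise ValueError(
            f"metadata sidecar must have columns {sorted(required)}; "
            f"found {list(meta.columns)}"
        )
    if meta["record_id"].duplicated().any():
        dups = meta.loc[meta["record_id"].duplicated(), "record_id"].tolist()
        raise ValueError(f"duplicate record_id in metadata: {dups}")
    return meta.set_index("record_id")


def read_dataset(
    fasta_path: str | os.PathLike,
    metadata: str | os.PathLike | None = None,
    label: str = "",
    default_source: str = "public",
) -> Dataset:
    """Parse a FASTA file (plus optional TSV sidecar) into a raw Dataset.

    Records keep their input order and sequences are upper-cased; no QC is
    applied. A record whose species cannot be resolved from either source
    raises an error naming the record, as does a duplicated record id.
    """
    meta = _read_sidecar(metadata) if metadata is not None else None

    records: list[BarcodeRecord] = []
    seen_ids: set[str] = set()
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        header = seq_rec.description
        parts = header.split("|")
        record_id = parts[0].strip()
        if record_id in seen_ids:
            raise ValueError(f"duplicate record_id {record_id!r} in FASTA")
        seen_ids.add(record_id)

        species = parts[1].strip() if len(parts) > 1 and parts[1].strip() else None
        source = default_source
        if meta is not None and record_id in meta.index:
            row = meta.loc[record_id]
            if isinstance(row.get("species"), str) and row["species"].strip():
                species = row["species"].strip()
            if "source" in meta.columns and isinstance(row.get("source"), str):
                source = row["source"].strip()
        if not species:
            raise ValueError(
                f"record {record_id!r} has no species label in header or sidecar"
            )
        records.append(
            BarcodeRecord(
                record_id=record_id,
                species=species,
                sequence=str(seq_rec.seq).upper(),
                source=source,
            )
        )
    lengths = {len(r.sequence) for r in records}
    aln_len = lengths.pop() if len(lengths) == 1 else None
    return Dataset(records=records, alignment_length=aln_len, label=label)


def write_fasta(ds: Dataset, path: str | os.PathLike) -> None:
    """Write passing records as single-line FASTA with ``id|species`` headers."""
    with open(path, "w") as fh:
        for rec in ds.records:
            if rec.qc_status != "pass":
                continue
            fh.write(f">{rec.record_id}|{rec.species}\n{rec.sequence}\n")


def write_sidecar(ds: Dataset, path: str | os.PathLike) -> None:
    rows = [
        {
            "record_id": r.record_id,
            "species": r.species,
            "genus": r.genus,
            "source": r.source,
        }
        for r in ds.records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
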