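"""End-to-end pipeline: QC -> distances -> gap/threshold -> composition.

run_pipeline chains every analysis stage over one input dataset and writes a
report bundle (TSV tables plus a JSON threshold report and a run manifest).
All stages are deterministic given the inputs and parameters.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np

from . import __version__
from .composition import compute_composition
from .distance import (
    dataset_summary,
    intra_inter_vectors,
    long_format,
    pairwise_matrix,
    species_summaries,
    summaries_to_dataframe,
)
from .io import read_dataset, write_fasta
from .qc import apply_synonyms, qc_filter
from .records import Dataset
from .threshold import (
    BIN_THRESHOLD,
    candidate_thresholds,
    distance_histogram,
    genus_table,
    per_genus_thresholds,
    select_optimum,
)


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    inputs: dict[str, str]
    parameters: dict
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "inputs": self.inputs,
                    "parameters": self.parameters,
                    "version": self.version,
                    "timestamp": self.timestamp,
                },
                fh,
                indent=2,
            )


def run_pipeline(
    fasta: str | os.PathLike,
    outdir: str | os.PathLike,
    metadata: str | os.PathLike | None = None,
    min_len: int = 658,
    scope: str = "dataset",
    fixed: tuple[float, ...] = (BIN_THRESHOLD,),
    min_species: int = 2,
    keep_morphospecies: bool = False,
    translation_check: bool = True,
    synonyms: dict[str, str] | None = None,
    grid_size: int = 512,
    label: str = "",
) -> dict:
    """Run the full analysis over one input dataset; return key results.

    Writes to ``outdir``: clean.fasta, qc.tsv, dm.tsv, pairs.tsv,
    species.tsv, report.json, genus.tsv, composition.tsv, histogram.tsv,
    manifest.json.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)

    raw = read_dataset(fasta, metadata=metadata, label=label)
    if synonyms:
        raw = apply_synonyms(raw, synonyms)
    clean, qc_report = qc_filter(
        raw,
        min_len=min_len,
        keep_morphospecies=keep_morphospecies,
        translation_check=translation_check,
    )
    write_fasta(clean, os.path.join(outdir, "clean.fasta"))
    qc_report.write(os.path.join(outdir, "qc.tsv"))

    dm = pairwise_matrix(clean)
    dm.write(os.path.join(outdir, "dm.tsv"))
    long_format(dm, clean).to_csv(
        os.path.join(outdir, "pairs.tsv"), sep="\t", index=False
    )

    summaries = species_summaries(dm, clean, scope=scope)
    summaries_to_dataframe(summaries).to_csv(
        os.path.join(outdir, "species.tsv"), sep="\t", index=False
    )
    overall = dataset_summary(dm, clean)

    intra, inter = intra_inter_vectors(dm, clean)
    hist_intra = distance_histogram(intra).assign(cls="intra")
    hist_inter = distance_histogram(inter).assign(cls="inter")
    import pandas as pd

    pd.concat([hist_intra, hist_inter]).rename(columns={"cls": "class"}).to_csv(
        os.path.join(outdir, "histogram.tsv"), sep="\t", index=False
    )

    pooled = np.concatenate([intra, inter])
    cands = candidate_thresholds(pooled, grid_size=grid_size)
    report = None
    if cands:
        report = select_optimum(cands, summaries, fixed=fixed)
        report.write(os.path.join(outdir, "report.json"))

    genus_entries = per_genus_thresholds(
        clean, dm, min_species=min_species, grid_size=grid_size
    )
    genus_table(genus_entries).to_csv(
        os.path.join(outdir, "genus.tsv"), sep="\t", index=False
    )

    comp = compute_composition(clean) if translation_check else None
    if comp is not None:
        comp.write(os.path.join(outdir, "composition.tsv"))

    manifest = RunManifest(
        inputs={
            "fasta": str(fasta),
            "fasta_sha256": _sha256(fasta),
            **(
                {"metadata": str(metadata), "metadata_sha256": _sha256(metadata)}
                if metadata is not None
                else {}
            ),
        },
        parameters={
            "min_len": min_len,
            "scope": scope,
            "fixed_thresholds": list(fixed),
            "min_species": min_species,
            "keep_morphospecies": keep_morphospecies,
            "translation_check": translation_check,
            "grid_size": grid_size,
        },
    )
    manifest.write(os.path.join(outdir, "manifest.json"))

    n_gapped = sum(1 for s in summaries if s.has_gap)
    return {
        "n_records": len(clean),
        "n_species": len(clean.species_names),
        "n_removed": len(qc_report),
        "summary": overall,
        "species_summaries": summaries,
        "n_gapped": n_gapped,
        "threshold_report": report,
        "genus_thresholds": genus_entries,
        "composition": comp,
        "dataset": clean,
        "distance_matrix": dm,
    }
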