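"""Synthetic barcode datasets with planted species structure.

Sequences evolve along a fixed balanced hierarchy (root -> genus ancestor ->
species ancestor -> individual) under the Kimura two-parameter substitution
process, so intraspecific divergence, congeneric divergence and
between-genus divergence are independently controllable and the realized
barcode gap is known exactly. Optional QC defects (short records, degenerate
bases, exact duplicates) are injected with recorded truth so the filter
chain is testable.

Substitution is simulated per site from the exact K2P transition
probabilities at elapsed time equal to the branch length (expected
substitutions per site), not by Gillespie stepping. With transition rate
alpha = kappa * beta and two transversion targets at rate beta each, scaled
so alpha + 2*beta = 1:

    P(transition)        = 1/4 + 1/4 e^{-4 beta t} - 1/2 e^{-2(alpha+beta) t}
    P(each transversion) = 1/4 - 1/4 e^{-4 beta t}

The K2P distance estimator applied to a simulated parent/child pair is a
consistent estimator of the branch length, which is what parameter-recovery
tests exploit.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .distance import pairwise_matrix, intra_inter_vectors
from .records import BarcodeRecord, Dataset

_ALPHABET = np.array(list("AGCT"))  # index encoding: A=0 G=1 C=2 T=3


@dataclass
class SimConfig:
    """Parameters of a synthetic barcode study.

    Defaults emulate a multi-genus curculionid barcode survey: a few
    sequences per species, small intraspecific divergence (~3%), an order
    of magnitude larger congeneric divergence (~20%), and a transition bias
    of kappa = 2. Branch lengths are expected substitutions per site.
    """

    n_genera: int = 10
    species_per_genus: int = 3
    seqs_per_species: int = 6
    seq_length: int = 658
    kappa: float = 2.0
    intra_branch: float = 0.03
    inter_branch: float = 0.20
    genus_branch: float = 0.05
    defect_rates: dict[str, float] = field(default_factory=dict)
    base_freqs: tuple[float, float, float, float] | None = None  # A,G,C,T
    seed: int = 0
    label: str = "sim"

    def __post_init__(self) -> None:
        if not (self.intra_branch < self.inter_branch):
            raise ValueError("intra_branch must be < inter_branch")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        for name, p in self.defect_rates.items():
            if name not in ("short", "degenerate", "duplicate"):
                raise ValueError(f"unknown defect type {name!r}")
            if not 0 <= p <= 1:
                raise ValueError(f"defect rate {name}={p} outside [0, 1]")


@dataclass
class SimTruth:
    """Planted ground truth for a simulated dataset."""

    config: SimConfig
    records: pd.DataFrame  # record_id, species, genus, defect
    gap_low: float | None  # max realized intra-GD (clean sequences)
    gap_high: float | None  # min realized inter-GD (clean sequences)

    @property
    def gap_interval(self) -> tuple[float, float] | None:
        if self.gap_low is None or self.gap_high is None:
            return None
        return (self.gap_low, self.gap_high)


def _k2p_site_probs(branch: float, kappa: float) -> tuple[float, float]:
    """(P(transition), P(each transversion)) after `branch` expected subs/site."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * branch)
    e2 = math.exp(-2.0 * (alpha + beta) * branch)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return p_ts, p_tv_each


def evolve_k2p(
    seq: str, branch: float, kappa: float, rng: np.random.Generator
) -> str:
    """Evolve a sequence for `branch` expected substitutions/site under K2P."""
    if branch < 0:
        raise ValueError("branch length must be non-negative")
    if branch == 0:
        return seq
    code = {"A": 0, "G": 1, "C": 2, "T": 3}
    x = np.fromiter((code[c] for c in seq), dtype=np.int64, count=len(seq))
    p_ts, p_tv = _k2p_site_probs(branch, kappa)
    u = rng.random(x.size)
    # event categories per site: [same | transition | transversion 1 | 2]
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out = x.copy()
    out[ts] = x[ts] ^ 1  # transition partner: A<->G, C<->T
    out[tv1] = (x[tv1] + 2) % 4  # first transversion target
    out[tv2] = ((x[tv2] ^ 1) + 2) % 4  # second transversion target
    return "".join(_ALPHABET[out])


def _random_root(
    length: int, rng: np.random.Generator,
    base_freqs: tuple[float, float, float, float] | None,
) -> str:
    if base_freqs is None:
        idx = rng.integers(0, 4, size=length)
    else:
        p = np.asarray(base_freqs, dtype=float)
        if p.min() < 0 or not math.isclose(p.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("base_freqs must be a probability vector (A,G,C,T)")
        idx = rng.choice(4, size=length, p=p)
    return "".join(_ALPHABET[idx])


_EPITHETS_PER_GENUS = 99  # zero-padded epithet numbering


def simulate_dataset(cfg: SimConfig) -> tuple[Dataset, SimTruth]:
    """Generate a barcode dataset plus its ground truth.

    The same seed yields byte-identical output. Defects are injected after
    the clean sequences (and the realized gap interval computed from them)
    are fixed, so truth is unaffected by defect injection.
    """
    rng = np.random.default_rng(cfg.seed)
    root = _random_root(cfg.seq_length, rng, cfg.base_freqs)

    records: list[BarcodeRecord] = []
    truth_rows: list[dict] = []
    for g in range(cfg.n_genera):
        genus = f"Simulium{g + 1:02d}"
        genus_anc = evolve_k2p(root, cfg.genus_branch, cfg.kappa, rng)
        for s in range(cfg.species_per_genus):
            species = f"{genus} species{s + 1:02d}"
            sp_anc = evolve_k2p(genus_anc, cfg.inter_branch / 2, cfg.kappa, rng)
            for i in range(cfg.seqs_per_species):
                seq = evolve_k2p(sp_anc, cfg.intra_branch / 2, cfg.kappa, rng)
                rid = f"SIM{g + 1:02d}-{s + 1:02d}-{i + 1:02d}"
                records.append(
                    BarcodeRecord(rid, species, seq, source="synthetic")
                )
                truth_rows.append(
                    {"record_id": rid, "species": species, "genus": genus,
                     "defect": ""}
                )

    # realized gap interval from the clean sequences
    clean = Dataset(records=list(records), alignment_length=cfg.seq_length)
    intra, inter = intra_inter_vectors(pairwise_matrix(clean), clean)
    gap_low = float(intra.max()) if intra.size else None
    gap_high = float(inter.min()) if inter.size else None

    # defect injection (after truth is fixed)
    rates = cfg.defect_rates
    out_records: list[BarcodeRecord] = []
    extra_truth: list[dict] = []
    for rec, row in zip(records, truth_rows):
        seq = rec.sequence
        if rates.get("short", 0) and rng.random() < rates["short"]:
            cut = int(rng.integers(cfg.seq_length // 2, cfg.seq_length))
            seq = seq[:cut]
            row["defect"] = "short"
        elif rates.get("degenerate", 0) and rng.random() < rates["degenerate"]:
            pos = int(rng.integers(0, len(seq)))
            seq = seq[:pos] + "N" + seq[pos + 1 :]
            row["defect"] = "degenerate"
        out_records.append(rec.copy(sequence=seq))
        if rates.get("duplicate", 0) and rng.random() < rates["duplicate"]:
            dup = rec.copy(record_id=rec.record_id + "-dup", sequence=seq)
            out_records.append(dup)
            extra_truth.append(
                {"record_id": dup.record_id, "species": dup.species,
                 "genus": dup.genus, "defect": "duplicate"}
            )

    truth = SimTruth(
        config=cfg,
        records=pd.DataFrame(truth_rows + extra_truth,
                             columns=["record_id", "species", "genus", "defect"]),
        gap_low=gap_low,
        gap_high=gap_high,
    )
    ds = Dataset(records=out_records, alignment_length=cfg.seq_length,
                 label=cfg.label)
    return ds, truth


def write_simulation(
    ds: Dataset, truth: SimTruth, outdir: str | os.PathLike
) -> None:
    """Write FASTA + sidecar (barcode_io-compatible), truth table, config echo."""
    from .io import write_fasta, write_sidecar

    os.makedirs(outdir, exist_ok=True)
    write_fasta(ds, os.path.join(outdir, "sim.fasta"))
    write_sidecar(ds, os.path.join(outdir, "sim_meta.tsv"))
    truth.records.to_csv(os.path.join(outdir, "sim_truth.tsv"), sep="\t",
                         index=False)
    cfg = asdict(truth.config)
    cfg["gap_low"] = truth.gap_low
    cfg["gap_high"] = truth.gap_high
    with open(os.path.join(outdir, "sim_config.json"), "w") as fh:
        json.dump(cfg, fh, indent=2)
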