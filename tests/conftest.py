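import numpy as np
import pytest

from barcodegap import BarcodeRecord, Dataset, SimConfig, simulate_dataset

# stop-free 658 bp building block: "ATGGCT" has no stop in any frame and
# repeats cleanly; trimmed to the standard barcode length.
STOPFREE_UNIT = "ATGGCT"


def stopfree_seq(length: int = 658) -> str:
    return (STOPFREE_UNIT * (length // len(STOPFREE_UNIT) + 1))[:length]


def make_record(rid, species, sequence, source="synthetic"):
    return BarcodeRecord(rid, species, sequence, source=source)


def make_dataset(records, length=None):
    return Dataset(records=list(records), alignment_length=length)


@pytest.fixture(scope="session")
def planted_sim():
    """3 genera x 3 species x 4 sequences with a wide planted gap."""
    cfg = SimConfig(
        n_genera=3,
        species_per_genus=3,
        seqs_per_species=4,
        intra_branch=0.01,
        inter_branch=0.25,
        genus_branch=0.12,
        kappa=2.0,
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220415)


def naive_k2p(a: str, b: str) -> float:
    """Independent K2P oracle: explicit per-site classification."""
    assert len(a) == len(b) and len(a) > 0
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    p = sum((x, y) in transitions for x, y in zip(a, b)) / len(a)
    q = sum(x != y and (x, y) not in transitions for x, y in zip(a, b)) / len(a)
    w1, w2 = 1 - 2 * p - q, 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        return float("nan")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def random_acgt(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
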