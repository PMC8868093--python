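import numpy as np
import pytest

from oxidtools.conservation import Msa, OrthologSet, ProteinRecord
from oxidtools.disorder import DisorderTrack


@pytest.fixture
def three_tracks():
    """Three predictors over a 10-residue protein, unanimous on residues 3-6."""
    base = np.array([0.1, 0.2, 0.9, 0.8, 0.9, 0.7, 0.4, 0.3, 0.6, 0.2])
    perturb = [0.0, 0.05, -0.05]
    return [
        DisorderTrack("prot1", f"pred{i}", np.clip(base + p, 0, 1))
        for i, p in enumerate(perturb)
    ]


@pytest.fixture
def small_msa():
    """Four species, reference 'r' aligned 'A-CDC' with one insertion column."""
    records = (
        ProteinRecord("r", "human", "ACDC"),
        ProteinRecord("s1", "mouse", "AKCDC"),
        ProteinRecord("s2", "frog", "AKCDS"),
        ProteinRecord("s3", "fish", "AKADA"),
    )
    aligned = ("A-CDC", "AKCDC", "AKCDS", "AKADA")
    return Msa(records=records, aligned=aligned, reference_id="r")


@pytest.fixture
def ortholog_pair():
    return OrthologSet(
        records=(
            ProteinRecord("a", "human", "CA" + "A" * 98),  # 1 C of 100 -> 1.00%
            ProteinRecord("b", "mouse", "CCCA" * 25),  # 75 C of 100 -> 75.00%
        ),
        reference_id="a",
    )
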