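import numpy as np
import pytest

from qmsdr import (
    EncodingConfig,
    GenePanel,
    MutationRecord,
    ScoreTable,
)


@pytest.fixture
def panel():
    return GenePanel(genes=("BRAF", "KRAS", "TP53"))


@pytest.fixture
def score_table():
    # BRAF V600E-like variant fully scored; KRAS variant VEST4-only;
    # TP53 variant absent from the table entirely
    return ScoreTable(
        algorithms=("CHASMplus", "VEST4", "CADD"),
        scores={
            ("chr7", 140753336, "A", "T"): np.array([0.996, 0.946, 0.289]),
            ("chr7", 140754001, "C", "G"): np.array([0.30, 0.20, np.nan]),
            ("chr12", 25245350, "C", "T"): np.array([np.nan, 0.41, np.nan]),
        },
    )


@pytest.fixture
def mutations():
    return [
        MutationRecord("s1", "BRAF", "chr7", 140753336, "A", "T", "p.V600E"),
        MutationRecord("s1", "KRAS", "chr12", 25245350, "C", "T", "p.G12D"),
        MutationRecord("s2", "BRAF", "chr7", 140754001, "C", "G", "p.D594G"),
        MutationRecord("s3", "TP53", "chr17", 7675088, "G", "A", "p.R273H"),
    ]


@pytest.fixture
def multi_qms_config():
    return EncodingConfig(mode="multi_qms", algorithms=("CHASMplus", "VEST4", "CADD"))
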