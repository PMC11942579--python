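import numpy as np
import pandas as pd
import pytest

from ginqc import BandDesign, BandMatrix, generate_band_matrix, load_reference_tables

# Printed per-sample band-profile entropies of the reference study (bits),
# frozen for comparison against the package's recomputation.
REFERENCE_H = {
    "PG01-1": 0.3943, "PG01-2": 0.3536, "PG01-3": 0.3943,
    "PG02-1": 1.4792, "PG02-2": 1.3141, "PG02-3": 1.4361,
    "PG03-1": 0.9690, "PG03-2": 1.1660, "PG03-3": 0.9690,
    "PG04-1": 1.3141, "PG04-2": 1.2016, "PG04-3": 1.2756,
    "PG05-1": 1.3536, "PG05-2": 1.1312, "PG05-3": 1.2016,
    "GG1": 0.1837, "GG2": 0.1660, "GG3": 0.1837,
    "FG1": 0.8797, "FG2": 0.9690, "FG3": 0.7956,
}

# Published per-batch genetic summaries: RSD (percent), HWEP size n, MQS (kg).
REFERENCE_GENETIC = {
    "PG01": (6.16, 44.30, 0.044),
    "PG02": (6.07, 43.02, 0.043),
    "PG03": (10.99, 141.00, 0.141),
    "PG04": (4.52, 23.86, 0.024),
    "PG05": (9.25, 99.80, 0.100),  # published MQS column shows 0.998, a slipped decimal
    "GG": (5.75, 38.53, 0.039),
    "FG": (9.83, 112.79, 0.113),
}

# Published per-batch chemical HWEP sizes for the two characteristic-peak panels.
REFERENCE_CHEMICAL_N = {
    "6peak": {
        "PG01": 113.07, "PG02": 920.99, "PG03": 1537.46, "PG04": 37.37,
        "PG05": 363.74, "GG": 93.85, "FG": 3070.03,
    },
    "3ginsenoside": {
        "PG01": 85.13, "PG02": 495.83, "PG03": 2097.62, "PG04": 39.15,
        "PG05": 265.30, "GG": 58.17, "FG": 3098.48,
    },
}

REFERENCE_PPB = {
    "UBC807": 85.7, "UBC808": 100.0, "UBC809": 60.0, "UBC823": 92.3,
    "UBC834": 76.9, "UBC840": 90.0, "UBC842": 72.7, "UBC873": 100.0,
}


def make_band_matrix(rows, band_ids, batch_of):
    """BandMatrix from a list of (sample_id, 0/1 row)."""
    values = pd.DataFrame(
        np.array([r for _, r in rows], dtype=np.int8),
        index=[s for s, _ in rows],
        columns=band_ids,
    )
    return BandMatrix(values, pd.Series(batch_of))


@pytest.fixture(scope="session")
def ref():
    return load_reference_tables()


@pytest.fixture()
def small_bm():
    """4 samples x 5 bands over 2 primers, 2 batches; hand-checkable."""
    return make_band_matrix(
        [
            ("s1", [1, 0, 1, 1, 0]),
            ("s2", [1, 0, 0, 1, 1]),
            ("s3", [1, 1, 1, 0, 0]),
            ("s4", [1, 1, 1, 1, 1]),
        ],
        ["pA:1", "pA:2", "pA:3", "pB:1", "pB:2"],
        {"s1": "b1", "s2": "b1", "s3": "b2", "s4": "b2"},
    )


@pytest.fixture(scope="session")
def study_like_bm():
    """Synthetic matrix mirroring the study design: 8 primers, 92 bands,
    7 batches x 3 samples."""
    primers = {
        "UBC807": 14, "UBC808": 12, "UBC809": 5, "UBC823": 13,
        "UBC834": 13, "UBC840": 10, "UBC842": 11, "UBC873": 14,
    }
    batches = [(b, 3, 0.6, f) for b, f in [
        ("PG01", 0.02), ("PG02", 0.05), ("PG03", 0.10), ("PG04", 0.03),
        ("PG05", 0.08), ("GG", 0.01), ("FG", 0.12),
    ]]
    return generate_band_matrix(BandDesign(primers, batches, seed=20260929))
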