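import numpy as np
import pandas as pd
import pytest

from ribomics import normde, ribo, synthio


@pytest.fixture(scope="session")
def small_multiomics():
    cfg = synthio.SimulationConfig(n_genes=400, n_reps_per_condition=4, seed=7)
    return synthio.generate_multiomics(cfg)


@pytest.fixture()
def abundance_matrix():
    data = pd.DataFrame(
        {
            "s1": [10.0, 20.0, 5.0, 100.0],
            "s2": [12.0, 18.0, 6.0, 90.0],
            "s3": [11.0, 22.0, 4.0, 110.0],
            "s4": [9.0, 21.0, 5.0, 95.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    conditions = {"s1": "control", "s2": "control", "s3": "treated", "s4": "treated"}
    return normde.AbundanceMatrix(data, conditions)


@pytest.fixture(scope="session")
def transcript_model():
    return synthio.generate_transcript("TX1", n_codons=80, utr5_len=30, utr3_len=30, seed=11)


def make_footprints(model, codon_counts, length=30, offset=12):
    """Footprint table putting `codon_counts[i]` P-sites on CDS codon i."""
    rows = []
    for i, c in enumerate(codon_counts):
        psite = model.utr5_len + 3 * i
        for _ in range(int(c)):
            rows.append((model.transcript_id, psite - offset, length))
    return pd.DataFrame(rows, columns=["transcript_id", "pos5", "length"])


@pytest.fixture()
def de_table_factory():
    """Minimal differential-result table builder for classification tests."""

    def build(rows):
        # rows: mapping gene -> (significant, direction, log2fc, q)
        df = pd.DataFrame.from_dict(
            rows, orient="index", columns=["significant", "direction", "log2fc", "q"]
        )
        df.index.name = "feature_id"
        return df

    return build


def run_de(matrix: normde.AbundanceMatrix, pseudocount=0.5, require_complete=False,
           threshold=0.05):
    filtered = normde.filter_features(matrix, require_complete=require_complete)
    norm = normde.normalize_matrix(filtered, normde.compute_size_factors(filtered))
    return norm, normde.welch_differential(norm, threshold=threshold, pseudocount=pseudocount)
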