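"""Shared fixtures: small whitelists, transcriptomes and simulated runs."""

import pytest

from cbtiseq.barcodes import SampleSheet, generate_barcode_set
from cbtiseq.demux import demultiplex_stream
from cbtiseq.simulate import SimConfig, make_transcriptome, simulate_library


@pytest.fixture(scope="session")
def set_a():
    return generate_barcode_set(10, seed=11, name="A")


@pytest.fixture(scope="session")
def set_b(set_a):
    return generate_barcode_set(10, seed=12, name="B", exclude=set_a.barcodes)


@pytest.fixture(scope="session")
def transcriptome():
    return make_transcriptome(25, seed=3)


@pytest.fixture(scope="session")
def errorfree_run(set_a, set_b, transcriptome):
    """Error-free 4-sample simulation decoded with trimming enabled.

    UMIs are drawn without replacement within each (sample, gene) so that
    deduplicated counts can be compared exactly against ground truth.
    """
    sheet = SampleSheet.diagonal(4)
    cfg = SimConfig(
        reads_per_sample=1500,
        substitution_error_rate=0.0,
        unique_umis=True,
        seed=21,
    )
    pairs, truth = simulate_library(transcriptome, sheet, set_a, set_b, cfg)
    records, stats = demultiplex_stream(pairs, set_a, set_b, sheet)
    return {
        "sheet": sheet,
        "cfg": cfg,
        "pairs": pairs,
        "truth": truth,
        "records": records,
        "stats": stats,
    }
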