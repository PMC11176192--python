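import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def toy_calls():
    """Ten SSV calls, four with single-caller support."""
    rows = []
    for i in range(10):
        callers = "mutect2;strelka2" if i < 6 else "mutect2"
        rows.append(
            {
                "sample_id": "s1",
                "chrom": "chr1",
                "pos": 100 + i,
                "ref": "A",
                "alt": "T",
                "vtype": "SNV",
                "callers": callers,
                "alt_reads_tumor": 10,
                "ref_reads_tumor": 79,
                "alt_reads_normal": 0,
                "vaf": 10 / 89,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def passing_sv():
    return {
        "chrom_a": "chr1",
        "pos_a": 1000,
        "chrom_b": "chr2",
        "pos_b": 2000,
        "algorithms": "manta;svaba",
        "alt_reads_tumor": 8,
        "alt_reads_normal": 0,
        "vaf": 0.2,
    }


def make_ccf_frame(keys, clonal):
    """Minimal CCF table: variant keys plus precomputed clonality flags."""
    rows = []
    for key, cl in zip(keys, clonal):
        chrom, rest = key.split(":")
        pos, change = rest.split("_")
        ref, alt = change.split(">")
        rows.append(
            {
                "chrom": chrom,
                "pos": int(pos),
                "ref": ref,
                "alt": alt,
                "vaf": 0.3,
                "alt_reads_tumor": 20,
                "clonal": cl,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
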