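import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A compact synthetic study, written to disk once for the whole session."""
    from lofburden.simulate import SimulationConfig, simulate_dataset

    out = tmp_path_factory.mktemp("smallds")
    cfg = SimulationConfig(
        n_accessions=150,
        n_snps=400,
        n_genes=120,
        n_expressed_genes=30,
        n_effects=4,
        seed=42,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = simulate_dataset(cfg, out_dir=str(out))
    return ds, out


@pytest.fixture(scope="session")
def small_calls(small_dataset):
    """LoF call set recomputed from the small dataset's files."""
    from cyvcf2 import VCF

    from lofburden.annotation import call_lof, read_deletions_tsv
    from lofburden.genes import read_gff3

    ds, out = small_dataset
    genes = read_gff3(str(out / "genes.gff3"))
    accessions = list(VCF(str(out / "variants.vcf")).samples)
    dels = read_deletions_tsv(str(out / "deletions.tsv"), accessions)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        calls = call_lof(str(out / "variants.vcf"), dels, genes, accessions)
    return genes, calls


def make_transcript(lengths, start=1000, intron=100, tid="t1"):
    """Helper: transcript with the given CDS exon lengths."""
    from lofburden.genes import TranscriptModel

    intervals = []
    pos = start
    for L in lengths:
        intervals.append((pos, pos + L))
        pos += L + intron
    return TranscriptModel(tid, intervals)
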