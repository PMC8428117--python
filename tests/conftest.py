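import pytest

from pirnascan.align import AlignParams, align_transcripts
from pirnascan.simulate import (
    SynthConfig,
    make_genome,
    make_isoform_set,
    plant_utr_matches,
    sample_pirna_reads,
)

# alignment parameters matched to the synthetic genome layout: intercopy
# spacers (4 kb) must exceed max_intron for locus copies to stay distinct
SYNTH_ALIGN = AlignParams(max_intron=2000)


@pytest.fixture(scope="session")
def clean_dataset():
    """One mutation-free synthetic dataset shared across tests."""
    cfg = SynthConfig(seed=11, copy_mutation_rate=0.0)
    truth = make_genome(cfg)
    transcripts, iso = make_isoform_set(cfg, truth)
    return cfg, truth, transcripts, iso


@pytest.fixture(scope="session")
def planted_utrs(clean_dataset):
    cfg, truth, transcripts, iso = clean_dataset
    utrs, planted = plant_utr_matches(cfg, transcripts, iso)
    return utrs, planted


@pytest.fixture(scope="session")
def read_set(clean_dataset):
    cfg, truth, transcripts, iso = clean_dataset
    return sample_pirna_reads(cfg, transcripts, truth, iso)


@pytest.fixture(scope="session")
def aligned_chains(clean_dataset):
    cfg, truth, transcripts, iso = clean_dataset
    return align_transcripts(transcripts, list(truth.genome), SYNTH_ALIGN)
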