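import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

from venomkit.annotate import TranscriptRecord, find_orfs, segment_precursor
from venomkit.simulate import (TBO_IT2_MATURE, TBO_IT2_TEMPLATE,
                               gen_precursor_library)

#: The five §-printed disulfide pairs of the flagship toxin, mature numbering.
TBO_PAIRS = [(1, 15), (8, 20), (14, 31), (17, 39), (22, 29)]


@pytest.fixture(scope="session")
def tbo_mature() -> str:
    return TBO_IT2_MATURE


@pytest.fixture(scope="session")
def synthetic_library():
    """200-record synthetic precursor library with ground truth."""
    transcripts, truths = gen_precursor_library(200, seed=42,
                                                frameworks=[TBO_IT2_TEMPLATE])
    return transcripts, truths


@pytest.fixture(scope="session")
def annotated_precursors(synthetic_library):
    """Precursor models recovered from the synthetic library by the
    annotation pipeline itself (not the ground truth)."""
    transcripts, _ = synthetic_library
    models = []
    for tid, dna in transcripts:
        orfs = find_orfs(TranscriptRecord(tid, dna), min_aa_len=60)
        models.append(segment_precursor(max(orfs, key=lambda o: len(o.aa_sequence))))
    return models
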