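import pytest
from hypothesis import settings

from shmscope.io import AnnotatedSequence, RegionMap

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_region_map(
    family="tV1", fr1=6, cdr1=3, fr2=6, cdr2=3, fr3=6, cdr3=6, j=6, c=3, frame_offset=0
) -> RegionMap:
    """Small contiguous region map for hand-built alignments."""
    widths = [("FR1", fr1), ("CDR1", cdr1), ("FR2", fr2), ("CDR2", cdr2),
              ("FR3", fr3), ("CDR3", cdr3), ("J", j), ("C", c)]
    intervals = []
    pos = 0
    for label, width in widths:
        intervals.append((label, pos, pos + width))
        pos += width
    return RegionMap(family_id=family, intervals=tuple(intervals),
                     frame_offset=frame_offset)


def make_seq(
    residues, seq_id="tV1_THY01_x", individual="I1", tissue="THY",
    family="tV1", region_map=None,
) -> AnnotatedSequence:
    if region_map is None:
        region_map = make_region_map(family=family)
    assert len(residues) >= region_map.alignment_length
    return AnnotatedSequence(
        seq_id=seq_id, individual_id=individual, tissue=tissue,
        family_id=family, residues=residues, region_map=region_map,
    )


@pytest.fixture
def region_map():
    return make_region_map()


@pytest.fixture(scope="session")
def default_dataset():
    """One small simulated repertoire shared across tests."""
    from shmscope.simulate import SimulationConfig, generate_dataset

    return generate_dataset(SimulationConfig(seed=11, n_founders=12, n_v_genes=4))


@pytest.fixture(scope="session")
def default_bundle(default_dataset):
    from shmscope.pipeline import analyze_sequences

    return analyze_sequences(default_dataset.sequences)
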