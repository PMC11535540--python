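import numpy as np
import pytest

from ladscreen.formats_io import GeneModel, GenomeLayout, SignalTrack, Transcript


@pytest.fixture
def tiny_layout() -> GenomeLayout:
    return GenomeLayout({"chr1": 100_000, "chr2": 80_000})


@pytest.fixture
def tiny_models() -> list[GeneModel]:
    return [
        GeneModel("gA", "chr1", "+", 1_000, 5_000, 2_000),
        GeneModel("gB", "chr1", "-", 10_000, 16_000, 3_000),
        GeneModel("gC", "chr2", "+", 2_000, 8_000, 4_000),
    ]


@pytest.fixture
def flat_track() -> SignalTrack:
    """Constant-value track covering chr1 0-100kb in 1-kb bins."""
    return SignalTrack([("chr1", s, s + 1_000, 2.5) for s in range(0, 100_000, 1_000)])


@pytest.fixture
def coding_transcripts() -> list[Transcript]:
    return [
        Transcript("txA1", "gA", "chr1", "+", 1_000, 5_000, 1_200, 4_800),
        Transcript("txA2", "gA", "chr1", "+", 900, 4_000, 1_500, 1_800),
        Transcript("txB1", "gB", "chr1", "-", 1_000, 5_000, 1_200, 4_800),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
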