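import pandas as pd
import pytest

from imprintscan.config import PipelineConfig
from imprintscan.model import MethylomeSample


def make_sample(cpgs, sample_id="s1", origin="androgenetic", stage="ESC", chrom="chr1"):
    """Build a MethylomeSample from (pos, meth, unmeth) triples."""
    calls = pd.DataFrame(cpgs, columns=["pos", "meth", "unmeth"])
    calls.insert(0, "chrom", chrom)
    return MethylomeSample(sample_id, origin, stage, calls)


@pytest.fixture
def config():
    return PipelineConfig()
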