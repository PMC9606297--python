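import numpy as np
import pandas as pd
import pytest

from scna.clonality import AllelicSegmentProfile


def make_profile(patient, region, segs, ploidy=2.0):
    """Build a region profile from (chrom, start, end, minor, major) tuples."""
    return AllelicSegmentProfile(
        patient_id=patient, region_id=region,
        segments=pd.DataFrame(
            segs, columns=["chrom", "start", "end", "raw_minor", "raw_major"]),
        ploidy=ploidy)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
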