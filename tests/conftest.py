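import numpy as np
import pandas as pd
import pytest

from petreldemog.demography import DemographicModel, SampleConfig
from petreldemog.sfs import GenotypeMatrix


def make_matrix(calls, sample_meta=None, locus_meta=None) -> GenotypeMatrix:
    """Small helper: build a GenotypeMatrix from a 2d list/array of codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    samples = pd.DataFrame(
        sample_meta or {}, index=pd.Index([f"S{i}" for i in range(n)], name="id")
    )
    loci = pd.DataFrame(
        locus_meta or {}, index=pd.Index([f"L{j}" for j in range(m)], name="locus_id")
    )
    return GenotypeMatrix(calls, samples, loci)


@pytest.fixture
def constant_model():
    return DemographicModel(demes=["A"], sizes=[1000.0])


@pytest.fixture
def two_deme_join_model():
    from petreldemog.demography import Join, Resize

    return DemographicModel(
        demes=["X", "Y"],
        sizes=[500.0, 800.0],
        events=[Join(100.0, "X", "Y"), Resize(100.0, "Y", 600.0)],
    )
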