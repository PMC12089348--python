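import pytest

import sgcohort
from sgcohort.io import VariantCall
from sgcohort.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic cohort (study-condition defaults, seed 0)."""
    return simulate_cohort(CohortConfig(), seed=0)


@pytest.fixture(scope="session")
def results(bundle):
    """Full pipeline results on the default cohort."""
    return sgcohort.analyze_cohort(bundle)


@pytest.fixture
def make_call():
    """Factory for variant calls with sensible defaults."""

    def _make(
        sample_id="S1", chrom="chr1", pos=100, ref="A", alt="G",
        t_depth=50, t_alt=20, n_depth=50, n_alt=0, **kwargs,
    ):
        return VariantCall(
            sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
            t_depth=t_depth, t_alt=t_alt, n_depth=n_depth, n_alt=n_alt, **kwargs,
        )

    return _make
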