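import pytest
from hypothesis import HealthCheck, settings

from molautopsy.io import VariantRecord, load_cohort_cases

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort_cases():
    """The packaged 50-case cohort."""
    return load_cohort_cases()


def make_variant(sample="S1", gene="GENE1", category=None, effect="missense", **kw):
    """Minimal valid variant for unit tests."""
    defaults = dict(
        sample_id=sample,
        chrom="1",
        pos=kw.pop("pos", 100),
        ref_allele="A",
        alt_allele="G",
        gene=gene,
        effect_class=effect,
        category=category,
    )
    defaults.update(kw)
    return VariantRecord(**defaults)
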