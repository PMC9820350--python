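import pytest

from pspkit import default_rules, gen_gliadin_peptides, GliadinSpec


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def gliadin_suite():
    """200 seeded gliadin-like peptides for property checks."""
    return gen_gliadin_peptides(GliadinSpec(seed=42), 200)
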