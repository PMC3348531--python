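import pytest

from polindex import build_template, template_candidates


@pytest.fixture(scope="session")
def template():
    """Template pooled from the packaged high-TI candidate peptides."""
    return build_template(template_candidates())
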