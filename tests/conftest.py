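import pytest

from gistia import IAAnalysis, clean_table, generate
from gistia.data_model import build_cohorts
from gistia.synthetic_data import GeneratorConfig


@pytest.fixture(scope="session")
def default_dataset():
    """The full default synthetic design (20 blocks x 21 images x 30 participants)."""
    return generate(GeneratorConfig())


@pytest.fixture(scope="session")
def cleaned_default(default_dataset):
    cleaned, report = clean_table(default_dataset.records)
    return cleaned, report


@pytest.fixture(scope="session")
def default_analysis(default_dataset, cleaned_default):
    cleaned, _ = cleaned_default
    cohorts, design = build_cohorts(cleaned)
    design.similar_pairs = default_dataset.design.similar_pairs
    return IAAnalysis(cleaned, design=design, cohorts=cohorts)


@pytest.fixture(scope="session")
def pooled_table(default_analysis):
    return default_analysis.word_ia_table("pooled")
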