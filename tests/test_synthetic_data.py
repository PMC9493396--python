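import numpy as np
import pandas as pd
import pytest

from gistia import IAAnalysis, generate, make_fixture
from gistia.data_model import SOA_LEVELS, build_cohorts
from gistia.synthetic_data import GENERIC_LEXICON, GeneratorConfig


def test_default_design_structure(default_dataset):
    records = default_dataset.records
    assert len(records) == 63_000  # 420 images x 3 SOAs x 10 participants x 5
    assert records["image_id"].nunique() == 420
    assert records["participant_id"].nunique() == 600
    # each (image, SOA) cell has exactly 10 participants
    cell_sizes = records.groupby(["image_id", "soa_ms"])["participant_id"].nunique()
    assert (cell_sizes == 10).all() and len(cell_sizes) == 1260
    # no image repeated within participant
    trials = records.drop_duplicates(["participant_id", "image_id", "soa_ms"])
    assert not trials.duplicated(["participant_id", "image_id"]).any()
    # 7 trials at each SOA per participant
    per_soa = trials.groupby(["participant_id", "soa_ms"]).size()
    assert (per_soa == 7).all()


def test_design_blocks_and_pairs(default_dataset):
    design = default_dataset.design
    assert len(design.blocks) == 20
    assert all(len(imgs) == 21 for imgs in design.blocks.values())
    assert len(design.similar_pairs) == 28  # 24 natural + 4 artificial
    block_of = {img: b for b, imgs in design.blocks.items() for img in imgs}
    for p in design.similar_pairs:
        assert block_of[p.image_a] != block_of[p.image_b]


def test_same_seed_identical_different_seed_same_shape():
    a = generate(GeneratorConfig(seed=5))
    b = generate(GeneratorConfig(seed=5))
    c = generate(GeneratorConfig(seed=6))
    pd.testing.assert_frame_equal(a.records, b.records)
    assert not a.records.equals(c.records)
    assert len(c.records) == len(a.records)
    sizes = c.records.groupby(["image_id", "soa_ms"])["participant_id"].nunique()
    assert (sizes == 10).all()


def test_ground_truth_covers_all_words(default_dataset):
    cleaned_words = set(default_dataset.ground_truth["word"])
    labels = set(default_dataset.ground_truth["label"])
    assert labels == {"specific", "generic", "noise"}
    specific = default_dataset.ground_truth.query("label == 'specific'")
    assert specific["image_id"].notna().all()
    assert set(GENERIC_LEXICON) >= set(
        default_dataset.ground_truth.query("label == 'generic'")["word"]
    )
    assert cleaned_words  # non-empty


def test_noise_words_carry_dont_know_confidence(default_dataset):
    records = default_dataset.records
    noise = records[records["raw_word"].str.startswith("zz-")]
    assert len(noise) > 0
    assert (noise["confidence"] == 1).all()


def test_infeasible_configs_are_rejected():
    with pytest.raises(ValueError, match="lexicon"):
        generate(GeneratorConfig(specific_lexicon_size=3))
    with pytest.raises(ValueError, match="divisible"):
        generate(GeneratorConfig(participants_per_block=31))
    with pytest.raises(ValueError, match="images_per_block"):
        generate(GeneratorConfig(images_per_block=20))


def test_deterministic_specific_word_reaches_ia_one():
    """With no noise/generic mass, a specific word reported by the whole
    cohort and nowhere else must score IA 1 by the closed form."""
    cfg = GeneratorConfig(
        n_blocks=2,
        noise_rate=0.0,
        misspelling_rate=0.0,
        inflection_rate=0.0,
        specific_prob={67: 1.0, 133: 1.0, 267: 1.0},
        specific_lexicon_size=5,
        n_natural_pairs=0,
        n_artificial_pairs=0,
        seed=3,
    )
    data = generate(cfg)
    records = data.records.assign(word=data.records["raw_word"])  # tokens are clean
    analysis = IAAnalysis(records, design=data.design)
    table = analysis.word_ia_table("pooled")
    defined = table[table["defined"]]
    assert len(defined) > 0
    assert (defined["ia"] == 1.0).all()


def test_full_overlap_pair_has_near_zero_sse():
    from gistia.similarity_sse import sse_pair

    cfg = GeneratorConfig(
        n_blocks=2,
        n_natural_pairs=1,
        natural_overlap=1.0,
        n_artificial_pairs=0,
        noise_rate=0.0,
        seed=9,
    )
    data = generate(cfg)
    pair = data.design.similar_pairs[0]
    paired = sse_pair(data.records.assign(word=data.records["raw_word"]),
                      pair.image_a, pair.image_b).sse
    others = [
        sse_pair(
            data.records.assign(word=data.records["raw_word"]), pair.image_a, img
        ).sse
        for img in data.design.images[:6]
        if img not in (pair.image_a, pair.image_b)
    ]
    # identical generative distributions: far smaller than unrelated images
    assert paired < min(others)


@pytest.mark.parametrize("name,expectation", [("eiffel", 1.0), ("uniform", 0.5)])
def test_fixture_word_ia_values(name, expectation):
    data = make_fixture(name)
    analysis = IAAnalysis(data.records, design=data.design)
    word = "eiffel-tower" if name == "eiffel" else "sky"
    assert analysis.word_ia(word, "imgA", 67).ia == pytest.approx(expectation)


def test_unknown_fixture_lists_available():
    with pytest.raises(KeyError, match="eiffel"):
        make_fixture("nope")


def test_soa_effect_is_monotone(default_analysis):
    means = [
        default_analysis.word_ia_table(soa).query("defined")["ia"].mean()
        for soa in SOA_LEVELS
    ]
    assert means[0] <= means[1] <= means[2]
    conf = default_analysis.records.groupby("soa_ms")["confidence"].mean()
    assert conf[67] <= conf[133] <= conf[267]
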