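"""Synthetic free-report datasets with a known specificity structure.

The generator emulates the masked-scene free-report design end to end: images
split into blocks, each participant assigned one block and seeing each of its
images exactly once, seven trials at each SOA (67/133/267 ms), exactly
``n_per_cell`` participants per (image, SOA) cell, and five typed words with
confidence ratings per trial.

What the vocabulary mixture emulates — and what it does not.  Each image owns
a disjoint lexicon of *specific* tokens (reported for that image only, more
often at longer SOAs); all images share a *generic* lexicon of common scene
words (reported indiscriminately, the coarse-gist floor); *noise* tokens are
arbitrary fillers entered with confidence 1, mimicking participants who ran
out of words.  Registered similar image pairs share part of their specific
lexicons.  Confidence is drawn conditional on word class and SOA (specific >
generic > noise), which builds in a positive confidence-specificity link with
a controllable effect size.  Words are tokens: there is no natural-language
structure, no synonymy, and no semantic gradient between "specific" and
"generic" — only the report statistics the IA machinery consumes.

Misspellings are planted only from the shipped manual map (and inflections
only from the shipped lemma table), so the cleaning pipeline's recovery is
exactly checkable: cleaning a generated table must restore every planted
surface form and remove no rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import SOA_LEVELS, SimilarPair, StudyDesign
from .preprocessing import default_lemma_table, default_manual_map

#: Shared coarse-gist vocabulary (all words are in the shipped wordlist).
GENERIC_LEXICON = (
    "sky water tree grass cloud sun light dark city street building house "
    "car road person child nature day green blue bright outdoor indoor "
    "mountain river beach field forest flower calm beautiful big small "
    "color scene view crowd morning weather"
).split()

#: Noise-token prefix; hyphenated so the cleaning pipeline passes them through.
NOISE_PREFIX = "zz"

_CONF_SPECIFIC = {
    67: (0.00, 0.05, 0.20, 0.40, 0.35),
    133: (0.00, 0.03, 0.12, 0.40, 0.45),
    267: (0.00, 0.02, 0.08, 0.35, 0.55),
}
_CONF_GENERIC = (0.00, 0.25, 0.40, 0.25, 0.10)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic design; defaults reproduce the full study shape."""

    n_blocks: int = 20
    images_per_block: int = 21
    participants_per_block: int = 30
    trials_per_soa: int = 7
    words_per_trial: int = 5
    specific_lexicon_size: int = 12
    #: probability that a word slot draws from the image-specific lexicon
    specific_prob: Mapping[int, float] = field(
        default_factory=lambda: {67: 0.45, 133: 0.55, 267: 0.65}
    )
    noise_rate: float = 0.05
    misspelling_rate: float = 0.02
    inflection_rate: float = 0.03
    n_natural_pairs: int = 24
    natural_overlap: float = 0.8
    n_artificial_pairs: int = 4
    artificial_overlap: float = 0.3
    seed: int = 0

    @property
    def n_per_cell(self) -> int:
        return self.participants_per_block // len(SOA_LEVELS)

    def validate(self) -> None:
        if self.participants_per_block % len(SOA_LEVELS):
            raise ValueError("participants_per_block must be divisible by 3")
        if self.images_per_block != len(SOA_LEVELS) * self.trials_per_soa:
            raise ValueError(
                "images_per_block must equal 3 * trials_per_soa so each "
                "participant sees every image of their block exactly once"
            )
        if self.specific_lexicon_size < self.words_per_trial:
            raise ValueError("specific lexicon smaller than words_per_trial")
        if len(GENERIC_LEXICON) < self.words_per_trial:
            raise ValueError("generic lexicon smaller than words_per_trial")
        for soa, p in self.specific_prob.items():
            if not 0.0 <= p + self.noise_rate <= 1.0:
                raise ValueError(f"class probabilities at SOA {soa} exceed 1")
        n_pair_images = 2 * (self.n_natural_pairs + self.n_artificial_pairs)
        if n_pair_images > self.n_blocks * self.images_per_block:
            raise ValueError("more similar-pair members than images")


@dataclass
class SyntheticDataset:
    """Generated responses plus the ground truth the tests recover."""

    records: pd.DataFrame
    ground_truth: pd.DataFrame  # word, label (specific|generic|noise), image_id
    design: StudyDesign


def _soa_grid(n_rows: int, n_cols: int, rng: np.random.Generator) -> np.ndarray:
    """SOA assignment: each row balanced across columns, each column across rows.

    The cyclic Latin-style pattern ``(r + c) % 3`` gives every participant
    ``n_cols/3`` trials per SOA and every image ``n_rows/3`` participants per
    SOA; permuting rows and columns randomises who gets what without touching
    the marginals.
    """
    base = (np.add.outer(np.arange(n_rows), np.arange(n_cols))) % 3
    return base[rng.permutation(n_rows)][:, rng.permutation(n_cols)]


def _draw(rng: np.random.Generator, probs: tuple[float, ...]) -> int:
    return int(rng.choice(5, p=probs)) + 1


def generate(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate a full-design response table with ground-truth word labels.

    At defaults this yields ``20 * 21 * 3 * 10 * 5 = 63,000`` rows, no image
    repeated within participant and exactly 10 participants per (image, SOA)
    cell.  Output is byte-identical for equal seeds.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_images = cfg.n_blocks * cfg.images_per_block
    images = [f"im{k:03d}" for k in range(1, n_images + 1)]
    shuffled = list(rng.permutation(images))
    blocks = {
        b + 1: sorted(
            shuffled[b * cfg.images_per_block : (b + 1) * cfg.images_per_block]
        )
        for b in range(cfg.n_blocks)
    }
    image_block = {img: b for b, imgs in blocks.items() for img in imgs}

    # similar pairs span different blocks (a pair inside one block would be
    # seen by the same participants, which the design forbids)
    pairs: list[SimilarPair] = []
    by_block = {b: list(imgs) for b, imgs in blocks.items()}
    kinds = ["natural"] * cfg.n_natural_pairs + ["artificial"] * cfg.n_artificial_pairs
    for k, kind in enumerate(kinds):
        b_a = (k % cfg.n_blocks) + 1
        b_b = ((k + 1) % cfg.n_blocks) + 1
        pairs.append(
            SimilarPair(
                pair_id=f"pair{k + 1:02d}",
                image_a=by_block[b_a].pop(),
                image_b=by_block[b_b].pop(),
                kind=kind,
            )
        )

    # image-specific lexicons; paired images share the leading tokens
    lexicon = {
        img: [f"obj{k:03d}-{chr(97 + j)}" for j in range(cfg.specific_lexicon_size)]
        for k, img in enumerate(images, start=1)
    }
    overlap_of = {"natural": cfg.natural_overlap, "artificial": cfg.artificial_overlap}
    for p in pairs:
        n_shared = round(overlap_of[p.kind] * cfg.specific_lexicon_size)
        lexicon[p.image_b][:n_shared] = lexicon[p.image_a][:n_shared]

    # inverse maps for planting surface variants of generic words
    mis_variants: dict[str, list[str]] = {}
    for bad, good in default_manual_map().items():
        mis_variants.setdefault(good, []).append(bad)
    inflected: dict[str, list[str]] = {}
    for form, base in default_lemma_table().items():
        inflected.setdefault(base, []).append(form)

    soas = list(SOA_LEVELS)
    rows: list[tuple] = []
    truth: dict[str, tuple[str, str | None]] = {}

    for b in range(1, cfg.n_blocks + 1):
        block_images = blocks[b]
        participants = [
            f"p{b:02d}-{k:02d}" for k in range(1, cfg.participants_per_block + 1)
        ]
        grid = _soa_grid(len(participants), len(block_images), rng)
        for r, pid in enumerate(participants):
            trial_order = rng.permutation(len(block_images))
            for trial_index, c in enumerate(trial_order, start=1):
                img = block_images[c]
                soa = soas[grid[r, c]]
                p_spec = cfg.specific_prob[soa]
                used: set[str] = set()
                for slot in range(1, cfg.words_per_trial + 1):
                    u = rng.random()
                    if u < cfg.noise_rate:
                        label = "noise"
                    elif u < cfg.noise_rate + p_spec:
                        label = "specific"
                    else:
                        label = "generic"

                    if label == "noise":
                        word = f"{NOISE_PREFIX}-{rng.integers(10000):04d}"
                        while word in used:
                            word = f"{NOISE_PREFIX}-{rng.integers(10000):04d}"
                        raw = word
                        conf = 1
                    elif label == "specific":
                        choices = [w for w in lexicon[img] if w not in used]
                        if not choices:
                            label = "generic"
                        else:
                            word = choices[rng.integers(len(choices))]
                            raw = word
                            conf = _draw(rng, _CONF_SPECIFIC[soa])
                    if label == "generic":
                        choices = [w for w in GENERIC_LEXICON if w not in used]
                        word = choices[rng.integers(len(choices))]
                        raw = word
                        conf = _draw(rng, _CONF_GENERIC)
                        if word in mis_variants and rng.random() < cfg.misspelling_rate:
                            raw = mis_variants[word][rng.integers(len(mis_variants[word]))]
                        elif word in inflected and rng.random() < cfg.inflection_rate:
                            raw = inflected[word][rng.integers(len(inflected[word]))]

                    used.add(word)
                    spec_img = img if label == "specific" else None
                    truth.setdefault(word, (label, spec_img))
                    rows.append(
                        (pid, b, img, soa, trial_index, slot, raw, conf)
                    )

    records = pd.DataFrame(
        rows,
        columns=[
            "participant_id", "block_id", "image_id", "soa_ms",
            "trial_index", "word_slot", "raw_word", "confidence",
        ],
    )
    ground_truth = pd.DataFrame(
        [
            {"word": w, "label": lab, "image_id": img}
            for w, (lab, img) in sorted(truth.items())
        ]
    )
    design = StudyDesign(
        images=sorted(images),
        blocks=blocks,
        similar_pairs=pairs,
        n_per_cell=cfg.n_per_cell,
    )
    return SyntheticDataset(records=records, ground_truth=ground_truth, design=design)


# ---------------------------------------------------------------------------
# Hand-checkable fixtures


def _fixture_frame(rows: list[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(
        rows,
        columns=[
            "participant_id", "block_id", "image_id", "soa_ms",
            "trial_index", "word_slot", "raw_word", "confidence",
        ],
    )
    df["word"] = df["raw_word"]  # fixture tokens are already normal forms
    return df


def _eiffel_fixture() -> SyntheticDataset:
    """One landmark word reported by 6 of 10 in one cell, by nobody elsewhere.

    Each reporter's within-fraction is 5/9 and every baseline fraction is 0,
    so every reporter AUC — and hence the Word IA — is exactly 1.
    """
    images = ["imgA", "imgB", "imgC", "imgD"]
    rows = []
    for img in images:
        for k in range(1, 11):
            pid = f"q{k:02d}"
            slot = 1
            if img == "imgA" and k <= 6:
                rows.append((pid, 1, img, 67, 1, slot, "eiffel-tower", 5))
                slot += 1
            while slot <= 5:
                rows.append((pid, 1, img, 67, 1, slot, f"fill-{img}-{pid}-{slot}", 2))
                slot += 1
    design = StudyDesign(images=images, blocks={1: images}, n_per_cell=10)
    records = _fixture_frame(rows)
    truth = pd.DataFrame(
        [{"word": "eiffel-tower", "label": "specific", "image_id": "imgA"}]
    )
    return SyntheticDataset(records=records, ground_truth=truth, design=design)


def _uniform_fixture() -> SyntheticDataset:
    """A word reported by the same half of every cohort on every image.

    For any reporter the within-fraction equals every baseline fraction
    (4/9 after the same-order exclusion), pinning the AUC at chance, 0.5.
    """
    images = ["imgA", "imgB", "imgC", "imgD"]
    rows = []
    for img in images:
        for k in range(1, 11):
            pid = f"q{k:02d}"
            slot = 1
            if k <= 5:
                rows.append((pid, 1, img, 67, 1, slot, "sky", 3))
                slot += 1
            while slot <= 5:
                rows.append((pid, 1, img, 67, 1, slot, f"fill-{img}-{pid}-{slot}", 2))
                slot += 1
    design = StudyDesign(images=images, blocks={1: images}, n_per_cell=10)
    records = _fixture_frame(rows)
    truth = pd.DataFrame([{"word": "sky", "label": "generic", "image_id": None}])
    return SyntheticDataset(records=records, ground_truth=truth, design=design)


def _sperling_fixture() -> SyntheticDataset:
    """Letter-array images whose tokens are perfectly image-specific.

    Every participant reports their image's full five-letter lexicon at
    every SOA, and no lexicons overlap: each letter's pooled Word IA is 1
    by the closed form, so Image IA is 1 for every image.
    """
    lexicons = {
        "sperling1": ["u", "p", "l", "e", "r"],
        "sperling2": ["a", "b", "c", "d", "f"],
        "fillerX": ["x1-a", "x1-b", "x1-c", "x1-d", "x1-e"],
        "fillerY": ["y1-a", "y1-b", "y1-c", "y1-d", "y1-e"],
    }
    images = list(lexicons)
    rows = []
    for c, img in enumerate(images):
        for k in range(30):
            pid = f"r{k + 1:02d}"
            soa = SOA_LEVELS[(k + c) % 3]
            for slot, word in enumerate(lexicons[img], start=1):
                rows.append((pid, 1, img, soa, c + 1, slot, word, 5))
    design = StudyDesign(
        images=images,
        blocks={1: images},
        similar_pairs=[SimilarPair("pair01", "sperling1", "sperling2", "artificial")],
        n_per_cell=10,
    )
    records = _fixture_frame(rows)
    truth = pd.DataFrame(
        [
            {"word": w, "label": "specific", "image_id": img}
            for img, lex in lexicons.items()
            for w in lex
        ]
    )
    return SyntheticDataset(records=records, ground_truth=truth, design=design)


_FIXTURES = {
    "eiffel": _eiffel_fixture,
    "uniform": _uniform_fixture,
    "sperling": _sperling_fixture,
}


def make_fixture(name: str) -> SyntheticDataset:
    """A small canned dataset with analytically forced IA values.

    Available: ``eiffel`` (Word IA = 1, target step at 5/9), ``uniform``
    (Word IA = 0.5), ``sperling`` (all pooled Word IA = 1, Image IA = 1).
    """
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
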