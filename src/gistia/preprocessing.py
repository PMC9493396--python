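"""Deterministic data-cleaning pipeline for free-report word tables.

The pipeline mirrors minimal-curation practice for typed free reports:

1. lowercase (and squeeze any stray whitespace into the hyphen the response
   screen asked participants to use),
2. spell-correction — accepted only when the dictionary proposes exactly one
   candidate, or when a user-supplied manual mapping has an entry; anything
   ambiguous is kept verbatim,
3. lemmatization via a fixed dictionary table shipped with the package, so
   plural/tense variants ("children"/"child", "walked"/"walk") collapse to one
   base form,
4. within-trial deduplication on the *normalized* form, keeping the earliest
   word slot and its confidence.

Every step is a pure function of its inputs: re-running the pipeline on its
own output changes nothing, and every change is logged in the
:class:`CleaningReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

_ASSETS = resources.files("gistia") / "assets"
_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def _read_two_column(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(",")
        if len(parts) != 2:
            raise ValueError(f"expected two columns, got: {line!r}")
        out[parts[0].strip().lower()] = parts[1].strip().lower()
    return out


def load_mapping(path: str | Path) -> dict[str, str]:
    """Load a two-column delimited mapping file (raw, replacement)."""
    return _read_two_column(Path(path).read_text(encoding="utf-8"))


def default_manual_map() -> dict[str, str]:
    """The shipped manual spell-correction map (raw -> replacement)."""
    return _read_two_column((_ASSETS / "manual_map.tsv").read_text())


def default_lemma_table() -> dict[str, str]:
    """The shipped lemma table (inflected form -> base form)."""
    return _read_two_column((_ASSETS / "lemma_table.tsv").read_text())


class Speller:
    """Deterministic dictionary-based spell checker.

    ``suggest`` returns every known word within edit distance one of the
    query (insertions, deletions, substitutions, adjacent transpositions).
    A correction is only ever *applied* by the pipeline when that set has
    exactly one element, which keeps the step reproducible.
    """

    def __init__(self, words: Iterable[str]):
        self.words = frozenset(w.lower() for w in words)

    @classmethod
    def default(cls) -> "Speller":
        text = (_ASSETS / "wordlist.txt").read_text()
        return cls(text.split())

    def known(self, word: str) -> bool:
        return word in self.words

    def _edits1(self, word: str) -> set[str]:
        splits = [(word[:i], word[i:]) for i in range(len(word) + 1)]
        deletes = {a + b[1:] for a, b in splits if b}
        transposes = {a + b[1] + b[0] + b[2:] for a, b in splits if len(b) > 1}
        replaces = {a + c + b[1:] for a, b in splits if b for c in _ALPHABET}
        inserts = {a + c + b for a, b in splits for c in _ALPHABET}
        return deletes | transposes | replaces | inserts

    def suggest(self, word: str) -> list[str]:
        """Sorted known words at edit distance 1 (empty if word is known)."""
        if word in self.words:
            return []
        return sorted(self._edits1(word) & self.words)


@dataclass
class CleaningConfig:
    """Dictionary services used by the pipeline; defaults ship with the package."""

    speller: Speller = field(default_factory=Speller.default)
    lemma_table: dict[str, str] = field(default_factory=default_lemma_table)
    manual_map: dict[str, str] = field(default_factory=default_manual_map)


@dataclass
class CleaningReport:
    """Per-run accounting of what the pipeline changed."""

    n_input_rows: int = 0
    n_dedup_removed: int = 0
    n_spell_corrected: int = 0
    n_lemmatized_changed: int = 0
    mapping_log: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_output_rows(self) -> int:
        return self.n_input_rows - self.n_dedup_removed

    def to_dict(self) -> dict:
        return {
            "n_input_rows": self.n_input_rows,
            "n_output_rows": self.n_output_rows,
            "n_dedup_removed": self.n_dedup_removed,
            "n_spell_corrected": self.n_spell_corrected,
            "n_lemmatized_changed": self.n_lemmatized_changed,
            "mapping_log": [list(m) for m in self.mapping_log],
        }


def normalize_word(
    raw: str,
    speller: Speller,
    lemma_table: Mapping[str, str],
    manual_map: Mapping[str, str],
) -> str:
    """Normalize one typed word: lowercase, spell-correct, lemmatize.

    Hyphens are preserved (participants used them in place of spaces, e.g.
    "sunny-afternoon"); whitespace is converted to hyphens; characters other
    than letters, digits and hyphens are dropped.  Spell-correction only
    touches purely alphabetic words, and only when unambiguous.  Unknown
    words pass through unchanged.  The function is idempotent.
    """
    word = "-".join(raw.strip().lower().split())
    word = "".join(c for c in word if c.isalnum() or c == "-").strip("-")
    if not word:
        return word
    if word in manual_map:
        word = manual_map[word]
    elif word.isalpha() and not speller.known(word):
        suggestions = speller.suggest(word)
        if len(suggestions) == 1:
            word = suggestions[0]
    return lemma_table.get(word, word)


def dedup_within_trial(trial: pd.DataFrame) -> pd.DataFrame:
    """Drop repeated words within one participant x image trial.

    Rows must already carry the normalized ``word`` column and share one
    (participant, image) pair.  The earliest ``word_slot`` of each distinct
    word survives, with its confidence; later repeats are removed.
    """
    if trial.empty:
        return trial
    ordered = trial.sort_values("word_slot", kind="stable")
    return ordered.drop_duplicates(subset="word", keep="first")


def clean_table(
    records: pd.DataFrame,
    config: CleaningConfig | None = None,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the full cleaning pipeline to a response table.

    Returns the cleaned table (with the ``word`` column filled) and a
    :class:`CleaningReport`.  Only ``word`` differs from ``raw_word``;
    participant/image/SOA/confidence fields are untouched.  Deduplication
    compares normalized forms, so spelling/inflection variants of one word
    within a trial collapse to a single row.
    """
    cfg = config or CleaningConfig()
    report = CleaningReport(n_input_rows=len(records))
    if records.empty:
        out = records.copy()
        out["word"] = pd.Series(dtype=str)
        return out, report

    source = (
        records["word"] if "word" in records.columns else records["raw_word"]
    ).astype(str)

    # per unique raw string, trace the three stages once
    stages: dict[str, tuple[str, str, str]] = {}
    for raw in source.unique():
        lowered = "-".join(raw.strip().lower().split())
        lowered = "".join(c for c in lowered if c.isalnum() or c == "-").strip("-")
        spelled = cfg.manual_map.get(lowered, lowered)
        if spelled == lowered and lowered and lowered.isalpha() and not cfg.speller.known(lowered):
            suggestions = cfg.speller.suggest(lowered)
            if len(suggestions) == 1:
                spelled = suggestions[0]
        final = cfg.lemma_table.get(spelled, spelled)
        stages[raw] = (lowered, spelled, final)

    counts = source.value_counts()
    for raw, (lowered, spelled, final) in stages.items():
        n = int(counts[raw])
        if spelled != lowered:
            report.n_spell_corrected += n
        if final != spelled:
            report.n_lemmatized_changed += n
        if final != raw:
            report.mapping_log.append((raw, final))
    report.mapping_log.sort()

    out = records.copy()
    out["word"] = source.map(lambda r: stages[r][2])

    ordered = out.sort_values(
        ["participant_id", "image_id", "word_slot"], kind="stable"
    )
    deduped = ordered.drop_duplicates(
        subset=["participant_id", "image_id", "word"], keep="first"
    ).sort_index()
    report.n_dedup_removed = len(out) - len(deduped)
    return deduped.reset_index(drop=True), report
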