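"""Domain types, study-design bookkeeping and table I/O.

The canonical in-memory container for response data is a :class:`pandas.DataFrame`
with one row per reported word (columns listed in :data:`RESPONSE_COLUMNS`).
Row-level views are available as :class:`ResponseRecord` for typed access.

The experimental design these tables describe: a pool of images is split into
blocks; each participant is assigned one block and sees every image of that
block exactly once, at one of three stimulus onset asynchronies (SOAs).  Within
a block each (image, SOA) cell is seen by a fixed number of participants
(10 in the full design), and every trial yields five freely typed words, each
with a 1-5 confidence rating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Stimulus onset asynchronies (ms) used in the design.
SOA_LEVELS = (67, 133, 267)

#: Canonical column order for response tables.
RESPONSE_COLUMNS = [
    "participant_id",
    "block_id",
    "image_id",
    "soa_ms",
    "trial_index",
    "word_slot",
    "raw_word",
    "word",
    "confidence",
]

#: Columns that must be present on ingest ("word" appears after preprocessing).
REQUIRED_FIELDS = [c for c in RESPONSE_COLUMNS if c != "word"]

#: Shipped column mappings: canonical field -> column header in the source file.
#: "synthetic" is the dialect this package emits.  "osf" is a best-effort map
#: for the public deposit; its headers are configuration, not contract —
#: confirm against the file and override via ``column_map`` if they differ.
DEFAULT_COLUMN_MAPS: dict[str, dict[str, str]] = {
    "synthetic": {c: c for c in RESPONSE_COLUMNS},
    "osf": {
        "participant_id": "subject",
        "block_id": "batch",
        "image_id": "image",
        "soa_ms": "soa",
        "trial_index": "trial",
        "word_slot": "word_order",
        "raw_word": "word_raw",
        "word": "word",
        "confidence": "confidence",
    },
}


class ConfigurationError(ValueError):
    """A required column or configuration entry could not be resolved."""


class ResponseValidationError(ValueError):
    """One or more rows failed type/range validation.

    Attributes
    ----------
    errors : list of (row_number, message) tuples, 0-based positional rows.
    """

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        preview = "; ".join(f"row {i}: {m}" for i, m in errors[:5])
        more = "" if len(errors) <= 5 else f" (+{len(errors) - 5} more)"
        super().__init__(f"{len(errors)} invalid row(s): {preview}{more}")


class DesignViolationError(ValueError):
    """The response table violates the study design (e.g. repeated image)."""


@dataclass(frozen=True)
class ResponseRecord:
    """One reported word with its participant, image, SOA, slot and confidence."""

    participant_id: str
    block_id: int
    image_id: str
    soa_ms: int
    trial_index: int
    word_slot: int
    raw_word: str
    confidence: int
    word: str | None = None


@dataclass(frozen=True)
class SimilarPair:
    """A registered pair of highly similar images."""

    pair_id: str
    image_a: str
    image_b: str
    kind: str  # "natural" | "artificial"

    def partner_of(self, image_id: str) -> str | None:
        if image_id == self.image_a:
            return self.image_b
        if image_id == self.image_b:
            return self.image_a
        return None


@dataclass
class StudyDesign:
    """Static structure of the experiment: images, blocks, similar pairs."""

    images: list[str]
    blocks: dict[int, list[str]]
    similar_pairs: list[SimilarPair] = field(default_factory=list)
    n_per_cell: int = 10

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for b, imgs in self.blocks.items():
            for im in imgs:
                if im in seen:
                    raise DesignViolationError(
                        f"image {im!r} assigned to blocks {seen[im]} and {b}"
                    )
                seen[im] = b

    @property
    def n_images(self) -> int:
        return len(self.images)

    def similar_partner(self, image_id: str) -> str | None:
        """The registered similar partner of ``image_id``, if any."""
        for pair in self.similar_pairs:
            partner = pair.partner_of(image_id)
            if partner is not None:
                return partner
        return None


@dataclass
class CohortIndex:
    """Per-(image, SOA) ordered participant lists.

    ``order`` positions are 1-based, unique and contiguous within a cell.
    The position is what the baseline same-order exclusion keys on.
    """

    cells: dict[tuple[str, int], list[str]]

    def participants(self, image_id: str, soa_ms: int) -> list[str]:
        return self.cells[(image_id, soa_ms)]

    def order_of(self, participant_id: str, image_id: str, soa_ms: int) -> int:
        """1-based order position of a participant within a cell."""
        cell = self.cells[(image_id, soa_ms)]
        try:
            return cell.index(participant_id) + 1
        except ValueError:
            raise KeyError(
                f"participant {participant_id!r} not in cell ({image_id!r}, {soa_ms})"
            ) from None

    def cell_sizes(self) -> dict[tuple[str, int], int]:
        return {k: len(v) for k, v in self.cells.items()}

    def irregular_cells(self, n_per_cell: int) -> list[tuple[str, int, int]]:
        """Cells whose size differs from ``n_per_cell``: (image, soa, size)."""
        return [
            (img, soa, len(v))
            for (img, soa), v in sorted(self.cells.items())
            if len(v) != n_per_cell
        ]

    @property
    def n_trials(self) -> int:
        """Total distinct (participant, image, SOA) trials indexed."""
        return sum(len(v) for v in self.cells.values())


# ---------------------------------------------------------------------------
# Readers / writers


def _resolve_columns(
    df: pd.DataFrame, column_map: Mapping[str, str]
) -> pd.DataFrame:
    missing = [
        canonical
        for canonical in REQUIRED_FIELDS
        if column_map.get(canonical) not in df.columns
    ]
    if missing:
        raise ConfigurationError(
            "column map does not resolve required field(s): "
            + ", ".join(
                f"{c} (mapped to {column_map.get(c)!r})" for c in missing
            )
        )
    rename = {
        column_map[c]: c
        for c in RESPONSE_COLUMNS
        if column_map.get(c) in df.columns
    }
    out = df.rename(columns=rename)
    keep = [c for c in RESPONSE_COLUMNS if c in out.columns]
    return out[keep]


def validate_responses(df: pd.DataFrame) -> list[tuple[int, str]]:
    """Row-level validation; returns (positional row, message) for each failure."""
    errors: list[tuple[int, str]] = []

    def _check(mask: pd.Series, message: str) -> None:
        for pos in (~mask).to_numpy().nonzero()[0]:
            errors.append((int(pos), message))

    _check(df["confidence"].isin([1, 2, 3, 4, 5]), "confidence not in 1..5")
    _check(df["soa_ms"].isin(SOA_LEVELS), f"soa_ms not in {SOA_LEVELS}")
    _check(df["word_slot"].between(1, 5), "word_slot not in 1..5")
    _check(
        df["raw_word"].astype(str).str.len() > 0, "empty raw_word"
    )
    errors.sort()
    return errors


def read_responses(
    path: str | Path,
    column_map: Mapping[str, str] | str = "synthetic",
) -> pd.DataFrame:
    """Read a delimited response table into canonical form.

    Parameters
    ----------
    path
        CSV file, UTF-8, header row, one row per reported word.
    column_map
        Either a mapping from canonical field names to the file's headers or
        the name of a shipped dialect ("synthetic", "osf").

    Raises
    ------
    ConfigurationError
        If a required column cannot be resolved.
    ResponseValidationError
        If any row fails type/range checks (all offending rows are listed;
        nothing is silently dropped).
    """
    if isinstance(column_map, str):
        try:
            column_map = DEFAULT_COLUMN_MAPS[column_map]
        except KeyError:
            raise ConfigurationError(
                f"unknown column-map dialect {column_map!r}; "
                f"available: {sorted(DEFAULT_COLUMN_MAPS)}"
            ) from None
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    df = _resolve_columns(raw, column_map)
    for col in ("block_id", "soa_ms", "trial_index", "word_slot", "confidence"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad_numeric = df[
        ["block_id", "soa_ms", "trial_index", "word_slot", "confidence"]
    ].isna().any(axis=1)
    errors = [
        (int(pos), "non-numeric value in integer column")
        for pos in bad_numeric.to_numpy().nonzero()[0]
    ]
    df = df.fillna({"confidence": -1, "soa_ms": -1, "word_slot": -1})
    errors.extend(
        e for e in validate_responses(df) if not bad_numeric.iloc[e[0]]
    )
    if errors:
        errors.sort()
        raise ResponseValidationError(errors)
    for col in ("block_id", "soa_ms", "trial_index", "word_slot", "confidence"):
        df[col] = df[col].astype(int)
    return df.reset_index(drop=True)


def write_responses(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical response table as UTF-8 CSV (round-trips exactly)."""
    cols = [c for c in RESPONSE_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False, encoding="utf-8")


def read_similar_pairs(path: str | Path) -> list[SimilarPair]:
    """Read a similar-pair registry: pair_id, image_a, image_b, class."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    needed = {"pair_id", "image_a", "image_b", "class"}
    if not needed.issubset(df.columns):
        raise ConfigurationError(
            f"similar-pair registry must have columns {sorted(needed)}"
        )
    return [
        SimilarPair(pid, a, b, kind)
        for pid, a, b, kind in zip(
            df["pair_id"], df["image_a"], df["image_b"], df["class"]
        )
    ]


def write_similar_pairs(pairs: Iterable[SimilarPair], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"pair_id": p.pair_id, "image_a": p.image_a, "image_b": p.image_b,
             "class": p.kind}
            for p in pairs
        ]
    ).to_csv(path, index=False)


def write_result_table(df: pd.DataFrame, stem: str | Path) -> tuple[Path, Path]:
    """Write a result table as both CSV and JSON with identical content.

    Returns the two paths written (``<stem>.csv``, ``<stem>.json``).
    """
    stem = Path(stem)
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")
    df.to_csv(csv_path, index=False, encoding="utf-8")
    records = json.loads(df.to_json(orient="records"))
    json_path.write_text(json.dumps(records, indent=1), encoding="utf-8")
    return csv_path, json_path


# ---------------------------------------------------------------------------
# Cohort construction


def build_cohorts(
    records: pd.DataFrame,
    order_column: str | None = None,
    n_per_cell: int | None = None,
) -> tuple[CohortIndex, StudyDesign]:
    """Index per-(image, SOA) cohorts and recover the study design.

    Participant order within a cell is the rank of first appearance in the
    table unless ``order_column`` names an explicit 1-based order column.
    The order is what the same-order baseline exclusion keys on, so it must
    be stable: re-reading a written table reproduces it.

    Raises
    ------
    DesignViolationError
        If a participant saw the same image more than once.
    """
    trials = records.drop_duplicates(
        subset=["participant_id", "image_id", "soa_ms"]
    )
    dup = trials.duplicated(subset=["participant_id", "image_id"], keep=False)
    if dup.any():
        bad = trials.loc[dup, ["participant_id", "image_id"]].drop_duplicates()
        pairs = [
            f"({r.participant_id!r}, {r.image_id!r})"
            for r in bad.head(5).itertuples(index=False)
        ]
        raise DesignViolationError(
            f"{len(bad)} participant/image pair(s) repeated across trials: "
            + ", ".join(pairs)
        )

    cells: dict[tuple[str, int], list[str]] = {}
    if order_column is not None:
        if order_column not in records.columns:
            raise ConfigurationError(f"order column {order_column!r} not found")
        ordered = records.drop_duplicates(
            subset=["participant_id", "image_id", "soa_ms"]
        ).sort_values(order_column, kind="stable")
        for row in ordered.itertuples(index=False):
            cells.setdefault((row.image_id, row.soa_ms), []).append(
                row.participant_id
            )
    else:
        for row in trials.itertuples(index=False):
            cells.setdefault((row.image_id, row.soa_ms), []).append(
                row.participant_id
            )

    cohorts = CohortIndex(cells)
    sizes = pd.Series(list(cohorts.cell_sizes().values()))
    inferred = n_per_cell if n_per_cell is not None else int(sizes.mode().iloc[0])

    block_map: dict[int, list[str]] = {}
    for row in records.drop_duplicates(subset=["image_id"]).itertuples(
        index=False
    ):
        block_map.setdefault(int(row.block_id), []).append(row.image_id)
    design = StudyDesign(
        images=sorted(records["image_id"].unique()),
        blocks={b: sorted(v) for b, v in sorted(block_map.items())},
        n_per_cell=inferred,
    )
    return cohorts, design
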