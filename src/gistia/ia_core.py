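"""Word IA and Image IA: ROC/AUC specificity of freely reported words.

The intersubjective-agreement (IA) index asks, for one word reported on one
image: how much more often do *other* participants report that word for this
image than for any other image in the set?  For each participant who reported
the word (a "reporter") we form

* the within-image report fraction — how many of the remaining participants
  in the reporter's cohort reported the word for the target image, and
* a baseline report fraction for every other image — how many participants
  of that image's cohort reported the word, with the participant occupying
  the reporter's order position excluded so every fraction shares the same
  denominator.

Sweeping a report-frequency criterion from 100% down to 0% over these yields
two cumulative curves; plotting target against baseline gives an ROC whose
area (AUC) is that reporter's specificity score.  Word IA is the mean AUC
over reporters, defined only when at least two participants reported the
word.  Image IA is the mean of the defined across-SOA Word IAs of an image.

Scopes: ``67 | 133 | 267`` restrict reporters and baselines to one SOA
cohort (denominator ``n_per_cell - 1``, 9 in the full design); ``"pooled"``
uses all three cohorts jointly (denominator ``3*(n_per_cell - 1)``, 27),
excluding the reporter's order position in each of the three cells.

The bulk path compares integer report counts (same denominator on both
sides), so AUCs are exact rationals evaluated in floating point; the curve
construction in :func:`make_curves` / :func:`roc_auc` is the reference
trapezoidal route and agrees with the closed form
``P(b < t) + 0.5 * P(b = t)`` (property-tested).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .data_model import SOA_LEVELS, CohortIndex, StudyDesign, build_cohorts

Scope = Literal[67, 133, 267, "pooled"]

_SOA_INDEX = {soa: i for i, soa in enumerate(SOA_LEVELS)}


class WordNotReportedError(KeyError):
    """The queried word was never reported on the image in the given scope."""


def scope_label(scope: Scope) -> str:
    return "pooled" if scope == "pooled" else f"soa_{scope}"


@dataclass(frozen=True)
class CumulativeCurve:
    """Cumulative report-frequency curve over a descending criterion grid.

    ``cumulative[k]`` is the proportion of units (the target image, or the
    set of other images) whose report fraction is >= ``criteria[k]``.
    """

    criteria: np.ndarray  # descending, from 1.0 to 0.0
    cumulative: np.ndarray  # nondecreasing along the grid

    def __post_init__(self) -> None:
        c = np.asarray(self.criteria, dtype=float)
        y = np.asarray(self.cumulative, dtype=float)
        if np.any(np.diff(c) > 0):
            raise ValueError("criteria must be descending")
        if np.any(np.diff(y) < -1e-12):
            raise ValueError("cumulative must be nondecreasing as criteria descend")
        object.__setattr__(self, "criteria", c)
        object.__setattr__(self, "cumulative", y)


@dataclass(frozen=True)
class WordIAResult:
    """Word IA for one (word, image, scope) group.

    ``ia`` is ``None`` (explicitly undefined, never 0) when fewer than two
    participants reported the word — a "rarely reported word".
    """

    word: str
    image_id: str
    scope: str
    n_reporters: int
    reporter_aucs: tuple[float, ...]
    ia: float | None

    @property
    def defined(self) -> bool:
        return self.ia is not None


@dataclass(frozen=True)
class ImageIAResult:
    """Image IA and rarely-reported-word accounting for one image."""

    image_id: str
    image_ia: float | None
    n_defined_words: int
    n_unique_words: int
    prop_rare: float


# ---------------------------------------------------------------------------
# Curve / AUC primitives (pure functions)


def make_curves(
    within: float, baseline: Sequence[float]
) -> tuple[CumulativeCurve, CumulativeCurve]:
    """Cumulative curves for the target image and the other images.

    The criterion grid is the descending sorted union of the observed
    fractions with the endpoints {1, 0}, so the step curves are exact.
    Returns ``(target_curve, baseline_curve)``.
    """
    b = np.asarray(baseline, dtype=float)
    if not (0.0 <= within <= 1.0) or np.any((b < 0) | (b > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    grid = np.unique(np.concatenate([[0.0, 1.0, within], b]))[::-1]
    target = (within >= grid).astype(float)
    if b.size:
        others = (b[None, :] >= grid[:, None]).mean(axis=1)
    else:
        others = (grid <= 0).astype(float)
    return CumulativeCurve(grid, target), CumulativeCurve(grid, others)


def roc_points(
    target: CumulativeCurve, baseline: CumulativeCurve
) -> tuple[np.ndarray, np.ndarray]:
    """ROC coordinates: baseline cumulative as x, target cumulative as y.

    The origin (0, 0) — the criterion above 100% that no unit passes — is
    prepended so the curve always spans x in [0, 1].
    """
    x = np.concatenate([[0.0], baseline.cumulative])
    y = np.concatenate([[0.0], target.cumulative])
    return x, y


def roc_auc(within: float, baseline: Sequence[float]) -> float:
    """Area under the ROC built from the two cumulative curves (trapezoid)."""
    target, others = make_curves(within, baseline)
    x, y = roc_points(target, others)
    return float(np.trapezoid(y, x))


def auc_closed_form(within: float, baseline: Sequence[float]) -> float:
    """``P(b < t) + 0.5 * P(b = t)`` over the baseline fractions ``b``.

    Algebraically identical to :func:`roc_auc`; kept separate so the two
    routes can check each other.
    """
    b = np.asarray(baseline, dtype=float)
    if b.size == 0:
        raise ValueError("need at least one baseline fraction")
    return float(((b < within).sum() + 0.5 * (b == within).sum()) / b.size)


# ---------------------------------------------------------------------------
# Analysis over a full response table


class IAAnalysis:
    """Word IA / Image IA computations over a cleaned response table.

    Parameters
    ----------
    records
        Cleaned response table (the ``word`` column must be present).
    design, cohorts
        Study design and per-cell participant order; derived from the table
        via :func:`gistia.data_model.build_cohorts` when omitted.  Supply a
        design explicitly to register similar image pairs, whose partners
        are excluded from each other's baselines.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        design: StudyDesign | None = None,
        cohorts: CohortIndex | None = None,
    ):
        if "word" not in records.columns:
            raise ValueError("records must be cleaned first (missing 'word')")
        if design is None or cohorts is None:
            built_cohorts, built_design = build_cohorts(records)
            cohorts = cohorts or built_cohorts
            design = design or built_design
        self.design = design
        self.cohorts = cohorts
        self.n = design.n_per_cell

        order_of: dict[tuple[str, str, int], int] = {}
        for (img, soa), pids in cohorts.cells.items():
            for pos, pid in enumerate(pids):
                order_of[(pid, img, soa)] = pos  # 0-based internally

        df = records.copy()
        df["order0"] = [
            order_of[(p, i, s)]
            for p, i, s in zip(df["participant_id"], df["image_id"], df["soa_ms"])
        ]
        df["soa_idx"] = df["soa_ms"].map(_SOA_INDEX)
        self.records = df

        # report masks: bit (order) per SOA cell; bit (soa_idx*n + order) pooled
        self._soa_masks: dict[tuple[str, int], dict[str, int]] = {}
        self._pooled_masks: dict[str, dict[str, int]] = {}
        n = self.n
        for word, img, s_idx, order in zip(
            df["word"], df["image_id"], df["soa_idx"], df["order0"]
        ):
            self._soa_masks.setdefault((word, s_idx), {}).setdefault(img, 0)
            self._soa_masks[(word, s_idx)][img] |= 1 << order
            self._pooled_masks.setdefault(word, {}).setdefault(img, 0)
            self._pooled_masks[word][img] |= 1 << (s_idx * n + order)

        self._partner = {
            img: design.similar_partner(img) for img in design.images
        }

    # -- scope plumbing ----------------------------------------------------

    def _masks(self, word: str, scope: Scope) -> dict[str, int]:
        if scope == "pooled":
            masks = self._pooled_masks.get(word)
        elif scope in _SOA_INDEX:
            masks = self._soa_masks.get((word, _SOA_INDEX[scope]))
        else:
            raise ValueError(f"scope must be one of {SOA_LEVELS} or 'pooled'")
        if not masks:
            raise WordNotReportedError(
                f"word {word!r} was never reported in scope {scope!r}"
            )
        return masks

    def _excl_mask(self, order0: int, scope: Scope) -> int:
        n = self.n
        if scope == "pooled":
            return (1 << order0) | (1 << (n + order0)) | (1 << (2 * n + order0))
        return 1 << order0

    def _denominator(self, scope: Scope) -> int:
        return 3 * (self.n - 1) if scope == "pooled" else self.n - 1

    # -- spec operations ---------------------------------------------------

    def within_fraction(
        self, word: str, image_id: str, scope: Scope, reporter_id: str
    ) -> float:
        """Fraction of the reporter's remaining cohort that reported the word.

        Per-SOA scope: over the other ``n-1`` participants of the reporter's
        (image, SOA) cell.  Pooled scope: over ``3*(n-1)`` participants — all
        of the image's participants minus the reporter and minus the
        participant at the reporter's order position in each other SOA cell.
        """
        masks = self._masks(word, scope)
        if image_id not in masks:
            raise WordNotReportedError(
                f"word {word!r} was never reported on image {image_id!r}"
            )
        row = self.records
        mine = row[
            (row["participant_id"] == reporter_id)
            & (row["image_id"] == image_id)
            & (row["word"] == word)
        ]
        if scope != "pooled":
            mine = mine[mine["soa_ms"] == scope]
        if mine.empty:
            raise ValueError(
                f"participant {reporter_id!r} did not report {word!r} "
                f"on {image_id!r} in scope {scope!r}"
            )
        order0 = int(mine["order0"].iloc[0])
        count = (masks[image_id] & ~self._excl_mask(order0, scope)).bit_count()
        return count / self._denominator(scope)

    def baseline_fractions(
        self,
        word: str,
        scope: Scope,
        target_image: str,
        reporter_order: int,
        exclude_similar: bool = True,
    ) -> np.ndarray:
        """Baseline report fraction of ``word`` for every non-target image.

        ``reporter_order`` is the 1-based order position of the reporter;
        the participant at that position in each baseline cell is excluded
        so all fractions share the reporter's denominator.  When the target
        has a registered similar partner and ``exclude_similar`` is set, the
        partner is dropped from the baseline (one fewer image).
        """
        try:
            masks = self._masks(word, scope)
        except WordNotReportedError:
            masks = {}
        excl = self._excl_mask(reporter_order - 1, scope)
        denom = self._denominator(scope)
        partner = self._partner.get(target_image) if exclude_similar else None
        out = [
            (masks.get(img, 0) & ~excl).bit_count() / denom
            for img in self.design.images
            if img != target_image and img != partner
        ]
        return np.asarray(out, dtype=float)

    def word_ia(
        self, word: str, image_id: str, scope: Scope, exclude_similar: bool = True
    ) -> WordIAResult:
        """Word IA of one (word, image) group in one scope.

        One AUC per reporter (their own leave-one-out within-fraction against
        the shared baseline construction, which shifts with reporter order);
        ``ia`` is their mean, undefined below two reporters.
        """
        masks = self._masks(word, scope)
        if image_id not in masks:
            raise WordNotReportedError(
                f"word {word!r} was never reported on image {image_id!r} "
                f"in scope {scope!r}"
            )
        return self._word_table_for_masks(
            word, masks, scope, exclude_similar, only_image=image_id
        )[0]

    def word_ia_table(
        self, scope: Scope, exclude_similar: bool = True
    ) -> pd.DataFrame:
        """Word IA for every (word, image) group observed in ``scope``.

        Returns one row per group: word, image_id, scope, n_reporters, ia
        (NaN when undefined) and the defined flag.
        """
        rows = []
        if scope == "pooled":
            words: Iterable[str] = self._pooled_masks
        else:
            s = _SOA_INDEX[scope]
            words = [w for (w, si) in self._soa_masks if si == s]
        for word in words:
            masks = self._masks(word, scope)
            for res in self._word_table_for_masks(word, masks, scope, exclude_similar):
                rows.append(
                    {
                        "word": res.word,
                        "image_id": res.image_id,
                        "scope": res.scope,
                        "n_reporters": res.n_reporters,
                        "ia": np.nan if res.ia is None else res.ia,
                        "defined": res.defined,
                    }
                )
        out = pd.DataFrame(
            rows,
            columns=["word", "image_id", "scope", "n_reporters", "ia", "defined"],
        )
        return out.sort_values(["image_id", "word"], ignore_index=True)

    # -- bulk kernel --------------------------------------------------------

    def _word_table_for_masks(
        self,
        word: str,
        masks: dict[str, int],
        scope: Scope,
        exclude_similar: bool,
        only_image: str | None = None,
    ) -> list[WordIAResult]:
        """Per-reporter AUCs for one word's report masks, vectorised by order.

        Counts are compared as integers (identical denominators on both
        sides), which is exactly the closed form P(b<t) + 0.5*P(b=t) of the
        trapezoidal ROC area.
        """
        n = self.n
        label = scope_label(scope)
        img_ids = list(masks)
        idx = {img: k for k, img in enumerate(img_ids)}
        m = np.array([masks[i] for i in img_ids], dtype=np.int64)
        n_images = self.design.n_images

        # counts with the order-o participant(s) excluded, per order column
        C = np.empty((len(img_ids), n), dtype=np.int64)
        for o in range(n):
            C[:, o] = np.bitwise_count(m & ~np.int64(self._excl_mask(o, scope)))
        sorted_cols = np.sort(C, axis=0)

        results: list[WordIAResult] = []
        for ii, img in enumerate(img_ids):
            if only_image is not None and img != only_image:
                continue
            bits = int(m[ii])
            reporter_orders = sorted(
                (b % n) if scope == "pooled" else b
                for b in range(bits.bit_length())
                if bits >> b & 1
            )
            n_reporters = bits.bit_count()
            partner = self._partner.get(img) if exclude_similar else None
            jj = idx.get(partner) if partner is not None else None
            n_other = n_images - 1 - (1 if partner is not None else 0)
            # images where the word was never reported contribute b = 0
            n_absent = n_other - (len(img_ids) - 1 - (1 if jj is not None else 0))

            aucs = []
            for o in reporter_orders:
                t = int(C[ii, o])
                col = sorted_cols[:, o]
                less = int(np.searchsorted(col, t, side="left"))
                eq = int(np.searchsorted(col, t, side="right")) - less
                eq -= 1  # own image's entry equals t by construction
                if jj is not None:
                    v = int(C[jj, o])
                    if v < t:
                        less -= 1
                    elif v == t:
                        eq -= 1
                if t > 0:
                    less += n_absent
                else:
                    eq += n_absent
                aucs.append((less + 0.5 * eq) / n_other)

            ia = float(np.mean(aucs)) if n_reporters >= 2 else None
            results.append(
                WordIAResult(
                    word=word,
                    image_id=img,
                    scope=label,
                    n_reporters=n_reporters,
                    reporter_aucs=tuple(aucs),
                    ia=ia,
                )
            )
        return results

    # -- image-level summaries ----------------------------------------------

    def image_ia_table(self, exclude_similar: bool = True) -> pd.DataFrame:
        """Image IA (mean defined pooled Word IA) and rare-word proportion."""
        words = self.word_ia_table("pooled", exclude_similar=exclude_similar)
        rows = []
        for img in self.design.images:
            sub = words[words["image_id"] == img]
            defined = sub[sub["defined"]]
            n_unique = len(sub)
            n_rare = int((sub["n_reporters"] == 1).sum())
            rows.append(
                {
                    "image_id": img,
                    "image_ia": defined["ia"].mean() if len(defined) else np.nan,
                    "n_defined_words": len(defined),
                    "n_unique_words": n_unique,
                    "prop_rare": n_rare / n_unique if n_unique else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def image_ia(self, image_id: str, exclude_similar: bool = True) -> ImageIAResult:
        table = self.image_ia_table(exclude_similar=exclude_similar)
        row = table[table["image_id"] == image_id]
        if row.empty:
            raise KeyError(f"image {image_id!r} not in design")
        r = row.iloc[0]
        return ImageIAResult(
            image_id=image_id,
            image_ia=None if pd.isna(r["image_ia"]) else float(r["image_ia"]),
            n_defined_words=int(r["n_defined_words"]),
            n_unique_words=int(r["n_unique_words"]),
            prop_rare=float(r["prop_rare"]),
        )


def ia_summary(word_table: pd.DataFrame) -> pd.DataFrame:
    """Distribution summary of defined IA values, per scope.

    One row per scope with mean, sd, median, quartiles of defined IAs and
    the counts of defined vs rarely-reported (word, image) groups.

    Raises ``ValueError`` when no scope has any defined IA.
    """
    if word_table.empty:
        raise ValueError("empty IA table")
    rows = []
    for scope, sub in word_table.groupby("scope"):
        defined = sub.loc[sub["defined"], "ia"]
        rows.append(
            {
                "scope": scope,
                "n_groups": len(sub),
                "n_defined": len(defined),
                "n_rare": int((sub["n_reporters"] == 1).sum()),
                "mean": defined.mean(),
                "sd": defined.std(ddof=1),
                "median": defined.median(),
                "q25": defined.quantile(0.25),
                "q75": defined.quantile(0.75),
            }
        )
    out = pd.DataFrame(rows)
    if out["n_defined"].sum() == 0:
        raise ValueError("no defined IA values in any scope")
    return out
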