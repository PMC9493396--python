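"""Headline analyses on top of the IA tables: correlations and rankings.

These are the summary statistics a study of report specificity leads with:
does the specificity of a word (its IA) track the confidence with which it
was reported, are images with many one-off words also the inconsistently
described ones, and which images are described most (least) consistently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .ia_core import IAAnalysis, Scope, scope_label


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its df, Fisher-z CI and p value."""

    r: float
    df: int
    ci: tuple[float, float]
    p: float
    n: int

    def __str__(self) -> str:  # journal-style one-liner
        return (
            f"r = {self.r:.2f}, df = {self.df}, p = {self.p:.3g}, "
            f"95%CI = [{self.ci[0]:.2f}, {self.ci[1]:.2f}]"
        )


def _pearson(x: np.ndarray, y: np.ndarray, ci_level: float = 0.95) -> CorrelationResult:
    if len(x) < 3:
        raise ValueError(f"need at least 3 points, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: an input is constant")
    r, p = stats.pearsonr(x, y)
    n = len(x)
    if 1.0 - abs(r) < 1e-12:  # Fisher z diverges; the CI collapses onto r
        ci = (float(r), float(r))
    else:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.5 + ci_level / 2) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return CorrelationResult(r=float(r), df=n - 2, ci=ci, p=float(p), n=n)


def _reporter_confidences(analysis: IAAnalysis) -> pd.DataFrame:
    """One row per (reporter, word, image): confidence and SOA."""
    return analysis.records[
        ["participant_id", "word", "image_id", "soa_ms", "confidence"]
    ]


def correlate_ia_confidence(
    analysis: IAAnalysis,
    level: Literal["word_pooled", "response_per_soa"] = "word_pooled",
    soa: int | None = None,
    exclude_dont_know: bool = False,
) -> CorrelationResult:
    """Pearson correlation between IA and confidence.

    ``word_pooled``: one point per defined (word, image) group — x is the
    mean confidence across the group's reporters, y the pooled Word IA.
    ``response_per_soa``: one point per individual response whose word has
    a defined Word IA at ``soa`` — x is that response's confidence, y the
    word's per-SOA IA.  ``exclude_dont_know`` drops confidence-1 responses
    (participants were told to pad with arbitrary words at confidence 1).
    """
    conf = _reporter_confidences(analysis)
    if exclude_dont_know:
        conf = conf[conf["confidence"] > 1]

    if level == "word_pooled":
        table = analysis.word_ia_table("pooled")
        defined = table[table["defined"]]
        mean_conf = (
            conf.groupby(["word", "image_id"])["confidence"].mean().rename("conf")
        )
        merged = defined.merge(mean_conf, on=["word", "image_id"], how="inner")
        return _pearson(merged["conf"].to_numpy(), merged["ia"].to_numpy())

    if level == "response_per_soa":
        if soa is None:
            raise ValueError("response_per_soa level needs an explicit soa")
        table = analysis.word_ia_table(soa)
        defined = table[table["defined"]][["word", "image_id", "ia"]]
        responses = conf[conf["soa_ms"] == soa]
        merged = responses.merge(defined, on=["word", "image_id"], how="inner")
        return _pearson(
            merged["confidence"].to_numpy(dtype=float), merged["ia"].to_numpy()
        )

    raise ValueError(f"unknown level {level!r}")


def correlate_rare_vs_imageia(analysis: IAAnalysis) -> CorrelationResult:
    """Correlation between an image's rare-word proportion and its Image IA."""
    table = analysis.image_ia_table()
    defined = table.dropna(subset=["image_ia", "prop_rare"])
    return _pearson(
        defined["prop_rare"].to_numpy(), defined["image_ia"].to_numpy()
    )


def rank_images(
    analysis: IAAnalysis,
    direction: Literal["top", "bottom"] = "top",
    k: int = 5,
    words_per_image: int = 5,
) -> pd.DataFrame:
    """The ``k`` most (least) consistently described images with their words.

    One row per displayed word: image rank, Image IA, rare-word proportion,
    then the image's words ordered by Word IA descending (for ``top``) or
    ascending (for ``bottom``), ties broken by report frequency descending,
    then lexicographically.  Frequencies and mean confidences accompany each
    word.
    """
    if direction not in ("top", "bottom"):
        raise ValueError("direction must be 'top' or 'bottom'")
    images = analysis.image_ia_table().dropna(subset=["image_ia"])
    if k > len(images):
        warnings.warn(
            f"requested k={k} images but only {len(images)} have a defined "
            "Image IA; truncating", stacklevel=2,
        )
        k = len(images)
    ascending = direction == "bottom"
    chosen = images.sort_values(
        ["image_ia", "image_id"], ascending=[ascending, True], kind="stable"
    ).head(k)

    words = analysis.word_ia_table("pooled")
    words = words[words["defined"]]
    conf = (
        _reporter_confidences(analysis)
        .groupby(["word", "image_id"])["confidence"]
        .mean()
        .rename("mean_confidence")
    )
    words = words.merge(conf, on=["word", "image_id"], how="left")

    rows = []
    for rank, img_row in enumerate(chosen.itertuples(index=False), start=1):
        sub = words[words["image_id"] == img_row.image_id].copy()
        sub = sub.sort_values(
            ["ia", "n_reporters", "word"],
            ascending=[ascending, False, True],
            kind="stable",
        ).head(words_per_image)
        for w in sub.itertuples(index=False):
            rows.append(
                {
                    "rank": rank,
                    "image_id": img_row.image_id,
                    "image_ia": img_row.image_ia,
                    "prop_rare": img_row.prop_rare,
                    "word": w.word,
                    "word_ia": w.ia,
                    "frequency": w.n_reporters,
                    "mean_confidence": w.mean_confidence,
                }
            )
    return pd.DataFrame(rows)


def model_ready_table(analysis: IAAnalysis) -> pd.DataFrame:
    """Per-response points for external mixed-model software.

    One row per individual response whose word has a defined per-SOA Word
    IA: participant, image, word, SOA, confidence and the word's IA.  The
    package deliberately does not fit multilevel models itself; this export
    feeds lme4-style tooling.
    """
    frames = []
    for soa in (67, 133, 267):
        table = analysis.word_ia_table(soa)
        defined = table[table["defined"]][["word", "image_id", "ia"]]
        conf = _reporter_confidences(analysis)
        sub = conf[conf["soa_ms"] == soa].merge(
            defined, on=["word", "image_id"], how="inner"
        )
        frames.append(sub)
    return pd.concat(frames, ignore_index=True).rename(columns={"ia": "word_ia"})
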