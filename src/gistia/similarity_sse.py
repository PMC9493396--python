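"""Report-frequency consistency between image pairs (SSE) and its bootstrap null.

Two highly similar images shown to two disjoint participant cohorts should
elicit near-identical word-frequency profiles.  Plotting each word's report
frequency for image A against image B, perfect consistency puts every point
on the y = x line; the SSE statistic sums the squared distances of the
points from that line over the union of reported words.

Distance conventions
--------------------
``perpendicular`` (default): squared Euclidean distance from (fA, fB) to the
y = x line, ``(fA - fB)**2 / 2``.  ``vertical``: ``(fA - fB)**2``.  The two
differ by an overall factor of 2 and never change orderings; the switch
exists because published SSE figures do not always state which was used.

The null distribution is built by re-pairing: from a pool of registered
similar pairs, each iteration picks one image per pair and re-partners it
with a random different image from the pool, recording the mean SSE of the
re-paired set.  Self-pairing is disallowed (it would contribute SSE = 0 and
bias the null toward consistency).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import SimilarPair

CONVENTIONS = ("perpendicular", "vertical")


def _scale(convention: str) -> float:
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    return 0.5 if convention == "perpendicular" else 1.0


@dataclass
class SSEResult:
    """SSE between two images' report-frequency vectors."""

    image_a: str
    image_b: str
    sse: float
    convention: str
    per_word_contributions: dict[str, float] = field(default_factory=dict)
    null_means: np.ndarray | None = None
    null_ci: tuple[float, float] | None = None


@dataclass
class BootstrapNull:
    """Null distribution of mean SSE under random re-pairing."""

    means: np.ndarray
    ci: tuple[float, float]
    ci_level: float


def frequency_vector(records: pd.DataFrame, image_id: str) -> dict[str, int]:
    """Number of distinct participants (across SOAs) reporting each word.

    With the full design each count is between 1 and 30; unreported words
    are absent (they enter pair unions as 0).
    """
    sub = records[records["image_id"] == image_id]
    counts = sub.groupby("word")["participant_id"].nunique()
    return {str(w): int(c) for w, c in counts.items()}


def sse_from_vectors(
    freq_a: Mapping[str, int],
    freq_b: Mapping[str, int],
    convention: str = "perpendicular",
) -> tuple[float, dict[str, float]]:
    """SSE and per-word contributions over the union of the two vocabularies."""
    scale = _scale(convention)
    contributions = {}
    for word in sorted(set(freq_a) | set(freq_b)):
        d = freq_a.get(word, 0) - freq_b.get(word, 0)
        contributions[word] = scale * d * d
    return float(sum(contributions.values())), contributions


def sse_pair(
    records: pd.DataFrame,
    image_a: str,
    image_b: str,
    convention: str = "perpendicular",
) -> SSEResult:
    """SSE between two images' reports; symmetric, 0 iff identical vectors."""
    fa = frequency_vector(records, image_a)
    fb = frequency_vector(records, image_b)
    sse, contrib = sse_from_vectors(fa, fb, convention)
    return SSEResult(
        image_a=image_a,
        image_b=image_b,
        sse=sse,
        convention=convention,
        per_word_contributions=contrib,
    )


def bootstrap_null(
    records: pd.DataFrame,
    pairs: Sequence[SimilarPair],
    n_iter: int = 100,
    seed: int | np.random.Generator = 0,
    convention: str = "perpendicular",
    ci_level: float = 0.99,
) -> BootstrapNull:
    """Null distribution of mean SSE over randomly re-paired pool images.

    Each iteration: for every registered pair, select one of its two images
    at random and partner it with a uniformly drawn *different* image from
    the pooled set of pair members; the mean SSE over these re-pairs is one
    null sample.  Returns all ``n_iter`` means and a central percentile
    interval at ``ci_level``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    pool = sorted({img for p in pairs for img in (p.image_a, p.image_b)})
    if len(pool) < 2:
        raise ValueError("need at least two images in the pool")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    freqs = {img: frequency_vector(records, img) for img in pool}

    means = np.empty(n_iter)
    for it in range(n_iter):
        total = 0.0
        for p in pairs:
            chosen = p.image_a if rng.integers(2) == 0 else p.image_b
            partner = chosen
            while partner == chosen:
                partner = pool[rng.integers(len(pool))]
            total += sse_from_vectors(freqs[chosen], freqs[partner], convention)[0]
        means[it] = total / len(pairs)

    alpha = (1.0 - ci_level) / 2.0
    ci = (
        float(np.quantile(means, alpha)),
        float(np.quantile(means, 1.0 - alpha)),
    )
    return BootstrapNull(means=means, ci=ci, ci_level=ci_level)


def similar_pair_table(
    records: pd.DataFrame,
    pairs: Sequence[SimilarPair],
    convention: str = "perpendicular",
) -> pd.DataFrame:
    """SSE for every registered pair: pair_id, images, class, sse."""
    rows = []
    for p in pairs:
        res = sse_pair(records, p.image_a, p.image_b, convention)
        rows.append(
            {
                "pair_id": p.pair_id,
                "image_a": p.image_a,
                "image_b": p.image_b,
                "class": p.kind,
                "sse": res.sse,
            }
        )
    return pd.DataFrame(rows)
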