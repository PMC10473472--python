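"""Ordinal russet-severity scoring of whole fruit.

Russet severity is rated per fruit on a 0-4 scale from the russeted
fraction of the surface: score 0 for a russet-free fruit, 1 for up to
10% russeted, 2 for up to 25%, 3 for up to 50% and 4 beyond.  The
printed integer bins are extended to continuous fractions as half-open
intervals (0, 10], (10, 25], (25, 50], (50, 100], so every fraction in
[0, 100] maps to exactly one score and any russet at all earns at least
score 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: Upper bin edges for scores 1..4 (score 0 is reserved for exactly 0%).
_BIN_UPPER = (10.0, 25.0, 50.0)


@dataclass(frozen=True)
class RussetRecord:
    """One fruit: its russeted surface fraction and ordinal score."""

    fruit_id: str
    russet_fraction_pct: float
    score: int


@dataclass(frozen=True)
class SeveritySummary:
    """Population summary of ordinal russet scores."""

    n: int
    mean_score: float
    se_score: float | None
    histogram: tuple[int, int, int, int, int]  # counts for scores 0..4


def russet_score(fraction_pct: float) -> int:
    """Map a russeted-area fraction (%) to the ordinal 0-4 score."""
    if not 0.0 <= fraction_pct <= 100.0:
        raise ValueError("russet fraction must lie in [0, 100] %")
    if fraction_pct == 0.0:
        return 0
    return int(np.searchsorted(_BIN_UPPER, fraction_pct, side="left")) + 1


def score_population(
    fractions: Iterable[float], fruit_ids: Sequence[str] | None = None
) -> list[RussetRecord]:
    """Score a population of russet fractions."""
    fractions = list(fractions)
    if fruit_ids is None:
        fruit_ids = [f"fruit-{i + 1:04d}" for i in range(len(fractions))]
    if len(fruit_ids) != len(fractions):
        raise ValueError("fruit_ids and fractions must have equal length")
    return [
        RussetRecord(fid, float(f), russet_score(float(f)))
        for fid, f in zip(fruit_ids, fractions)
    ]


def severity_summary(records: Sequence[RussetRecord]) -> SeveritySummary:
    """Mean score +/- SE and the score histogram for a population."""
    if not records:
        raise ValueError("need at least one record")
    scores = np.array([r.score for r in records], dtype=float)
    hist = np.bincount(scores.astype(int), minlength=5)
    se = (
        float(scores.std(ddof=1) / math.sqrt(scores.size))
        if scores.size >= 2
        else None
    )
    return SeveritySummary(
        n=int(scores.size),
        mean_score=float(scores.mean()),
        se_score=se,
        histogram=tuple(int(c) for c in hist[:5]),
    )


def plot_histogram(summary: SeveritySummary, path: str) -> None:
    """Render the score histogram to a PNG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(range(5), summary.histogram, color="peru")
    ax.set_xlabel("russet score")
    ax.set_ylabel("fruit count")
    ax.set_xticks(range(5))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
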