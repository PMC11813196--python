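"""System Usability Scale (SUS) scoring and multi-user summaries.

The SUS is the standard 10-item usability questionnaire, each item rated
1-5, with alternating polarity: odd-numbered items are worded positively
(item rating contributes ``rating - 1``), even-numbered items negatively
(contributes ``5 - rating``). The contribution sum (0-40) is multiplied by
2.5, giving a score from 0 to 100 in steps of 2.5; higher is better. Scores
above 68 are conventionally read as above average and scores above 80 as
top-decile usability. Input must follow instrument item order — no
reverse-scoring auto-detection is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ResponseDomainError

__all__ = ["SusResponse", "SusSummary", "read_sus_csv", "sus_score", "sus_summary"]

N_ITEMS = 10


@dataclass(frozen=True)
class SusResponse:
    """One respondent's ten ratings, in instrument order."""

    respondent: str
    ratings: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.ratings) != N_ITEMS:
            raise ResponseDomainError(
                f"SUS requires exactly {N_ITEMS} ratings, got {len(self.ratings)}"
            )
        for n, r in enumerate(self.ratings, start=1):
            if not isinstance(r, int) or not 1 <= r <= 5:
                raise ResponseDomainError(
                    f"SUS item {n} rating must be an integer in [1, 5], got {r!r}"
                )


def sus_score(resp: SusResponse) -> float:
    """Standard SUS score in [0, 100] (always a multiple of 2.5)."""
    contributions = 0
    for n, rating in enumerate(resp.ratings, start=1):
        contributions += (rating - 1) if n % 2 == 1 else (5 - rating)
    return contributions * 2.5


@dataclass(frozen=True)
class SusSummary:
    n: int
    mean: float
    min: float
    max: float
    scores: tuple[float, ...]

    def percent_above(self, threshold: float) -> float:
        """Percentage of respondents scoring strictly above *threshold*
        (use 68 for the above-average benchmark, 80 for top decile)."""
        return 100.0 * sum(s > threshold for s in self.scores) / self.n

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "min": self.min,
            "max": self.max,
            "percent_above_68": self.percent_above(68),
            "percent_above_80": self.percent_above(80),
        }


def sus_summary(responses: Sequence[SusResponse]) -> SusSummary:
    """Arithmetic mean and range over one or more scored responses."""
    if not responses:
        raise ResponseDomainError("SUS summary requires at least one response")
    scores = tuple(sus_score(r) for r in responses)
    return SusSummary(
        n=len(scores),
        mean=sum(scores) / len(scores),
        min=min(scores),
        max=max(scores),
        scores=scores,
    )


def read_sus_csv(path: str | Path) -> list[SusResponse]:
    """Read responses from a CSV with header ``respondent,q1..q10``."""
    frame = pd.read_csv(path)
    expected = ["respondent"] + [f"q{i}" for i in range(1, N_ITEMS + 1)]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ResponseDomainError(f"{path}: missing SUS columns {missing}")
    out = []
    for _, row in frame.iterrows():
        out.append(
            SusResponse(
                respondent=str(row["respondent"]),
                ratings=tuple(int(row[f"q{i}"]) for i in range(1, N_ITEMS + 1)),
            )
        )
    return out
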