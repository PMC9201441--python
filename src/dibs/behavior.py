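"""Scoring of dyadic idea-generation behaviour.

Two participants take turns producing ideas (alternative uses in the creative
condition, object characteristics in the control condition).  Individual
performance is scored by fluency (non-redundant ideas), originality (ideas
produced by at most 5% of the cohort) and flexibility (categories / fluency);
dyad scores are member sums.  Cooperation is quantified by the index of
cooperation

    IOC = converge / (group fluency - converge)

where ``converge`` counts responses (second onward, in the merged
chronological log) whose category matches the immediately preceding
substantive response.  "Pass" turns produce no category and are skipped: the
previous substantive response stays the comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Response",
    "ResponseLog",
    "BehaviorScores",
    "normalize_key",
    "score_fluency",
    "score_originality",
    "score_flexibility",
    "compute_ioc",
    "interrater_icc",
]


def normalize_key(s: str) -> str:
    """Canonical form of a response string: lower-cased, whitespace collapsed."""
    return " ".join(s.strip().lower().split())


@dataclass(frozen=True)
class Response:
    speaker: int  # 1 or 2
    t: float  # seconds from task start
    key: str  # normalized response string
    category: str | None  # None for a "pass" turn
    is_pass: bool = False


@dataclass
class ResponseLog:
    """Merged chronological idea log of one dyad for one task."""

    task: str  # "AUT" or "OCT"
    records: list[Response] = field(default_factory=list)

    def __post_init__(self) -> None:
        ts = [r.t for r in self.records]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("response timestamps must be strictly increasing")
        for r in self.records:
            if r.speaker not in (1, 2):
                raise ValueError("speaker must be 1 or 2")
            if not r.is_pass and r.category is None:
                raise ValueError("substantive responses need a category")

    def substantive(self) -> list[Response]:
        return [r for r in self.records if not r.is_pass]

    def participant_keys(self, speaker: int) -> list[str]:
        return [r.key for r in self.substantive() if r.speaker == speaker]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "task": self.task,
                "speaker": [r.speaker for r in self.records],
                "t": [r.t for r in self.records],
                "response": [r.key for r in self.records],
                "category": [r.category if r.category is not None else "" for r in self.records],
                "is_pass": [r.is_pass for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, task: str | None = None) -> "ResponseLog":
        task = task if task is not None else str(df["task"].iloc[0])
        records = [
            Response(
                speaker=int(row.speaker),
                t=float(row.t),
                key=normalize_key(str(row.response)),
                category=None if bool(row.is_pass) else str(row.category),
                is_pass=bool(row.is_pass),
            )
            for row in df.itertuples()
        ]
        return cls(task=task, records=records)


@dataclass
class BehaviorScores:
    fluency: dict[int, int]
    originality: dict[int, float] | None
    flexibility: dict[int, float] | None
    converge: int
    ioc: float

    @property
    def dyad_fluency(self) -> int:
        return sum(self.fluency.values())


def score_fluency(log: ResponseLog) -> dict[int, int]:
    """Non-redundant response count per participant.

    Duplicates (same participant, same normalized key) count once.
    """
    return {sp: len(set(log.participant_keys(sp))) for sp in (1, 2)}


def score_originality(cohort_keys: list[set[str]], threshold: float = 0.05) -> list[int]:
    """Objective originality: one point per response given by <= ``threshold``
    of the cohort's participants.

    Parameters
    ----------
    cohort_keys:
        One set of normalized response keys per participant, whole cohort.

    Returns
    -------
    One integer score per participant, in input order.
    """
    n = len(cohort_keys)
    if n < 2:
        raise ValueError("originality needs a cohort of >= 2 participants")
    counts: dict[str, int] = {}
    for keys in cohort_keys:
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
    return [sum(1 for k in keys if counts[k] / n <= threshold) for keys in cohort_keys]


def score_flexibility(log: ResponseLog) -> dict[int, float | None]:
    """Distinct categories divided by fluency, per participant.

    Compensates fluent participants who stay within few categories. ``None``
    when fluency is zero (undefined).
    """
    out: dict[int, float | None] = {}
    for sp in (1, 2):
        resp = [r for r in log.substantive() if r.speaker == sp]
        fluency = len({r.key for r in resp})
        if fluency == 0:
            out[sp] = None
        else:
            out[sp] = len({r.category for r in resp}) / fluency
    return out


def compute_ioc(log: ResponseLog) -> tuple[int, float]:
    """Converge count and index of cooperation for a merged dyad log.

    ``converge`` scans the substantive responses in chronological order and
    counts those (second onward) whose category equals the previous one.
    Group fluency is the member sum of non-redundant counts.
    """
    resp = log.substantive()
    converge = sum(1 for a, b in zip(resp, resp[1:]) if a.category == b.category)
    group_fluency = sum(score_fluency(log).values())
    if group_fluency <= converge:
        raise ZeroDivisionError(
            f"IOC undefined: converge ({converge}) >= group fluency ({group_fluency})"
        )
    return converge, converge / (group_fluency - converge)


def interrater_icc(rater1, rater2) -> float:
    """Inter-rater consistency as Cronbach's alpha for two raters.

    alpha = 2 * (1 - (V1 + V2) / V_total), with V_total the variance of the
    rater sum. Returns NaN (with a warning) when the total variance is zero.
    """
    r1 = np.asarray(rater1, dtype=float)
    r2 = np.asarray(rater2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("rater score vectors must be equal-length 1-D")
    if r1.size < 3:
        raise ValueError("need >= 3 subjects")
    v_tot = np.var(r1 + r2, ddof=1)
    if v_tot == 0:
        import warnings

        warnings.warn("zero total variance: Cronbach's alpha undefined", stacklevel=2)
        return float("nan")
    return float(2.0 * (1.0 - (np.var(r1, ddof=1) + np.var(r2, ddof=1)) / v_tot))


def score_dyad(log: ResponseLog) -> BehaviorScores:
    """Fluency, flexibility and IOC for one dyad log (originality needs the
    whole cohort; see :func:`score_originality`)."""
    converge, ioc = compute_ioc(log)
    return BehaviorScores(
        fluency=score_fluency(log),
        originality=None,
        flexibility=score_flexibility(log),  # type: ignore[arg-type]
        converge=converge,
        ioc=ioc,
    )
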