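"""Scoring of the four developmental assessments.

Three phonological-awareness tasks (rhyme production, onset segment
deletion, phoneme synthesis) each comprise 12 targets; expressive
vocabulary is a picture-naming task with a configurable item count.
Inputs are pre-judged correctness flags -- whether a child's response
counts as a correct rhyme is a human judgment made upstream.

The composite phonemic-awareness score (composite PA) is the sum of the
two phoneme-level tasks, onset deletion and phoneme synthesis, giving a
0-24 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

N_ITEMS = 12  # targets per phonological-awareness task
COMPOSITE_MAX = 2 * N_ITEMS

TASKS = ("rhyme", "onset_deletion", "phoneme_synthesis", "composite_pa", "vocabulary")


class SchemaError(ValueError):
    """Raised when a response sheet does not match the task structure."""


@dataclass
class SkillScores:
    """Per-child scores on the behavioral assessments.

    A score of ``None`` marks a task the child did not complete (one
    first-grader skipped the rhyming task in the study design this
    mirrors); missing values propagate -- they never silently become 0.
    """

    speaker_id: str
    rhyme: Optional[int] = None
    onset_deletion: Optional[int] = None
    phoneme_synthesis: Optional[int] = None
    vocabulary: Optional[int] = None
    vocabulary_max: int = 36
    cohort: Optional[str] = None

    def __post_init__(self) -> None:
        for name, hi in (
            ("rhyme", N_ITEMS),
            ("onset_deletion", N_ITEMS),
            ("phoneme_synthesis", N_ITEMS),
            ("vocabulary", self.vocabulary_max),
        ):
            v = getattr(self, name)
            if v is None:
                continue
            if not (0 <= int(v) <= hi):
                raise ValueError(f"{name}={v} outside [0, {hi}]")
            setattr(self, name, int(v))

    @property
    def composite_pa(self) -> Optional[int]:
        return composite_pa(self.onset_deletion, self.phoneme_synthesis)

    def to_dict(self) -> dict:
        return {
            "speaker_id": self.speaker_id,
            "cohort": self.cohort,
            "rhyme": self.rhyme,
            "onset_deletion": self.onset_deletion,
            "phoneme_synthesis": self.phoneme_synthesis,
            "composite_pa": self.composite_pa,
            "vocabulary": self.vocabulary,
            "vocabulary_max": self.vocabulary_max,
        }


def score_rhyme(responses: Sequence[Iterable[bool]]) -> int:
    """Score rhyme production: 1 point per target with >= 1 correct rhyme.

    ``responses`` holds, for each of the 12 target words, the judged
    correctness flags of every rhyme the child offered for that target.
    Producing six valid rhymes for one target still earns a single point,
    so the score reflects how *generally* the child can rhyme rather than
    fluency on a few targets.
    """
    if len(responses) != N_ITEMS:
        raise SchemaError(f"rhyme task needs {N_ITEMS} targets, got {len(responses)}")
    return sum(1 for target in responses if any(bool(r) for r in target))


def score_item_task(items: Sequence[bool]) -> int:
    """Score a 12-item task (onset deletion / phoneme synthesis): count correct."""
    if len(items) != N_ITEMS:
        raise SchemaError(f"item task needs {N_ITEMS} items, got {len(items)}")
    return sum(1 for i in items if bool(i))


def composite_pa(onset_deletion: Optional[int], phoneme_synthesis: Optional[int]) -> Optional[int]:
    """Composite phonemic awareness = onset deletion + phoneme synthesis.

    Returns ``None`` (missing) if either sub-score is missing.
    """
    if onset_deletion is None or phoneme_synthesis is None:
        return None
    if not (0 <= onset_deletion <= N_ITEMS and 0 <= phoneme_synthesis <= N_ITEMS):
        raise ValueError("sub-scores must lie in [0, 12]")
    return int(onset_deletion) + int(phoneme_synthesis)


def scores_to_frame(scores: Iterable[SkillScores]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in scores])


def summarize_scores(scores, by: str = "cohort") -> pd.DataFrame:
    """Per-cohort mean and min-max range for each task, excluding missing.

    Accepts a list of :class:`SkillScores` or an equivalent DataFrame.
    Output layout mirrors a descriptive table: one row per (task, cohort)
    with columns ``mean``, ``min``, ``max``, ``n``.
    """
    df = scores if isinstance(scores, pd.DataFrame) else scores_to_frame(scores)
    rows = []
    for task in TASKS:
        if task not in df.columns:
            continue
        for level, grp in df.groupby(by, sort=True, dropna=False):
            vals = pd.to_numeric(grp[task], errors="coerce").dropna()
            if vals.empty:
                continue
            rows.append(
                {
                    "task": task,
                    by: level,
                    "mean": float(vals.mean()),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame(rows, columns=["task", by, "mean", "min", "max", "n"])
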