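"""Score-threshold filtering of candidate bioactive peptides.

Bioactivity-likelihood scores (probability-like values in [0, 1], e.g. from
an external peptide classifier) are consumed as data — this package never
computes them.  The screening workflow keeps peptides whose score strictly
exceeds a threshold, 0.8 by default.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .motif_db import fixture_path, normalize_activity
from .sequences import validate_sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoredPeptide:
    sequence: str
    score: float
    activities: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(
                f"{self.sequence}: score {self.score} outside [0, 1]"
            )
        object.__setattr__(self, "activities", tuple(self.activities))


def load_scores(path: str | Path, *, strict_labels: bool = False) -> list[ScoredPeptide]:
    """Load scored peptides from TSV (``sequence / score / activities``).

    Activities are semicolon-separated.  A sequence listed on several rows is
    merged into a single peptide carrying the union of activities and the
    maximum score, with a logged warning — published score tables do repeat
    entries with different annotations.
    """
    merged: dict[str, tuple[float, list[str]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sequence", "score"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected TSV columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            try:
                score = float(row["score"])
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: malformed score {row['score']!r}") from exc
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"{path}:{i}: score {score} outside [0, 1]")
            acts = [
                normalize_activity(a, strict=strict_labels)
                for a in (row.get("activities") or "").split(";") if a.strip()
            ]
            seq = validate_sequence(row["sequence"])
            if seq in merged:
                logger.warning(
                    "%s:%d duplicate peptide %s: merging activities, keeping max score",
                    path, i, seq,
                )
                prev_score, prev_acts = merged[seq]
                score = max(score, prev_score)
                acts = prev_acts + [a for a in acts if a not in prev_acts]
            merged[seq] = (score, acts)
    return [
        ScoredPeptide(seq, score, tuple(acts)) for seq, (score, acts) in merged.items()
    ]


def load_fixture_scores() -> list[ScoredPeptide]:
    """The packaged score table for the alpha-zein candidate peptides."""
    return load_scores(fixture_path("table4_scores.tsv"))


def filter_by_score(
    peptides: Sequence[ScoredPeptide], threshold: float = 0.8
) -> list[ScoredPeptide]:
    """Keep peptides with score strictly greater than the threshold.

    Output is ordered by descending score, then sequence, so the ranking is
    stable and reproducible.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    kept = [p for p in peptides if p.score > threshold]
    return sorted(kept, key=lambda p: (-p.score, p.sequence))
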