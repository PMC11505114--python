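"""Motif-occurrence search and the occurrence-frequency statistic A.

For a protein of N residues and a bioactivity with motif set M, the frequency
of occurrence is

    A = a / N

where ``a`` depends on the analysis mode:

* profile mode (intact protein): ``a`` is the total number of positional,
  possibly overlapping occurrences of every motif of the activity in the
  intact sequence — the potential of the protein as a precursor, independent
  of any protease;
* digest mode (after simulated proteolysis): ``a`` is the number of released
  peptide instances (counted with multiplicity) whose full sequence equals
  some motif of the activity.  A released pentapeptide that merely contains a
  bioactive dipeptide does not count: an encrypted fragment is only active
  once actually excised.

N is always the parent protein's residue count, in both modes.  A is reported
rounded half-up to 4 decimal places.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

from .digestion import DigestResult
from .motif_db import MotifDatabase
from .sequences import ProteinRecord


def round_frequency(a: int, n: int, decimals: int = 4) -> float:
    """round(a/n) to ``decimals`` places, half-up (0.00005 -> 0.0001)."""
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(a) / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP))


def find_occurrences(sequence: str, motif: str) -> list[int]:
    """0-based start positions of every (possibly overlapping) match of motif."""
    if not motif:
        raise ValueError("motif must be non-empty")
    positions, i = [], sequence.find(motif)
    while i != -1:
        positions.append(i)
        i = sequence.find(motif, i + 1)
    return positions


@dataclass(frozen=True)
class ActivityProfile:
    """Matched fragments, occurrence count a and frequency A for one activity.

    ``fragments`` holds the distinct matched motifs; ``a`` counts occurrences
    (profile mode) or released instances (digest mode), so ``a`` can exceed
    ``len(fragments)``.
    """

    accession: str
    mode: str                      # "profile" | "digest"
    activity: str
    fragments: tuple[str, ...]
    a: int
    N: int
    enzymes: tuple[str, ...] = ()

    @property
    def A(self) -> float:
        return round_frequency(self.a, self.N)


def profile_potential(record: ProteinRecord, db: MotifDatabase) -> list[ActivityProfile]:
    """Profile the intact sequence: one ActivityProfile per activity with a > 0."""
    profiles = []
    for activity, motifs in db.by_activity().items():
        counts = {m: len(find_occurrences(record.sequence, m)) for m in sorted(motifs)}
        matched = tuple(m for m, c in counts.items() if c)
        if not matched:
            continue
        profiles.append(ActivityProfile(
            accession=record.accession, mode="profile", activity=activity,
            fragments=matched, a=sum(counts.values()), N=len(record),
        ))
    return profiles


def per_motif_counts(record: ProteinRecord, motifs: Iterable[str]) -> dict[str, int]:
    """Occurrence count of each motif in the intact sequence (overlaps included)."""
    return {m: len(find_occurrences(record.sequence, m)) for m in motifs}


def profile_digest(result: DigestResult, db: MotifDatabase) -> list[ActivityProfile]:
    """Profile a digest: count released peptides exactly equal to a motif.

    Multiplicity counts — a dipeptide released twice contributes 2 to ``a``.
    N is the parent protein's length, not the peptide count.
    """
    profiles = []
    for activity, motifs in db.by_activity().items():
        released = [p for p in result.peptides if p in motifs]
        if not released:
            continue
        profiles.append(ActivityProfile(
            accession=result.parent.accession, mode="digest", activity=activity,
            fragments=tuple(sorted(set(released))), a=len(released),
            N=len(result.parent), enzymes=result.enzymes,
        ))
    return profiles


def render_report(profiles: Sequence[ActivityProfile]) -> str:
    """Render profiles as a TSV report with a fixed, deterministic ordering.

    Columns: ``accession  mode  activity  fragments  a  N  A`` with A printed
    to exactly 4 decimals.
    """
    lines = ["accession\tmode\tactivity\tfragments\ta\tN\tA"]
    for p in sorted(profiles, key=lambda p: (p.accession, p.mode, p.activity)):
        lines.append("\t".join([
            p.accession, p.mode, p.activity, ", ".join(p.fragments),
            str(p.a), str(p.N), f"{p.A:.4f}",
        ]))
    return "\n".join(lines) + "\n"


def write_report(profiles: Sequence[ActivityProfile], path: str | Path) -> None:
    Path(path).write_text(render_report(profiles))


def read_report(path: str | Path) -> list[ActivityProfile]:
    """Read a report written by :func:`write_report` (A is recomputed from a/N)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(ActivityProfile(
                accession=row["accession"], mode=row["mode"], activity=row["activity"],
                fragments=tuple(f for f in row["fragments"].split(", ") if f),
                a=int(row["a"]), N=int(row["N"]),
            ))
    return out
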