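"""Access to the packaged golden tables transcribed from the published analyses.

Each row is one (protein, mode, activity) cell: the distinct bioactive
fragments and the frequency A as printed.  Rows carry provenance and two
quality flags:

* ``consistent`` — block-level: three of the six printed protein blocks are
  internally inconsistent (fragments listed that do not occur in the printed
  sequence, or frequencies implying a different length than both the printed
  sequence and the catalogue).  Those blocks are excluded from golden tests
  and never "corrected".
* ``note`` — row-level, for profile-mode rows of the consistent blocks:
  ``ok`` when the printed fragment set and A are exactly reproduced by
  re-profiling the printed sequence, otherwise a description of the
  discrepancy (for example a printed A that disagrees with the row's own
  fragment list).  Flagged rows are reported, not asserted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .digestion import GoldenDigestCell
from .motif_db import fixture_path

#: Blocks whose printed sequence and frequency rows agree (see module docstring).
CONSISTENT_BLOCKS = ("P06674", "P06676", "Q94IM1")


@dataclass(frozen=True)
class GoldenRow:
    accession: str
    mode: str                     # "profile" | "gi" | "subtilisin"
    activity: str
    fragments: frozenset[str]
    A: float
    source: str
    consistent: bool
    note: str

    @property
    def verified(self) -> bool:
        return self.note == "ok"


def load_golden_rows(path: str | Path | None = None) -> list[GoldenRow]:
    path = path or fixture_path("golden_tables23.tsv")
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if not row["A"]:
                continue  # a handful of printed cells lack a frequency value
            rows.append(GoldenRow(
                accession=row["accession"],
                mode=row["mode"],
                activity=row["activity"],
                fragments=frozenset(f for f in row["fragments"].split(", ") if f),
                A=float(row["A"]),
                source=row["source"],
                consistent=row["consistent"] == "yes",
                note=row["note"],
            ))
    return rows


def golden_digest_cells(mode: str) -> list[GoldenDigestCell]:
    """Published digest cells for the consistent blocks — the calibration corpus."""
    if mode not in {"gi", "subtilisin"}:
        raise ValueError("mode must be 'gi' or 'subtilisin'")
    return [
        GoldenDigestCell(r.accession, r.activity, r.fragments, r.A)
        for r in load_golden_rows()
        if r.mode == mode and r.consistent and r.fragments
    ]


def golden_profile_rows(verified_only: bool = True) -> list[GoldenRow]:
    """Profile-mode rows of the consistent blocks (optionally only ``ok`` rows)."""
    return [
        r for r in load_golden_rows()
        if r.mode == "profile" and r.consistent and (r.verified or not verified_only)
    ]
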