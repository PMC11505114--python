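"""The bioactive-motif database: short peptides annotated with activity labels.

Motifs are short peptide sequences (mostly di- and tri-peptides) known to
exert a physiological effect — ACE inhibition, DPP-IV/DPP-III inhibition,
antioxidative action and so on.  The packaged fixture is the subset of such
annotations that covers the six printed alpha-zein analyses; the loader
accepts arbitrarily larger user-supplied exports in the same TSV dialect, so
a full database export can be dropped in without code changes.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .sequences import CANONICAL_AA, SequenceValidationError, validate_sequence

logger = logging.getLogger(__name__)

MAX_MOTIF_LENGTH = 25

#: Controlled vocabulary of bioactivity labels: long name -> abbreviation.
ACTIVITY_VOCABULARY: dict[str, str] = {
    "ACE inhibitor": "ACE",
    "Activating ubiquitin-mediated proteolysis": "AUP",
    "Acylaminoacyl peptidase inhibitor": "API",
    "Alanine carboxypeptidase inhibitor": "ALCP",
    "Alpha-amylase inhibitor": "AMY",
    "Alpha-glucosidase inhibitor": "AI",
    "Antiammnestic": "AA",
    "Antibacterial peptide": "AP",
    "Anti-inflammatory": "AIN",
    "Antioxidative": "ANT",
    "Calpain 1 inhibitor": "CALP",
    "CaMPDE inhibitor": "CaMPDE",
    "Celiac toxic": "CEL",
    "D-Ala-D-Ala dipeptidase inhibitor": "DDPI",
    "Dipeptidyl peptidase III inhibitor": "DPPIII",
    "Dipeptidyl peptidase IV inhibitor": "DPPIV",
    "Glutamate carboxypeptidase inhibitor": "GCI",
    "HMG-CoA reductase inhibitor": "HMG-CoA",
    "Hypotensive": "HYP",
    "Hypouricemic": "HYC",
    "Immunomodulating": "IMMU",
    "Immunostimulating": "IMS",
    "Inhibitor of cytosol alanyl aminopeptidase": "ICAA",
    "Inhibitor of tripeptidyl peptidase II": "ITPII",
    "Lactocepin inhibitor": "LACT",
    "Leucyltransferase inhibitor": "LEUC",
    "Neprilysin 2 inhibitor": "NEPR",
    "Neuropeptide": "NEP",
    "Opioid": "OPI",
    "Pancreatic lipase inhibitor": "PANC",
    "Phospholipase A2 inhibitor": "PHOS",
    "Regulating (phosphoglycerate kinase activity)": "REG",
    "Renin inhibitor": "RENIN",
    "Stimulating (glucose uptake stimulating peptide)": "STIG",
    "Stimulating (vasoactive substance release)": "STIV",
    "Tubulin-tyrosine ligase inhibitor": "TTL",
    "Xaa-Pro inhibitor": "XAAP",
}

_CANON = {k.lower(): k for k in ACTIVITY_VOCABULARY}
_CANON.update({v.lower(): k for k, v in ACTIVITY_VOCABULARY.items()})


class UnknownActivityError(ValueError):
    """Raised when an activity label is not in the controlled vocabulary."""

    def __init__(self, label: str):
        known = ", ".join(sorted(ACTIVITY_VOCABULARY))
        super().__init__(f"unknown activity label {label!r}; known labels: {known}")
        self.label = label


def normalize_activity(label: str, *, strict: bool = True) -> str:
    """Map a label (long name or abbreviation, any case) to its canonical form."""
    canon = _CANON.get(label.strip().lower())
    if canon is None:
        if strict:
            raise UnknownActivityError(label)
        return label.strip()
    return canon


@dataclass(frozen=True, order=True)
class ActivityMotif:
    """A short peptide annotated with one bioactivity label."""

    motif: str
    activity: str
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        motif = validate_sequence(self.motif, record=self.motif)
        if len(motif) > MAX_MOTIF_LENGTH:
            raise SequenceValidationError(
                f"motif {motif!r} exceeds the maximum length of {MAX_MOTIF_LENGTH}"
            )
        object.__setattr__(self, "motif", motif)


class MotifDatabase:
    """A set of (motif, activity) annotations with per-activity lookup.

    The same motif may carry several activities (PF, for instance, is both an
    ACE-inhibitor and a DPP-IV-inhibitor motif); the (motif, activity) pair is
    unique.
    """

    def __init__(self, entries: Iterable[ActivityMotif] = ()):
        self._entries: dict[tuple[str, str], ActivityMotif] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: ActivityMotif) -> bool:
        """Add an entry; returns False (and keeps the first) on duplicates."""
        key = (entry.motif, entry.activity)
        if key in self._entries:
            return False
        self._entries[key] = entry
        return True

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(sorted(self._entries.values()))

    def __contains__(self, key: tuple[str, str]) -> bool:
        return tuple(key) in self._entries

    @property
    def activities(self) -> list[str]:
        return sorted({e.activity for e in self._entries.values()})

    def motifs_for(self, activity: str) -> frozenset[str]:
        activity = normalize_activity(activity, strict=False)
        return frozenset(
            e.motif for e in self._entries.values() if e.activity == activity
        )

    def by_activity(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for e in self._entries.values():
            out.setdefault(e.activity, set()).add(e.motif)
        return {k: frozenset(v) for k, v in sorted(out.items())}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MotifDatabase):
            return NotImplemented
        return set(self._entries) == set(other._entries)


def load_motifs(path: str | Path, *, strict: bool = True) -> MotifDatabase:
    """Load a motif database from TSV (columns ``motif / activity / source``).

    Duplicate (motif, activity) rows are collapsed with a logged warning.
    Unknown activity labels raise :class:`UnknownActivityError` unless
    ``strict=False``, which admits user-defined labels.
    """
    db = MotifDatabase()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"motif", "activity", "source"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: expected TSV header with columns {sorted(required)}"
            )
        for i, row in enumerate(reader, start=2):
            activity = normalize_activity(row["activity"], strict=strict)
            entry = ActivityMotif(row["motif"], activity, row.get("source", ""))
            if not db.add(entry):
                logger.warning("%s:%d duplicate entry (%s, %s) collapsed",
                               path, i, entry.motif, entry.activity)
    return db


def save_motifs(db: MotifDatabase, path: str | Path) -> None:
    """Write a motif database in the TSV dialect read by :func:`load_motifs`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["motif", "activity", "source"])
        for e in db:
            writer.writerow([e.motif, e.activity, e.source])


def fixture_path(name: str) -> Path:
    """Path to a packaged data file."""
    return Path(str(resources.files("zeinpep").joinpath("data", name)))


def build_fixture() -> MotifDatabase:
    """The packaged motif database distilled from the printed per-protein tables.

    It is the union, over the six printed protein blocks, of every
    (fragment, activity) pair listed in profile and digest columns.  Tokens
    with non-canonical residues in the printed source (OCR artefacts such as
    "OS") are excluded, not guessed at.
    """
    return load_motifs(fixture_path("biopep_subset_tables23.tsv"))
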