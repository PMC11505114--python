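"""Protein records, FASTA I/O, pairwise identity and identity-threshold grouping.

The screening workflow starts from a set of storage-protein sequences that
may contain near-duplicates (UniProtKB lists many alpha-zein entries that
differ by a handful of residues).  Proteins whose pairwise identity reaches a
threshold (90% in the default workflow) are treated as the same protein; a
single representative per group is carried forward to motif profiling and
digestion.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical one-letter amino-acid codes.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class SequenceValidationError(ValueError):
    """Raised when a sequence contains characters outside the canonical alphabet."""


def validate_sequence(sequence: str, *, record: str = "<sequence>") -> str:
    """Uppercase, strip whitespace and validate against the canonical alphabet.

    Printed sequences frequently carry line-wrap spaces; amino-acid sequences
    contain no whitespace, so all of it is removed before validation.
    """
    cleaned = "".join(sequence.split()).upper()
    if not cleaned:
        raise SequenceValidationError(f"record {record!r}: empty sequence")
    bad = sorted(set(cleaned) - CANONICAL_AA)
    if bad:
        raise SequenceValidationError(
            f"record {record!r}: non-canonical residue(s) {', '.join(bad)}"
        )
    return cleaned


@dataclass(frozen=True)
class ProteinRecord:
    """An accession-tagged amino-acid sequence.

    ``len(record)`` is the residue count N used as the denominator of the
    occurrence-frequency statistic.  When a catalogued length is supplied and
    disagrees with the actual sequence, the record is flagged rather than
    silently reconciled: printed tables occasionally disagree with their own
    sequences and that disagreement is evidence worth keeping.
    """

    accession: str
    sequence: str
    name: str = ""
    length_declared: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", validate_sequence(self.sequence, record=self.accession)
        )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_length_discrepancy(self) -> bool:
        return self.length_declared is not None and self.length_declared != len(self)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into validated :class:`ProteinRecord` objects.

    The header is parsed as ``accession name...``.  Wrapped and unwrapped
    sequence lines, and stray mid-sequence whitespace, are both accepted.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(accession=rec.id, name=rec.description[len(rec.id):].strip(),
                          sequence=str(rec.seq))
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.name)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_catalog(path: str | Path) -> dict[str, tuple[str, int]]:
    """Read an ``accession / name / length`` TSV catalog."""
    out: dict[str, tuple[str, int]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["accession"]] = (row["name"], int(row["length"]))
    return out


def read_identity_pairs(path: str | Path) -> dict[frozenset[str], float]:
    """Read a pairwise-identity TSV (``accession_a / accession_b / identity_pct``)."""
    pairs: dict[frozenset[str], float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pairs[frozenset((row["accession_a"], row["accession_b"]))] = float(
                row["identity_pct"]
            )
    return pairs


def _make_aligner() -> PairwiseAligner:
    # Identity scoring: match +1, mismatch 0, affine gaps open -10 extend -0.5.
    # End gaps are free so that length differences are not penalised.
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.target_end_open_gap_score = 0.0
    aligner.target_end_extend_gap_score = 0.0
    aligner.query_end_open_gap_score = 0.0
    aligner.query_end_extend_gap_score = 0.0
    return aligner


def percent_identity(a: ProteinRecord | str, b: ProteinRecord | str) -> float:
    """Global-alignment percent identity between two sequences.

    Returns ``100 * identical_columns / alignment_length`` where the alignment
    length excludes terminal-gap columns (overhangs do not count against
    identity).  The scoring scheme is fixed (match +1, mismatch 0, affine gaps
    open -10 / extend -0.5), which makes the value deterministic.
    """
    sa = a.sequence if isinstance(a, ProteinRecord) else validate_sequence(a)
    sb = b.sequence if isinstance(b, ProteinRecord) else validate_sequence(b)
    if sa == sb:
        return 100.0
    # canonical argument order: co-optimal alignments are picked identically
    # for (a, b) and (b, a), so the value is exactly symmetric
    sa, sb = sorted((sa, sb))
    alignment = _make_aligner().align(sa, sb)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    # trim terminal-gap columns on either sequence
    start = max(len(ga) - len(ga.lstrip("-")), len(gb) - len(gb.lstrip("-")))
    end = len(ga) - max(len(ga) - len(ga.rstrip("-")), len(gb) - len(gb.rstrip("-")))
    core_a, core_b = ga[start:end], gb[start:end]
    identical = sum(x == y and x != "-" for x, y in zip(core_a, core_b))
    length = end - start
    if length <= 0:  # fully staggered co-optimal alignment of unrelated residues
        return 0.0
    return 100.0 * identical / length


@dataclass
class IdentityGrouping:
    """A single-linkage partition of accessions at an identity threshold.

    Any two accessions in the same group are connected by a chain of pairs
    each at or above the threshold; the representative of a group is its
    longest member (ties broken by lexicographically smallest accession).
    """

    threshold: float
    pairs: dict[frozenset[str], float]
    groups: list[frozenset[str]]
    representatives: list[str] = field(default_factory=list)

    def group_of(self, accession: str) -> frozenset[str]:
        for g in self.groups:
            if accession in g:
                return g
        raise KeyError(accession)


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: str, y: str) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def group_from_pairs(
    accessions: Sequence[str],
    pairs: Mapping[frozenset[str], float],
    threshold: float,
    lengths: Mapping[str, int] | None = None,
) -> IdentityGrouping:
    """Single-linkage grouping from a precomputed pairwise-identity map.

    Accepts e.g. a published identity matrix, so the grouping rule can be
    applied even when only pair percentages (not sequences) are available.
    """
    uf = _UnionFind(accessions)
    acc_set = set(accessions)
    for pair, pct in pairs.items():
        a, b = tuple(pair)
        if a in acc_set and b in acc_set and pct >= threshold:
            uf.union(a, b)
    clusters: dict[str, set[str]] = {}
    for acc in accessions:
        clusters.setdefault(uf.find(acc), set()).add(acc)
    groups = sorted((frozenset(g) for g in clusters.values()), key=lambda g: sorted(g)[0])
    lengths = lengths or {}
    reps = [
        min(g, key=lambda acc: (-lengths.get(acc, 0), acc))
        for g in groups
    ]
    return IdentityGrouping(threshold=threshold, pairs=dict(pairs), groups=groups,
                            representatives=reps)


def group_by_identity(
    records: Sequence[ProteinRecord], threshold: float = 90.0
) -> IdentityGrouping:
    """Compute all pairwise identities and group records by single linkage."""
    if not records:
        raise ValueError("at least one record is required")
    pairs: dict[frozenset[str], float] = {}
    for i, a in enumerate(records):
        for b in records[i + 1:]:
            pairs[frozenset((a.accession, b.accession))] = percent_identity(a, b)
    lengths = {r.accession: len(r) for r in records}
    return group_from_pairs([r.accession for r in records], pairs, threshold, lengths)
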