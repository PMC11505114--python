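"""Synthetic sequences with known ground truth for end-to-end validation.

Three generators cover the pipeline's needs:

* :func:`background` — i.i.d. residue sampling under a controlled composition
  (e.g. the leucine/proline/alanine-rich composition typical of prolamin
  storage proteins);
* :func:`plant_motifs` — short motifs written into a background sequence at
  known, non-overlapping positions, with the truth recounted after insertion
  so accidental background matches are part of the recorded totals;
* :func:`sequence_with_cuts` — a sequence concatenated from fragments whose
  junctions are exactly the cut sites of a given rule set, so a digest must
  recover both the sites and the fragments verbatim.

All randomness flows through ``numpy.random.default_rng(seed)``; no global
state is touched, so every artefact is bit-reproducible from its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .digestion import CleavageRule, cleavage_sites
from .profiling import find_occurrences
from .sequences import CANONICAL_AA, ProteinRecord, write_fasta

#: Residue composition echoing a prolamin-like bias: leucine 19.3%,
#: proline 9.0%, alanine 8.3%, remainder uniform over the other 17 residues.
ZEIN_LIKE_COMPOSITION: dict[str, float] = {
    "L": 0.193, "P": 0.090, "A": 0.083,
    **{aa: (1.0 - 0.193 - 0.090 - 0.083) / 17
       for aa in sorted(CANONICAL_AA - {"L", "P", "A"})},
}


@dataclass(frozen=True)
class SyntheticTruth:
    """A synthetic sequence plus everything a test needs to check against it."""

    sequence: str
    planted: dict[str, list[int]] = field(default_factory=dict)
    cut_sites: tuple[int, ...] | None = None
    seed: int | None = None

    def to_record(self, accession: str = "SYN1") -> ProteinRecord:
        return ProteinRecord(accession=accession, sequence=self.sequence,
                             name="synthetic")

    def write(self, fasta_path: str | Path, truth_path: str | Path,
              accession: str = "SYN1") -> None:
        """Emit FASTA plus a JSON truth sidecar."""
        write_fasta([self.to_record(accession)], fasta_path)
        Path(truth_path).write_text(json.dumps({
            "sequence": self.sequence,
            "planted": self.planted,
            "cut_sites": list(self.cut_sites) if self.cut_sites is not None else None,
            "seed": self.seed,
        }, indent=1))


def background(length: int, composition: Mapping[str, float] | None = None,
               seed: int = 0) -> str:
    """An i.i.d. random sequence under the given residue composition."""
    if length < 1:
        raise ValueError("length must be >= 1")
    composition = dict(composition or ZEIN_LIKE_COMPOSITION)
    bad = set(composition) - CANONICAL_AA
    if bad:
        raise ValueError(f"non-canonical residues in composition: {sorted(bad)}")
    residues = sorted(composition)
    probs = np.array([composition[r] for r in residues], dtype=float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("composition probabilities must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    return "".join(np.array(residues)[rng.choice(len(residues), size=length, p=probs)])


def plant_motifs(background_seq: str, plan: Mapping[str, int],
                 seed: int = 0) -> SyntheticTruth:
    """Overwrite non-overlapping windows of the background with planted motifs.

    The returned truth records the occurrence positions of every planted motif
    *after* insertion (a full recount), so callers whose motifs share letters
    with the background still get exact expected counts.
    """
    rng = np.random.default_rng(seed)
    seq = list(background_seq)
    occupied: set[int] = set()
    for motif, count in sorted(plan.items()):
        if count < 0:
            raise ValueError(f"negative count for motif {motif}")
        placed = 0
        # candidate windows that don't overlap anything already planted
        starts = [
            s for s in range(len(seq) - len(motif) + 1)
            if not any(p in occupied for p in range(s, s + len(motif)))
        ]
        rng.shuffle(starts)
        for s in starts:
            if placed == count:
                break
            if any(p in occupied for p in range(s, s + len(motif))):
                continue
            seq[s:s + len(motif)] = motif
            occupied.update(range(s, s + len(motif)))
            placed += 1
        if placed < count:
            raise ValueError(
                f"sequence of length {len(seq)} cannot host {count} "
                f"non-overlapping copies of {motif!r} (placed {placed})"
            )
    final = "".join(seq)
    planted = {m: find_occurrences(final, m) for m in plan}
    return SyntheticTruth(sequence=final, planted=planted, seed=seed)


def sequence_with_cuts(fragments: Sequence[str],
                       rules: Sequence[CleavageRule]) -> SyntheticTruth:
    """Concatenate fragments whose junctions are exactly the rule set's cut sites.

    Preconditions checked per fragment: every fragment except possibly the
    last must end in a P1 residue of some subrule; no fragment may contain an
    internal cut site; no junction may fall in a blocked P1' context.
    """
    if not fragments:
        raise ValueError("at least one fragment is required")
    subrules = [s for r in rules for s in r.subrules]

    def cuts_after(p1: str, p1prime: str | None) -> bool:
        return any(
            p1 in s.p1_residues and (p1prime is None or p1prime not in s.p1prime_blocked)
            for s in subrules
        )

    for idx, frag in enumerate(fragments):
        if not frag:
            raise ValueError(f"fragment {idx} is empty")
        # bonds within a fragment are 0..len-2; the junction bond lies outside it
        internal = cleavage_sites(frag, rules)
        if internal:
            raise ValueError(
                f"fragment {idx} ({frag!r}) contains internal cut site(s) {internal}"
            )
        if idx < len(fragments) - 1:
            nxt = fragments[idx + 1][0]
            if not cuts_after(frag[-1], nxt):
                raise ValueError(
                    f"fragment {idx} ({frag!r}) does not end in a cuttable "
                    f"P1 residue before {nxt!r}"
                )
    sequence = "".join(fragments)
    junctions, pos = [], 0
    for frag in fragments[:-1]:
        pos += len(frag)
        junctions.append(pos - 1)
    actual = cleavage_sites(sequence, rules)
    if actual != junctions:
        # can only happen if a junction creates a new site spanning fragments
        raise ValueError(
            f"junction context creates unexpected cut sites: planned {junctions}, "
            f"rules yield {actual}"
        )
    return SyntheticTruth(sequence=sequence, cut_sites=tuple(junctions))
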