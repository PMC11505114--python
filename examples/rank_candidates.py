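"""Filter candidate peptides by bioactivity-likelihood score.

Scores (probabilities in [0, 1] from an external classifier) are consumed as
data.  The screening threshold is strict: score > 0.8, the level at which
false-positive rates for short peptides drop appreciably.
"""

from zeinpep import filter_by_score, load_fixture_scores

peptides = load_fixture_scores()
kept = filter_by_score(peptides, threshold=0.8)
print(f"{len(kept)} of {len(peptides)} candidate peptides exceed 0.8:\n")
for p in kept[:10]:
    print(f"  {p.sequence:<6} {p.score:.4f}  {'; '.join(p.activities)}")
print("  ...")
print("\nA peptide listed twice in the source table (PF) carries the union "
      "of its annotations:")
pf = next(p for p in kept if p.sequence == "PF")
print(f"  PF -> {'; '.join(pf.activities)}")
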