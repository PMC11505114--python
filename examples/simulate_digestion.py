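"""Simulate gastrointestinal and subtilisin proteolysis of one alpha-zein.

Digest mode is stricter than profile mode: a bioactive motif only counts if a
released peptide equals it exactly — a motif buried inside a longer released
peptide stays encrypted.  The drop from profile-mode to digest-mode A values
shows how much of the encoded potential each protease actually liberates.
"""

from zeinpep import PRESETS, build_fixture, digest, profile_digest, read_fasta
from zeinpep.motif_db import fixture_path

db = build_fixture()
rec = next(r for r in read_fasta(fixture_path("alpha_zein_printed.fasta"))
           if r.accession == "P06674")

for preset in ("gi", "subtilisin"):
    enzymes = PRESETS[preset]
    result = digest(rec, list(enzymes))
    print(f"\n=== {preset}: {' + '.join(e.enzyme for e in enzymes)} ===")
    print(f"{len(result.cut_sites)} cuts -> {len(result.peptides)} peptides "
          f"(parent {len(rec)} residues)")
    for row in profile_digest(result, db):
        print(f"  {row.activity:<45} released {', '.join(row.fragments):<22}"
              f" a={row.a:<3} A={row.A:.4f}")
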