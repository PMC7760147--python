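"""Canonical seed-site scanning of a transcript with miR-378a-3p.

Builds the 8mer / 7mer-m8 / 7mer-A1 target-strand patterns from the mature
miR-378a-3p sequence and scans a small hand-made transcript whose CDS
boundaries are known, reporting each site with its region.
"""

from mirtargetome import TranscriptModel, scan_transcript, seed_patterns
from mirtargetome.reference import mir378a_3p

mirna = mir378a_3p()
patterns = seed_patterns(mirna)
print(f"{mirna.id}: {mirna.sequence}")
print(f"  8mer    {patterns.site_8mer}")
print(f"  7mer-m8 {patterns.site_7mer_m8}")
print(f"  7mer-A1 {patterns.site_7mer_A1}")

# one 8mer in the 5'UTR, one 7mer-m8 in the CDS, one 7mer-A1 in the 3'UTR
seq = (
    "GGCGGC" + patterns.site_8mer + "GGCGGCGGCG"          # 5'UTR
    + "AUGGGC" + patterns.site_7mer_m8 + "CGGCGGCUAG"     # CDS
    + "GGCGGC" + patterns.site_7mer_A1 + "GGCGGC"         # 3'UTR
)
tx = TranscriptModel("demo-tx", "DEMO", seq, cds_start=24, cds_end=47)

for m in scan_transcript(tx, patterns):
    print(f"{m.site_type:8s} {m.region:5s} [{m.start}, {m.end})")
# Each planted site is reported once with the region of its 5'-most
# nucleotide; an 8mer suppresses the 7mers embedded at the same locus.
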