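"""Canonical miRNA seed-site construction and transcript scanning.

A miRNA represses a transcript mainly through Watson-Crick pairing of its
5' "seed" (positions 2-7/2-8) with the target strand.  The three canonical
site classes scanned here are

* ``8mer``     -- perfect match to miRNA positions 2-8 followed by an A on
  the target opposite miRNA position 1,
* ``7mer-m8``  -- perfect match to positions 2-8,
* ``7mer-A1``  -- perfect match to positions 2-7 followed by the target A.

The target A of the A1 classes is required regardless of the identity of
miRNA position 1.  Sites are classified hierarchically: an 8mer occurrence
subsumes the 7mers embedded at the same locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

SITE_8MER = "8mer"
SITE_7MER_M8 = "7mer-m8"
SITE_7MER_A1 = "7mer-A1"
SITE_TYPES = (SITE_8MER, SITE_7MER_M8, SITE_7MER_A1)

REGION_5UTR = "5UTR"
REGION_CDS = "CDS"
REGION_3UTR = "3UTR"
REGIONS = (REGION_5UTR, REGION_CDS, REGION_3UTR)

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_VALID = set("ACGU")


def _normalize_rna(seq: str, what: str = "sequence") -> str:
    """Uppercase, map T->U, and validate the alphabet."""
    s = seq.upper().replace("T", "U")
    for i, c in enumerate(s):
        if c not in _VALID:
            raise ValueError(f"invalid character {c!r} at position {i} in {what}")
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement in the RNA alphabet.

    DNA input (T) is accepted and treated as U; the result is always RNA.
    """
    s = _normalize_rna(seq)
    return s.translate(_RNA_COMPLEMENT)[::-1]


@dataclass
class MatureMiRNA:
    """A mature miRNA given 5'->3'; T is accepted and mapped to U."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = _normalize_rna(self.sequence, f"miRNA {self.id}")
        if len(self.sequence) < 8:
            raise ValueError(
                f"miRNA {self.id} has length {len(self.sequence)} < 8; "
                "seed patterns need positions 1-8"
            )


@dataclass(frozen=True)
class SitePatterns:
    """Target-strand 5'->3' match patterns for the three canonical site types."""

    site_8mer: str
    site_7mer_m8: str
    site_7mer_A1: str

    def pattern(self, site_type: str) -> str:
        return {
            SITE_8MER: self.site_8mer,
            SITE_7MER_M8: self.site_7mer_m8,
            SITE_7MER_A1: self.site_7mer_A1,
        }[site_type]


@dataclass
class TranscriptModel:
    """A transcript sequence with CDS boundaries (0-based, half-open) or noncoding."""

    id: str
    gene: str
    sequence: str
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        self.sequence = _normalize_rna(self.sequence, f"transcript {self.id}")
        if self.noncoding:
            if (self.cds_start is None) != (self.cds_end is None):
                raise ValueError(f"transcript {self.id}: give both CDS bounds or neither")
        else:
            if not 0 <= self.cds_start < self.cds_end <= len(self.sequence):
                raise ValueError(
                    f"transcript {self.id}: CDS [{self.cds_start}, {self.cds_end}) "
                    f"outside sequence of length {len(self.sequence)}"
                )

    @property
    def noncoding(self) -> bool:
        return self.cds_start is None or self.cds_end is None


@dataclass(frozen=True)
class SeedMatch:
    """One classified seed site; coordinates 0-based half-open on the transcript."""

    transcript: str
    site_type: str
    region: Optional[str]
    start: int
    end: int


def seed_patterns(mirna: MatureMiRNA) -> SitePatterns:
    """Build the three canonical target-strand patterns from a mature miRNA.

    7mer-m8 is the reverse complement of miRNA positions 2-8; the 8mer is the
    7mer-m8 followed by A; the 7mer-A1 is the reverse complement of positions
    2-6..7 followed by A (the target A faces miRNA position 1 whatever that
    position is).
    """
    seq = mirna.sequence
    m8 = reverse_complement(seq[1:8])
    return SitePatterns(
        site_8mer=m8 + "A",
        site_7mer_m8=m8,
        site_7mer_A1=reverse_complement(seq[1:7]) + "A",
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) occurrence starts of needle in haystack."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def scan_sequence(
    seq: str, patterns: SitePatterns, transcript: str = ""
) -> list[SeedMatch]:
    """Scan a sequence for canonical seed sites with hierarchical classification.

    Every 8mer occurrence is reported once, and the 7mer-m8 / 7mer-A1 matches it
    embeds at the same locus are suppressed.  Remaining 7mer-m8 and then
    7mer-A1 occurrences are reported; overlapping occurrences at distinct loci
    are all kept.  Scanning is case-insensitive and U/T-agnostic.
    """
    s = _normalize_rna(seq)
    matches: list[SeedMatch] = []
    starts_8 = _find_all(s, patterns.site_8mer)
    claimed_8 = set(starts_8)
    for i in starts_8:
        matches.append(SeedMatch(transcript, SITE_8MER, None, i, i + 8))
    taken_7: set[int] = set()
    for i in _find_all(s, patterns.site_7mer_m8):
        # the 8mer is m8 + A, so an 8mer at i embeds a 7mer-m8 at i
        if i in claimed_8:
            continue
        matches.append(SeedMatch(transcript, SITE_7MER_M8, None, i, i + 7))
        taken_7.add(i)
    for i in _find_all(s, patterns.site_7mer_A1):
        # an 8mer at i-1 embeds a 7mer-A1 at i; a locus already reported as
        # 7mer-m8 (degenerate equal patterns) keeps the higher class
        if (i - 1) in claimed_8 or i in taken_7:
            continue
        matches.append(SeedMatch(transcript, SITE_7MER_A1, None, i, i + 7))
    matches.sort(key=lambda m: (m.start, SITE_TYPES.index(m.site_type)))
    return matches


def assign_region(t: TranscriptModel, start: int) -> str:
    """Region containing a match's 5'-most nucleotide.

    Sites on noncoding transcripts are reported under 3UTR by convention.
    """
    if t.noncoding:
        return REGION_3UTR
    if start < t.cds_start:
        return REGION_5UTR
    if start < t.cds_end:
        return REGION_CDS
    return REGION_3UTR


def scan_transcript(t: TranscriptModel, patterns: SitePatterns) -> list[SeedMatch]:
    """Scan a transcript and assign each match the region of its start coordinate."""
    return [
        SeedMatch(t.id, m.site_type, assign_region(t, m.start), m.start, m.end)
        for m in scan_sequence(t.sequence, patterns, transcript=t.id)
    ]
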