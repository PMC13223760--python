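"""Sequence-derived features of introns: length, GC content, splice-site
dinucleotides/canonicality and DRACH (m6A consensus) motif counts.

All sequence work is on the sense (mRNA-equivalent) strand of the intron;
soft-masked genome bases are uppercased before matching. Canonicality is the
binary GT-AG statistic — the minor GC-AG and AT-AC spliceosomal classes are
reported via their dinucleotides but counted non-canonical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from pyfaidx import Fasta

from .annotation import GenomeInterval

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHN", "TGCAYRMKVBHDN")

# D=[AGT] R=[AG] A C H=[ACT]; lookahead so overlapping windows all count
_DRACH_RE = re.compile(r"(?=[AGT][AG]AC[ACT])")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_sequence(genome: Fasta, interval: GenomeInterval) -> str:
    """Sense-strand sequence of an interval, uppercase (reverse complement
    of the + strand for intervals on -)."""
    if interval.chrom not in genome:
        raise KeyError(f"chromosome {interval.chrom!r} absent from FASTA")
    contig = genome[interval.chrom]
    if interval.end > len(contig):
        raise ValueError(
            f"interval end {interval.end} beyond contig "
            f"{interval.chrom} length {len(contig)}"
        )
    seq = str(contig[interval.start:interval.end]).upper()
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq


def gc_content(seq: str) -> float:
    """(#G + #C) / #unambiguous bases; ambiguity codes excluded from both
    numerator and denominator."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T") + s.count("U")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / (gc + at)


def splice_dinucleotides(
    genome: Fasta, intron: GenomeInterval
) -> tuple[str, str, bool]:
    """(donor 2-mer, acceptor 2-mer, canonical GT-AG?) for an intron."""
    if len(intron) < 4:
        raise ValueError(f"intron shorter than 4 nt: {intron}")
    seq = extract_sequence(genome, intron)
    donor2, acceptor2 = seq[:2], seq[-2:]
    return donor2, acceptor2, (donor2 == "GT" and acceptor2 == "AG")


def drach_count(seq: str) -> int:
    """Occurrences of the m6A consensus DRACH ([AGT][AG]AC[ACT]) on the sense
    strand, overlapping windows all counted; U treated as T."""
    s = seq.upper().replace("U", "T")
    if len(s) < 5:
        return 0
    return len(_DRACH_RE.findall(s))


@dataclass(frozen=True)
class IntronFeatures:
    length_nt: int
    gc_fraction: float
    donor2: str
    acceptor2: str
    canonical: bool
    drach_count: int


def intron_features(genome: Fasta, intron: GenomeInterval) -> IntronFeatures:
    seq = extract_sequence(genome, intron)
    donor2, acceptor2, canonical = splice_dinucleotides(genome, intron)
    return IntronFeatures(
        length_nt=len(intron),
        gc_fraction=gc_content(seq),
        donor2=donor2,
        acceptor2=acceptor2,
        canonical=canonical,
        drach_count=drach_count(seq),
    )
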