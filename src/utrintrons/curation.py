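"""Reference curation: high-confidence transcript selection and the
genome-wide indices of coding-intron boundaries and reference junctions.

The classifier matches queries against a *curated* reference subset
(transcript support level 1–2 with an APPRIS principal/alternative:1/2 tag)
but tests splice-boundary sharing and junction novelty against indices built
from the *full* reference annotation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotation import (
    AnnotationError,
    TranscriptModel,
    acceptor_position,
    donor_position,
    stop_codon_of,
)

logger = logging.getLogger(__name__)

APPRIS_ALLOWED_DEFAULT = frozenset({"principal", "alternative:1", "alternative:2"})

BoundaryKey = tuple[str, str, int, str]  # chrom, strand, position, donor/acceptor
JunctionKey = tuple[str, str, int, int]  # chrom, strand, start, end


def tsl_of(tx: TranscriptModel) -> int | None:
    """Numeric transcript support level, parsed from the leading integer of
    the attribute; non-numeric values ("NA", absent) yield None."""
    raw = tx.attributes.get("transcript_support_level")
    if raw is None:
        return None
    head = raw.strip().split()[0] if raw.strip() else ""
    try:
        return int(head)
    except ValueError:
        return None


def appris_class(tx: TranscriptModel) -> str | None:
    """Map Ensembl appris_* tags to {principal, alternative:1, alternative:2}."""
    for tag in tx.tags():
        if tag.startswith("appris_principal"):
            return "principal"
        if tag.startswith("appris_alternative_1"):
            return "alternative:1"
        if tag.startswith("appris_alternative_2"):
            return "alternative:2"
    return None


def filter_high_confidence(
    refs: Iterable[TranscriptModel],
    max_tsl: int = 2,
    appris_allowed: frozenset[str] = APPRIS_ALLOWED_DEFAULT,
) -> list[TranscriptModel]:
    """Keep transcripts with numeric TSL <= max_tsl AND an allowed APPRIS tag.

    Transcripts missing either attribute are excluded.
    """
    out = []
    for tx in refs:
        tsl = tsl_of(tx)
        if tsl is None or tsl > max_tsl:
            continue
        if appris_class(tx) not in appris_allowed:
            continue
        out.append(tx)
    return out


@dataclass(frozen=True)
class ReferenceIndices:
    """Deterministic lookup structures over a reference annotation.

    ``coding_boundaries``: donor/acceptor positions of introns lying between
    the start and stop codon (transcript order) of any reference transcript.
    ``all_junctions``: every intron of every reference transcript.
    """

    coding_boundaries: frozenset[BoundaryKey]
    all_junctions: frozenset[JunctionKey]
    high_confidence_ids: frozenset[str]

    def is_coding_boundary(self, chrom: str, strand: str, pos: int,
                           side: str) -> bool:
        return (chrom, strand, pos, side) in self.coding_boundaries

    def has_junction(self, chrom: str, strand: str, start: int, end: int) -> bool:
        return (chrom, strand, start, end) in self.all_junctions


def coding_introns(tx: TranscriptModel, include_utr5: bool = False):
    """Introns whose genomic span lies between the start codon and stop codon
    of ``tx`` in transcript order (5' UTR introns excluded by default)."""
    if not tx.cds:
        return []
    stop = stop_codon_of(tx)
    span = tx.cds_span
    if tx.strand == "+":
        lo = tx.exons[0].start if include_utr5 else span.start
        hi = stop.start
        return [i for i in tx.introns if i.start >= lo and i.end <= hi]
    lo = stop.end
    hi = tx.exons[-1].end if include_utr5 else span.end
    return [i for i in tx.introns if i.start >= lo and i.end <= hi]


def build_indices(
    refs_full: Sequence[TranscriptModel],
    refs_hc: Sequence[TranscriptModel] | None = None,
    include_utr5: bool = False,
) -> ReferenceIndices:
    """Build boundary and junction indices from the full reference annotation.

    A CDS-bearing transcript whose stop codon cannot be derived is skipped for
    ``coding_boundaries`` only (with a warning); its junctions still count.
    """
    boundaries: set[BoundaryKey] = set()
    junctions: set[JunctionKey] = set()
    for tx in refs_full:
        junctions.update(tx.introns.junctions())
        if not tx.cds:
            continue
        try:
            cintrons = coding_introns(tx, include_utr5=include_utr5)
        except AnnotationError as exc:
            warnings.warn(
                f"skipping {tx.transcript_id} for coding boundaries: {exc}",
                stacklevel=2,
            )
            continue
        for i in cintrons:
            boundaries.add((i.chrom, i.strand, donor_position(i), "donor"))
            boundaries.add((i.chrom, i.strand, acceptor_position(i), "acceptor"))
    hc_ids = frozenset(t.transcript_id for t in refs_hc) if refs_hc else frozenset()
    return ReferenceIndices(
        coding_boundaries=frozenset(boundaries),
        all_junctions=frozenset(junctions),
        high_confidence_ids=hc_ids,
    )


def export_boundaries_bed(indices: ReferenceIndices, path) -> None:
    """Coding-intron boundary positions as BED6 (name = side)."""
    rows = sorted(indices.coding_boundaries)
    with open(path, "w") as fh:
        for chrom, strand, pos, side in rows:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{side}\t0\t{strand}\n")


def export_junctions_tsv(indices: ReferenceIndices, path) -> None:
    rows = sorted(indices.all_junctions)
    with open(path, "w") as fh:
        fh.write("chrom\tstrand\tstart\tend\n")
        for chrom, strand, start, end in rows:
            fh.write(f"{chrom}\t{strand}\t{start}\t{end}\n")
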