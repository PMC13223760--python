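"""Merge-stage filters removing uninformative assembled transcripts.

Assemblers emit many transcripts that are fragments of reference models,
mono-exonic pieces of retained introns, or pre-mRNA UTR fragments. Before 3UI
classification the assembly is reduced to transcripts that are either exact
copies of reference models or genuinely novel overlapping isoforms, and that
reach TPM > 1 in at least one sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotation import TranscriptModel
from .expression import QuantTable

IDENTICAL = "identical"
FRAGMENT = "fragment"
CONTAINED_INTRONIC = "contained_intronic"
CONTAINED_UTR = "contained_utr"
OVERLAPPING_NOVEL = "overlapping_novel"
INTERGENIC = "intergenic"

# keep a transcript if ANY reference legitimizes it
_PRECEDENCE = [
    IDENTICAL,
    FRAGMENT,
    OVERLAPPING_NOVEL,
    CONTAINED_UTR,
    CONTAINED_INTRONIC,
    INTERGENIC,
]
_RANK = {c: i for i, c in enumerate(_PRECEDENCE)}

KEEP_CATEGORIES = frozenset({IDENTICAL, OVERLAPPING_NOVEL})


@dataclass(frozen=True)
class OverlapVerdict:
    transcript_id: str
    category: str


def _chains_identical(q: TranscriptModel, r: TranscriptModel) -> bool:
    return (
        q.strand == r.strand
        and [(e.start, e.end) for e in q.exons] == [(e.start, e.end) for e in r.exons]
    )


def _is_fragment(q: TranscriptModel, r: TranscriptModel) -> bool:
    """Query exon chain is a contiguous sub-chain of the reference: internal
    junctions match a consecutive run of reference junctions and the boundary
    exons are contained in the corresponding reference exons."""
    if q.strand != r.strand:
        return False
    if _chains_identical(q, r):
        return False
    qj = [(i.start, i.end) for i in q.introns]
    rj = [(i.start, i.end) for i in r.introns]
    if not qj:
        # single-exon query: fragment if contained in some reference exon
        e = q.exons[0]
        return any(re.start <= e.start and e.end <= re.end for re in r.exons)
    n = len(qj)
    for off in range(len(rj) - n + 1):
        if rj[off:off + n] != qj:
            continue
        first, last = q.exons[0], q.exons[-1]
        ref_first, ref_last = r.exons[off], r.exons[off + n]
        if (
            ref_first.start <= first.start
            and first.end == ref_first.end
            and last.start == ref_last.start
            and last.end <= ref_last.end
        ):
            return True
    return False


def _contained_in_intron(q: TranscriptModel, r: TranscriptModel) -> bool:
    span = q.span
    return any(
        i.start <= span.start and span.end <= i.end for i in r.introns
    )


def _contained_in_utr(q: TranscriptModel, r: TranscriptModel) -> bool:
    """Query span inside the genomic extent of the reference 5' or 3' UTR."""
    cds_span = r.cds_span
    if cds_span is None:
        return False
    span = q.span
    left = (r.span.start, cds_span.start)
    right = (cds_span.end, r.span.end)
    for lo, hi in (left, right):
        if lo < hi and lo <= span.start and span.end <= hi:
            return True
    return False


def _exonic_overlap(q: TranscriptModel, r: TranscriptModel) -> bool:
    """Exon-level overlap, ignoring strand."""
    if q.chrom != r.chrom:
        return False
    for qe in q.exons:
        for re_ in r.exons:
            if qe.start < re_.end and re_.start < qe.end:
                return True
    return False


def overlap_class(
    query: TranscriptModel, refs: Iterable[TranscriptModel]
) -> OverlapVerdict:
    """Assign the query one category against the reference set.

    Per-reference verdicts are combined by precedence identical > fragment >
    overlapping_novel > contained_utr > contained_intronic; a query with no
    exonic overlap on either strand is intergenic.
    """
    best = INTERGENIC
    for r in refs:
        if r.chrom != query.chrom:
            continue
        if _chains_identical(query, r):
            cat = IDENTICAL
        elif _is_fragment(query, r):
            cat = FRAGMENT
        elif _contained_in_utr(query, r):
            cat = CONTAINED_UTR
        elif _contained_in_intron(query, r):
            cat = CONTAINED_INTRONIC
        elif _exonic_overlap(query, r):
            cat = OVERLAPPING_NOVEL
        else:
            continue
        if _RANK[cat] < _RANK[best]:
            best = cat
        if best == IDENTICAL:
            break
    return OverlapVerdict(transcript_id=query.transcript_id, category=best)


def apply_merge_filters(
    assembly: Sequence[TranscriptModel],
    refs: Sequence[TranscriptModel],
    tpm: QuantTable,
    min_tpm: float = 1.0,
) -> list[TranscriptModel]:
    """Keep transcripts with TPM > min_tpm in at least one sample AND overlap
    category in {identical, overlapping_novel}. Idempotent; raising min_tpm
    never enlarges the surviving set."""
    missing = [t.transcript_id for t in assembly
               if t.transcript_id not in tpm.transcripts]
    if missing:
        raise KeyError(
            "transcripts absent from quantification: " + ", ".join(sorted(missing))
        )
    kept = []
    for tx in assembly:
        if tpm.max_tpm(tx.transcript_id) <= min_tpm:
            continue
        if overlap_class(tx, refs).category in KEEP_CATEGORIES:
            kept.append(tx)
    return kept


def verdict_report(
    assembly: Sequence[TranscriptModel], refs: Sequence[TranscriptModel]
) -> list[OverlapVerdict]:
    return [overlap_class(tx, refs) for tx in assembly]
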