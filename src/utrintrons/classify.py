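"""Core 3' UTR intron (3UI) detection and classification.

A query transcript carries a 3UI relative to a curated reference transcript
when (i) the reference's start codon falls in an exon of the query, (ii) the
query shares an identical intron chain with the reference within the genomic
span of the reference CDS, and (iii) the query has additional introns 3' of
the reference stop codon. Each such intron is classified:

* ``co3UI`` — shares its donor or acceptor position with an intron located in
  the coding region of *any* reference transcript (typically the signature of
  an early premature termination codon pushing coding introns into the UTR);
* ``e3UI`` — exclusively-UTR intron: neither boundary is used by any coding
  intron (the bona-fide 3' UTR splicing events);

and flagged ``novel`` when its exact (donor, acceptor) pair occurs in no
reference transcript at all.

Distances from the stop codon are spliced (mature-mRNA exonic) distances,
matching the ribosome/EJC geometry of the >55-nt NMD rule; the genomic
distance is carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .annotation import (
    AnnotationError,
    GenomeInterval,
    TranscriptModel,
    acceptor_position,
    donor_position,
    stop_codon_of,
)
from .curation import ReferenceIndices

E3UI = "e3UI"
CO3UI = "co3UI"

NMD_THRESHOLD_NT_DEFAULT = 55


@dataclass(frozen=True)
class UTRIntronRecord:
    """One detected 3UI for one (query transcript, matched reference) pair."""

    transcript_id: str
    gene_id: str
    intron: GenomeInterval
    matched_reference_id: str
    klass: str  # e3UI | co3UI
    novel: bool
    distance_to_stop: int  # spliced nt from stop-codon 3' end to intron donor
    genomic_distance: int
    max_distance_flag: bool = False

    def __post_init__(self) -> None:
        if self.klass not in (E3UI, CO3UI):
            raise ValueError(f"bad class {self.klass!r}")
        if self.distance_to_stop < 0:
            raise ValueError("negative distance")


@dataclass(frozen=True)
class NMDExpectation:
    threshold_nt: int
    expected_sensitive: bool


def nmd_expectation(distance: int,
                    threshold: int = NMD_THRESHOLD_NT_DEFAULT) -> NMDExpectation:
    """Classical EJC rule: a junction strictly more than ``threshold`` nt
    downstream of the stop codon is expected to sensitize the transcript to
    nonsense-mediated decay."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    return NMDExpectation(threshold_nt=threshold,
                          expected_sensitive=distance > threshold)


def candidate_references(
    query: TranscriptModel, refs_hc: Iterable[TranscriptModel]
) -> list[TranscriptModel]:
    """Curated references whose start-codon first base lies in a query exon
    (same chromosome and strand)."""
    out = []
    for ref in refs_hc:
        if ref.chrom != query.chrom or ref.strand != query.strand:
            continue
        if not ref.cds and ref.start_codon is None:
            continue
        try:
            pos = ref.start_codon_first_base()
        except AnnotationError:
            continue
        if query.is_exonic(pos):
            out.append(ref)
    return out


def cds_chain_match(query: TranscriptModel, ref: TranscriptModel) -> bool:
    """True iff query and reference have identical intron chains within the
    genomic span of the reference CDS.

    Intron sets are compared as exact coordinate pairs over introns contained
    in the span; an intron of either transcript that overlaps the span without
    being contained in it counts as a mismatch (intron retention across the
    CDS boundary breaks the chain).
    """
    span = ref.cds_span
    if span is None:
        raise AnnotationError(f"{ref.transcript_id}: reference has no CDS")

    def inside(tx: TranscriptModel):
        contained = set()
        for i in tx.introns:
            if i.start >= span.start and i.end <= span.end:
                contained.add((i.start, i.end))
            elif i.start < span.end and i.end > span.start:
                return None  # straddles the CDS span boundary
        return contained

    q = inside(query)
    r = inside(ref)
    if q is None or r is None:
        return False
    return q == r


def utr_introns(query: TranscriptModel, ref: TranscriptModel) -> list[GenomeInterval]:
    """Query introns whose donor lies transcript-downstream of the last base
    of the reference's stop codon (a donor immediately after the stop codon
    counts, at distance 0)."""
    stop = stop_codon_of(ref)
    if query.strand == "+":
        picked = [i for i in query.introns if i.start >= stop.end]
    else:
        picked = [i for i in query.introns if i.end <= stop.start]
        picked.reverse()  # transcript order
    return picked


def distance_to_stop(
    query: TranscriptModel, ref: TranscriptModel, intron: GenomeInterval
) -> int:
    """Spliced distance (exonic nt along the query) from the base immediately
    after the reference stop codon to the intron donor."""
    stop = stop_codon_of(ref)
    last_base = stop.end - 1 if query.strand == "+" else stop.start
    if not query.is_exonic(last_base):
        raise AnnotationError(
            f"{query.transcript_id}: stop codon of {ref.transcript_id} is not "
            "exonic in the query"
        )
    if query.strand == "+":
        return query.exonic_bases_in(stop.end, intron.start)
    return query.exonic_bases_in(intron.end, stop.start)


def genomic_distance_to_stop(
    query: TranscriptModel, ref: TranscriptModel, intron: GenomeInterval
) -> int:
    stop = stop_codon_of(ref)
    if query.strand == "+":
        return intron.start - stop.end
    return stop.start - intron.end


def _donor_rank(intron: GenomeInterval) -> int:
    """Sort key placing the transcript-downstream-most donor last."""
    return donor_position(intron) if intron.strand == "+" else -donor_position(intron)


def max_distance(records: Sequence[UTRIntronRecord]) -> int:
    """Maximal stop-codon distance across one transcript's 3UI records."""
    if not records:
        raise ValueError("max_distance of empty record list")
    return max(r.distance_to_stop for r in records)


def _flag_max_distance(records: list[UTRIntronRecord]) -> list[UTRIntronRecord]:
    """Set max_distance_flag on the record achieving the transcript's maximal
    distance; ties break towards the most 3' (downstream) intron."""
    if not records:
        return records
    best = max(r.distance_to_stop for r in records)
    winners = [i for i, r in enumerate(records) if r.distance_to_stop == best]
    pick = max(winners, key=lambda i: (_donor_rank(records[i].intron),
                                       records[i].matched_reference_id))
    return [
        replace(r, max_distance_flag=(i == pick)) for i, r in enumerate(records)
    ]


@dataclass
class ClassificationResult:
    records: list[UTRIntronRecord]
    skipped: list[str] = field(default_factory=list)  # queries with no match

    def by_transcript(self) -> dict[str, list[UTRIntronRecord]]:
        out: dict[str, list[UTRIntronRecord]] = {}
        for r in self.records:
            out.setdefault(r.transcript_id, []).append(r)
        return out

    def intron_summary(self) -> dict[tuple[str, int, int], dict]:
        """Per (transcript, intron) summary: co3UI wins over e3UI across
        references ('shares a coding boundary anywhere' demotes the intron);
        novelty and distances are reference-independent or aggregated by max.
        """
        out: dict[tuple[str, int, int], dict] = {}
        for r in self.records:
            key = (r.transcript_id, r.intron.start, r.intron.end)
            cur = out.get(key)
            if cur is None:
                out[key] = {
                    "transcript_id": r.transcript_id,
                    "gene_id": r.gene_id,
                    "chrom": r.intron.chrom,
                    "strand": r.intron.strand,
                    "intron_start": r.intron.start,
                    "intron_end": r.intron.end,
                    "klass": r.klass,
                    "novel": r.novel,
                    "max_distance_to_stop": r.distance_to_stop,
                }
            else:
                if r.klass == CO3UI:
                    cur["klass"] = CO3UI
                cur["max_distance_to_stop"] = max(
                    cur["max_distance_to_stop"], r.distance_to_stop
                )
        return out

    def e3ui_transcripts(self) -> set[str]:
        """Transcripts all of whose 3UIs are e3UI under every matched
        reference (a single co3UI call anywhere excludes the transcript)."""
        status: dict[str, bool] = {}
        for r in self.records:
            status[r.transcript_id] = (
                status.get(r.transcript_id, True) and r.klass == E3UI
            )
        return {tid for tid, ok in status.items() if ok}


def classify_3ui(
    queries: Iterable[TranscriptModel],
    refs_hc: Sequence[TranscriptModel],
    indices: ReferenceIndices,
) -> ClassificationResult:
    """Run detection and classification over a set of query transcripts.

    Output is deterministic and invariant to query input order (records are
    sorted by transcript id, intron coordinates, then reference id). Queries
    with no candidate or no CDS-chain match produce no records and are listed
    in ``skipped``.
    """
    # bucket references by (chrom, strand) once
    buckets: dict[tuple[str, str], list[TranscriptModel]] = {}
    for ref in refs_hc:
        buckets.setdefault((ref.chrom, ref.strand), []).append(ref)

    all_records: list[UTRIntronRecord] = []
    skipped: list[str] = []
    for query in queries:
        cands = candidate_references(
            query, buckets.get((query.chrom, query.strand), ())
        )
        tx_records: list[UTRIntronRecord] = []
        matched_any = False
        for ref in cands:
            try:
                if not cds_chain_match(query, ref):
                    continue
                introns = utr_introns(query, ref)
            except AnnotationError:
                continue
            # a query intron can swallow the reference stop codon entirely;
            # such a pairing has no measurable UTR geometry and is skipped
            if introns:
                last_base = (
                    stop_codon_of(ref).end - 1
                    if query.strand == "+"
                    else stop_codon_of(ref).start
                )
                if not query.is_exonic(last_base):
                    continue
            matched_any = True
            for intron in introns:
                donor = donor_position(intron)
                acceptor = acceptor_position(intron)
                shares_coding = indices.is_coding_boundary(
                    intron.chrom, intron.strand, donor, "donor"
                ) or indices.is_coding_boundary(
                    intron.chrom, intron.strand, acceptor, "acceptor"
                )
                novel = not indices.has_junction(
                    intron.chrom, intron.strand, intron.start, intron.end
                )
                tx_records.append(
                    UTRIntronRecord(
                        transcript_id=query.transcript_id,
                        gene_id=query.gene_id,
                        intron=intron,
                        matched_reference_id=ref.transcript_id,
                        klass=CO3UI if shares_coding else E3UI,
                        novel=novel,
                        distance_to_stop=distance_to_stop(query, ref, intron),
                        genomic_distance=genomic_distance_to_stop(
                            query, ref, intron
                        ),
                    )
                )
        if not matched_any:
            skipped.append(query.transcript_id)
            continue
        tx_records.sort(
            key=lambda r: (r.intron.start, r.intron.end, r.matched_reference_id)
        )
        all_records.extend(_flag_max_distance(tx_records))

    all_records.sort(
        key=lambda r: (
            r.transcript_id, r.intron.start, r.intron.end, r.matched_reference_id
        )
    )
    skipped.sort()
    return ClassificationResult(records=all_records, skipped=skipped)
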