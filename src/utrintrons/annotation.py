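"""Transcript models, GTF I/O and strand-aware coordinate arithmetic.

All internal coordinates are 0-based half-open; the GTF reader/writer converts
from/to the 1-based inclusive convention at the boundary. The Ensembl GTF
dialect is assumed throughout: ``CDS`` features exclude the stop codon and an
explicit ``stop_codon`` feature, when present, takes precedence over deriving
the stop from the CDS.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence


class AnnotationError(ValueError):
    """Invalid transcript structure or unusable annotation."""


class GtfParseError(AnnotationError):
    """Malformed GTF input; message names the offending line number."""


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A genomic interval: 0-based half-open ``[start, end)`` on a strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise AnnotationError(f"negative start {self.start}")
        if self.start >= self.end:
            raise AnnotationError(f"empty/inverted interval {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"strand must be +/- (got {self.strand!r})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def donor_position(intron: GenomeInterval) -> int:
    """Genomic coordinate labelling the transcript-5' (donor) intron boundary.

    On ``+`` this is the first intronic base; on ``-`` the half-open end, so
    that mirror-reflection of a locus maps donors to donors.
    """
    return intron.start if intron.strand == "+" else intron.end


def acceptor_position(intron: GenomeInterval) -> int:
    """Genomic coordinate labelling the transcript-3' (acceptor) boundary."""
    return intron.end if intron.strand == "+" else intron.start


@dataclass(frozen=True)
class IntronChain:
    """Ordered introns of a transcript (genomic order, ascending start)."""

    introns: tuple[GenomeInterval, ...]

    def __len__(self) -> int:
        return len(self.introns)

    def __iter__(self) -> Iterator[GenomeInterval]:
        return iter(self.introns)

    @property
    def donors(self) -> tuple[int, ...]:
        return tuple(donor_position(i) for i in self.introns)

    @property
    def acceptors(self) -> tuple[int, ...]:
        return tuple(acceptor_position(i) for i in self.introns)

    def junctions(self) -> tuple[tuple[str, str, int, int], ...]:
        """(chrom, strand, start, end) keys, one per intron."""
        return tuple((i.chrom, i.strand, i.start, i.end) for i in self.introns)


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exon structure plus optional CDS/stop-codon annotation.

    ``exons`` are sorted by genomic start and non-overlapping. ``cds`` holds
    the coding intervals (stop codon excluded, Ensembl dialect). A stop codon
    split across an exon junction is stored as the interval spanning its first
    to last genomic base with ``stop_codon_split`` set; every distance in this
    package is an exonic walk, so the split is immaterial downstream.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomeInterval, ...]
    cds: tuple[GenomeInterval, ...] | None = None
    stop_codon: GenomeInterval | None = None
    start_codon: GenomeInterval | None = None
    stop_codon_split: bool = False
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript has no exons")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom or ex.strand != self.strand:
                raise AnnotationError(
                    f"{self.transcript_id}: exon on {ex.chrom}/{ex.strand} "
                    f"inconsistent with transcript {self.chrom}/{self.strand}"
                )
            if ex.start < prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons overlap or are unsorted at "
                    f"{ex.start}"
                )
            prev_end = ex.end
        if self.cds is not None:
            for c in self.cds:
                if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                    raise AnnotationError(
                        f"{self.transcript_id}: CDS piece {c.start}..{c.end} not "
                        "contained in any exon"
                    )

    # -- basic geometry -------------------------------------------------

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> IntronChain:
        gaps = []
        for a, b in zip(self.exons, self.exons[1:]):
            gaps.append(GenomeInterval(self.chrom, a.end, b.start, self.strand))
        return IntronChain(tuple(gaps))

    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def is_exonic(self, pos: int) -> bool:
        return any(e.contains(pos) for e in self.exons)

    def exonic_bases_in(self, gstart: int, gend: int) -> int:
        """Number of exonic bases with genomic coordinate in ``[gstart, gend)``."""
        if gstart >= gend:
            return 0
        return sum(
            max(0, min(e.end, gend) - max(e.start, gstart)) for e in self.exons
        )

    def transcript_coordinate(self, pos: int) -> int:
        """Spliced (mature-mRNA) coordinate of an exonic genomic base."""
        if not self.is_exonic(pos):
            raise AnnotationError(
                f"{self.transcript_id}: position {pos} is not exonic"
            )
        upstream = self.exonic_bases_in(self.exons[0].start, pos)
        if self.strand == "+":
            return upstream
        return self.exonic_length() - 1 - upstream

    # -- CDS / codons ---------------------------------------------------

    @property
    def cds_span(self) -> GenomeInterval | None:
        if not self.cds:
            return None
        return GenomeInterval(
            self.chrom,
            min(c.start for c in self.cds),
            max(c.end for c in self.cds),
            self.strand,
        )

    def start_codon_first_base(self) -> int:
        """Genomic coordinate of the first (transcript-order) start-codon base."""
        if self.start_codon is not None:
            sc = self.start_codon
            return sc.start if self.strand == "+" else sc.end - 1
        span = self.cds_span
        if span is None:
            raise AnnotationError(f"{self.transcript_id}: no CDS or start_codon")
        return span.start if self.strand == "+" else span.end - 1

    def tags(self) -> frozenset[str]:
        raw = self.attributes.get("tag", "")
        return frozenset(t for t in raw.split(",") if t)


def introns_of(tx: TranscriptModel) -> IntronChain:
    """Gaps between consecutive sorted exons (empty for single-exon)."""
    return tx.introns


def _walk_exonic(tx: TranscriptModel, from_pos: int, n: int, forward: bool):
    """Collect ``n`` exonic genomic coordinates strictly down/upstream of a
    boundary coordinate, in genomic order of travel."""
    out: list[int] = []
    if forward:
        for e in tx.exons:
            lo = max(e.start, from_pos)
            for p in range(lo, e.end):
                out.append(p)
                if len(out) == n:
                    return out
    else:
        for e in reversed(tx.exons):
            hi = min(e.end, from_pos)
            for p in range(hi - 1, e.start - 1, -1):
                out.append(p)
                if len(out) == n:
                    return out
    return out


def stop_codon_of(tx: TranscriptModel) -> GenomeInterval:
    """The transcript's stop codon (explicit feature preferred, else derived).

    Derivation walks 3 exonic bases transcript-downstream of the CDS 3' end
    (Ensembl dialect: CDS excludes the stop codon).
    """
    if tx.stop_codon is not None:
        return tx.stop_codon
    span = tx.cds_span
    if span is None:
        raise AnnotationError(f"{tx.transcript_id}: no stop codon and no CDS")
    if tx.strand == "+":
        bases = _walk_exonic(tx, span.end, 3, forward=True)
    else:
        bases = _walk_exonic(tx, span.start, 3, forward=False)
    if len(bases) < 3:
        raise AnnotationError(
            f"{tx.transcript_id}: fewer than 3 exonic bases downstream of CDS"
        )
    return GenomeInterval(tx.chrom, min(bases), max(bases) + 1, tx.strand)


def spliced_distance(tx: TranscriptModel, a: int, b: int) -> int:
    """Exonic (mature-transcript) base count between two exonic positions.

    Symmetric and never larger than the genomic distance ``|b - a|``.
    """
    for pos in (a, b):
        if not tx.is_exonic(pos):
            raise AnnotationError(
                f"{tx.transcript_id}: position {pos} falls in an intron or "
                "outside the transcript"
            )
    lo, hi = sorted((a, b))
    return tx.exonic_bases_in(lo, hi)


# ---------------------------------------------------------------------------
# GTF I/O (Ensembl attribute dialect)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"\s*;')


def _parse_attributes(field9: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for key, value in _ATTR_RE.findall(field9):
        if key in attrs:
            attrs[key] = attrs[key] + "," + value
        else:
            attrs[key] = value
    if not attrs:
        raise GtfParseError(f"line {lineno}: unparsable attribute field")
    return attrs


def parse_gtf(path: str | Path, dialect: str = "ensembl") -> list[TranscriptModel]:
    """Read a GTF into TranscriptModels (one per ``transcript_id``).

    Exon coordinates are converted from 1-based inclusive to 0-based half-open
    and sorted ascending regardless of file order. ``CDS``, ``stop_codon`` and
    ``start_codon`` features are attached when present; other feature types
    are ignored. Malformed lines raise :class:`GtfParseError` naming the line.
    """
    if dialect != "ensembl":
        raise ValueError(f"unsupported GTF dialect {dialect!r}")
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, raw = (
                fields
            )
            if feature not in ("exon", "CDS", "stop_codon", "start_codon"):
                continue
            try:
                start = int(start_s) - 1
                end = int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if start < 0 or start >= end:
                raise GtfParseError(f"line {lineno}: bad coordinates {start_s}-{end_s}")
            if strand not in ("+", "-"):
                raise GtfParseError(f"line {lineno}: bad strand {strand!r}")
            attrs = _parse_attributes(raw, lineno)
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id")
            if tid is None or gid is None:
                raise GtfParseError(
                    f"line {lineno}: missing transcript_id/gene_id attribute"
                )
            rec = per_tx.get(tid)
            if rec is None:
                rec = {
                    "gene_id": gid,
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                    "stop": [],
                    "start": [],
                    "attrs": {},
                }
                per_tx[tid] = rec
                order.append(tid)
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise GtfParseError(
                    f"line {lineno}: transcript {tid} mixes chromosomes/strands"
                )
            for k, v in attrs.items():
                if k == "tag":
                    prev = rec["attrs"].get("tag", "")
                    have = set(prev.split(",")) if prev else set()
                    if v not in have:
                        rec["attrs"]["tag"] = prev + "," + v if prev else v
                else:
                    rec["attrs"].setdefault(k, v)
            iv = GenomeInterval(chrom, start, end, strand)
            {"exon": rec["exons"], "CDS": rec["cds"], "stop_codon": rec["stop"],
             "start_codon": rec["start"]}[feature].append(iv)

    out: list[TranscriptModel] = []
    for tid in order:
        rec = per_tx[tid]
        exons = tuple(sorted(rec["exons"], key=lambda e: e.start))
        cds = tuple(sorted(rec["cds"], key=lambda c: c.start)) or None
        stop = None
        split = False
        if rec["stop"]:
            parts = sorted(rec["stop"], key=lambda p: p.start)
            stop = GenomeInterval(
                rec["chrom"], parts[0].start, parts[-1].end, rec["strand"]
            )
            split = len(parts) > 1
        start_c = None
        if rec["start"]:
            parts = sorted(rec["start"], key=lambda p: p.start)
            start_c = GenomeInterval(
                rec["chrom"], parts[0].start, parts[-1].end, rec["strand"]
            )
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=exons,
                cds=cds,
                stop_codon=stop,
                start_codon=start_c,
                stop_codon_split=split,
                attributes=dict(rec["attrs"]),
            )
        )
    return out


def _fmt_attrs(tx: TranscriptModel) -> str:
    parts = [f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";']
    for k, v in tx.attributes.items():
        if k in ("gene_id", "transcript_id"):
            continue
        if k == "tag":
            for t in v.split(","):
                if t:
                    parts.append(f'tag "{t}";')
        else:
            parts.append(f'{k} "{v}";')
    return " ".join(parts)


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path,
              include_cds: bool = True) -> None:
    """Write transcripts as Ensembl-dialect GTF (exon/CDS/codon features)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = _fmt_attrs(tx)
            rows: list[tuple[str, GenomeInterval]] = [("exon", e) for e in tx.exons]
            if include_cds and tx.cds:
                rows += [("CDS", c) for c in tx.cds]
            if include_cds and tx.start_codon is not None:
                rows.append(("start_codon", tx.start_codon))
            if include_cds and tx.stop_codon is not None:
                rows.append(("stop_codon", tx.stop_codon))
            for feature, iv in rows:
                fh.write(
                    f"{tx.chrom}\tutrintrons\t{feature}\t{iv.start + 1}\t{iv.end}"
                    f"\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def intervals_to_bed6(intervals: Iterable[tuple[GenomeInterval, str, float]],
                      path: str | Path) -> None:
    """Write (interval, name, score) triples as BED6."""
    with open(path, "w") as fh:
        for iv, name, score in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


def transcripts_to_bed12(transcripts: Iterable[TranscriptModel],
                         path: str | Path) -> None:
    """Write transcript exon structures as BED12 (thick region = CDS span)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            s = tx.span
            span_cds = tx.cds_span
            thick_s = span_cds.start if span_cds else s.start
            thick_e = span_cds.end if span_cds else s.start
            sizes = ",".join(str(len(e)) for e in tx.exons)
            starts = ",".join(str(e.start - s.start) for e in tx.exons)
            fh.write(
                f"{tx.chrom}\t{s.start}\t{s.end}\t{tx.transcript_id}\t0\t"
                f"{tx.strand}\t{thick_s}\t{thick_e}\t0\t{len(tx.exons)}\t"
                f"{sizes},\t{starts},\n"
            )


# ---------------------------------------------------------------------------
# Locus reflection (used by symmetry tests and fixture tooling)
# ---------------------------------------------------------------------------

def reflect_interval(iv: GenomeInterval, length: int) -> GenomeInterval:
    """Mirror an interval through a contig of ``length`` bp, flipping strand."""
    return GenomeInterval(
        iv.chrom, length - iv.end, length - iv.start,
        "-" if iv.strand == "+" else "+",
    )


def reflect_transcript(tx: TranscriptModel, length: int) -> TranscriptModel:
    """Mirror a transcript through a contig of ``length`` bp (x -> L - x)."""
    flip = "-" if tx.strand == "+" else "+"
    return replace(
        tx,
        strand=flip,
        exons=tuple(sorted((reflect_interval(e, length) for e in tx.exons),
                           key=lambda e: e.start)),
        cds=tuple(sorted((reflect_interval(c, length) for c in tx.cds),
                         key=lambda c: c.start)) if tx.cds else None,
        stop_codon=(reflect_interval(tx.stop_codon, length)
                    if tx.stop_codon else None),
        start_codon=(reflect_interval(tx.start_codon, length)
                     if tx.start_codon else None),
    )
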