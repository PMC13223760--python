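"""Literal brute-force 3UI classifier used as an independent oracle.

Everything here enumerates definitions directly over explicit base-position
lists: no transcript-coordinate arithmetic, no interval algebra, no shared
helpers with the package's optimized classifier. Also hosts a random small
locus generator (queries with <= 4 introns, <= 3 references) that perturbs
transcripts into matching, mismatching and degenerate configurations.
"""

from __future__ import annotations

import numpy as np

from utrintrons.annotation import GenomeInterval, TranscriptModel


def _exonic_positions(tx) -> list[int]:
    """Every exonic genomic base, in transcript (5'->3') order."""
    pos = [p for e in sorted(tx.exons, key=lambda e: e.start)
           for p in range(e.start, e.end)]
    return pos if tx.strand == "+" else pos[::-1]


def _introns(tx) -> list[tuple[int, int]]:
    ex = sorted(tx.exons, key=lambda e: e.start)
    return [(a.end, b.start) for a, b in zip(ex, ex[1:])]


def _brute_stop(tx) -> tuple[int, int]:
    if tx.stop_codon is not None:
        return (tx.stop_codon.start, tx.stop_codon.end)
    pos = _exonic_positions(tx)
    if tx.strand == "+":
        last_cds = max(c.end for c in tx.cds) - 1
    else:
        last_cds = min(c.start for c in tx.cds)
    i = pos.index(last_cds)
    nxt = pos[i + 1:i + 4]
    if len(nxt) < 3:
        raise ValueError("no room for stop codon")
    return (min(nxt), max(nxt) + 1)


def brute_classify(queries, refs_hc, refs_full) -> set[tuple]:
    """Set of (transcript_id, intron_start, intron_end, reference_id, klass,
    novel, distance) tuples derived by literal enumeration."""
    coding_boundaries: set[tuple] = set()
    all_junctions: set[tuple] = set()
    for r in refs_full:
        for (s, e) in _introns(r):
            all_junctions.add((r.chrom, r.strand, s, e))
        if not r.cds:
            continue
        try:
            st = _brute_stop(r)
        except ValueError:
            continue
        lo = min(c.start for c in r.cds)
        hi = max(c.end for c in r.cds)
        for (s, e) in _introns(r):
            if r.strand == "+":
                coding = s >= lo and e <= st[0]
            else:
                coding = s >= st[1] and e <= hi
            if coding:
                dpos = s if r.strand == "+" else e
                apos = e if r.strand == "+" else s
                coding_boundaries.add((r.chrom, r.strand, dpos, "donor"))
                coding_boundaries.add((r.chrom, r.strand, apos, "acceptor"))

    out: set[tuple] = set()
    for q in queries:
        qpos = _exonic_positions(q)
        qpos_set = set(qpos)
        qintrons = _introns(q)
        for r in refs_hc:
            if r.chrom != q.chrom or r.strand != q.strand or not r.cds:
                continue
            start_first = (min(c.start for c in r.cds) if r.strand == "+"
                           else max(c.end for c in r.cds) - 1)
            if start_first not in qpos_set:
                continue
            lo = min(c.start for c in r.cds)
            hi = max(c.end for c in r.cds)

            def contained(introns):
                inside = set()
                for (s, e) in introns:
                    if s >= lo and e <= hi:
                        inside.add((s, e))
                    elif s < hi and e > lo:
                        return None  # straddles the CDS span
                return inside

            qi = contained(qintrons)
            ri = contained(_introns(r))
            if qi is None or ri is None or qi != ri:
                continue
            try:
                st = _brute_stop(r)
            except ValueError:
                continue
            stop_last = st[1] - 1 if q.strand == "+" else st[0]
            post_stop = []
            for (s, e) in qintrons:
                if q.strand == "+" and s >= st[1]:
                    post_stop.append((s, e))
                if q.strand == "-" and e <= st[0]:
                    post_stop.append((s, e))
            if post_stop and stop_last not in qpos_set:
                continue  # stop codon swallowed by a query intron
            for (s, e) in post_stop:
                adj = s - 1 if q.strand == "+" else e  # exon base at the donor
                dist = qpos.index(adj) - qpos.index(stop_last)
                dpos = s if q.strand == "+" else e
                apos = e if q.strand == "+" else s
                shares = (
                    (q.chrom, q.strand, dpos, "donor") in coding_boundaries
                    or (q.chrom, q.strand, apos, "acceptor") in coding_boundaries
                )
                novel = (q.chrom, q.strand, s, e) not in all_junctions
                out.add(
                    (q.transcript_id, s, e, r.transcript_id,
                     "co3UI" if shares else "e3UI", novel, dist)
                )
    return out


# ---------------------------------------------------------------------------
# random small-locus generator
# ---------------------------------------------------------------------------

def _reflect(tx: TranscriptModel, L: int) -> TranscriptModel:
    def f(iv):
        return GenomeInterval(iv.chrom, L - iv.end, L - iv.start,
                              "-" if iv.strand == "+" else "+")
    from dataclasses import replace
    return replace(
        tx,
        strand="-" if tx.strand == "+" else "+",
        exons=tuple(sorted((f(e) for e in tx.exons), key=lambda e: e.start)),
        cds=tuple(sorted((f(c) for c in tx.cds), key=lambda c: c.start))
        if tx.cds else None,
        stop_codon=f(tx.stop_codon) if tx.stop_codon else None,
        start_codon=f(tx.start_codon) if tx.start_codon else None,
    )


def random_locus(rng: np.random.Generator):
    """(queries, refs_hc, refs_full) for one random small instance.

    Built on + then possibly mirrored; queries carry <= 4 introns and at most
    3 references exist. Query perturbations cover identical chains, extra
    post-stop introns, CDS intron insertion/retention, boundary shifts and
    stop-swallowing introns.
    """
    chrom = "c"
    u5 = int(rng.integers(4, 30))
    k = int(rng.integers(0, 3))
    seg = [int(rng.integers(12, 50)) for _ in range(k + 1)]
    ilen = [int(rng.integers(8, 30)) for _ in range(k)]
    d = int(rng.integers(0, 40))
    L3 = int(rng.integers(8, 40))
    tail = int(rng.integers(20, 60))

    exons = []
    cds = []
    pos, cur = u5, 0
    for i in range(k + 1):
        cds.append((pos, pos + seg[i]))
        pos += seg[i]
        if i < k:
            exons.append((cur, pos))
            pos += ilen[i]
            cur = pos
    stop = (pos, pos + 3)
    pos += 3 + d
    donor = pos
    end = pos + L3 + tail

    def mk(tid, exlist, cdslist=None, stop_iv=None):
        return TranscriptModel(
            transcript_id=tid, gene_id="g", chrom=chrom, strand="+",
            exons=tuple(GenomeInterval(chrom, a, b, "+") for a, b in exlist),
            cds=tuple(GenomeInterval(chrom, a, b, "+") for a, b in cdslist)
            if cdslist else None,
            stop_codon=GenomeInterval(chrom, *stop_iv, "+") if stop_iv else None,
        )

    ref_exons = exons + [(cur, end)]
    spliced_exons = exons + [(cur, donor), (donor + L3, end)]
    refs = [mk("ref1", ref_exons, cds,
               stop if rng.random() < 0.7 else None)]
    if rng.random() < 0.4:
        refs.append(mk("ref3", spliced_exons, cds, stop))
    if rng.random() < 0.4 and tail >= 12:
        t0 = donor + L3
        cds2 = cds[:-1] + [(cds[-1][0], donor), (t0, t0 + 6)]
        refs.append(mk("ref2", spliced_exons, cds2, (t0 + 6, t0 + 9)))

    # query: start from the spliced or retained chain, then perturb
    base = spliced_exons if rng.random() < 0.8 else ref_exons
    qex = [list(e) for e in base]
    mode = rng.integers(0, 6)
    if mode == 1 and d >= 10:
        # second post-stop intron inside the pre-3UI UTR stretch
        s2 = stop[1] + int(rng.integers(1, d - 6))
        for i, (a, b) in enumerate(qex):
            if a < s2 and s2 + 4 < b:
                qex[i:i + 1] = [[a, s2], [s2 + 4, b]]
                break
    elif mode == 2 and k >= 1:
        # retention: merge the first two exons (CDS chain mismatch)
        qex[0:2] = [[qex[0][0], qex[1][1]]]
    elif mode == 3 and seg[0] >= 20:
        # novel intron inside the CDS (mismatch)
        s2 = u5 + 5
        qex[0:1] = [[qex[0][0], s2], [s2 + 6, qex[0][1]]]
    elif mode == 4:
        # intron swallowing the stop codon
        s2 = max(stop[0] - 2, qex[-2][0] + 1) if len(qex) >= 2 else stop[0] - 2
        for i, (a, b) in enumerate(qex):
            if a < s2 and stop[1] + 2 < b:
                qex[i:i + 1] = [[a, s2], [stop[1] + 2, b]]
                break
    elif mode == 5:
        # truncate 5' so the start codon may fall outside the query
        cut = u5 + int(rng.integers(0, sum(seg) + 2))
        qex = [[max(a, cut), b] for a, b in qex if b > cut + 1]
    queries = [mk("q", [tuple(e) for e in qex])] if qex else []

    if rng.random() < 0.5:
        L = end + int(rng.integers(0, 20))
        refs = [_reflect(t, L) for t in refs]
        queries = [_reflect(t, L) for t in queries]
    return queries, refs, refs
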