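"""3UI detection and classification: matching, classes, distances, NMD rule,
and brute-force oracle equivalence on random small loci."""

import numpy as np
import pytest

from brute_oracle import brute_classify, random_locus
from conftest import make_tx
from utrintrons.classify import (
    candidate_references,
    cds_chain_match,
    classify_3ui,
    distance_to_stop,
    max_distance,
    nmd_expectation,
    utr_introns,
)
from utrintrons.curation import build_indices


def hc(tx):
    """Stamp high-confidence attributes onto a reference transcript."""
    attrs = dict(tx.attributes)
    attrs.update(
        {"transcript_support_level": "1", "tag": "appris_principal_1"}
    )
    from dataclasses import replace

    return replace(tx, attributes=attrs)


# one gene: REF1 with a CDS intron, query splices an extra 3' UTR intron
REF1 = make_tx(
    tid="ref1",
    exons=((0, 200), (260, 500)),
    cds=((100, 200), (260, 357)),
    stop=(357, 360),
    start=(100, 103),
)
QUERY = make_tx(
    tid="q1",
    exons=((0, 200), (260, 380), (470, 560)),
)


class TestCandidates:
    def test_start_codon_in_query_exon(self):
        assert candidate_references(QUERY, [REF1]) == [REF1]

    def test_opposite_strand_excluded(self):
        ref = make_tx(tid="r-", strand="-", exons=((0, 500),),
                      cds=((100, 360),))
        assert candidate_references(QUERY, [ref]) == []

    def test_start_codon_in_query_intron_excluded(self):
        ref = make_tx(tid="r2", exons=((0, 500),), cds=((220, 360),))
        assert candidate_references(QUERY, [ref]) == []


class TestChainMatch:
    def test_identical_cds_introns(self):
        assert cds_chain_match(QUERY, REF1)

    def test_retention_breaks_match(self):
        q = make_tx(tid="q", exons=((0, 380), (470, 560)))
        assert not cds_chain_match(q, REF1)

    def test_extra_cds_intron_breaks_match(self):
        q = make_tx(
            tid="q", exons=((0, 150), (160, 200), (260, 380), (470, 560))
        )
        assert not cds_chain_match(q, REF1)

    def test_straddling_intron_fails(self):
        # query intron crossing the CDS 3' boundary
        q = make_tx(tid="q", exons=((0, 200), (260, 340), (380, 560)))
        assert not cds_chain_match(q, REF1)


class TestUtrIntrons:
    def test_post_stop_intron_found(self):
        (iv,) = utr_introns(QUERY, REF1)
        assert (iv.start, iv.end) == (380, 470)

    def test_pre_stop_intron_excluded(self):
        assert utr_introns(REF1, REF1) == []

    def test_distance(self):
        (iv,) = utr_introns(QUERY, REF1)
        assert distance_to_stop(QUERY, REF1, iv) == 20

    def test_donor_immediately_after_stop(self):
        q = make_tx(tid="q", exons=((0, 200), (260, 360), (470, 560)))
        (iv,) = utr_introns(q, REF1)
        assert distance_to_stop(q, REF1, iv) == 0


class TestClassification:
    def make_world(self, with_readthrough=False, with_annotated=False):
        refs = [REF1]
        if with_readthrough:
            # isoform whose CDS extends across the query's UTR intron
            refs.append(
                make_tx(
                    tid="ref2",
                    exons=((0, 200), (260, 380), (470, 560)),
                    cds=((100, 200), (260, 380), (470, 500)),
                    stop=(500, 503),
                    start=(100, 103),
                )
            )
        if with_annotated:
            refs.append(
                make_tx(
                    tid="ref3",
                    exons=((0, 200), (260, 380), (470, 560)),
                    cds=((100, 200), (260, 357)),
                    stop=(357, 360),
                    start=(100, 103),
                )
            )
        refs = [hc(r) for r in refs]
        return refs, build_indices(refs, refs)

    def test_novel_e3ui(self):
        refs, idx = self.make_world()
        res = classify_3ui([QUERY], refs, idx)
        (rec,) = res.records
        assert (rec.klass, rec.novel) == ("e3UI", True)
        assert rec.distance_to_stop == 20

    def test_co3ui_via_shared_coding_boundary(self):
        refs, idx = self.make_world(with_readthrough=True)
        res = classify_3ui([QUERY], refs, idx)
        recs = [r for r in res.records if r.matched_reference_id == "ref1"]
        assert all(r.klass == "co3UI" for r in recs)
        assert all(not r.novel for r in recs)

    def test_annotated_e3ui(self):
        refs, idx = self.make_world(with_annotated=True)
        res = classify_3ui([QUERY], refs, idx)
        assert {r.klass for r in res.records} == {"e3UI"}
        assert all(not r.novel for r in res.records)

    def test_unmatched_query_skipped_not_error(self):
        refs, idx = self.make_world()
        orphan = make_tx(tid="far", exons=((5000, 5200),))
        res = classify_3ui([orphan], refs, idx)
        assert res.records == [] and res.skipped == ["far"]

    def test_order_invariance(self):
        refs, idx = self.make_world(with_annotated=True)
        q2 = make_tx(tid="q0", exons=((0, 200), (260, 500)))
        a = classify_3ui([QUERY, q2], refs, idx)
        b = classify_3ui([q2, QUERY], refs, idx)
        assert a.records == b.records and a.skipped == b.skipped


class TestDistanceAggregation:
    def test_multiple_stop_codons_hras_like(self):
        """One donor 8 nt past a distal stop and 135 nt past a proximal
        alternative stop, via two matched references."""
        exons = ((0, 400), (460, 560))
        q = make_tx(tid="q", exons=exons)
        ref_near = make_tx(tid="near", exons=((0, 500),),
                           cds=((100, 389),), stop=(389, 392))
        ref_far = make_tx(tid="far", exons=((0, 500),),
                          cds=((50, 262),), stop=(262, 265))
        refs = [hc(ref_near), hc(ref_far)]
        idx = build_indices(refs, refs)
        res = classify_3ui([q], refs, idx)
        by_ref = {r.matched_reference_id: r for r in res.records}
        assert by_ref["near"].distance_to_stop == 8
        assert by_ref["far"].distance_to_stop == 135
        assert max_distance(res.records) == 135
        assert by_ref["far"].max_distance_flag
        assert not by_ref["near"].max_distance_flag

    def test_ctnnb1_like_common_donor(self):
        q = make_tx(tid="q", exons=((0, 375), (680, 800)))
        ref = make_tx(tid="r", exons=((0, 800),), cds=((100, 357),),
                      stop=(357, 360))
        refs = [hc(ref)]
        idx = build_indices(refs, refs)
        (rec,) = classify_3ui([q], refs, idx).records
        assert rec.distance_to_stop == 15

    def test_max_distance_empty_errors(self):
        with pytest.raises(ValueError):
            max_distance([])


class TestNMDRule:
    @pytest.mark.parametrize(
        "distance,sensitive",
        [(8, False), (55, False), (56, True), (135, True)],
    )
    def test_boundary(self, distance, sensitive):
        assert nmd_expectation(distance).expected_sensitive is sensitive

    def test_configurable_threshold(self):
        assert nmd_expectation(52, threshold=50).expected_sensitive


class TestOracleEquivalence:
    def test_brute_force_agreement_small(self):
        """Optimized classifier matches the literal definition enumerator on
        random small loci (both strands, degenerate perturbations)."""
        rng = np.random.default_rng(424242)
        for _ in range(100):
            queries, refs_hc, refs_full = random_locus(rng)
            idx = build_indices(refs_full, refs_hc)
            res = classify_3ui(queries, refs_hc, idx)
            got = {
                (r.transcript_id, r.intron.start, r.intron.end,
                 r.matched_reference_id, r.klass, r.novel, r.distance_to_stop)
                for r in res.records
            }
            expected = brute_classify(queries, refs_hc, refs_full)
            assert got == expected
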