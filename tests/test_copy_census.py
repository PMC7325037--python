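"""Locus clustering oracle, classification boundaries and census recovery."""

import numpy as np
import pytest

from tcmariner.copy_census import (
    CensusThresholds,
    CopyClass,
    Locus,
    census,
    classify_locus,
    cluster_loci,
)
from tcmariner.element_annotate import TIRPair, annotate
from tcmariner.seqio import HitRecord
from tcmariner.synthetic_data import ElementSpec, GenomeSpec, sim_element, sim_hit_table


def mk_hit(identity, q_start, q_end, subject="scaf1", s_start=1000, query="el"):
    span = q_end - q_start + 1
    return HitRecord(
        query, subject, identity, span, 0, 0, q_start, q_end, s_start, s_start + span - 1,
        1e-20, float(span),
    )


class TestClusterLoci:
    def test_nearby_hits_merge(self):
        hits = [mk_hit(96, 1, 100, s_start=1000), mk_hit(96, 1, 100, s_start=1150)]
        assert len(cluster_loci(hits, element_length=100)) == 1

    def test_different_scaffolds_split(self):
        hits = [mk_hit(96, 1, 100, subject="a"), mk_hit(96, 1, 100, subject="b")]
        assert len(cluster_loci(hits, element_length=100)) == 2

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError):
            cluster_loci([mk_hit(96, 1, 10), mk_hit(96, 1, 10, query="other")], 100)

    def test_single_linkage_oracle(self):
        """Partition equals brute-force single-linkage within max_gap."""
        rng = np.random.default_rng(55)
        for _ in range(200):
            n = int(rng.integers(2, 12))
            hits = []
            for _k in range(n):
                subject = f"s{int(rng.integers(0, 3))}"
                s_start = int(rng.integers(1, 5000))
                span = int(rng.integers(20, 300))
                minus = rng.random() < 0.3
                a, b = s_start, s_start + span - 1
                if minus:
                    a, b = b, a
                hits.append(
                    HitRecord("el", subject, 90.0, span, 0, 0, 1, span, a, b, 1e-9, 1.0)
                )
            max_gap = 150
            loci = cluster_loci(hits, element_length=100, max_gap=max_gap)
            # brute force: union-find over pairs on same subject+strand
            parent = list(range(len(hits)))

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            for i in range(len(hits)):
                for j in range(i + 1, len(hits)):
                    hi, hj = hits[i], hits[j]
                    if hi.subject_id != hj.subject_id or hi.strand != hj.strand:
                        continue
                    (a1, b1), (a2, b2) = hi.subject_interval, hj.subject_interval
                    gap = max(a1, a2) - min(b1, b2)
                    if gap <= max_gap:
                        parent[find(i)] = find(j)
            brute = {}
            for i in range(len(hits)):
                brute.setdefault(find(i), set()).add(id(hits[i]))
            got = [set(id(h) for h in l.hits) for l in loci]
            assert sorted(map(sorted, got)) == sorted(map(sorted, brute.values()))


ELEMENT_LEN = 1000
TIR = TIRPair(tir5=(0, 20), tir3=(980, 1000), length=20, identity_pct=100.0)


def classify_one(*hits, tir=TIR):
    locus = Locus(hits[0].subject_id, hits[0].strand, list(hits))
    return classify_locus(locus, ELEMENT_LEN, tir)


class TestClassifyLocus:
    def test_full_length_boundary_inclusive(self):
        assert classify_one(mk_hit(95.0, 1, 950)) is CopyClass.full_length

    def test_mite_from_two_tir_hits(self):
        got = classify_one(mk_hit(96, 1, 20), mk_hit(96, 981, 1000))
        assert got is CopyClass.mite

    def test_mite_from_one_spanning_hit_low_identity_elsewhere(self):
        # a single high-identity hit covering both TIRs but only 30% of the
        # element is a MITE, not a partial
        got = classify_one(mk_hit(96, 1, 20), mk_hit(96, 981, 1000), mk_hit(81, 1, 500))
        assert got is CopyClass.mite

    def test_partial(self):
        assert classify_one(mk_hit(80.0, 1, 500)) is CopyClass.partial

    def test_non_autonomous(self):
        assert classify_one(mk_hit(60.0, 1, 300)) is CopyClass.non_autonomous

    def test_unclassified_despite_full_coverage(self):
        assert classify_one(mk_hit(40.0, 1, 1000)) is CopyClass.unclassified

    def test_no_tir_never_mite(self):
        got = classify_one(mk_hit(96, 1, 20), mk_hit(96, 981, 1000), tir=None)
        assert got is not CopyClass.mite

    def test_boundaries_exclusive_below(self):
        assert classify_one(mk_hit(94.9, 1, 950)) is not CopyClass.full_length
        assert classify_one(mk_hit(79.9, 1, 500)) is not CopyClass.partial
        assert classify_one(mk_hit(49.9, 1, 300)) is CopyClass.unclassified

    def test_threshold_ordering_validated(self):
        with pytest.raises(ValueError):
            CensusThresholds(full_min_identity_pct=70.0)


class TestCensus:
    def test_empty_hit_table(self):
        el, _ = sim_element(ElementSpec(), 1)
        counts = census([], el, annotate(el))
        assert all(v == 0 for v in counts.values())

    def test_planted_counts_recovered(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            spec = GenomeSpec(
                n_full=int(rng.integers(0, 5)),
                n_partial=int(rng.integers(0, 5)),
                n_mite=int(rng.integers(0, 5)),
                n_nonaut=int(rng.integers(0, 5)),
            )
            el, truth = sim_element(ElementSpec(), rng)
            hits, expected = sim_hit_table(spec, el, (truth.tir5, truth.tir3), rng)
            got = census(hits, el, annotate(el))
            assert {c.value: n for c, n in got.items()} == expected

    def test_counts_conserve_locus_number(self):
        el, truth = sim_element(ElementSpec(), 9)
        hits, _ = sim_hit_table(GenomeSpec(), el, (truth.tir5, truth.tir3), 9)
        counts = census(hits, el, annotate(el))
        assert sum(counts.values()) == len(cluster_loci(hits, len(el.bases)))

    def test_duplicate_assembly_doubles_counts(self):
        """Concatenating the genome twice (duplicate WGS) doubles every
        class count - the motivation for selecting a single assembly."""
        el, truth = sim_element(ElementSpec(), 10)
        hits, _ = sim_hit_table(GenomeSpec(), el, (truth.tir5, truth.tir3), 10)
        doubled = hits + [
            HitRecord(
                h.query_id, h.subject_id + "_dup", h.pct_identity, h.aln_length,
                h.mismatches, h.gap_opens, h.q_start, h.q_end, h.s_start, h.s_end,
                h.evalue, h.bitscore,
            )
            for h in hits
        ]
        c1 = census(hits, el, annotate(el))
        c2 = census(doubled, el, annotate(el))
        assert {k: 2 * v for k, v in c1.items()} == c2

    def test_monotonicity_in_full_threshold(self):
        el, truth = sim_element(ElementSpec(), 11)
        hits, _ = sim_hit_table(GenomeSpec(n_full=4), el, (truth.tir5, truth.tir3), 11)
        base = census(hits, el, annotate(el))[CopyClass.full_length]
        stricter = CensusThresholds(full_min_identity_pct=99.0)
        tighter = census(hits, el, annotate(el), thresholds=stricter)[CopyClass.full_length]
        assert tighter <= base
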