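"""Pairwise identity reporting, genome copy checks and the HTT decision table."""

import numpy as np
import pytest

from tcmariner.htt_screen import (
    CopyReport,
    HTTThresholds,
    PairIdentities,
    _decide,
    genome_copy_check,
    pair_identities,
    screen_pairs,
)
from tcmariner.seqio import HitRecord, NucRecord
from tcmariner.synthetic_data import ElementSpec, sim_element, sim_htt_benchmark


def mk_hit(element_id, identity, subject, span):
    return HitRecord(
        element_id, subject, identity, span, 0, 0, 1, span, 1, span, 1e-20, float(span)
    )


class TestPairIdentities:
    def test_identical_elements_all_hundred(self):
        el, _ = sim_element(ElementSpec(), 50)
        other = NucRecord("copy", el.bases, el.flank5, el.flank3)
        ids = pair_identities(el, other)
        assert ids.aa_identity_dde == 100.0
        assert ids.nt_identity_transposase == 100.0
        assert ids.nt_identity_full_element == 100.0

    def test_partial_element_full_identity_na(self):
        el, truth = sim_element(ElementSpec(), 51)
        # strip the TIRs: a partial element with the ORF only
        partial = NucRecord("partial", el.bases[truth.tir5[1] : truth.tir3[0]])
        ids = pair_identities(el, partial)
        assert ids.nt_identity_transposase is not None
        assert ids.nt_identity_full_element is None

    def test_planted_divergence_tracks_nt_identity(self):
        """~10% of transposase sites diverged gives ~90% nt identity.

        Mutations go to third codon positions of stop-safe codons so the
        reading frame (and hence the longest-ORF choice) is undisturbed.
        """
        rng = np.random.default_rng(52)
        el, truth = sim_element(ElementSpec(), rng)
        bases = list(el.bases)
        orf_len = truth.orf_end - truth.orf_start
        safe = []
        for codon_idx in range(1, orf_len // 3 - 1):
            start = truth.orf_start + 3 * codon_idx
            if "".join(bases[start : start + 2]) not in ("TA", "TG"):
                safe.append(start + 2)
        n_mut = int(0.10 * orf_len)
        assert len(safe) >= n_mut
        picks = rng.choice(len(safe), size=n_mut, replace=False)
        for k in picks:
            p = safe[int(k)]
            bases[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bases[p]]
        mutated = NucRecord("mut", "".join(bases), el.flank5, el.flank3)
        ids = pair_identities(el, mutated)
        assert ids.nt_identity_transposase == pytest.approx(90.0, abs=2.0)

    def test_no_motif_is_unverifiable_not_exception(self):
        a = NucRecord("a", "ATG" + "GGA" * 80 + "TAA")  # ORF without any D/E triad
        b = NucRecord("b", "ATG" + "GGA" * 80 + "TAA")
        ids = pair_identities(a, b)
        assert ids.aa_identity_dde is None and ids.unverifiable_reason


class TestGenomeCopyCheck:
    def test_single_locus_flags_contamination(self):
        el, _ = sim_element(ElementSpec(), 53)
        report = genome_copy_check(el, [mk_hit(el.id, 99.0, "s1", len(el.bases))])
        assert report.copy_count == 1 and report.single_copy

    def test_multi_copy_no_flag(self):
        el, _ = sim_element(ElementSpec(), 54)
        hits = [mk_hit(el.id, 96.0 + k, f"s{k}", len(el.bases)) for k in range(5)]
        report = genome_copy_check(el, hits)
        assert report.copy_count == 5 and not report.single_copy
        assert report.best_identity == 100.0

    def test_planted_single_insertion_always_flagged(self):
        rng = np.random.default_rng(55)
        for _ in range(50):
            el, _ = sim_element(ElementSpec(name=f"e{rng.integers(1e6)}"), rng)
            report = genome_copy_check(
                el, [mk_hit(el.id, float(95 + rng.random() * 5), "scafX", len(el.bases))]
            )
            assert report.single_copy


def ids_ok(full=96.0):
    return PairIdentities(95.0, 96.0, full)


def report(n, best):
    return CopyReport("el", n, [best] * n)


class TestDecisionTable:
    T = HTTThresholds()

    def test_single_copy_rejected(self):
        flags, verdict = _decide(ids_ok(), report(1, 99.0), report(4, 97.0), self.T)
        assert verdict == "rejected_contamination_suspect"
        assert "single_copy_contamination_suspect" in flags

    def test_low_per_copy_identity_rejected_divergent(self):
        flags, verdict = _decide(ids_ok(), report(3, 91.0), report(4, 97.0), self.T)
        assert verdict == "rejected_divergent" and "divergent_pair" in flags

    def test_low_full_element_identity_rejected_divergent(self):
        flags, verdict = _decide(ids_ok(full=75.0), report(3, 97.0), report(4, 97.0), self.T)
        assert verdict == "rejected_divergent"

    def test_asymmetric_identity_rejected(self):
        flags, verdict = _decide(ids_ok(), report(3, 97.0), report(4, 93.0), self.T)
        assert verdict == "rejected_contamination_suspect"
        assert "asymmetric_identity" in flags

    def test_clean_multi_copy_candidate(self):
        flags, verdict = _decide(ids_ok(), report(3, 97.0), report(4, 96.5), self.T)
        assert verdict == "candidate" and not flags

    def test_missing_genome_unverifiable(self):
        flags, verdict = _decide(ids_ok(), None, report(4, 97.0), self.T)
        assert verdict == "unverifiable"

    def test_tightening_never_creates_candidates(self):
        """Any rejection under default thresholds stays a rejection when a
        threshold is tightened."""
        scenarios = [
            (ids_ok(), report(1, 99.0), report(4, 97.0)),
            (ids_ok(), report(3, 91.0), report(4, 97.0)),
            (ids_ok(full=75.0), report(3, 97.0), report(4, 97.0)),
            (ids_ok(), report(3, 97.0), report(4, 93.0)),
        ]
        tighter = HTTThresholds(
            copy_identity_low_pct=94.0, full_element_low_pct=85.0
        )
        for ids, ra, rb in scenarios:
            _, base = _decide(ids, ra, rb, self.T)
            _, hard = _decide(ids, ra, rb, tighter)
            assert base != "candidate"
            assert hard != "candidate"


class TestScreenPairs:
    def test_same_phylum_pair_not_evaluated(self):
        cases, table = sim_htt_benchmark(2, 60)
        vertical = [c for c in cases if c.kind == "vertical"]
        for c in vertical:
            verdicts = screen_pairs(
                [(c.element_a, c.host_a), (c.element_b, c.host_b)],
                table,
                {c.element_a.id: c.hits_a, c.element_b.id: c.hits_b},
            )
            assert verdicts == []

    def test_planted_verdicts(self):
        cases, table = sim_htt_benchmark(5, 61)
        for c in cases:
            verdicts = screen_pairs(
                [(c.element_a, c.host_a), (c.element_b, c.host_b)],
                table,
                {c.element_a.id: c.hits_a, c.element_b.id: c.hits_b},
            )
            if c.kind == "vertical":
                assert verdicts == []
            elif c.kind == "transfer":
                assert verdicts[0].verdict == "candidate"
            else:
                assert verdicts[0].verdict == "rejected_contamination_suspect"

    def test_genome_unavailable_unverifiable(self):
        cases, table = sim_htt_benchmark(1, 62)
        c = next(x for x in cases if x.kind == "transfer")
        verdicts = screen_pairs(
            [(c.element_a, c.host_a), (c.element_b, c.host_b)],
            table,
            {c.element_a.id: c.hits_a},  # no hits for element_b
        )
        assert verdicts[0].verdict == "unverifiable"

    def test_determinism(self):
        cases, table = sim_htt_benchmark(2, 63)
        c = cases[0]
        args = (
            [(c.element_a, c.host_a), (c.element_b, c.host_b)],
            table,
            {c.element_a.id: c.hits_a, c.element_b.id: c.hits_b},
        )
        v1 = screen_pairs(*args)
        v2 = screen_pairs(*args)
        assert [x.verdict for x in v1] == [x.verdict for x in v2]
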