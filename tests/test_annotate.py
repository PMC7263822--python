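"""Tests for hit merging, intronless classification, truncation, ORF and
motif scanning, and synteny support."""
import numpy as np
import pytest

import retrofossil as rf
from retrofossil.annotate import MotifScan, detect_deaminase_motifs
from retrofossil.matcher import find_candidate_hits

from conftest import call_for_copy, parent_call


def _hit(qs, qe, ss, se, strand="+", subject="c1"):
    return rf.CandidateHit(
        query_id="q", subject_id=subject, q_start=qs, q_end=qe,
        s_start=ss, s_end=se, strand=strand,
    )


class TestMergeHits:
    def test_two_collinear_close_hits_merge(self):
        loci = rf.merge_hits([_hit(0, 100, 1000, 1100), _hit(100, 200, 1110, 1210)])
        assert len(loci) == 1
        assert (loci[0].q_start, loci[0].q_end) == (0, 200)
        assert (loci[0].s_start, loci[0].s_end) == (1000, 1210)

    def test_distant_hits_stay_separate(self):
        loci = rf.merge_hits([_hit(0, 100, 1000, 1100), _hit(100, 200, 11100, 11200)])
        assert len(loci) == 2

    def test_mixed_strands_never_merge(self):
        loci = rf.merge_hits(
            [_hit(0, 100, 1000, 1100, "+"), _hit(100, 200, 1110, 1210, "-")]
        )
        assert len(loci) == 2

    def test_non_collinear_mrna_refused(self):
        # second fragment goes backwards on the mRNA: not one retrocopy
        loci = rf.merge_hits([_hit(500, 600, 1000, 1100), _hit(0, 100, 1110, 1210)])
        assert len(loci) == 2

    def test_random_fragmentation_recovers_planted_span(self, rng):
        # fragment one true alignment into abutting chunks; merge restores it
        for _ in range(20):
            span = int(rng.integers(300, 1200))
            q0 = int(rng.integers(0, 50))
            s0 = int(rng.integers(1000, 5000))
            n_frag = int(rng.integers(1, 6))
            cuts = sorted(set(rng.integers(30, span - 30, n_frag - 1))) if n_frag > 1 else []
            bounds = [0] + [int(c) for c in cuts] + [span]
            hits = [
                _hit(q0 + a, q0 + b, s0 + a, s0 + b)
                for a, b in zip(bounds, bounds[1:])
            ]
            order = rng.permutation(len(hits))
            loci = rf.merge_hits([hits[i] for i in order])
            assert len(loci) == 1
            assert (loci[0].q_start, loci[0].s_start) == (q0, s0)
            assert (loci[0].q_end, loci[0].s_end) == (q0 + span, s0 + span)


class TestClassifyIntronless:
    def test_planted_copies_and_parent_recovered(self, small_dataset, small_calls):
        for copy in small_dataset.copies:
            assert call_for_copy(small_calls, copy).is_intronless is True
        assert parent_call(small_calls, small_dataset).is_intronless is False

    def test_single_exon_locus_indeterminate(self, small_dataset):
        parent = small_dataset.parent
        # a hit confined to exon 1 covers no junction
        j0 = parent.mrna_junctions[0]
        hit = _hit(0, j0 - 5, 100, 100 + j0 - 5)
        locus = rf.merge_hits([hit])[0]
        assert rf.classify_intronless(locus, parent) is None


class TestMeasureTruncation:
    def test_planted_truncations_exact_at_age_zero(self, small_dataset, small_calls):
        for copy in small_dataset.copies:
            if copy.age_years == 0:
                call = call_for_copy(small_calls, copy)
                assert call.truncation_5p == copy.truncation_5p

    def test_truncation_cohort_matches_geometric_model(self):
        specs = tuple(rf.CopySpec(age_years=0.0) for _ in range(250))
        config = rf.GeneratorConfig(
            seed=3, copies=specs, n_contigs=4, p_full_length=0.0,
            truncation_mean=300.0,
        )
        # sample truncations through the public generator machinery
        ds = rf.generate_dataset(config)
        truncs = np.array([c.truncation_5p for c in ds.copies], dtype=float)
        truncated = truncs[truncs > 0]
        se = truncated.std(ddof=1) / np.sqrt(truncated.size)
        assert abs(truncated.mean() - 300.0) <= 3 * se

    def test_locus_beyond_mrna_rejected(self, small_dataset):
        parent = small_dataset.parent
        locus = rf.merge_hits([_hit(0, len(parent.mrna_seq) + 10, 0, 10)])[0]
        with pytest.raises(ValueError):
            rf.measure_truncation(locus, parent)


def oracle_longest_orf(seq: str):
    """Brute force: enumerate every ATG, scan to the next in-frame stop."""
    candidates = []
    L = len(seq)

    def scan(s, strand):
        for start in range(L):
            if s[start : start + 3] != "ATG":
                continue
            end = None
            i = start + 3
            while i + 3 <= len(s):
                if s[i : i + 3] in ("TAA", "TAG", "TGA"):
                    end = i + 3
                    break
                i += 3
            if end is None:
                n_cod = (len(s) - start) // 3
                span = (start, start + 3 * n_cod)
            else:
                n_cod = (end - start) // 3 - 1
                span = (start, end)
            if strand == "+":
                candidates.append((n_cod, 0, span[0], span, strand))
            else:
                fwd = (len(s) - span[1], len(s) - span[0])
                candidates.append((n_cod, 1, fwd[0], fwd, strand))

    scan(seq, "+")
    from retrofossil._codec import revcomp

    scan(revcomp(seq), "-")
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    best = candidates[0] if candidates else None
    if best is None or best[0] == 0:
        return (0, 0, 0, "+")
    return (best[3][0], best[3][1], best[0], best[4])


class TestLongestOrf:
    def test_simple_orf(self):
        hit = rf.longest_orf("ATGAAATAA")
        assert (hit.start, hit.end, hit.n_codons) == (0, 9, 2)

    def test_no_atg_gives_empty(self):
        hit = rf.longest_orf("CCCCCCCCC")
        assert hit.n_codons == 0 and (hit.start, hit.end) == (0, 0)

    def test_open_ended_orf_runs_to_last_codon(self):
        hit = rf.longest_orf("ATGAAAAAAA")
        assert (hit.start, hit.end, hit.n_codons) == (0, 9, 3)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(300):
            L = int(rng.integers(10, 400))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
            hit = rf.longest_orf(seq, strand_mode="both")
            start, end, n_cod, strand = oracle_longest_orf(seq)
            assert (hit.start, hit.end, hit.n_codons, hit.strand) == (
                start, end, n_cod, strand,
            )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            rf.longest_orf("")


def oracle_motif_scan(p: str, lo: int = 20, hi: int = 40) -> MotifScan:
    """Position-by-position pattern oracle with the same greedy N->C rule."""
    full, used = [], set()
    i = 0
    n = len(p)
    while i + 2 < n:
        hxe = p[i] == "H" and p[i + 2] == "E"
        hit_c = None
        if hxe:
            for c in range(i + 3 + lo, min(i + 3 + hi, n - 4) + 1):
                if p[c] == "C" and p[c + 3] == "C":
                    hit_c = c
                    break
        if hit_c is not None:
            full.append((i, hit_c + 4))
            used.add(hit_c)
            i = hit_c + 4
        else:
            i += 1
    partial = [
        (c, c + 4)
        for c in range(n - 3)
        if p[c] == "C" and p[c + 3] == "C" and c not in used
        and not any(s <= c < e for s, e in full)
    ]
    return full, partial


class TestDeaminaseMotifs:
    def test_constructed_positive(self):
        seq = "MAHAE" + "K" * 29 + "CAACW"
        scan = detect_deaminase_motifs(seq)
        assert len(scan.full) == 1
        hit = scan.full[0]
        assert seq[hit.start] == "H" and seq[hit.end - 1] == "C"

    def test_poly_alanine_negative(self):
        scan = detect_deaminase_motifs("A" * 100)
        assert scan.full == [] and scan.partial == []

    def test_cxxc_without_hxe_is_partial(self):
        scan = detect_deaminase_motifs("AAAACAACAAAA")
        assert scan.full == []
        assert [(h.start, h.end) for h in scan.partial] == [(4, 8)]

    def test_generator_parent_has_exactly_two_hits(self, small_dataset):
        scan = detect_deaminase_motifs(small_dataset.parent.protein_seq)
        assert [(h.start, h.end) for h in scan.full] == small_dataset.parent_motifs
        assert scan.partial == []

    def test_matches_pattern_oracle(self, rng):
        alphabet = "HCEAKLRS"  # enriched so hits actually occur
        for _ in range(300):
            L = int(rng.integers(20, 120))
            p = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), L))
            scan = detect_deaminase_motifs(p)
            full, partial = oracle_motif_scan(p)
            assert [(h.start, h.end) for h in scan.full] == full
            assert [(h.start, h.end) for h in scan.partial] == partial


class TestSyntenySupport:
    def test_identical_flanks_both_sides(self):
        s = rf.synteny_support("L1", ["A", "B"], ["C", "D"], ["B", "A"], ["D"])
        assert s.category == "both_sides"

    def test_shared_gene_on_one_side(self):
        s = rf.synteny_support("L1", ["A"], ["C"], ["A"], ["X"])
        assert s.category == "one_side"

    def test_empty_flanks_warn_and_none(self):
        with pytest.warns(UserWarning):
            s = rf.synteny_support("L1", [], [], ["A"], ["B"])
        assert s.category == "none"

    def test_matches_set_intersection_oracle(self, rng):
        genes = [f"g{i}" for i in range(12)]
        for _ in range(100):
            pick = lambda: [genes[i] for i in rng.integers(0, 12, rng.integers(0, 5))]
            ua, da, ub, db = pick(), pick(), pick(), pick()
            if not (ua or da) or not (ub or db):
                continue
            s = rf.synteny_support("L", ua, da, ub, db)
            up = set(ua) & set(ub)
            down = set(da) & set(db)
            expect = (
                "both_sides" if up and down else "one_side" if up or down else "none"
            )
            assert s.category == expect
            assert s.shared_upstream == up and s.shared_downstream == down


class TestEndToEndRecovery:
    def test_planted_mutations_recovered_at_age_zero(self, small_dataset, small_calls):
        for copy in small_dataset.copies:
            if copy.age_years != 0 or not copy.planted_mutations:
                continue
            call = call_for_copy(small_calls, copy)
            got = sorted((m.kind, m.parent_codon) for m in call.inactivating_mutations)
            want = sorted((m["kind"], m["parent_codon"]) for m in copy.planted_mutations)
            assert got == want

    def test_clean_age_zero_copy_has_full_orf_and_motifs(
        self, small_dataset, small_calls
    ):
        for copy in small_dataset.copies:
            if copy.age_years == 0 and copy.truncation_5p == 0 and not copy.planted_mutations:
                call = call_for_copy(small_calls, copy)
                assert call.longest_orf.n_codons == small_dataset.config.parent_codons
                assert len(call.motif_hits) == 2
                assert call.inactivating_mutations == []

    def test_matcher_finds_planted_loci_on_both_strands(self, small_dataset):
        hits = find_candidate_hits(
            small_dataset.parent.mrna_seq, dict(small_dataset.genome)
        )
        strands = set()
        for copy in small_dataset.copies:
            over = [
                h for h in hits
                if h.subject_id == copy.subject_id
                and h.s_start < copy.end and copy.start < h.s_end
            ]
            assert over, f"no hits over {copy.copy_id}"
            strands.update(h.strand for h in over)
        assert strands == {"+", "-"}
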