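"""Heptamer matching, window scanning, clusters, and RSS classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ragprint.rss import (
    CANONICAL_HEPTAMER,
    RSSConfig,
    RSSStatus,
    RuleApplied,
    Tolerance,
    classify_cohort,
    classify_rss_status,
    detect_breakpoint_clusters,
    distance_to_nearest_rss,
    heptamer_pfm,
    match_heptamer,
    scan_inside_window,
)
from ragprint.sv_catalog import Breakend, Category, RetainedSide, SVRecord, SVType, revcomp


def oracle_match(seq7: str, tolerance: str, max_tail=2, max_relaxed=3):
    """Literal translation of the matching rule, kept independent of the
    implementation."""
    dev = [seq7[i] != CANONICAL_HEPTAMER[i] for i in range(7)]
    if tolerance == "strict_canonical":
        return seq7 == CANONICAL_HEPTAMER
    if tolerance == "base":
        return seq7[:4] == "CACA" and sum(dev[4:]) <= max_tail
    return seq7[:3] == "CAC" and sum(dev[3:]) <= max_relaxed


class TestMatchHeptamer:
    def test_canonical_matches_every_tolerance(self):
        for tol in Tolerance:
            ok, ndev = match_heptamer("CACAGTG", tol)
            assert ok and ndev == 0

    def test_prefix_violation_fails_base(self):
        ok, _ = match_heptamer("TACAGTG", Tolerance.BASE)
        assert not ok

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError):
            match_heptamer("CACA", Tolerance.BASE)

    @pytest.mark.parametrize("tolerance", ["strict_canonical", "base", "relaxed"])
    def test_exhaustive_enumeration_matches_rule_oracle(self, tolerance):
        # all 4^7 heptamers against the independent literal-rule oracle
        for mer in itertools.product("ACGT", repeat=7):
            seq = "".join(mer)
            ok, ndev = match_heptamer(seq, tolerance)
            assert ok == oracle_match(seq, tolerance), seq
            assert ndev == sum(a != b for a, b in zip(seq, CANONICAL_HEPTAMER))

    def test_n_counts_as_deviation(self):
        ok, ndev = match_heptamer("CACANNN", Tolerance.BASE)
        assert not ok and ndev == 3
        ok, _ = match_heptamer("CACAGTN", Tolerance.BASE)
        assert ok  # one tail deviation within budget


class TestScanWindow:
    def test_planted_motif_at_distance_zero(self):
        window = "CACAGTG" + "T" * 23
        hits = scan_inside_window(window, "plus")
        assert hits[0].distance_bp == 0 and hits[0].motif_seq == "CACAGTG"

    def test_all_n_window_yields_nothing(self):
        assert scan_inside_window("N" * 30, "plus") == []

    def test_minus_scan_reports_reverse_complement_motif(self):
        # CACTGTG on the forward strand at the end of a bnd2-inside window
        window = "T" * 23 + "CACTGTG"
        hits = scan_inside_window(window, "minus")
        assert len(hits) >= 1
        assert hits[0].motif_seq == "CACAGTG"
        assert hits[0].distance_bp == 0
        assert hits[0].orientation == "minus"

    def test_ref_pos_mapping_minus(self):
        window = "T" * 10 + "CACTGTG" + "A" * 13
        hits = scan_inside_window(window, "minus", ref_start=500)
        assert any(h.ref_pos == 510 for h in hits)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=7, max_size=50),
           st.sampled_from(["plus", "minus"]))
    def test_scan_equals_exhaustive_substring_enumeration(self, window, orientation):
        hits = scan_inside_window(window, orientation)
        oriented = revcomp(window.upper()) if orientation == "minus" else window.upper()
        expected = set()
        for off in range(len(oriented) - 6):
            mer = oriented[off : off + 7]
            if "N" not in mer and oracle_match(mer, "base"):
                expected.add((off, mer))
        assert {(h.distance_bp, h.motif_seq) for h in hits} == expected


def _sv(p, q, sv_id="sv", sample="S", chrom="c", category=Category.COOPERATING):
    return SVRecord(
        sv_id=sv_id, sample_id=sample, sv_type=SVType.DEL,
        bnd1=Breakend(chrom, p, RetainedSide.LEFT),
        bnd2=Breakend(chrom, q, RetainedSide.RIGHT),
        category=category, caller_hom_len=0,
    )


class TestClusters:
    def test_single_linkage_toy(self):
        svs = [_sv(100, 150, "a", "S1"), _sv(220, 5000, "b", "S2")]
        clusters = detect_breakpoint_clusters(svs, cluster_window=300, min_cluster_size=3)
        assert len(clusters) == 1
        assert (clusters[0].start, clusters[0].end) == (100, 220)
        assert len(clusters[0].member_breakends) == 3

    def test_below_min_size_discarded(self):
        svs = [_sv(100, 5000, "a", "S1")]
        assert detect_breakpoint_clusters(svs) == []

    def test_allowlist_interval_attaches_motif(self):
        svs = [_sv(100, 150, "a"), _sv(220, 5000, "b")]
        clusters = detect_breakpoint_clusters(
            svs, allowlist=[("c", 0, 300, "CATACTG")]
        )
        assert clusters[0].allowlist_motif == "CATACTG"


def _ref_with(p, q, motif1=None, motif2=None, length=6000, seed=0):
    """Toy reference: low-complexity background with motifs planted inside
    the two breakpoints (motif2 written reverse-complemented)."""
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list("AT"), size=length)))  # no CAC background
    if motif1 is not None:
        d, m = motif1
        seq[p + d : p + d + 7] = list(m)
    if motif2 is not None:
        d, m = motif2
        seq[q - d - 7 : q - d] = list(revcomp(m))
    return {"c": "".join(seq)}


class TestClassify:
    def test_base_rule_both_canonical(self):
        ref = _ref_with(1000, 3000, motif1=(0, "CACAGTG"), motif2=(0, "CACAGTG"))
        cl = classify_rss_status(_sv(1000, 3000), ref)
        assert cl.status is RSSStatus.PLUS
        assert cl.rule_applied is RuleApplied.BASE
        assert cl.motifs_counted == 2
        assert cl.best_hit_bnd1.distance_bp == 0 and cl.best_hit_bnd2.distance_bp == 0

    def test_exception1_relaxed_partner(self):
        # CACTGTA keeps only the CAC prefix -> needs exception 1
        ref = _ref_with(1000, 3000, motif1=(3, "CACAGTG"), motif2=(5, "CACTGTA"))
        cl = classify_rss_status(_sv(1000, 3000), ref)
        assert cl.status is RSSStatus.PLUS
        assert cl.rule_applied is RuleApplied.EXCEPTION1

    def test_exception2_distant_partner(self):
        ref = _ref_with(1000, 3000, motif1=(2, "CACAGTG"), motif2=(60, "CACAGTG"))
        cl = classify_rss_status(_sv(1000, 3000), ref)
        assert cl.status is RSSStatus.PLUS
        assert cl.rule_applied is RuleApplied.EXCEPTION2
        assert cl.best_hit_bnd2.distance_bp == 60

    def test_no_motifs_is_minus(self):
        ref = _ref_with(1000, 3000)
        cl = classify_rss_status(_sv(1000, 3000), ref)
        assert cl.status is RSSStatus.MINUS
        assert cl.rule_applied is RuleApplied.NONE
        assert cl.motifs_counted == 0

    def test_unscannable_windows_flagged_minus(self):
        ref = {"c": "N" * 6000}
        cl = classify_rss_status(_sv(1000, 3000), ref)
        assert cl.status is RSSStatus.MINUS
        assert "unscannable" in cl.flags

    def test_partition_and_exclusive_status(self, small_cohort):
        cls, _ = classify_cohort(
            small_cohort.svs, small_cohort.ref, allowlist=small_cohort.allowlist
        )
        assert len(cls) == len(small_cohort.svs)
        for c in cls:
            assert c.status in (RSSStatus.PLUS, RSSStatus.MINUS)

    def test_monotonicity_relaxing_never_loses_plus(self, small_cohort):
        base_cfg = RSSConfig()
        loose_cfg = RSSConfig(max_tail_mismatches=3, max_relaxed_mismatches=4,
                              extended_window=150)
        tight, _ = classify_cohort(small_cohort.svs, small_cohort.ref, base_cfg,
                                   allowlist=small_cohort.allowlist)
        loose, _ = classify_cohort(small_cohort.svs, small_cohort.ref, loose_cfg,
                                   allowlist=small_cohort.allowlist)
        for a, b in zip(tight, loose):
            if a.status is RSSStatus.PLUS:
                assert b.status is RSSStatus.PLUS

    def test_strand_duality_on_mirrored_reference(self):
        ref = _ref_with(1000, 3000, motif1=(4, "CACAGTG"), motif2=(9, "CACAGTA"))
        n = len(ref["c"])
        mirror = {"c": revcomp(ref["c"])}
        cl = classify_rss_status(_sv(1000, 3000), ref)
        cl_m = classify_rss_status(_sv(n - 3000, n - 1000), mirror)
        assert cl.status == cl_m.status
        assert cl.rule_applied == cl_m.rule_applied
        assert cl.motifs_counted == cl_m.motifs_counted

    def test_cluster_rescue_and_allowlist_in_cohort(self, small_cohort):
        cls, clusters = classify_cohort(
            small_cohort.svs, small_cohort.ref, allowlist=small_cohort.allowlist
        )
        rules = {c.rule_applied for c in cls}
        assert RuleApplied.CLUSTER_RESCUE in rules
        assert RuleApplied.EXCEPTION4 in rules
        rescued = [c for c in cls if c.rule_applied is RuleApplied.CLUSTER_RESCUE]
        for c in rescued:
            assert c.motifs_counted == 1
            assert small_cohort.truth[c.sv_id].rescue_planted

    def test_motif_count_identity(self, small_cohort):
        """sum(motifs_counted) == 2 * (#RSS+) - (#cluster-rescued breakends)."""
        cls, _ = classify_cohort(
            small_cohort.svs, small_cohort.ref, allowlist=small_cohort.allowlist
        )
        n_plus = sum(c.status is RSSStatus.PLUS for c in cls)
        n_rescued = sum(c.rescued_breakend is not None for c in cls)
        assert sum(c.motifs_counted for c in cls) == 2 * n_plus - n_rescued
        assert n_rescued >= 1

    def test_classifier_recovers_planted_truth(self, small_cohort):
        cls, _ = classify_cohort(
            small_cohort.svs, small_cohort.ref, allowlist=small_cohort.allowlist
        )
        truth = small_cohort.truth
        rag = [c for c in cls if truth[c.sv_id].is_rag]
        neg = [c for c in cls if not truth[c.sv_id].rss_planted]
        sens = np.mean([c.status is RSSStatus.PLUS for c in rag])
        spec = np.mean([c.status is RSSStatus.MINUS for c in neg])
        assert sens >= 0.95
        assert spec >= 0.90


class TestDistance:
    def test_planted_offset_recovered(self):
        ref = _ref_with(1000, 3000, motif1=(12, "CACAGTG"))
        bnd = Breakend("c", 1000, RetainedSide.LEFT)
        assert distance_to_nearest_rss(bnd, ref) == 12

    def test_absent_when_out_of_range(self):
        ref = _ref_with(1000, 3000)
        bnd = Breakend("c", 1000, RetainedSide.LEFT)
        assert distance_to_nearest_rss(bnd, ref, max_search=200) is None

    def test_cohort_distances_track_planted_offsets(self, small_cohort):
        truth = small_cohort.truth
        agree = total = 0
        for sv in small_cohort.svs:
            t = truth[sv.sv_id]
            if not t.is_rag or t.d1 is None:
                continue
            d = distance_to_nearest_rss(sv.bnd1, small_cohort.ref)
            total += 1
            agree += d == t.d1
        assert total > 50
        assert agree / total >= 0.90  # occasional nearer background motif


class TestPFM:
    def test_canonical_one_hot(self):
        from ragprint.rss import RSSHit, RSSClassification

        hit = RSSHit("CACAGTG", 0, "bnd1", "plus", 0, 0)
        cls = [
            RSSClassification("s%d" % i, RSSStatus.PLUS, hit, None,
                              RuleApplied.BASE, 1)
            for i in range(10)
        ]
        pfm = heptamer_pfm(cls)
        order = "ACGT"
        for i, b in enumerate("CACAGTG"):
            assert pfm[i, order.index(b)] == 10
            assert pfm[i].sum() == 10

    def test_mixed_final_position(self):
        from ragprint.rss import RSSHit, RSSClassification

        mk = lambda m, i: RSSClassification(
            f"s{i}", RSSStatus.PLUS, RSSHit(m, 0, "bnd1", "plus", 0, 0), None,
            RuleApplied.BASE, 1)
        cls = [mk("CACAGTG", i) for i in range(5)] + [mk("CACAGTA", 5 + i) for i in range(5)]
        pfm = heptamer_pfm(cls)
        assert pfm[6, 2] == 5 and pfm[6, 0] == 5  # G:5, A:5

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            heptamer_pfm([])

    def test_cohort_pfm_equals_direct_tally(self, small_cohort):
        cls, _ = classify_cohort(
            small_cohort.svs, small_cohort.ref, allowlist=small_cohort.allowlist
        )
        plus = [c for c in cls if c.status is RSSStatus.PLUS]
        pfm = heptamer_pfm(plus)
        # independent tally
        tally = np.zeros((7, 4), dtype=int)
        order = {"A": 0, "C": 1, "G": 2, "T": 3}
        for c in plus:
            for h in (c.best_hit_bnd1, c.best_hit_bnd2):
                if h is None:
                    continue
                for i, b in enumerate(h.motif_seq):
                    tally[i, order[b]] += 1
        assert (pfm == tally).all()
        assert pfm.sum() == 7 * sum(c.motifs_counted for c in plus)
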