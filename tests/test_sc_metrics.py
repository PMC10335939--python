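"""QC/marker filtering, gene-set scoring, phase assignment, Shannon index."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ragprint.sc_metrics import (
    CellMatrix,
    Phase,
    assign_phase,
    cycling_fraction,
    diversity_by_sample,
    leukemic_filter,
    normalize_log2,
    phase_cutoffs,
    qc_filter,
    score_gene_set,
    shannon_index,
)


def _matrix(counts, genes=None, cells=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[1])]
    cells = cells or [f"c{i}" for i in range(counts.shape[0])]
    return CellMatrix(genes=genes, cells=cells, counts=counts)


class TestQCFilter:
    def test_high_mito_removed_boundary_retained(self):
        genes = ["MT-1", "RP-1", "x", "y", "z"]
        counts = np.array([
            [35, 10, 20, 20, 15],  # mito 35% -> removed
            [30, 10, 30, 15, 15],  # mito exactly 30% -> retained
            [5, 70, 15, 5, 5],     # ribo 70% -> removed
        ])
        kept = qc_filter(_matrix(counts, genes), ["MT-1"], ["RP-1"], min_genes=2)
        assert kept == ["c1"]

    def test_min_genes_boundary_exactly_1000_retained(self):
        n_genes = 1200
        row_pass = np.zeros(n_genes, dtype=int)
        row_pass[:1000] = 1  # exactly 1,000 expressed genes -> retained
        row_fail = np.zeros(n_genes, dtype=int)
        row_fail[:999] = 1
        genes = ["MT-1", "RP-1"] + [f"g{i}" for i in range(n_genes - 2)]
        kept = qc_filter(_matrix(np.vstack([row_pass, row_fail]), genes),
                         ["MT-1"], ["RP-1"])
        assert kept == ["c0"]

    def test_empty_gene_lists_raise(self):
        with pytest.raises(ValueError):
            qc_filter(_matrix([[1, 2]]), [], ["g0"])

    def test_idempotent(self, sc_bundle):
        from ragprint.simulate import MITO_GENES, RIBO_GENES

        m = sc_bundle["matrix"]
        kept = qc_filter(m, MITO_GENES, RIBO_GENES)
        m2 = m.subset_cells(kept)
        kept2 = qc_filter(m2, MITO_GENES, RIBO_GENES)
        assert kept2 == kept

    def test_planted_failures_exactly_removed(self, sc_bundle):
        from ragprint.simulate import MITO_GENES, RIBO_GENES

        m, truth = sc_bundle["matrix"], sc_bundle["truth"]
        kept = qc_filter(m, MITO_GENES, RIBO_GENES)
        removed = set(m.cells) - set(kept)
        assert removed == set(truth.index[truth.qc_fail != ""])


class TestLeukemicFilter:
    GENES = ["DNTT", "LYZ", "GZMH", "IL32", "CD3E", "CD3G", "CD8A", "x"]

    def _m(self, rows, cells=None):
        return _matrix(np.array(rows), genes=self.GENES, cells=cells)

    def test_marker_rules(self):
        rows = [
            [0, 5, 0, 0, 0, 0, 0, 1],  # no DNTT + LYZ -> removed
            [2, 5, 0, 0, 0, 0, 0, 1],  # DNTT present -> retained
            [2, 0, 0, 0, 3, 0, 0, 1],  # CD3E -> removed regardless of DNTT
            [0, 0, 0, 0, 0, 0, 0, 1],  # no markers at all -> retained
        ]
        m = self._m(rows)
        kept = leukemic_filter(m, {c: "k" for c in m.cells})
        assert kept == ["c1", "c3"]

    def test_cluster_removed_above_60_percent(self):
        rows = [[0, 5, 0, 0, 0, 0, 0, 1]] * 7 + [[2, 0, 0, 0, 0, 0, 0, 1]] * 3
        m = self._m(rows)
        kept = leukemic_filter(m, {c: "k" for c in m.cells})
        assert kept == []  # 7/10 flagged -> whole cluster dropped

    def test_cluster_kept_at_60_percent(self):
        rows = [[0, 5, 0, 0, 0, 0, 0, 1]] * 6 + [[2, 0, 0, 0, 0, 0, 0, 1]] * 4
        m = self._m(rows)
        kept = leukemic_filter(m, {c: "k" for c in m.cells})
        assert len(kept) == 4  # flagged cells removed, cluster survives

    def test_missing_marker_warns_not_fails(self, caplog):
        m = _matrix([[1, 2], [0, 3]], genes=["DNTT", "x"])
        with caplog.at_level("WARNING"):
            kept = leukemic_filter(m, {c: "k" for c in m.cells})
        assert kept == ["c0", "c1"]
        assert "absent" in caplog.text

    def test_planted_contaminants_exactly_removed(self, sc_bundle):
        from ragprint.simulate import MITO_GENES, RIBO_GENES

        m, truth = sc_bundle["matrix"], sc_bundle["truth"]
        m2 = m.subset_cells(qc_filter(m, MITO_GENES, RIBO_GENES))
        kept = leukemic_filter(m2, sc_bundle["cluster_labels"])
        removed = set(m2.cells) - set(kept)
        assert removed == set(truth.index[truth.non_leukemic]) & set(m2.cells)


class TestScoring:
    def test_zero_cell_scores_zero(self):
        m = _matrix([[0, 0, 0], [1, 2, 3]])
        scores = score_gene_set(m, ["g0", "g1"])
        assert scores[0] == 0.0

    def test_one_gene_identity(self):
        m = _matrix([[4, 4], [2, 6]])
        lognorm = normalize_log2(m, scale=8.0)
        scores = score_gene_set(m, ["g0"], lognorm=lognorm)
        assert scores[0] == pytest.approx(math.log2(4 / 8 * 8 + 1))
        assert scores[1] == pytest.approx(math.log2(2 / 8 * 8 + 1))

    def test_no_member_present_raises(self):
        with pytest.raises(ValueError):
            score_gene_set(_matrix([[1]]), ["nope"])

    def test_planted_cycling_cells_score_higher(self, sc_bundle):
        m, truth, sets = (sc_bundle["matrix"], sc_bundle["truth"],
                          sc_bundle["gene_sets"])
        scores = score_gene_set(m, sets["G2M"])
        t = truth.loc[m.cells]
        ok_cells = (t.qc_fail == "").to_numpy()
        hi = scores[(t.phase == "G2M").to_numpy() & ok_cells]
        lo = scores[(t.phase != "G2M").to_numpy() & ok_cells]
        assert hi.min() > np.percentile(lo, 99)


class TestPhase:
    def test_all_equal_scores_all_g0(self):
        calls = assign_phase([1.0] * 5, [2.0] * 5)
        assert all(c.phase is Phase.G0 for c in calls)

    def test_truth_table_with_explicit_cutoffs(self):
        calls = assign_phase(
            [0.0, 2.0, 0.0, 2.0], [0.0, 0.0, 2.0, 2.0], cutoffs=(1.0, 1.0)
        )
        assert [c.phase for c in calls] == [Phase.G0, Phase.G1S, Phase.G2M, Phase.G2M]

    def test_boundary_is_not_exceeding(self):
        calls = assign_phase([1.0, 1.0001], [0.0, 0.0], cutoffs=(1.0, 1.0))
        assert calls[0].phase is Phase.G0
        assert calls[1].phase is Phase.G1S

    def test_partition(self, rng):
        g1s, g2m = rng.normal(size=500), rng.normal(size=500)
        calls = assign_phase(g1s, g2m)
        assert len(calls) == 500
        assert sum(c.phase is Phase.G0 for c in calls) + sum(
            c.phase is Phase.G1S for c in calls
        ) + sum(c.phase is Phase.G2M for c in calls) == 500

    def test_subsample_cutoffs_differ_from_pooled(self, rng):
        g1s = np.concatenate([rng.normal(0, 1, 400), rng.normal(3, 1, 100)])
        pooled = phase_cutoffs(g1s, g1s)
        subset = phase_cutoffs(g1s[:400], g1s[:400])
        assert pooled[0] != pytest.approx(subset[0])

    def test_fewer_than_two_cells_raise(self):
        with pytest.raises(ValueError):
            assign_phase([1.0], [1.0])

    def test_planted_cycling_fraction_recovered(self, sc_bundle):
        from ragprint.simulate import MITO_GENES, RIBO_GENES

        m, truth, sets = (sc_bundle["matrix"], sc_bundle["truth"],
                          sc_bundle["gene_sets"])
        m = m.subset_cells(qc_filter(m, MITO_GENES, RIBO_GENES))
        m = m.subset_cells(leukemic_filter(m, sc_bundle["cluster_labels"]))
        g1s = score_gene_set(m, sets["G1S"])
        g2m = score_gene_set(m, sets["G2M"])
        calls = assign_phase(g1s, g2m, cells=m.cells)
        t = truth.loc[m.cells]
        for subtype in ("Early-Pro", "Inter-Pro", "Late-Pro"):
            idx = (t.subtype == subtype).to_numpy()
            got = cycling_fraction([c for c, k in zip(calls, idx) if k])
            planted = float((t.phase[idx] != "G0").mean())
            assert got == pytest.approx(planted, abs=0.02)


class TestCycling:
    def test_extremes_and_arithmetic(self):
        mk = lambda ph: [type("C", (), {"phase": p})() for p in ph]
        assert cycling_fraction(mk([Phase.G0] * 4)) == 0.0
        assert cycling_fraction(mk([Phase.G2M] * 4)) == 1.0
        assert cycling_fraction(
            mk([Phase.G1S] * 2 + [Phase.G2M] * 3 + [Phase.G0] * 5)
        ) == 0.5

    def test_identity_with_g0_complement(self, rng):
        phases = rng.choice([Phase.G0, Phase.G1S, Phase.G2M], size=200)
        calls = [type("C", (), {"phase": p})() for p in phases]
        assert cycling_fraction(calls) == pytest.approx(
            1 - np.mean([p is Phase.G0 for p in phases])
        )


class TestShannon:
    def test_single_category_zero(self):
        assert shannon_index({"a": 7}) == 0.0

    def test_uniform_closed_form(self):
        assert shannon_index({k: 5 for k in "abcd"}) == pytest.approx(math.log(4),
                                                                      abs=1e-12)

    def test_known_value(self):
        assert shannon_index({"a": 2, "b": 1, "c": 1}) == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            shannon_index({"a": 0})

    def test_log2_base_option(self):
        assert shannon_index({k: 1 for k in "abcd"}, base=2) == pytest.approx(2.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=2, max_size=8))
    def test_permutation_invariant_and_below_uniform_max(self, counts):
        keys = [f"k{i}" for i in range(len(counts))]
        h = shannon_index(dict(zip(keys, counts)))
        h_perm = shannon_index(dict(zip(keys, reversed(counts))))
        assert h == pytest.approx(h_perm)
        assert h <= math.log(len(counts)) + 1e-12

    def test_diversity_by_sample_recovers_planted_profiles(self, sc_bundle):
        truth = sc_bundle["truth"]
        leuk = truth[(truth.qc_fail == "") & (~truth.non_leukemic)].reset_index()
        res = diversity_by_sample(leuk.rename(columns={"lineage": "annotation"}))
        cfg = sc_bundle["cfg"]
        subtype_of = dict(cfg.sc_samples)
        for r in res:
            profile = cfg.sc_lineage_profiles[subtype_of[r.sample_id]]
            h_planted = -sum(p * math.log(p) for p in profile.values())
            assert r.shannon_h == pytest.approx(h_planted, abs=0.25)
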