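import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metaexpr.discovery import (CorrelationRecord, DERecord, ceg_votes,
                                correlate_target, de_per_dataset, deg_votes,
                                intersect)
from statsmodels.stats.multitest import multipletests

from conftest import make_cohort


def corr_rec(gene, cid, r, p):
    return CorrelationRecord(gene=gene, cohort_id=cid, r=r, p=p)


def de_rec(gene, cid, lfc, adj_p):
    return DERecord(gene=gene, cohort_id=cid, log2fc=lfc, p=adj_p, adj_p=adj_p)


class TestCorrelateTarget:
    def make(self):
        rng = np.random.default_rng(11)
        base = rng.normal(8, 1, size=20)
        values = np.vstack([base, base, -base, rng.normal(8, 1, 20),
                            np.full(20, 3.0)])
        return make_cohort(values, ["MAOA", "COPY", "ANTI", "NOISE", "FLAT"],
                           [f"c{i}" for i in range(10)],
                           [f"n{i}" for i in range(10)])

    def test_self_copy_and_mirror(self):
        records = {r.gene: r for r in correlate_target(self.make(), "MAOA")}
        assert records["COPY"].r == pytest.approx(1.0)
        assert records["COPY"].p < 1e-10
        assert records["ANTI"].r == pytest.approx(-1.0)
        assert "MAOA" not in records  # target excluded from its own screen

    def test_constant_gene_flagged(self):
        records = {r.gene: r for r in correlate_target(self.make(), "MAOA")}
        assert records["FLAT"].constant
        assert records["FLAT"].r == 0.0 and records["FLAT"].p == 1.0

    def test_t_based_p_value(self):
        # r=0.3 at n=20: t = 0.3*sqrt(18/0.91), p = 0.199 two-sided
        n = 20
        rng = np.random.default_rng(0)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        # construct a gene with exact sample correlation 0.3 to the target
        x = (x - x.mean()) / x.std()
        y = y - y.mean()
        y -= x * (x @ y) / (x @ x)  # orthogonalize
        y /= y.std()
        g = 0.3 * x + np.sqrt(1 - 0.09) * y
        cohort = make_cohort(np.vstack([x, g]), ["MAOA", "G"],
                             [f"c{i}" for i in range(10)],
                             [f"n{i}" for i in range(10)])
        rec = correlate_target(cohort, "MAOA")[0]
        assert rec.r == pytest.approx(0.3, abs=1e-12)
        assert rec.p == pytest.approx(0.199, abs=5e-4)


class TestDePerDataset:
    def test_planted_deg_recovered(self, demo_study):
        cohorts, _, truth = demo_study
        records = {r.gene: r for r in de_per_dataset(cohorts[0])}
        planted_down = [g for g in truth.down_degs if g not in truth.pos_cegs][0]
        rec = records[planted_down]
        assert rec.log2fc == pytest.approx(-1.5, abs=0.4)
        assert rec.adj_p < 0.05

    def test_null_calibration_of_p_values(self):
        rng = np.random.default_rng(21)
        cohort = make_cohort(rng.normal(8, 1, size=(400, 40)),
                             [f"G{i}" for i in range(400)],
                             [f"c{i}" for i in range(20)],
                             [f"n{i}" for i in range(20)])
        records = de_per_dataset(cohort)
        frac = np.mean([r.p < 0.05 for r in records])
        assert 0.02 < frac < 0.08

    def test_bh_step_up_hand_example(self):
        adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        assert adj.tolist() == pytest.approx([0.03, 0.03, 0.04])
        # and the same adjustment emerges from the per-cohort screen
        rng = np.random.default_rng(3)
        cohort = make_cohort(rng.normal(8, 1, (3, 12)), ["A", "B", "C"],
                             [f"c{i}" for i in range(6)],
                             [f"n{i}" for i in range(6)])
        records = de_per_dataset(cohort)
        raw = [r.p for r in records]
        expected = multipletests(raw, method="fdr_bh")[1]
        assert [r.adj_p for r in records] == pytest.approx(expected.tolist())


class TestVotes:
    def test_strict_r_boundary_no_vote(self):
        records = [corr_rec("G", f"c{i}", 0.3, 0.001) for i in range(12)]
        pos, neg, table = ceg_votes(records, min_votes=9)
        assert pos == [] and neg == []
        assert table.counts.loc["G", "n_pos"] == 0

    def test_eight_votes_below_floor(self):
        records = ([corr_rec("G", f"c{i}", 0.5, 0.001) for i in range(8)]
                   + [corr_rec("G", "c8", 0.1, 0.8)])
        pos, _, _ = ceg_votes(records, min_votes=9)
        assert pos == []

    def test_ten_votes_qualify(self):
        records = ([corr_rec("G", f"c{i}", 0.5, 0.001) for i in range(10)]
                   + [corr_rec("G", f"d{i}", 0.0, 0.9) for i in range(2)])
        pos, neg, table = ceg_votes(records, min_votes=9)
        assert pos == ["G"] and neg == []
        assert table.counts.loc["G", "n_cohorts_tested"] == 12

    def test_strict_lfc_boundary_no_vote(self):
        records = [de_rec("G", f"c{i}", 1.0, 0.001) for i in range(10)]
        up, down, _ = deg_votes(records, min_votes=8)
        assert up == [] and down == []

    def test_down_deg_at_floor(self):
        records = [de_rec("G", f"c{i}", -1.2, 0.01) for i in range(8)]
        up, down, _ = deg_votes(records, min_votes=8)
        assert down == ["G"] and up == []

    def test_conflicting_directions_do_not_cancel(self):
        records = ([de_rec("G", f"u{i}", 1.5, 0.01) for i in range(4)]
                   + [de_rec("G", f"d{i}", -1.5, 0.01) for i in range(4)])
        up, down, table = deg_votes(records, min_votes=8)
        assert up == [] and down == []
        assert table.counts.loc["G", "n_up"] == 4
        assert table.counts.loc["G", "n_down"] == 4

    @given(st.floats(0.3, 0.8), st.floats(0.3, 0.8))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_vote_counts_monotone_in_r_threshold(self, r1, r2):
        rng = np.random.default_rng(17)
        records = [corr_rec(f"G{j}", f"c{i}", float(rng.uniform(-1, 1)),
                            float(rng.uniform(0, 0.1)))
                   for j in range(20) for i in range(12)]
        lo, hi = sorted([r1, r2])
        _, _, tight = ceg_votes(records, r_min=hi, min_votes=1)
        _, _, loose = ceg_votes(records, r_min=lo, min_votes=1)
        assert (tight.counts["n_pos"] <= loose.counts["n_pos"]).all()
        assert (tight.counts["n_neg"] <= loose.counts["n_neg"]).all()


class TestIntersect:
    def test_disjoint_inputs_empty(self):
        a, b = intersect(["A"], ["B"], ["C"], ["D"])
        assert a == [] and b == []

    def test_set_algebra_consistency(self):
        a, b = intersect(["A", "B"], ["C"], ["C", "X"], ["B", "Y"])
        assert a == ["B"] and b == ["C"]
        assert set(a).isdisjoint(b)
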