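"""RPKM rules, multiread policies, percentage normalizations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pspkit import (
    AlignmentRecord,
    ExpressionRecord,
    FractionActivity,
    ReadSimSpec,
    active_psp_percentages,
    contig_weight,
    count_units,
    fraction_percentages,
    gen_alignment_table,
    load_expression_table,
    load_published_percentages,
    quantify,
    rpkm,
)


class TestContigWeight:
    @pytest.mark.parametrize("contig,aligned,expected", [
        (1000, 1000, 1.0),
        (1000, 800, 0.8),
        (1000, 501, 0.501),
        (1000, 500, 0.0),   # exactly half is below the strict cutoff
        (1000, 400, 0.0),
        (1000, 0, 0.0),
    ])
    def test_branchwise(self, contig, aligned, expected):
        assert contig_weight(contig, aligned) == pytest.approx(expected)

    @pytest.mark.parametrize("contig,aligned", [(0, 0), (100, -1), (100, 101)])
    def test_invalid_lengths(self, contig, aligned):
        with pytest.raises(ValueError):
            contig_weight(contig, aligned)


def _rec(read, contig, score=100.0, alen=100, clen=100):
    return AlignmentRecord(read, contig, score, alen, clen)


class TestCountUnits:
    def test_unique_reads(self):
        records = [_rec(f"r{i}", "c1") for i in range(10)]
        assert count_units(records) == {"c1": 10.0}

    def test_multiread_counts_once_tie_lexicographic(self):
        records = [_rec("r1", "c2"), _rec("r1", "c1")]
        assert count_units(records) == {"c1": 1.0, "c2": 0.0}

    def test_multiread_best_score_wins(self):
        records = [_rec("r1", "c1", score=50), _rec("r1", "c2", score=90)]
        assert count_units(records) == {"c1": 0.0, "c2": 1.0}

    def test_fractional_policy_splits(self):
        records = [_rec("r1", "c1"), _rec("r1", "c2")]
        assert count_units(records, "fractional") == {"c1": 0.5, "c2": 0.5}

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_units_sum_to_read_count(self, data):
        n_reads = data.draw(st.integers(1, 20))
        contigs = ["c1", "c2", "c3"]
        records = []
        for i in range(n_reads):
            hits = data.draw(st.lists(st.sampled_from(contigs), min_size=1,
                                      max_size=3, unique=True))
            for c in hits:
                records.append(_rec(f"r{i}", c,
                                    score=data.draw(st.integers(0, 100))))
        for policy in ("best", "fractional"):
            total = sum(count_units(records, policy).values())
            assert total == pytest.approx(n_reads)


class TestRpkm:
    def test_unit_case(self):
        assert rpkm(1000, 1000, 10**6) == pytest.approx(1000.0)

    def test_scale_invariance(self):
        assert rpkm(294, 1000, 2 * 10**6) == pytest.approx(
            rpkm(147, 1000, 10**6))

    def test_table_scale(self):
        assert rpkm(147, 1000, 10**6) == pytest.approx(147.0)

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 10**6)
        with pytest.raises(ValueError):
            rpkm(1, 1000, 0)


class TestQuantifyRecovery:
    def test_clean_table_recovers_truth_exactly(self):
        records, truth = gen_alignment_table(ReadSimSpec(seed=1))
        got = quantify(records).set_index("contig_id")["rpkm"]
        for gene, value in truth.items():
            assert got[gene] == pytest.approx(value, abs=0)

    def test_multireads_with_unique_best_recover_truth(self):
        records, truth = gen_alignment_table(
            ReadSimSpec(multiread_frac=0.2, seed=2))
        got = quantify(records, policy="best").set_index("contig_id")["rpkm"]
        for gene, value in truth.items():
            assert got[gene] == pytest.approx(value, abs=0)

    def test_partials_reduce_rpkm(self):
        records, truth = gen_alignment_table(
            ReadSimSpec(partial_frac=0.5, seed=3))
        got = quantify(records).set_index("contig_id")["rpkm"]
        assert all(got[g] <= truth[g] for g in truth)
        assert any(got[g] < truth[g] for g in truth)


class TestActivePercentages:
    @pytest.mark.parametrize("species", ["tcastaneum", "tmolitor"])
    def test_reproduces_published_percentages(self, species):
        records = active_psp_percentages(load_expression_table(species))
        printed = load_published_percentages(species)
        got = {r.gene_id: r.percent_active for r in records
               if r.percent_active is not None}
        assert set(got) == set(printed)
        for gene, value in printed.items():
            assert got[gene] == pytest.approx(value, abs=0.05)

    @pytest.mark.parametrize("species", ["tcastaneum", "tmolitor"])
    def test_percentages_sum_to_100(self, species):
        records = active_psp_percentages(load_expression_table(species))
        total = sum(r.percent_active for r in records
                    if r.percent_active is not None)
        assert total == pytest.approx(100.0, abs=0.3)

    def test_inactive_types_excluded(self):
        records = active_psp_percentages(load_expression_table("tcastaneum"))
        for r in records:
            if r.psp_type in {"DPP10", "LAP", "CND"}:
                assert r.percent_active is None

    def test_single_active_gene_is_100(self):
        recs = [ExpressionRecord("g", "XPD", 5.0, True),
                ExpressionRecord("h", "CND", 50.0, False)]
        out = active_psp_percentages(recs)
        assert out[0].percent_active == 100.0
        assert out[1].percent_active is None

    def test_zero_active_sum_rejected(self):
        with pytest.raises(ValueError):
            active_psp_percentages([ExpressionRecord("g", "XPD", 0.0, True)])


class TestFractionPercentages:
    def _fa(self, am, pm):
        fractions = ["soluble_contents", "insoluble_contents",
                     "soluble_tissue", "insoluble_tissue"]
        acts = {("AM", f): v for f, v in zip(fractions, am)}
        acts.update({("PM", f): v for f, v in zip(fractions, pm)})
        return FractionActivity("pep", acts)

    def test_am_pm_split(self):
        (am, pm), _ = fraction_percentages(
            self._fa([30, 10, 10, 10], [20, 10, 5, 5]))
        assert (am, pm) == (pytest.approx(60.0), pytest.approx(40.0))

    def test_equal_fractions_are_quarters(self):
        _, dist = fraction_percentages(self._fa([5, 5, 5, 5], [1, 1, 1, 1]))
        assert all(v == pytest.approx(25.0) for v in dist["AM"].values())
        assert all(v == pytest.approx(25.0) for v in dist["PM"].values())

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(vals=st.lists(st.floats(0.01, 1e3), min_size=8, max_size=8))
    def test_percentage_sets_sum_to_100(self, vals):
        (am, pm), dist = fraction_percentages(self._fa(vals[:4], vals[4:]))
        assert am + pm == pytest.approx(100.0, abs=1e-9)
        for sec in ("AM", "PM"):
            assert sum(dist[sec].values()) == pytest.approx(100.0, abs=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fraction_percentages(self._fa([0, 0, 0, 0], [0, 0, 0, 0]))
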