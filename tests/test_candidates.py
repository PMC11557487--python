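"""Candidate prioritization cascade: per-stage filters and bookkeeping."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bsamap.candidates import (FilterConfig, conservation_filter, ems_classify,
                               exome_filter, expression_filter,
                               qual_depth_filter, run_cascade, sift_filter)
from bsamap.reference import SRH1_PEAK_INTERVAL, load_candidate_table
from bsamap.scan import IntervalCall


def _variants(rows, columns):
    return pd.DataFrame(rows, columns=columns)


class TestQualDepth:
    COLS = ["chrom", "pos", "qual", "rd_mut", "rd_wt"]

    @pytest.mark.parametrize("qual,rd_mut,rd_wt,kept", [
        (50, 50, 50, False),    # qual at the discard boundary
        (300, 11, 10, True),    # combined depth 21, just above boundary
        (300, 10, 10, False),   # combined depth exactly 20
        (51, 200, 200, True),
        (10, 500, 500, False),  # bad quality at any depth
    ])
    def test_boundaries(self, qual, rd_mut, rd_wt, kept):
        df = _variants([("chr1", 1, qual, rd_mut, rd_wt)], self.COLS)
        assert (len(qual_depth_filter(df)) == 1) is kept


class TestExome:
    EXONS = pd.DataFrame({
        "gene_id": ["g1", "g1", "g2", "g3"],
        "chrom": ["chr1", "chr1", "chr1", "chr2"],
        "start": [100, 300, 1000, 50],
        "end": [200, 400, 2000, 60],
    })

    def test_boundary_base_is_inside(self):
        df = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100, 200]})
        out = exome_filter(df, self.EXONS)
        assert len(out) == 2 and set(out["gene_id"]) == {"g1"}

    def test_intron_gap_removed(self):
        df = pd.DataFrame({"chrom": ["chr1"], "pos": [250]})
        assert exome_filter(df, self.EXONS).empty

    def test_matches_brute_force_membership(self, rng):
        pos = rng.integers(1, 2500, 10)
        df = pd.DataFrame({"chrom": "chr1", "pos": pos})
        out = exome_filter(df, self.EXONS)
        expected = {
            (p, e.gene_id)
            for p in pos for e in self.EXONS.itertuples()
            if e.chrom == "chr1" and e.start <= p <= e.end
        }
        assert {(r.pos, r.gene_id) for r in out.itertuples()} == expected


class TestExpression:
    def test_zero_expression_removed_at_zero_cutoff(self):
        df = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"], "pos": [1]})
        cfg = FilterConfig(expression_min=0.0)
        assert expression_filter(df, {"g": 0.0}, cfg).empty

    def test_expressed_gene_kept(self):
        df = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"], "pos": [1]})
        assert len(expression_filter(df, {"g": 12.3})) == 1

    def test_toy_table_counts(self):
        genes = [f"g{i}" for i in range(7)]
        expr = {g: v for g, v in zip(genes, [0.0, 0.1, 0.4, 0.6, 2.0, 9.0, 0.5])}
        df = pd.DataFrame({"gene_id": genes, "pos": range(7)})
        out = expression_filter(df, expr)   # cutoff 0.5, strict
        assert list(out["gene_id"]) == ["g3", "g4", "g5"]

    def test_unknown_gene_treated_unexpressed(self):
        df = pd.DataFrame({"gene_id": ["mystery"], "pos": [1]})
        assert expression_filter(df, {}).empty


class TestSift:
    def test_published_candidates_all_pass(self):
        table = load_candidate_table()
        assert len(sift_filter(table)) == 7

    @pytest.mark.parametrize("consequence,sift,kept", [
        ("synonymous", 0.0, False),
        ("missense", 0.06, False),
        ("missense", 0.05, True),
        ("stop_gained", 0.0, True),
        ("missense", None, True),   # retained with a warning
    ])
    def test_rule(self, consequence, sift, kept):
        df = pd.DataFrame({"gene_id": ["g"], "consequence": [consequence],
                           "sift": [sift]})
        assert (len(sift_filter(df)) == 1) is kept


class TestEmsClassify:
    def test_published_set(self):
        table = load_candidate_table()
        classes = [ems_classify(r, a) for r, a in zip(table["ref"], table["alt"])]
        assert classes.count("canonical") == 4
        assert classes.count("atypical") == 3

    def test_partition_of_all_substitutions(self):
        classes = {(r, a): ems_classify(r, a)
                   for r, a in itertools.permutations("ACGT", 2)}
        canonical = [k for k, v in classes.items() if v == "canonical"]
        assert sorted(canonical) == [("C", "T"), ("G", "A")]
        assert len(classes) == 12

    def test_reverse_complement_pair_is_atypical(self):
        assert ems_classify("T", "C") == "atypical"

    def test_indel_rejected(self):
        with pytest.raises(ValueError):
            ems_classify("C", "CT")


class TestConservation:
    def test_published_values_all_pass(self):
        assert len(conservation_filter(load_candidate_table())) == 7

    @pytest.mark.parametrize("pct,kept", [(69.9, False), (70.0, True),
                                          (100.0, True), (None, False)])
    def test_boundary(self, pct, kept):
        df = pd.DataFrame({"gene_id": ["g"], "conservation_pct": [pct]})
        assert (len(conservation_filter(df)) == 1) is kept


class TestCascade:
    def test_published_table_seven_survivors(self):
        report = run_cascade(load_candidate_table(), SRH1_PEAK_INTERVAL)
        assert len(report.table) == 7
        assert report.table["ems_class"].value_counts().to_dict() == \
            {"canonical": 4, "atypical": 3}

    def test_empty_input(self):
        report = run_cascade(load_candidate_table().iloc[0:0],
                             SRH1_PEAK_INTERVAL)
        assert report.table.empty
        assert all(n == 0 for _, n in report.stage_counts)

    def test_counts_non_increasing(self):
        report = run_cascade(load_candidate_table(), SRH1_PEAK_INTERVAL)
        counts = [n for _, n in report.stage_counts]
        assert counts == sorted(counts, reverse=True)

    def test_sift_and_conservation_commute(self):
        table = load_candidate_table().copy()
        table.loc[2, "sift"] = 0.5           # knock one out per filter
        table.loc[4, "conservation_pct"] = 10
        a = conservation_filter(sift_filter(table))
        b = sift_filter(conservation_filter(table))
        assert set(a["gene_id"]) == set(b["gene_id"])

    def test_synthetic_cascade_counts_match_manual_bookkeeping(self):
        iv = IntervalCall("chr1", 0, 1000, 0.5, 0.9, 500)
        rows = [
            # pos, qual, rd_mut, rd_wt, gene, cons, consequence, sift, pct
            (100, 99, 30, 30, "g1", "missense", 0.0, 90.0),   # survives all
            (200, 40, 30, 30, "g1", "missense", 0.0, 90.0),   # fails qual
            (300, 99, 30, 30, "g2", "missense", 0.0, 90.0),   # g2 unexpressed
            (400, 99, 30, 30, "g3", "synonymous", 0.0, 90.0), # fails sift stage
            (500, 99, 30, 30, "g4", "missense", 0.5, 90.0),   # fails sift
            (600, 99, 30, 30, "g5", "missense", 0.0, 30.0),   # fails conservation
            (2000, 99, 30, 30, "g6", "missense", 0.0, 90.0),  # outside interval
        ]
        df = pd.DataFrame(rows, columns=["pos", "qual", "rd_mut", "rd_wt",
                                         "gene", "consequence", "sift",
                                         "conservation_pct"])
        df["chrom"] = "chr1"
        df["ref"], df["alt"] = "C", "T"
        exons = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(1, 7)],
            "chrom": "chr1",
            "start": [1, 1, 1, 1, 1, 1],
            "end": [3000] * 6,
        })
        expression = {g: 5.0 for g in exons["gene_id"] if g != "g2"}
        # manual bookkeeping: 7 -> 6 (interval) -> 5 (qual) -> 4 (expression)
        # -> 2 (sift: drops synonymous + tolerated) -> 1 (conservation)
        df["gene_id"] = df["gene"]
        report = run_cascade(df, iv, exons=None, expression=expression)
        counts = dict(report.stage_counts)
        assert counts["input"] == 7
        assert counts["interval"] == 6
        assert counts["qual_depth"] == 5
        assert counts["expression"] == 4
        assert counts["sift"] == 2
        assert counts["conservation"] == 1
        assert list(report.table["gene_id"]) == ["g1"]
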