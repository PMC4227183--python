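import pandas as pd
import pytest

from crackseq import (
    CandidateRule,
    DEFAULT_RULES,
    classify_candidates,
    merge_annotations,
    summarize_categories,
    summarize_hit_counts,
    summarize_hits,
)
from crackseq.annotation import filter_hits, percent_of


def hits_df(rows):
    return pd.DataFrame(rows, columns=["unigene_id", "database", "description", "e_value"])


class TestMergeAnnotations:
    def test_priority_order(self):
        hits = hits_df(
            [("u1", "COG", "cog desc", 1e-30), ("u1", "NR", "nr desc", 1e-10)]
        )
        merged = merge_annotations(hits)
        assert merged.iloc[0]["source_db"] == "NR"
        assert merged.iloc[0]["description"] == "nr desc"

    def test_single_source(self):
        merged = merge_annotations(hits_df([("u1", "KEGG", "k desc", 1e-8)]))
        assert merged.iloc[0]["source_db"] == "KEGG"

    def test_best_evalue_within_database(self):
        hits = hits_df(
            [("u1", "NR", "weak", 1e-8), ("u1", "NR", "strong", 1e-20)]
        )
        assert merge_annotations(hits).iloc[0]["description"] == "strong"

    def test_order_independence(self):
        rows = [
            ("u1", "SwissProt", "sp", 1e-12),
            ("u1", "NR", "nr", 1e-6),
            ("u2", "COG", "cog", 1e-9),
            ("u2", "KEGG", "kegg", 1e-9),
        ]
        a = merge_annotations(hits_df(rows))
        b = merge_annotations(hits_df(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_database_rejected(self):
        hits = hits_df([("u1", "NR", "d", 1e-9)])
        with pytest.raises(ValueError):
            merge_annotations(hits, priority=("SwissProt",))

    def test_evalue_filter_is_strict(self):
        hits = hits_df([("u1", "NR", "at cutoff", 1e-5), ("u2", "NR", "below", 9e-6)])
        kept = filter_hits(hits, 1e-5)
        assert list(kept["unigene_id"]) == ["u2"]


class TestSummarizeHits:
    def test_printed_percentages(self):
        # assembly-scale hit counts and total are inputs; percentages computed
        table = summarize_hit_counts(
            {"NR": 32_479, "SwissProt": 25_010, "COG": 12_981, "KEGG": 9_504, "any": 32_640},
            total_unigenes=46_641,
        )
        pct = dict(zip(table["database"], table["percent"]))
        assert pct == {
            "NR": 69.64,
            "SwissProt": 53.62,
            "COG": 27.83,
            "KEGG": 20.38,
            "any": 69.98,
        }

    def test_from_hit_table_distinct_unigenes(self):
        hits = hits_df(
            [
                ("u1", "NR", "a", 1e-9),
                ("u1", "NR", "b", 1e-8),  # same unigene counted once
                ("u2", "SwissProt", "c", 1e-9),
            ]
        )
        table = summarize_hits(hits, total_unigenes=4)
        row = dict(zip(table["database"], table["n_hits"]))
        assert row == {"NR": 1, "SwissProt": 1, "any": 2}
        pct = dict(zip(table["database"], table["percent"]))
        assert pct["any"] == 50.0

    def test_per_db_counts_bounded_by_any(self):
        hits = hits_df([("u%d" % k, "NR", "d", 1e-9) for k in range(5)])
        table = summarize_hits(hits, total_unigenes=10)
        any_n = int(table.loc[table["database"] == "any", "n_hits"].iloc[0])
        assert (table["n_hits"] <= any_n).all() and any_n <= 10

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            summarize_hit_counts({"NR": 0}, 0)


class TestSummarizeCategories:
    def test_classified_base_convention(self):
        # 3 categories over 4 classified unigenes (u1 in two categories)
        pairs = [("u1", "A"), ("u1", "B"), ("u2", "A"), ("u3", "C"), ("u4", "A")]
        table = summarize_categories(pairs, base="classified")
        assert list(table["category"]) == ["A", "B", "C"] or list(table["count"])[0] == 3
        a = table[table["category"] == "A"].iloc[0]
        assert a["count"] == 3 and a["percent"] == 75.0

    def test_assignment_base_sums_to_hundred(self):
        pairs = [("u%d" % k, c) for k, c in enumerate("AABBBCCCCD")]
        table = summarize_categories(pairs, base="assignments")
        assert sum(table["percent"]) == pytest.approx(100.0, abs=0.01 * len(table))

    def test_single_category_is_hundred(self):
        table = summarize_categories([("u1", "only")])
        assert table.iloc[0]["percent"] == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_categories([])

    @pytest.mark.parametrize(
        "count,base,expected", [(4358, 25166, 17.32), (1430, 4992, 28.65), (817, 4992, 16.37)]
    )
    def test_half_up_rounding_matches_printed_values(self, count, base, expected):
        assert percent_of(count, base) == expected


class TestClassifyCandidates:
    def deg_row(self, uid, direction="up", log2fc=2.0):
        return {
            "unigene_id": uid,
            "rpkm_1": 1.0,
            "rpkm_2": 4.0,
            "log2fc": log2fc,
            "p_value": 1e-9,
            "fdr": 1e-8,
            "is_deg": True,
            "direction": direction,
        }

    def merged_row(self, uid, desc):
        return {"unigene_id": uid, "source_db": "NR", "description": desc, "e_value": 1e-20}

    def test_aquaporin_to_water_transport(self):
        degs = pd.DataFrame([self.deg_row("u1")])
        merged = pd.DataFrame([self.merged_row("u1", "aquaporin PIP2-like")])
        rules = [CandidateRule("water transport", "PIP", r"PIP")]
        out = classify_candidates(degs, merged, rules)
        assert list(out[["pathway", "family_label"]].iloc[0]) == ["water transport", "PIP"]

    def test_unmatched_deg_omitted(self):
        degs = pd.DataFrame([self.deg_row("u1")])
        merged = pd.DataFrame([self.merged_row("u1", "unknown protein")])
        assert classify_candidates(degs, merged, DEFAULT_RULES).empty

    def test_first_matching_rule_wins_single_assignment(self):
        degs = pd.DataFrame([self.deg_row("u1")])
        merged = pd.DataFrame(
            [self.merged_row("u1", "UDP-glucosyltransferase / beta-glucosidase fusion")]
        )
        rules = [
            CandidateRule("ABA metabolism", "GT", "glucosyltransferase"),
            CandidateRule("ABA metabolism", "beta-Glu", "glucosidase"),
        ]
        out = classify_candidates(degs, merged, rules)
        assert len(out) == 1  # at most one assignment per DEG
        assert out.iloc[0]["family_label"] == "GT"

    def test_non_degs_ignored(self):
        row = self.deg_row("u1")
        row.update(is_deg=False, direction="none")
        degs = pd.DataFrame([row])
        merged = pd.DataFrame([self.merged_row("u1", "aquaporin")])
        assert classify_candidates(degs, merged, DEFAULT_RULES).empty

    def test_each_deg_assigned_at_most_once_brute_force(self):
        descs = [
            "aquaporin SIP1-like",
            "gibberellin receptor GID1",
            "abscisic acid 8'-hydroxylase CYP707A2",
            "calcineurin B-like protein CBL3",
            "polygalacturonase precursor",
            "expansin-A4",
        ]
        degs = pd.DataFrame([self.deg_row(f"u{k}") for k in range(len(descs))])
        merged = pd.DataFrame([self.merged_row(f"u{k}", d) for k, d in enumerate(descs)])
        out = classify_candidates(degs, merged, DEFAULT_RULES)
        assert len(out) == len(descs)
        assert out["unigene_id"].is_unique

    def test_duplicate_rule_rejected(self):
        rules = [
            CandidateRule("water transport", "PIP", "PIP"),
            CandidateRule("water transport", "PIP", "PIP2"),
        ]
        with pytest.raises(ValueError):
            classify_candidates(pd.DataFrame([self.deg_row("u1")]),
                                pd.DataFrame([self.merged_row("u1", "x")]), rules)


class TestCandidateRule:
    def test_bad_pattern_rejected(self):
        with pytest.raises(ValueError):
            CandidateRule("p", "f", "(unclosed")

    def test_default_rules_have_examples_matching_patterns(self):
        for r in DEFAULT_RULES:
            assert r.example is not None
            assert r.regex.search(r.example)
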