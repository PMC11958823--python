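"""Corpus harmonisation: top-DEG selection, aggregation, imaging normalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pdkg import corpus as corpus_mod
from pdkg.corpus import (
    SchemaError,
    aggregate_corpus,
    harmonize_imaging,
    normalize_imaging,
    select_top_degs,
)


def deg_frame(genes, p, fc=None):
    fc = fc if fc is not None else [1.0] * len(genes)
    return pd.DataFrame({"gene": genes, "log2fc": fc, "p_adjust": p})


class TestSelectTopDegs:
    def test_already_sorted_table_returned_in_order(self):
        out = select_top_degs(deg_frame(["A", "B", "C"], [0.01, 0.02, 0.03]), 3)
        assert list(out["gene"]) == ["A", "B", "C"]

    def test_matches_full_sort_oracle_on_200_rows(self):
        rng = np.random.default_rng(11)
        table = deg_frame(
            [f"G{i:03d}" for i in range(200)],
            rng.uniform(size=200),
            rng.normal(size=200),
        )
        out = select_top_degs(table, 100)
        expected = set(table.sort_values("p_adjust").head(100)["gene"])
        assert set(out["gene"]) == expected
        assert out["p_adjust"].is_monotonic_increasing

    def test_four_study_tables_concatenate_to_400_records(self, scenario):
        mono = [select_top_degs(scenario.deg_tables[d], 100)
                for d in ("LRRK2", "SNCA", "GBA", "MIRO1")]
        assert sum(len(t) for t in mono) == 400

    def test_idempotent_on_its_own_output(self):
        rng = np.random.default_rng(5)
        table = deg_frame([f"G{i}" for i in range(50)], rng.uniform(size=50), rng.normal(size=50))
        once = select_top_degs(table, 20)
        twice = select_top_degs(once, 20)
        pd.testing.assert_frame_equal(once, twice)

    def test_biotype_flags_removed_before_ranking(self):
        table = deg_frame(["LNC1", "A", "PSG1", "B"], [0.001, 0.01, 0.002, 0.02])
        flags = {"LNC1": "lncRNA", "PSG1": "pseudogene", "A": "protein_coding"}
        out = select_top_degs(table, 2, exclude=flags)
        assert list(out["gene"]) == ["A", "B"]

    def test_tie_break_is_absfc_then_symbol(self):
        table = deg_frame(["Z", "A", "M"], [0.01, 0.01, 0.01], fc=[1.0, -1.0, 2.0])
        out = select_top_degs(table, 3)
        assert list(out["gene"]) == ["M", "A", "Z"]  # |fc| desc, then symbol

    def test_direction_derived_from_sign(self):
        out = select_top_degs(deg_frame(["A", "B"], [0.01, 0.02], fc=[2.0, -0.5]), 2)
        assert list(out["direction"]) == ["UP", "DOWN"]

    def test_schema_and_parse_errors(self):
        with pytest.raises(SchemaError, match="missing"):
            select_top_degs(pd.DataFrame({"gene": ["A"], "log2fc": [1.0]}), 1)
        with pytest.raises(SchemaError, match="non-numeric"):
            select_top_degs(deg_frame(["A"], ["not-a-p"]), 1)
        with pytest.raises(ValueError):
            select_top_degs(deg_frame([], []), 1)


class TestAggregateCorpus:
    def test_hand_count_concatenated_vs_unique(self):
        lists = {
            "S1": deg_frame(["A", "B"], [0.01, 0.02]),
            "S2": deg_frame(["B", "C"], [0.01, 0.02]),
        }
        c = aggregate_corpus(lists)
        assert c.n_records == 4
        assert c.n_unique_genes == 3

    def test_single_list_unique_equals_concatenated(self):
        c = aggregate_corpus({"S1": deg_frame(["A", "B", "C"], [0.01, 0.02, 0.03])})
        assert c.n_unique_genes == c.n_records == 3

    def test_unique_le_concatenated_with_equality_iff_disjoint(self):
        disjoint = aggregate_corpus({
            "S1": deg_frame(["A"], [0.01]),
            "S2": deg_frame(["B"], [0.01]),
        })
        assert disjoint.n_unique_genes == disjoint.n_records
        overlapping = aggregate_corpus({
            "S1": deg_frame(["A"], [0.01]),
            "S2": deg_frame(["A"], [0.01]),
        })
        assert overlapping.n_unique_genes < overlapping.n_records

    def test_duplicate_gene_dataset_rows_collapse_to_smallest_p(self):
        lists = {"S1": deg_frame(["A", "A", "B"], [0.03, 0.01, 0.02])}
        with pytest.warns(UserWarning, match="collapsed"):
            c = aggregate_corpus(lists)
        row = c.degs[c.degs["gene"] == "A"]
        assert len(row) == 1
        assert row["p_adjust"].iloc[0] == 0.01

    def test_core_proteins_deduplicated_across_studies(self):
        lists = {"S1": deg_frame(["A"], [0.01]), "S2": deg_frame(["B"], [0.01])}
        c = aggregate_corpus(lists, core_protein_lists={"S1": ("TH", "GFAP"), "S2": ("TH",)})
        assert c.n_unique_core_proteins == 2
        assert len(c.core_proteins) == 3  # (protein, dataset) pairs

    def test_symbols_cleaned_at_ingestion(self):
        c = aggregate_corpus({"S1": deg_frame([" th ", "Gfap"], [0.01, 0.02])})
        assert set(c.degs["gene"]) == {"TH", "GFAP"}


class TestHarmonizeImaging:
    def make_sources(self):
        a = pd.DataFrame({
            "Cell Line": ["L1", "L2"], "cond": ["PD", "CTRL"],
            "day": [30, 30], "marker": ["TH", "TH"], "val": [1.0, 2.0],
        })
        b = pd.DataFrame({
            "line_id": ["L3", "L3"], "condition": ["PD", "PD"], "timepoint": [30, 60],
            "feature": ["TH", "TH"], "value_raw": [3.0, 4.0],
        })
        column_map = {
            "a": {"Cell Line": "cell_line", "cond": "condition", "day": "timepoint",
                  "marker": "feature", "val": "value_raw"},
            "b": {"line_id": "cell_line"},
        }
        return {"a": a, "b": b}, column_map

    def test_dialects_merge_onto_canonical_columns(self):
        sources, cmap = self.make_sources()
        out = harmonize_imaging(sources, cmap)
        assert list(out.columns) == ["cell_line", "condition", "timepoint", "feature",
                                     "value_raw", "source", "unpaired"]
        assert len(out) == 4
        assert set(out["source"]) == {"a", "b"}

    def test_timepoint_present_in_one_source_flagged_unpaired(self):
        sources, cmap = self.make_sources()
        out = harmonize_imaging(sources, cmap)
        assert out.loc[out["timepoint"] == 60, "unpaired"].all()
        assert not out.loc[out["timepoint"] == 30, "unpaired"].any()

    def test_unmappable_column_reported_with_headers(self):
        sources, cmap = self.make_sources()
        del cmap["a"]["val"]
        with pytest.raises(SchemaError, match="value_raw"):
            harmonize_imaging(sources, cmap)

    def test_round_trip_write_read_identity(self, tmp_path):
        sources, cmap = self.make_sources()
        out = harmonize_imaging(sources, cmap)
        out.to_csv(tmp_path / "img.tsv", sep="\t", index=False)
        back = pd.read_csv(tmp_path / "img.tsv", sep="\t")
        pd.testing.assert_frame_equal(out.reset_index(drop=True), back)


class TestNormalizeImaging:
    def imaging(self, values, lines=None):
        lines = lines or [f"L{i}" for i in range(len(values))]
        return pd.DataFrame({
            "cell_line": lines, "condition": "PD", "timepoint": 30,
            "feature": "TH", "value_raw": values,
        })

    def test_constant_feature_normalizes_to_one(self):
        out = normalize_imaging(self.imaging([5.0, 5.0, 5.0]))
        np.testing.assert_allclose(out["value_norm"], 1.0)

    def test_values_2_4_6_normalize_to_half_one_threehalves(self):
        out = normalize_imaging(self.imaging([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(out["value_norm"], [0.5, 1.0, 1.5])

    def test_group_mean_of_value_norm_is_one_on_random_table(self):
        rng = np.random.default_rng(2)
        frames = []
        for cond in ("PD", "CTRL"):
            for feat in ("TH", "GFAP"):
                for line in ("L1", "L2", "L3"):
                    frames.append((line, cond, 30, feat, rng.uniform(1, 10)))
        table = pd.DataFrame(frames, columns=["cell_line", "condition", "timepoint",
                                              "feature", "value_raw"])
        out = normalize_imaging(table)
        per_line = out.groupby(["feature", "condition", "timepoint", "cell_line"])["value_norm"].mean()
        group_means = per_line.groupby(level=["feature", "condition", "timepoint"]).mean()
        np.testing.assert_allclose(group_means, 1.0)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, c):
        base = self.imaging([2.0, 4.0, 6.0])
        scaled = base.assign(value_raw=base["value_raw"] * c)
        np.testing.assert_allclose(
            normalize_imaging(base)["value_norm"],
            normalize_imaging(scaled)["value_norm"],
            rtol=1e-9,
        )

    def test_repeated_measurements_of_one_line_weighted_once(self):
        table = self.imaging([2.0, 2.0, 2.0, 4.0], lines=["L1", "L1", "L1", "L2"])
        out = normalize_imaging(table)
        # reference is mean of per-line means (2, 4) -> 3, not the row mean 2.5
        np.testing.assert_allclose(out["value_norm"], [2 / 3, 2 / 3, 2 / 3, 4 / 3])

    def test_zero_group_mean_raises(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_imaging(self.imaging([0.0, 0.0]))


def test_corpus_write_read_round_trip(tmp_path, study_corpus):
    manifest = corpus_mod.write_corpus(study_corpus, tmp_path / "corpus")
    back = corpus_mod.read_corpus(tmp_path / "corpus")
    assert manifest["n_unique_genes"] == study_corpus.n_unique_genes
    assert back.datasets == study_corpus.datasets
    assert back.n_records == study_corpus.n_records
    pd.testing.assert_frame_equal(back.degs, study_corpus.degs)
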