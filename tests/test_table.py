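import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assemblage.table import (
    RANKS,
    CommunityTable,
    TableError,
    TaxonomyMap,
    aggregate_functional_profile,
    collapse_to_level,
    read_table,
    to_presence_absence,
    to_proportions,
    write_table,
)
from conftest import random_counts_table


class TestReadWrite:
    def test_tsv_round_trip_is_exact(self, small_counts, tmp_path):
        path = tmp_path / "t.tsv"
        write_table(small_counts, path)
        back = read_table(path)
        assert back.taxon_ids == small_counts.taxon_ids
        assert back.sample_ids == small_counts.sample_ids
        assert (back.values == small_counts.values).all()
        assert back.mode == "counts"

    def test_fixture_shape_and_mode(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("id\ts1\ts2\na\t1\t2\nb\t0\t3\nc\t5\t0\n")
        t = read_table(path)
        assert t.shape == (3, 2)
        assert t.mode == "counts"
        assert t.taxon_ids == ["a", "b", "c"]

    def test_negative_cell_names_coordinates(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("id\ts1\ts2\na\t1\t2\nb\t-3\t3\n")
        with pytest.raises(TableError, match="'b'.*'s1'"):
            read_table(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("id\ts1\na\tx\n")
        with pytest.raises(TableError, match="non-numeric"):
            read_table(path)

    def test_duplicate_taxon_labels_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("id\ts1\na\t1\na\t2\n")
        with pytest.raises(TableError, match="duplicate"):
            read_table(path)

    def test_biom_like_json(self, tmp_path):
        import json

        doc = {
            "rows": [{"id": "a"}, {"id": "b"}],
            "columns": [{"id": "s1"}, {"id": "s2"}],
            "matrix_type": "sparse",
            "data": [[0, 0, 3], [1, 1, 7]],
        }
        path = tmp_path / "t.json"
        path.write_text(json.dumps(doc))
        t = read_table(path, format="biom-like-json")
        assert t.values.tolist() == [[3, 0], [0, 7]]


class TestProportions:
    def test_simple_column(self):
        t = CommunityTable(
            pd.DataFrame({"s": [2, 2, 4]}, index=["a", "b", "c"]), mode="counts"
        )
        p, zero = to_proportions(t)
        assert zero == []
        assert np.allclose(p.values[:, 0], [0.25, 0.25, 0.5])

    def test_all_zero_column_flagged_and_unchanged(self):
        t = CommunityTable(
            pd.DataFrame({"s1": [1, 1], "s2": [0, 0]}, index=["a", "b"]),
            mode="counts",
        )
        p, zero = to_proportions(t)
        assert zero == ["s2"]
        assert (p.values[:, 1] == 0).all()

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_columns_sum_to_one_and_idempotent(self, seed):
        t = random_counts_table(np.random.default_rng(seed))
        p, _ = to_proportions(t)
        assert np.allclose(p.values.sum(axis=0), 1.0, atol=1e-9)
        p2, _ = to_proportions(p)
        assert np.allclose(p.values, p2.values, atol=1e-12)


class TestPresenceAbsence:
    @pytest.mark.parametrize(
        "threshold,expected", [(1, [0, 1, 1]), (5, [0, 0, 1])]
    )
    def test_thresholding(self, threshold, expected):
        t = CommunityTable(
            pd.DataFrame({"s": [0, 1, 7]}, index=["a", "b", "c"]), mode="counts"
        )
        pa = to_presence_absence(t, threshold=threshold)
        assert pa.values[:, 0].tolist() == expected

    def test_occupancy_conserves_nonzero_cells(self, rng):
        t = random_counts_table(rng)
        pa = to_presence_absence(t)
        assert pa.occupancy.sum() == (t.values >= 1).sum()


class TestCollapse:
    @staticmethod
    def _tax(entries):
        return TaxonomyMap(
            {tid: tuple(lin) + (None,) * (len(RANKS) - len(lin))
             for tid, lin in entries.items()}
        )

    def test_additivity_within_genus(self):
        t = CommunityTable(
            pd.DataFrame({"s": [3, 5]}, index=["a1", "a2"]), mode="counts"
        )
        tax = self._tax({
            "a1": ["d", "p", "c", "o", "f", "G"],
            "a2": ["d", "p", "c", "o", "f", "G"],
        })
        c = collapse_to_level(t, tax, "genus")
        assert c.shape == (1, 1)
        assert c.values[0, 0] == 8

    def test_unclassified_pooled_by_deepest_prefix(self):
        # 4 taxa, one unclassified at genus -> 3 genus rows + 1 pooled row
        t = CommunityTable(
            pd.DataFrame({"s": [1, 2, 3, 4]}, index=list("abcd")), mode="counts"
        )
        tax = self._tax({
            "a": ["d", "p", "c", "o", "f", "G1"],
            "b": ["d", "p", "c", "o", "f", "G2"],
            "c": ["d", "p", "c", "o", "f", "G3"],
            "d": ["d", "p", "c", "o", "f", None],
        })
        c = collapse_to_level(t, tax, "genus")
        assert c.shape == (4, 1)
        assert "unclassified-d;p;c;o;f" in c.taxon_ids
        assert c.data.loc["unclassified-d;p;c;o;f", "s"] == 4

    def test_column_totals_conserved(self, rng):
        t = random_counts_table(rng, n_taxa=12)
        lineages = {}
        for i, tid in enumerate(t.taxon_ids):
            lineages[tid] = (
                "d0", f"p{i % 2}", f"c{i % 3}", f"o{i % 4}", f"f{i % 5}",
                f"g{i % 6}" if i % 7 else None,
            )
        tax = TaxonomyMap(lineages)
        for level in RANKS:
            c = collapse_to_level(t, tax, level)
            assert (c.values.sum(axis=0) == t.values.sum(axis=0)).all()

    def test_unknown_rank_rejected(self, small_counts):
        tax = self._tax({tid: ["d"] for tid in small_counts.taxon_ids})
        with pytest.raises(TableError, match="unknown rank"):
            collapse_to_level(small_counts, tax, "species")


class TestFunctionalAggregation:
    def test_two_contig_example(self):
        cov = pd.DataFrame({"s": [3.0, 1.0]}, index=["c1", "c2"])
        fp = aggregate_functional_profile(
            cov, {"p1": "c1", "p2": "c2"}, {"p1": ["A"], "p2": ["B"]}
        )
        assert np.allclose(fp.data["s"].loc[["A", "B"]], [0.75, 0.25])

    def test_single_group_gets_everything(self):
        cov = pd.DataFrame({"s": [3.0, 1.0]}, index=["c1", "c2"])
        fp = aggregate_functional_profile(
            cov, {"p1": "c1", "p2": "c2"}, {"p1": ["A"], "p2": ["A"]}
        )
        assert fp.data.loc["A", "s"] == pytest.approx(1.0)

    def test_columns_normalized(self, rng):
        cov = pd.DataFrame(
            rng.random((4, 3)), index=[f"c{i}" for i in range(4)],
            columns=list("xyz"),
        )
        p2c = {f"p{i}": f"c{i % 4}" for i in range(6)}
        p2g = {f"p{i}": [f"G{i % 2}"] for i in range(6)}
        fp = aggregate_functional_profile(cov, p2c, p2g)
        assert np.allclose(fp.values.sum(axis=0), 1.0, atol=1e-9)

    def test_missing_contig_rejected(self):
        cov = pd.DataFrame({"s": [1.0]}, index=["c1"])
        with pytest.raises(TableError, match="absent"):
            aggregate_functional_profile(cov, {"p1": "c9"}, {"p1": ["A"]})

    def test_exclusion_list_applied(self):
        cov = pd.DataFrame({"s": [1.0, 1.0]}, index=["c1", "c2"])
        fp = aggregate_functional_profile(
            cov, {"p1": "c1", "p2": "c2"}, {"p1": ["A"], "p2": ["junk"]},
            exclude_groups=["junk"],
        )
        assert fp.group_ids == ["A"]
        assert fp.data.loc["A", "s"] == pytest.approx(1.0)
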