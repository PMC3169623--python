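import warnings

import numpy as np
import pandas as pd
import pytest

from oceanbeta import (
    ClassificationError,
    FormatError,
    OtuTable,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
    aggregate_by_rank,
    classify_ecosystem,
    mean_composition,
    read_metadata,
    read_otu_table,
    read_taxonomy,
    remove_singletons,
    summarize_dataset,
    write_otu_table,
)
from oceanbeta.synthetic_data import generate_community
from tests.conftest import small_params


class TestReadOtuTable:
    def test_tsv_parse(self, tmp_path, tiny_table):
        p = tmp_path / "t.tsv"
        p.write_text("sample_id\to1\to2\to3\ns1\t1\t0\t2\ns2\t0\t3\t0\n")
        t = read_otu_table(p)
        assert t.sample_ids == ["s1", "s2"]
        assert list(t.sample_sums) == [3, 3]
        assert t == tiny_table

    def test_empty_sample_named_in_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sample_id\to1\to2\ns1\t1\t2\nbad\t0\t0\n")
        with pytest.raises(ValidationError, match="bad"):
            read_otu_table(p)

    def test_roundtrip(self, tmp_path, tiny_table):
        p = tmp_path / "t.tsv"
        write_otu_table(tiny_table, p)
        assert read_otu_table(p) == tiny_table

    def test_duplicate_ids(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sample_id\to1\to1\ns1\t1\t2\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_otu_table(p)

    def test_negative_counts(self):
        with pytest.raises(ValidationError):
            OtuTable(["s1"], ["o1"], [[-1]])

    def test_non_integer_counts(self):
        with pytest.raises(ValidationError):
            OtuTable(["s1"], ["o1", "o2"], [[1.5, 1.0]])

    def test_dot_forbidden_in_ids(self):
        with pytest.raises(FormatError, match="forbidden"):
            OtuTable(["s.1"], ["o1"], [[1]])

    def test_biom_dense_orientation(self, tmp_path):
        import json

        doc = {
            "matrix_type": "dense",
            "rows": [{"id": "o1"}, {"id": "o2"}],
            "columns": [{"id": "s1"}, {"id": "s2"}],
            "data": [[1, 2], [3, 4]],  # observations x samples
        }
        p = tmp_path / "t.biom"
        p.write_text(json.dumps(doc))
        t = read_otu_table(p, format="biom_dense")
        assert t.sample_ids == ["s1", "s2"]
        assert t.counts[0, 0] == 1 and t.counts[0, 1] == 3


class TestMetadata:
    def test_parse(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "sample_id\tlatitude\tlongitude\twater_depth\tdistance_to_coast\t"
            "sample_depth_kind\tspecial_habitat\tdate\tlonghurst_productivity\t"
            "fisheries_class\textra\n"
            "s1\t54.1\t7.9\t30\t12\twater\tnone\t2003-06-14\t3\t2\tfoo\n"
        )
        meta = read_metadata(p)
        assert meta.frame.loc["s1", "latitude"] == 54.1
        assert meta.frame.loc["s1", "extra"] == "foo"  # opaque columns preserved

    def test_latitude_out_of_range(self, tiny_metadata):
        df = tiny_metadata.frame.copy()
        df.loc["s1", "latitude"] = 95.0
        with pytest.raises(ValidationError, match="latitude"):
            SampleMetadata(df)

    def test_day_difference_leap_year(self, tiny_metadata):
        # 2003-06-14 -> 2004-06-14 spans 2004-02-29
        days = tiny_metadata.days_since_earliest()
        assert days.max() == 366

    def test_missing_column(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("sample_id\tlatitude\ns1\t10\n")
        with pytest.raises(FormatError, match="missing"):
            read_metadata(p)


class TestClassifyEcosystem:
    def _rec(self, kind="water", dist=50.0, depth=30.0, special="none"):
        return dict(
            sample_depth_kind=kind,
            distance_to_coast=dist,
            water_depth=depth,
            special_habitat=special,
        )

    def test_coastal_water(self):
        assert classify_ecosystem(self._rec()) == ("coastal", "pelagic")

    def test_deep_seafloor(self):
        rec = self._rec(kind="sediment", dist=500.0, depth=3000.0)
        assert classify_ecosystem(rec) == ("deep_seafloor", "benthic")

    def test_vent_override(self):
        rec = self._rec(dist=500.0, depth=10.0, special="vent")
        assert classify_ecosystem(rec) == ("vent", "pelagic")

    def test_surface_and_deep_open_ocean(self):
        assert classify_ecosystem(self._rec(dist=500, depth=10)) == (
            "surface_open_ocean", "pelagic")
        assert classify_ecosystem(self._rec(dist=500, depth=500)) == (
            "deep_open_ocean", "pelagic")

    def test_boundaries_are_total(self):
        # exactly 200 nmi / 200 m fall on the deep/open side
        assert classify_ecosystem(self._rec(dist=200, depth=10))[0] == "surface_open_ocean"
        assert classify_ecosystem(self._rec(dist=10, depth=200))[0] == "deep_open_ocean"
        assert classify_ecosystem(self._rec(kind="sediment", depth=200))[0] == "deep_seafloor"

    def test_missing_field(self):
        with pytest.raises(ClassificationError):
            classify_ecosystem({"sample_depth_kind": "water"})

    def test_total_and_deterministic(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            rec = self._rec(
                kind=rng.choice(["water", "sediment"]),
                dist=rng.uniform(0, 3000),
                depth=rng.uniform(0, 6000),
                special=rng.choice(["none", "vent", "anoxic"]),
            )
            first = classify_ecosystem(rec)
            assert classify_ecosystem(rec) == first
            assert first[0] in {
                "coastal", "surface_open_ocean", "deep_open_ocean",
                "deep_seafloor", "vent", "anoxic",
            }


def _tax(frame_rows):
    ranks = ["domain", "phylum", "class", "order", "family", "genus"]
    df = pd.DataFrame(frame_rows).T
    df.columns = ranks
    return TaxonomyTable(df)


class TestAggregateByRank:
    def test_hand_summation(self):
        t = OtuTable(["s1"], ["a", "b", "c"], [[5, 3, 2]])
        tax = _tax({
            "a": ["Bacteria", "P1", "Gamma", "UNASSIGNED", "UNASSIGNED", "UNASSIGNED"],
            "b": ["Bacteria", "P1", "Gamma", "UNASSIGNED", "UNASSIGNED", "UNASSIGNED"],
            "c": ["Bacteria", "UNASSIGNED"] + ["UNASSIGNED"] * 4,
        })
        agg, report = aggregate_by_rank(t, tax, "class")
        assert agg.otu_ids == ["Gamma"]
        assert agg.counts[0, 0] == 8
        assert report["n_otus_assigned"] == 2 and report["n_otus"] == 3
        assert report["n_sequences_assigned"] == 8 and report["n_sequences"] == 10

    def test_all_unassigned_warns(self):
        t = OtuTable(["s1"], ["a"], [[5]])
        tax = _tax({"a": ["Bacteria"] + ["UNASSIGNED"] * 5})
        with pytest.warns(UserWarning, match="no OTUs assigned"):
            agg, report = aggregate_by_rank(t, tax, "class")
        assert agg.n_otus == 0

    def test_column_count_equals_distinct_phyla(self, small_dataset):
        agg, _ = aggregate_by_rank(small_dataset.table, small_dataset.taxonomy, "phylum")
        assigned = small_dataset.taxonomy.frame.loc[small_dataset.table.otu_ids]
        expect = assigned.loc[assigned["phylum"] != "UNASSIGNED", "phylum"].nunique()
        assert agg.n_otus == expect

    def test_sequence_conservation(self, small_dataset):
        t = small_dataset.table
        agg, report = aggregate_by_rank(t, small_dataset.taxonomy, "family")
        assert int(agg.counts.sum()) == report["n_sequences_assigned"]
        dropped = report["n_sequences"] - report["n_sequences_assigned"]
        assert int(agg.counts.sum()) + dropped == int(t.counts.sum())

    def test_missing_otu_warns(self):
        t = OtuTable(["s1"], ["a", "zz"], [[5, 1]])
        tax = _tax({"a": ["Bacteria", "P1", "C1", "O1", "F1", "G1"]})
        with pytest.warns(UserWarning, match="missing from taxonomy"):
            agg, _ = aggregate_by_rank(t, tax, "phylum")
        assert agg.otu_ids == ["P1"]


class TestTaxonomyPrefixRepair:
    def test_violation_repaired(self):
        ranks = ["domain", "phylum", "class", "order", "family", "genus"]
        df = pd.DataFrame(
            [["Bacteria", "P1", "UNASSIGNED", "O1", "F1", "G1"]],
            index=["a"], columns=ranks,
        )
        with pytest.warns(UserWarning, match="repaired"):
            tax = TaxonomyTable(df)
        assert (tax.frame.loc["a", ["order", "family", "genus"]] == "UNASSIGNED").all()


class TestMeanComposition:
    def test_single_sample_group(self):
        t = OtuTable(["s1"], ["A", "B"], [[2, 2]])
        means, sds = mean_composition(t, pd.Series({"s1": "g"}))
        assert np.allclose(means.loc["g"], [0.5, 0.5])
        assert np.allclose(sds.loc["g"], [0.0, 0.0])

    def test_sample_sd(self):
        t = OtuTable(["s1", "s2"], ["A", "B"], [[1, 0], [0, 1]])
        means, sds = mean_composition(t, pd.Series({"s1": "g", "s2": "g"}))
        assert np.allclose(means.loc["g"], [0.5, 0.5])
        assert np.allclose(sds.loc["g"], [np.sqrt(0.5), np.sqrt(0.5)])

    def test_top_n_with_other_bucket(self):
        rng = np.random.default_rng(1)
        t = OtuTable(["s1", "s2"], [f"T{i}" for i in range(12)],
                     rng.integers(1, 50, (2, 12)))
        means, _ = mean_composition(t, pd.Series({"s1": "g", "s2": "g"}), top_n=10)
        assert means.shape[1] == 11 and "other" in means.columns
        assert np.allclose(means.sum(axis=1), 1.0)


class TestRemoveSingletons:
    def test_dataset_wide_definition(self):
        t = OtuTable(["s1", "s2"], ["a", "b", "c"], [[1, 1, 5], [0, 1, 5]])
        out = remove_singletons(t)
        # a occurs once in total -> removed; b has total 2 (1+1) -> kept
        assert out.otu_ids == ["b", "c"]

    def test_no_singletons_identity(self):
        t = OtuTable(["s1"], ["a", "b"], [[2, 3]])
        assert remove_singletons(t) == t

    def test_sequence_reduction_invariant(self, small_dataset):
        t = small_dataset.table
        out = remove_singletons(t)
        n_singletons = int((t.otu_sums == 1).sum())
        assert int(t.counts.sum()) - int(out.counts.sum()) == n_singletons


class TestSummarizeDataset:
    def test_group_sequence_sums_close(self, small_dataset):
        s = summarize_dataset(small_dataset.table, small_dataset.metadata)
        eco_rows = s.frame.loc[
            [i for i in s.frame.index if i[1] not in ("total", "grand_total")]
        ]
        assert eco_rows["n_samples"].sum() == s.grand_total("n_samples")
        assert eco_rows["n_sequences"].sum() == s.grand_total("n_sequences")
        assert (s.frame["n_singleton_otus"] <= s.frame["n_otus"]).all()

    def test_disjoint_groups_otu_sums(self):
        t = OtuTable(["s1", "s2"], ["a", "b", "c", "d"], [[3, 2, 0, 0], [0, 0, 4, 5]])
        meta = _meta_for(["s1", "s2"], kinds=["water", "sediment"])
        s = summarize_dataset(t, meta)
        eco_rows = s.frame.loc[
            [i for i in s.frame.index if i[1] not in ("total", "grand_total")]
        ]
        assert eco_rows["n_otus"].sum() == s.grand_total("n_otus")

    def test_shared_otus_overcount(self):
        t = OtuTable(["s1", "s2"], ["a", "b"], [[3, 2], [1, 4]])
        meta = _meta_for(["s1", "s2"], kinds=["water", "sediment"])
        s = summarize_dataset(t, meta)
        eco_rows = s.frame.loc[
            [i for i in s.frame.index if i[1] not in ("total", "grand_total")]
        ]
        assert eco_rows["n_otus"].sum() > s.grand_total("n_otus")

    def test_generator_bookkeeping(self):
        ds = generate_community(small_params(seed=7))
        s = summarize_dataset(ds.table, ds.metadata)
        assert s.grand_total("n_samples") == ds.table.n_samples
        assert s.grand_total("n_sequences") == int(ds.table.counts.sum())
        assert s.grand_total("n_otus") == ds.table.n_otus
        assert s.grand_total("n_singleton_otus") == int((ds.table.otu_sums == 1).sum())


def _meta_for(ids, kinds):
    df = pd.DataFrame(
        {
            "latitude": 10.0,
            "longitude": 10.0,
            "water_depth": 50.0,
            "distance_to_coast": 50.0,
            "sample_depth_kind": kinds,
            "special_habitat": "none",
            "date": "2003-01-01",
            "longhurst_productivity": 1,
            "fisheries_class": 1,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return SampleMetadata(df)
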