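import numpy as np
import pandas as pd
import pytest

from lagshift.errors import DataError, ParameterError
from lagshift.expression import (
    FeatureTable,
    abundance_floor,
    de_filter,
    remove_rrna,
    top_metabolic_genes,
    tpm,
)


def make_table(records, samples=("s1",)):
    df = pd.DataFrame(records)
    return FeatureTable(df=df, samples=tuple(samples))


@pytest.fixture
def small_table():
    return make_table(
        [
            {"gene_id": "g1", "length": 1000, "s1": 100, "s2": 50, "is_rrna": False},
            {"gene_id": "g2", "length": 2000, "s1": 100, "s2": 50, "is_rrna": False},
            {"gene_id": "g3", "length": 500, "s1": 10, "s2": 1000, "is_rrna": True},
        ],
        samples=("s1", "s2"),
    )


class TestRemoveRrna:
    def test_flagged_rows_dropped(self, small_table):
        out = remove_rrna(small_table)
        assert out.gene_ids() == ["g1", "g2"]
        assert out.samples == small_table.samples

    def test_no_flags_is_identity(self, small_table):
        df = small_table.df.copy()
        df["is_rrna"] = False
        out = remove_rrna(make_table(df.to_dict("records"), samples=("s1", "s2")))
        assert len(out) == 3

    def test_all_flagged_warns_and_empties(self, small_table):
        df = small_table.df.copy()
        df["is_rrna"] = True
        table = make_table(df.to_dict("records"), samples=("s1", "s2"))
        with pytest.warns(UserWarning):
            out = remove_rrna(table)
        assert len(out) == 0


class TestTpm:
    def test_single_gene_takes_whole_million(self):
        t = tpm(make_table([{"gene_id": "g1", "length": 700, "s1": 42}]))
        assert t.df["tpm_s1"].iloc[0] == pytest.approx(1e6)

    def test_length_normalization(self):
        # equal counts, lengths 1000 and 2000 -> TPM 2/3 and 1/3 of a million
        t = tpm(
            make_table(
                [
                    {"gene_id": "g1", "length": 1000, "s1": 100},
                    {"gene_id": "g2", "length": 2000, "s1": 100},
                ]
            )
        )
        np.testing.assert_allclose(
            t.df["tpm_s1"], [2e6 / 3, 1e6 / 3], rtol=1e-9
        )

    def test_depth_invariance(self, small_table):
        doubled = small_table.df.copy()
        doubled["s1"] = doubled["s1"] * 2
        t1 = tpm(small_table)
        t2 = tpm(make_table(doubled.to_dict("records"), samples=("s1", "s2")))
        np.testing.assert_allclose(t1.df["tpm_s1"], t2.df["tpm_s1"], rtol=1e-12)

    def test_columns_sum_to_a_million(self, small_table):
        t = tpm(small_table)
        for s in t.samples:
            assert t.df[f"tpm_{s}"].sum() == pytest.approx(1e6, rel=1e-6)

    def test_zero_total_rate_rejected(self):
        with pytest.raises(DataError):
            tpm(make_table([{"gene_id": "g1", "length": 1000, "s1": 0}]))


class TestTopGenes:
    def _table(self):
        records = [
            {
                "gene_id": f"g{i}",
                "length": 1000,
                "s1": count,
                "metabolic": i % 2 == 0,
            }
            for i, count in enumerate([10, 500, 30, 500, 30, 40])
        ]
        return tpm(make_table(records))

    def test_ranking_and_truncation(self):
        # metabolic set is {g0: 10, g2: 30, g4: 30}; g2/g4 tie, id breaks it
        top = top_metabolic_genes(self._table(), "metabolic", ["s1"], k=2)
        assert list(top["gene_id"]) == ["g2", "g4"]

    def test_tie_broken_by_gene_id(self):
        top = top_metabolic_genes(self._table(), "metabolic", ["s1"], k=3)
        assert list(top["gene_id"]) == ["g2", "g4", "g0"]
        means = top["mean_tpm"].to_numpy()
        assert np.all(np.diff(means) <= 1e-9)

    def test_k_larger_than_set_returns_all(self):
        top = top_metabolic_genes(self._table(), "metabolic", ["s1"], k=100)
        assert len(top) == 3

    def test_row_order_invariance(self):
        t = self._table()
        shuffled = FeatureTable(
            df=t.df.sample(frac=1.0, random_state=0).reset_index(drop=True),
            samples=t.samples,
        )
        a = top_metabolic_genes(t, "metabolic", ["s1"], k=3)
        b = top_metabolic_genes(shuffled, "metabolic", ["s1"], k=3)
        assert list(a["gene_id"]) == list(b["gene_id"])

    def test_unknown_gene_set_rejected(self):
        with pytest.raises(ParameterError):
            top_metabolic_genes(self._table(), "nope", ["s1"])


class TestDeFilter:
    def _table(self, rows):
        records = [
            {"gene_id": f"g{i}", "length": 1000, "s1": 10, **row}
            for i, row in enumerate(rows)
        ]
        return make_table(records)

    def test_threshold_logic(self):
        table = self._table(
            [
                {"log2fc": 0.60, "padj": 0.01},   # kept
                {"log2fc": 0.50, "padj": 0.001},  # fc below threshold
                {"log2fc": -0.9, "padj": 0.2},    # padj above threshold
                {"log2fc": 0.585, "padj": 0.05},  # inclusive boundaries kept
                {"log2fc": None, "padj": 0.01},   # untested gene excluded
            ]
        )
        out = de_filter(table)
        assert out.gene_ids() == ["g0", "g3"]

    def test_empty_table_passes_through(self):
        table = self._table([{"log2fc": 0.9, "padj": 0.001}])
        empty = de_filter(de_filter(table, padj_max=-1))  # nothing survives p <= -1
        assert len(empty) == 0

    def test_idempotent(self):
        table = self._table(
            [{"log2fc": 0.9, "padj": 0.001}, {"log2fc": 0.1, "padj": 0.9}]
        )
        once = de_filter(table)
        twice = de_filter(once)
        assert once.gene_ids() == twice.gene_ids()


class TestAbundanceFloor:
    def _table(self):
        records = [
            # group means: g1 [10, 60], g2 [49.9, 49.9], g3 [60, 0]
            {"gene_id": "g1", "length": 1000, "s1": 10, "s2": 60},
            {"gene_id": "g2", "length": 1000, "s1": 49.9, "s2": 49.9},
            {"gene_id": "g3", "length": 1000, "s1": 60, "s2": 0},
        ]
        t = make_table(records, samples=("s1", "s2"))
        # bypass TPM: inject the abundances directly as TPM columns
        df = t.df.copy()
        df["tpm_s1"] = df["s1"]
        df["tpm_s2"] = df["s2"]
        return FeatureTable(df=df, samples=t.samples)

    def test_max_of_group_means(self):
        out = abundance_floor(self._table(), [["s1"], ["s2"]], min_mean_tpm=50)
        assert out.gene_ids() == ["g1", "g3"]

    def test_all_groups_below_floor_dropped(self):
        out = abundance_floor(self._table(), [["s1", "s2"]], min_mean_tpm=50)
        # pooled means: 35, 49.9, 30 -> nothing reaches 50
        assert out.gene_ids() == []

    def test_zero_floor_is_identity(self):
        out = abundance_floor(self._table(), [["s1"], ["s2"]], min_mean_tpm=0)
        assert len(out) == 3

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            abundance_floor(self._table(), [[]])


class TestFilterAlgebra:
    def _table(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(50):
            records.append(
                {
                    "gene_id": f"g{i:03d}",
                    "length": int(rng.integers(200, 3000)),
                    "s1": float(rng.integers(0, 500)),
                    "s2": float(rng.integers(0, 500)),
                    "log2fc": float(rng.uniform(-2, 2)),
                    "padj": float(rng.uniform(0, 1)),
                }
            )
        return tpm(make_table(records, samples=("s1", "s2")))

    def test_de_and_abundance_filters_commute(self):
        table = self._table()
        groups = [["s1"], ["s2"]]
        ab_then_de = de_filter(abundance_floor(table, groups))
        de_then_ab = abundance_floor(de_filter(table), groups)
        assert ab_then_de.gene_ids() == de_then_ab.gene_ids()

    def test_filters_idempotent(self):
        table = self._table()
        groups = [["s1"], ["s2"]]
        once = abundance_floor(table, groups)
        assert abundance_floor(once, groups).gene_ids() == once.gene_ids()
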