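"""Normalization, differential expression, external-table import."""

import numpy as np
import pandas as pd
import pytest

from stresslink.diffexpr import (CountMatrix, de_test, expression_filter,
                                 import_external_de, size_factors)
from stresslink.enrichment import bh_adjust


def make_cm(counts: dict, strains: dict, batches: dict | None = None):
    df = pd.DataFrame(counts)
    meta = pd.DataFrame({
        "strain": pd.Series(strains),
        "batch": pd.Series(batches or {s: "b1" for s in df.columns}),
        "replicate": pd.Series({s: s for s in df.columns}),
    })
    return CountMatrix(counts=df, metadata=meta)


class TestCountMatrix:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_cm({"s1": [-1, 2]}, {"s1": "WT"})

    def test_missing_metadata_rejected(self):
        df = pd.DataFrame({"s1": [1], "s2": [2]})
        meta = pd.DataFrame({"strain": ["WT"], "batch": ["b1"]},
                            index=["s1"])
        with pytest.raises(ValueError, match="s2"):
            CountMatrix(counts=df, metadata=meta)


class TestSizeFactors:
    def test_doubled_sample_gets_double_factor(self):
        cm = make_cm({"s1": [10, 20, 30], "s2": [20, 40, 60]},
                     {"s1": "WT", "s2": "WT"})
        f = size_factors(cm.counts)
        assert f["s2"] / f["s1"] == pytest.approx(2.0)

    def test_identical_samples_equal_factors(self):
        cm = make_cm({"s1": [5, 7], "s2": [5, 7], "s3": [5, 7]},
                     {s: "WT" for s in ("s1", "s2", "s3")})
        f = size_factors(cm.counts)
        assert f.nunique() == 1

    def test_scale_equivariance(self):
        base = pd.DataFrame({"s1": [10, 20, 5], "s2": [12, 18, 6]})
        f0 = size_factors(base)
        scaled = base.copy()
        scaled["s2"] = scaled["s2"] * 3
        f1 = size_factors(scaled)
        # factors are defined up to proportionality: the s2/s1 ratio triples
        assert (f1["s2"] / f1["s1"]) / (f0["s2"] / f0["s1"]) == \
            pytest.approx(3.0)

    def test_fallback_when_no_common_gene(self, caplog):
        counts = pd.DataFrame({"s1": [10, 0], "s2": [0, 10]})
        with caplog.at_level("WARNING"):
            f = size_factors(counts)
        assert (f > 0).all()
        assert "upper-quartile" in caplog.text


class TestDeTest:
    def null_cm(self, rng, n_genes=300, reps=4):
        mu = rng.uniform(20, 200, n_genes)
        cols, strains = {}, {}
        for s, strain in [(f"wt{i}", "WT") for i in range(reps)] + \
                         [(f"m{i}", "mut") for i in range(reps)]:
            cols[s] = rng.poisson(mu)
            strains[s] = strain
        return make_cm(cols, strains)

    def test_exact_doubling_gives_unit_log2fc(self):
        # 9 stable genes anchor the size factors at 1; one gene doubled
        stable = list(range(100, 1000, 100))
        wt = {f"wt{i}": stable + [400] for i in range(3)}
        mut = {f"m{i}": stable + [800] for i in range(3)}
        cm = make_cm({**wt, **mut},
                     {**{k: "WT" for k in wt}, **{k: "mut" for k in mut}})
        de = de_test(cm, "mut", "WT", batch_covariate=False, pseudocount=0.0)
        assert de["log2fc"].iloc[-1] == pytest.approx(1.0, abs=0.02)
        assert de["log2fc"].iloc[:-1].abs().max() < 0.02

    def test_planted_shift_recovered_with_batch_model(self, rng):
        cm = self.null_cm(rng, n_genes=200, reps=6)
        counts = cm.counts.copy()
        mut_cols = [c for c in counts if c.startswith("m")]
        counts.loc[counts.index[:20], mut_cols] *= 4
        batches = {c: f"b{i % 2}" for i, c in enumerate(counts.columns)}
        cm2 = make_cm(counts.to_dict("list"),
                      cm.metadata["strain"].to_dict(), batches)
        cm2.counts.index = counts.index
        de = de_test(cm2, "mut", "WT", batch_covariate=True, fdr=0.01)
        planted = de.iloc[:20]
        assert planted["significant"].mean() >= 0.9
        assert planted["log2fc"].mean() == pytest.approx(2.0, abs=0.3)

    def test_sample_order_invariance(self, rng):
        cm = self.null_cm(rng)
        de1 = de_test(cm, "mut", "WT")
        shuffled = cm.counts[list(cm.counts.columns[::-1])]
        cm2 = CountMatrix(counts=shuffled, metadata=cm.metadata)
        de2 = de_test(cm2, "mut", "WT")
        pd.testing.assert_frame_equal(de1, de2)

    def test_batch_relabeling_invariance(self, rng):
        cm = self.null_cm(rng)
        batches = {c: f"b{i % 2}" for i, c in enumerate(cm.counts.columns)}
        relabeled = {c: {"b0": "x", "b1": "y"}[b] for c, b in batches.items()}
        cm1 = make_cm(cm.counts.to_dict("list"),
                      cm.metadata["strain"].to_dict(), batches)
        cm2 = make_cm(cm.counts.to_dict("list"),
                      cm.metadata["strain"].to_dict(), relabeled)
        de1 = de_test(cm1, "mut", "WT")
        de2 = de_test(cm2, "mut", "WT")
        np.testing.assert_allclose(de1["p"], de2["p"], atol=1e-12)

    def test_single_replicate_rejected(self, rng):
        cm = make_cm({"wt0": [1, 2], "m0": [3, 4], "m1": [5, 6]},
                     {"wt0": "WT", "m0": "mut", "m1": "mut"})
        with pytest.raises(ValueError):
            de_test(cm, "mut", "WT")


class TestExpressionFilter:
    def test_low_expression_genes_dropped(self, rng):
        counts = pd.DataFrame({
            "s1": [100, 0, 3], "s2": [120, 1, 0],
            "m1": [90, 0, 0], "m2": [95, 0, 1]},
            index=["high", "off", "low"])
        cm = CountMatrix(counts=counts, metadata=pd.DataFrame({
            "strain": ["WT", "WT", "m", "m"], "batch": ["b"] * 4},
            index=counts.columns))
        kept = expression_filter(cm, min_mean=1.0)
        assert "high" in kept and "off" not in kept


class TestImportExternalDe:
    def test_round_trip(self, tmp_path, rng):
        tab = pd.DataFrame({
            "gene": [f"g{i}" for i in range(10)],
            "log2fc": rng.normal(size=10),
            "p": rng.uniform(size=10)})
        tab["q"] = bh_adjust(tab["p"])
        path = tmp_path / "de.tsv"
        tab.to_csv(path, sep="\t", index=False)
        out = import_external_de(path)
        np.testing.assert_allclose(out["q"], tab["q"])

    def test_q_recomputed_from_p_only(self, tmp_path):
        path = tmp_path / "de.tsv"
        pd.DataFrame({"gene": ["a", "b", "c"], "log2fc": [1, -1, 0],
                      "p": [0.01, 0.02, 0.03]}).to_csv(path, sep="\t",
                                                       index=False)
        out = import_external_de(path)
        np.testing.assert_allclose(out["q"], bh_adjust([0.01, 0.02, 0.03]))

    def test_column_mapping(self, tmp_path):
        path = tmp_path / "de.tsv"
        pd.DataFrame({"id": ["a"], "lfc": [2.0], "pval": [0.5]}
                     ).to_csv(path, sep="\t", index=False)
        out = import_external_de(path, column_map={
            "gene": "id", "log2fc": "lfc", "p": "pval"})
        assert out.loc["a", "log2fc"] == 2.0

    def test_missing_columns_named(self, tmp_path):
        path = tmp_path / "de.tsv"
        pd.DataFrame({"gene": ["a"], "p": [0.1]}).to_csv(path, sep="\t",
                                                         index=False)
        with pytest.raises(ValueError, match="log2fc"):
            import_external_de(path)

    def test_malformed_numeric_reported_by_row(self, tmp_path):
        path = tmp_path / "de.tsv"
        pd.DataFrame({"gene": ["a", "b"], "log2fc": [1.0, "oops"],
                      "p": [0.1, 0.2]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="row"):
            import_external_de(path)
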