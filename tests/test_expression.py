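"""TMM factors, FPKM arithmetic, ordinal binning and pattern rules."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from devtome import expression as ex
from devtome.synthetic import STAGES


def _random_counts(seed, n=300, libs=4):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.negative_binomial(5, 0.01, size=(n, libs)).astype(float),
                        columns=[f"lib{i}" for i in range(libs)])


class TestTmm:
    def test_identical_libraries_give_unit_factors(self):
        counts = _random_counts(0, libs=2)
        counts["lib1"] = counts["lib0"]
        assert np.allclose(ex.tmm_factors(counts), 1.0)

    def test_uniformly_doubled_library_equalizes_fpkm(self):
        counts = _random_counts(1, libs=2)
        counts["lib1"] = 2.0 * counts["lib0"]
        lengths = pd.Series(1000.0, index=counts.index)
        values = ex.fpkm(counts, ex.tmm_factors(counts), lengths)
        assert np.allclose(values["lib0"], values["lib1"], rtol=1e-6)

    def test_trimming_removes_composition_bias_from_shifted_minority(self):
        """An 8-fold up-shift in 10% of genes must not distort the rest.

        The shifted genes inflate the library total; trimming excludes them
        from the factor, so FPKM of the unshifted majority stays put.
        """
        rng = np.random.default_rng(2)
        mu = 10.0 ** rng.uniform(2.5, 4.0, 300)
        counts = pd.DataFrame({"lib0": rng.poisson(mu).astype(float),
                               "lib1": rng.poisson(mu).astype(float)})
        lengths = pd.Series(1000.0, index=counts.index)
        base = ex.fpkm(counts, ex.tmm_factors(counts), lengths)
        shifted = counts.copy()
        idx = shifted.index[:len(shifted) // 10]
        shifted.loc[idx, "lib1"] *= 8.0
        values = ex.fpkm(shifted, ex.tmm_factors(shifted), lengths)
        rest = counts.index.difference(idx)
        ratio = (values.loc[rest, "lib1"] / values.loc[rest, "lib0"]) \
            / (base.loc[rest, "lib1"] / base.loc[rest, "lib0"])
        assert abs(np.median(ratio) - 1.0) < 0.01

    def test_all_zero_library_rejected(self):
        counts = _random_counts(3, libs=2)
        counts["lib1"] = 0.0
        with pytest.raises(ValueError):
            ex.tmm_factors(counts)

    def test_matches_edger_at_equal_depth(self, tmp_path):
        counts = _random_counts(4, libs=4)
        counts = counts.div(counts.sum(axis=0), axis=1) * 1e6  # matched depth
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t")
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.delim("{path}", row.names=1));'
            'f <- calcNormFactors(x, method="TMM", logratioTrim=0.30, sumTrim=0.05);'
            'cat(sprintf("%.12f ", f))'
        )
        result = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                text=True, check=True)
        edger = np.array([float(v) for v in result.stdout.split()])
        assert np.allclose(ex.tmm_factors(counts).to_numpy(), edger, atol=1e-8)


class TestFpkm:
    def test_plugin_value(self):
        counts = pd.DataFrame({"a": [100.0, 999_900.0]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000.0, "g2": 1.0})
        factors = pd.Series({"a": 1.0})
        values = ex.fpkm(counts, factors, lengths)
        assert values.loc["g1", "a"] == pytest.approx(100.0)

    def test_zero_count_zero_fpkm_and_formula(self):
        rng = np.random.default_rng(5)
        counts = _random_counts(5, n=50, libs=3)
        counts.iloc[0] = 0.0
        lengths = pd.Series(rng.integers(300, 4000, 50).astype(float),
                            index=counts.index)
        factors = ex.tmm_factors(counts)
        values = ex.fpkm(counts, factors, lengths)
        assert (values.iloc[0] == 0).all()
        sizes = counts.sum(axis=0)
        for lib in counts.columns:
            expected = 1e9 * counts[lib] / (lengths * sizes[lib] * factors[lib])
            assert np.allclose(values[lib], expected)

    def test_zero_length_rejected(self):
        counts = _random_counts(6, n=5, libs=2)
        lengths = pd.Series([1000, 0, 1000, 1000, 1000], index=counts.index, dtype=float)
        with pytest.raises(ValueError):
            ex.fpkm(counts, ex.tmm_factors(counts), lengths)


class TestBinning:
    @pytest.mark.parametrize("value,code", [
        (0.0, 1), (0.4, 1), (0.5, 2), (3.0, 2), (3.4, 2), (4.0, 3), (10.0, 3),
        (25.4, 4), (25.5, 5), (50.0, 5), (75.0, 6), (500.0, 7), (1e6, 8),
    ])
    def test_default_edges(self, value, code):
        m = pd.DataFrame({"s": [value]})
        assert ex.bin_expression(m).iloc[0, 0] == code

    def test_floor_mode_differs_on_halves(self):
        m = pd.DataFrame({"s": [25.5]})
        assert ex.bin_expression(m, integerize="floor").iloc[0, 0] == 4

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ex.bin_expression(pd.DataFrame({"s": [-1.0]}))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1e7), min_size=2, max_size=20))
    def test_monotone(self, values):
        m = pd.DataFrame({"s": sorted(values)})
        codes = ex.bin_expression(m)["s"].to_numpy()
        assert (np.diff(codes) >= 0).all()


class TestStagePatterns:
    def _classify(self, codes):
        m = pd.DataFrame([codes], columns=list(STAGES), index=["g"])
        return ex.classify_stage_patterns(m).loc["g"]

    def test_rule_instances(self):
        assert self._classify((6, 6, 6, 6, 6, 6))["label"] == "constitutive_high"
        row = self._classify((1, 5, 1, 1, 1, 1))
        assert row["label"] == "specific_1" and row["stages"] == "larvae"
        row = self._classify((6, 6, 1, 1, 2, 1))
        assert row["label"] == "specific_2" and row["stages"] == "egg+larvae"
        assert self._classify((2, 3, 1, 2, 3, 2))["label"] == "constitutive_low"
        assert self._classify((4, 4, 1, 1, 1, 1))["label"] == "other"

    def test_single_stage_rule_uses_moderate_threshold(self):
        # code 4 qualifies for 1-stage specificity but not for k>=2 patterns
        assert self._classify((4, 1, 1, 1, 1, 1))["label"] == "specific_1"
        assert self._classify((4, 4, 1, 1, 1, 1))["label"] == "other"

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=8), min_size=6, max_size=6))
    def test_labels_exhaustive_and_exclusive(self, codes):
        label = self._classify(tuple(codes))["label"]
        assert label in {"constitutive_high", "constitutive_low", "other",
                         "specific_1", "specific_2", "specific_3", "specific_4",
                         "specific_5"}


def test_scale_invariance_of_pipeline(small_dataset):
    _, _, truth, counts = small_dataset
    lengths = truth.transcripts.set_index("transcript_id")["length"].astype(float)
    gene_map = truth.transcripts.set_index("transcript_id")["gene_id"]
    _, v1, c1, _ = ex.expression_profile(counts, lengths, gene_map)
    scaled = counts.copy()
    scaled["pupae"] *= 2.0
    _, v2, c2, _ = ex.expression_profile(scaled, lengths, gene_map)
    rel = (v1 - v2).abs() / v1.where(v1 > 0, 1.0)
    assert float(rel.max().max()) < 1e-6
    assert (c1 == c2).all().all()


def test_planted_patterns_recovered(small_dataset):
    _, _, truth, counts = small_dataset
    lengths = truth.transcripts.set_index("transcript_id")["length"].astype(float)
    gene_map = truth.transcripts.set_index("transcript_id")["gene_id"]
    *_, patterns = ex.expression_profile(counts, lengths, gene_map)
    genes = truth.genes.set_index("gene_id")
    merged = patterns.join(genes[["pattern", "is_background"]])
    agree = (merged["label"] == merged["pattern"]).mean()
    assert agree >= 0.9


def test_compare_bin_distributions_conserves_counts(small_dataset):
    _, _, truth, counts = small_dataset
    lengths = truth.transcripts.set_index("transcript_id")["length"].astype(float)
    gene_map = truth.transcripts.set_index("transcript_id")["gene_id"]
    _, _, cats, _ = ex.expression_profile(counts, lengths, gene_map)
    table = ex.compare_bin_distributions(cats, cats)
    for (dataset, stage), sub in table.groupby(["dataset", "stage"]):
        assert sub["n_genes"].sum() == len(cats)
    a = table[table["dataset"] == "A"].set_index(["stage", "code"])["n_genes"]
    b = table[table["dataset"] == "B"].set_index(["stage", "code"])["n_genes"]
    assert (a == b).all()
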