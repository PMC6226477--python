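"""Normalization, ES/dES arithmetic, filter rules, ranks, invariances."""

import numpy as np
import pandas as pd
import pytest

from g4rp.enrichment import (
    CountsMatrix,
    compute_size_factors,
    enrichment_score,
    enrichment_score_change,
    filter_and_rank,
    mean_read_count,
    normalize_counts,
    score_dataset,
)


def _cm(counts: dict, samples: list[tuple[str, str, str, int]]) -> CountsMatrix:
    counts_df = pd.DataFrame(counts, index=pd.Index([f"g{i}" for i in range(len(next(iter(counts.values()))))], name="gene_id"))
    samples_df = pd.DataFrame(
        samples, columns=["sample_id", "condition", "assay", "replicate"]
    ).set_index("sample_id")
    return CountsMatrix(counts=counts_df, samples=samples_df)


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        s = compute_size_factors(df)
        assert np.allclose(s, [1.0, 1.0])

    def test_doubled_sample_hand_computation(self):
        # sample b = 2 x sample a, no zeros: median ratio to the per-gene
        # geometric mean is 1/sqrt(2) and sqrt(2); geometric mean already 1
        df = pd.DataFrame({"a": [100, 4, 50], "b": [200, 8, 100]})
        s = compute_size_factors(df)
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)])
        assert np.exp(np.log(s).mean()) == pytest.approx(1.0)

    def test_genes_with_zeros_excluded_from_median(self):
        # the zero-containing gene would otherwise drag sample b's median down
        df = pd.DataFrame({"a": [100, 4, 50, 1000], "b": [200, 8, 100, 0]})
        s = compute_size_factors(df)
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)])

    def test_no_all_positive_gene_errors_and_fallback(self):
        df = pd.DataFrame({"a": [10, 0], "b": [0, 10]})
        with pytest.raises(ValueError, match="pseudo_reference"):
            compute_size_factors(df)
        with pytest.raises(ValueError):
            compute_size_factors(df, pseudo_reference=True)  # <2 positive samples/gene

    def test_agrees_with_deseq2_reference_implementation(self, small_dataset):
        """Independent cross-check against the DESeq2-style median-of-ratios."""
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        _, cm, _ = small_dataset
        _, ref = pydeseq2.deseq2_norm(cm.counts.T)
        ref = np.asarray(ref, dtype=float)
        ref = ref / np.exp(np.mean(np.log(ref)))  # same geometric-mean convention
        ours = compute_size_factors(cm).to_numpy()
        # pydeseq2 interpolates the even-count median in log space (geometric
        # mean of the middle pair) where we use the ratio scale, so agreement
        # is near-exact rather than bitwise
        assert np.allclose(ours, ref, rtol=1e-4)

    def test_scaling_one_sample_scales_its_factor(self, small_dataset):
        _, cm, _ = small_dataset
        s0 = compute_size_factors(cm.counts)
        scaled = cm.counts.copy()
        col = scaled.columns[0]
        scaled[col] = scaled[col] * 3
        s1 = compute_size_factors(scaled)
        gamma = 3 ** (1 / len(scaled.columns))  # geometric-mean renormalization
        assert np.allclose(s1[col], s0[col] * 3 / gamma, rtol=1e-9)
        others = [c for c in scaled.columns if c != col]
        assert np.allclose(s1[others], s0[others] / gamma, rtol=1e-9)
        # normalized profile of the scaled sample is unchanged up to gamma
        n0 = normalize_counts(cm.counts, s0)
        n1 = normalize_counts(scaled, s1)
        assert np.allclose(n1[col], n0[col] * gamma, rtol=1e-9)


class TestNormalization:
    def test_unit_factors_identity(self):
        df = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
        s = pd.Series([1.0, 1.0], index=["a", "b"])
        assert normalize_counts(df, s).equals(df.astype(float))

    def test_mean_read_count(self):
        df = pd.DataFrame({"a": [100.0], "b": [300.0]})
        s = pd.Series([1.0, 1.0], index=["a", "b"])
        assert mean_read_count(normalize_counts(df, s)).iloc[0] == 200.0


class TestEnrichmentScore:
    def _norm_and_sheet(self):
        norm = pd.DataFrame(
            {
                "u_input_1": [1000.0, 1000.0, 0.0],
                "u_G4RP_1": [1000.0, 4000.0, 10.0],
            },
            index=["g0", "g1", "g2"],
        )
        samples = pd.DataFrame(
            {
                "condition": ["u", "u"],
                "assay": ["input", "G4RP"],
                "replicate": [1, 1],
            },
            index=pd.Index(["u_input_1", "u_G4RP_1"], name="sample_id"),
        )
        return norm, samples

    def test_es_ratio_examples(self):
        norm, samples = self._norm_and_sheet()
        es = enrichment_score(norm, samples, "u", pseudocount=0.5)
        assert es["g0"] == pytest.approx(1.0)  # equal signal, eps symmetric
        assert es["g1"] == pytest.approx(4000.5 / 1000.5)
        assert es["g2"] == pytest.approx(21.0)  # zero input stays finite
        assert (es > 0).all()

    def test_missing_input_errors(self):
        norm, samples = self._norm_and_sheet()
        samples_no_input = samples[samples["assay"] != "input"]
        with pytest.raises(ValueError, match="no input"):
            enrichment_score(norm[["u_G4RP_1"]], samples_no_input, "u")

    def test_des_examples_and_boundary(self):
        es_u = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        es_t = pd.Series([2.0, 3.5, 4.0], index=list("abc"))
        des = enrichment_score_change(es_t, es_u)
        assert des.tolist() == pytest.approx([1.0, 1.75, 2.0])
        frame = pd.DataFrame(
            {"mean_count": [600.0, 600.0, 600.0], "es_u": es_u, "es_t": es_t, "des_t": des}
        )
        out = filter_and_rank(frame, reference="u", ligands=["t"])
        # the induction rule is strict: dES == 1.75 is NOT induced
        assert out["induced_t"].tolist() == [False, False, True]

    def test_nan_des_excluded_from_induced(self):
        frame = pd.DataFrame(
            {
                "mean_count": [600.0, 600.0],
                "es_u": [1.0, 1.0],
                "es_t": [3.0, 3.0],
                "des_t": [np.nan, 3.0],
            },
            index=["a", "b"],
        )
        out = filter_and_rank(frame, reference="u", ligands=["t"])
        assert out["induced_t"].tolist() == [False, True]


class TestFilterAndRank:
    def _frame(self):
        return pd.DataFrame(
            {
                "mean_count": [600.0, 40.0, 900.0, 50.0],
                "es_u": [2.0, 2.0, 1.0, 1.5],
                "es_t": [4.0, 3.6, 1.2, 1.5],
                "des_t": [2.0, 1.8, 1.2, 1.0],
            },
            index=["gene1", "gene2", "gene3", "gene4"],
        )

    def test_filter_rules(self):
        out = filter_and_rank(self._frame(), reference="u", ligands=["t"])
        # mean exactly 50 is NOT expressed (strict >); 40 fails too
        assert out["expressed"].tolist() == [True, False, True, False]
        # abundance boundary is inclusive by default
        assert out.loc["gene1", "abundant"] and out.loc["gene3", "abundant"]
        # induced: gene1 only (gene2 not expressed, gene3 below dES threshold)
        assert out["induced_t"].tolist() == [True, False, False, False]
        assert out["top_t"].tolist() == [True, False, False, False]

    def test_strict_abundance_flag(self):
        frame = self._frame()
        frame.loc["gene1", "mean_count"] = 500.0
        out = filter_and_rank(frame, reference="u", ligands=["t"])
        assert out.loc["gene1", "abundant"]
        strict = filter_and_rank(
            frame, reference="u", ligands=["t"], strict_abundant=True
        )
        assert not strict.loc["gene1", "abundant"]

    def test_ranks_cover_expressed_and_nan_elsewhere(self):
        out = filter_and_rank(self._frame(), reference="u", ligands=["t"])
        expressed = out["expressed"]
        ranks = out.loc[expressed, "rank_es_u"]
        assert sorted(ranks) == [1.0, 2.0]
        assert out.loc[~expressed, "rank_es_u"].isna().all()

    def test_equal_es_ties_break_by_gene_id(self):
        frame = pd.DataFrame(
            {
                "mean_count": [600.0] * 3,
                "es_u": [1.0, 1.0, 1.0],
            },
            index=["c", "a", "b"],
        )
        out = filter_and_rank(frame, reference="u", ligands=[])
        assert out.loc[["a", "b", "c"], "rank_es_u"].tolist() == [1.0, 2.0, 3.0]


class TestScoreDataset:
    def test_scale_invariance_of_es(self, small_dataset):
        """Rescaling one library leaves ES essentially unchanged (pseudocount only)."""
        _, cm, _ = small_dataset
        base = score_dataset(cm).frame
        scaled_counts = cm.counts.copy()
        col = cm.pulldown_samples("untreated")[0]
        scaled_counts[col] = scaled_counts[col] * 4
        cm2 = CountsMatrix(counts=scaled_counts, samples=cm.samples.copy())
        scaled = score_dataset(cm2).frame
        sel = base["mean_count"] >= 500
        ratio = scaled.loc[sel, "es_untreated"] / base.loc[sel, "es_untreated"]
        assert np.allclose(ratio, 1.0, rtol=1e-3)

    def test_missing_input_condition_rejected(self, small_dataset):
        _, cm, _ = small_dataset
        keep = [s for s in cm.counts.columns if s != "untreated_input_1"]
        with pytest.raises(ValueError, match="untreated"):
            CountsMatrix(counts=cm.counts[keep], samples=cm.samples.loc[keep])

    def test_pulldown_ratio_variant_matches_definition(self, small_dataset):
        _, cm, _ = small_dataset
        alt = score_dataset(cm, des_mode="pulldown_ratio").frame
        expected = (alt["pulldown_mean_BRACO-19"] + 0.5) / (
            alt["pulldown_mean_untreated"] + 0.5
        )
        assert np.allclose(alt["des_BRACO-19"], expected)

    def test_unknown_reference_rejected(self, small_dataset):
        _, cm, _ = small_dataset
        with pytest.raises(ValueError, match="reference"):
            score_dataset(cm, reference="mock")


class TestCountsMatrixValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            _cm(
                {"u_input_1": [1, -2], "u_G4RP_1": [1, 2]},
                [("u_input_1", "u", "input", 1), ("u_G4RP_1", "u", "G4RP", 1)],
            )

    def test_duplicate_gene_ids_rejected(self):
        counts = pd.DataFrame(
            {"u_input_1": [1, 2], "u_G4RP_1": [1, 2]}, index=["g", "g"]
        )
        samples = pd.DataFrame(
            {"condition": ["u", "u"], "assay": ["input", "G4RP"], "replicate": [1, 1]},
            index=pd.Index(["u_input_1", "u_G4RP_1"], name="sample_id"),
        )
        with pytest.raises(ValueError, match="duplicate gene ids"):
            CountsMatrix(counts=counts, samples=samples)

    def test_sample_sheet_mismatch_names_samples(self):
        counts = pd.DataFrame({"u_input_1": [1], "orphan": [1]}, index=["g"])
        samples = pd.DataFrame(
            {"condition": ["u"], "assay": ["input"], "replicate": [1]},
            index=pd.Index(["u_input_1"], name="sample_id"),
        )
        with pytest.raises(ValueError, match="orphan"):
            CountsMatrix(counts=counts, samples=samples)
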