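"""Expression, copy-number and methylation scorers."""

import numpy as np
import pandas as pd
import pytest

from oncoscape import (
    OmicsMatrix,
    ProbeAnnotation,
    ScoringConfig,
    ValidationError,
    build_paired_cohort,
    map_segments_to_genes,
    score_copy_number,
    score_expression,
    score_methylation,
)
from oncoscape.scoring import PairedCohort

from conftest import make_matrix, make_paired_map


class TestSegMapping:
    def test_overlap_weighted_mean(self):
        seg = pd.DataFrame(
            {
                "sample": ["S1", "S1"],
                "chrom": ["1", "1"],
                "start": [1, 151],
                "end": [150, 300],
                "seg_mean": [0.4, 0.8],
            }
        )
        genes = pd.DataFrame(
            {"gene": ["G"], "chrom": ["1"], "start": [101], "end": [200]}
        )
        m = map_segments_to_genes(seg, genes)
        assert m.values.loc["G", "S1"] == pytest.approx(0.6)

    def test_single_segment_identity(self):
        seg = pd.DataFrame(
            {"sample": ["S1"], "chrom": ["2"], "start": [1], "end": [10_000],
             "seg_mean": [-0.3]}
        )
        genes = pd.DataFrame(
            {"gene": ["G"], "chrom": ["2"], "start": [500], "end": [900]}
        )
        m = map_segments_to_genes(seg, genes)
        assert m.values.loc["G", "S1"] == pytest.approx(-0.3)

    def test_uncovered_chromosome_missing(self):
        seg = pd.DataFrame(
            {"sample": ["S1"], "chrom": ["1"], "start": [1], "end": [100],
             "seg_mean": [0.5]}
        )
        genes = pd.DataFrame(
            {"gene": ["G"], "chrom": ["X"], "start": [10], "end": [20]}
        )
        m = map_segments_to_genes(seg, genes)
        assert np.isnan(m.values.loc["G", "S1"])


def _expression_cohort(rng, n_pairs=20, n_null=999, shift=2.0):
    """One shifted gene among exchangeable nulls."""
    genes = ["HIT"] + [f"N{i:04d}" for i in range(n_null)]
    normal = rng.normal(8, 1, (len(genes), n_pairs))
    tumor = rng.normal(8, 1, (len(genes), n_pairs))
    tumor[0] = normal[0] + shift
    m = make_matrix(np.hstack([tumor, normal]), genes, n_pairs, n_pairs)
    return build_paired_cohort(m, make_paired_map(n_pairs))


class TestExpression:
    def test_planted_gene_flagged_activating(self, rng):
        calls = score_expression(_expression_cohort(rng))
        assert calls.frame.loc["HIT", "activating"]
        assert not calls.frame.loc["HIT", "inactivating"]

    def test_equal_tumor_normal_unflagged(self, rng):
        cohort = _expression_cohort(rng, shift=0.0)
        calls = score_expression(cohort)
        assert not calls.frame.loc["HIT", ["activating", "inactivating"]].any()

    def test_flags_mutually_exclusive(self, rng):
        calls = score_expression(_expression_cohort(rng, n_null=50))
        f = calls.frame
        assert not (f["activating"] & f["inactivating"]).any()

    def test_too_few_pairs_unavailable(self, rng):
        genes = ["A", "B"]
        vals = rng.normal(size=(2, 8))
        vals[1, :2] = np.nan  # gene B has only 2 complete pairs
        m = make_matrix(vals, genes, 4, 4)
        cohort = build_paired_cohort(m, make_paired_map(4))
        calls = score_expression(cohort)
        assert calls.frame.loc["A", "available"]
        assert not calls.frame.loc["B", "available"]

    def test_requires_deduplicated_map(self, rng):
        from oncoscape import SampleMap

        smap = SampleMap(
            pd.DataFrame(
                {
                    "patient_id": ["P0", "P0"],
                    "sample_id": ["P000-T", "P000-N"],
                    "sample_class": ["tumor_primary", "normal"],
                    "cancer_type": "X",
                }
            )
        )
        m = make_matrix(rng.normal(size=(1, 2)), ["A"], 1, 1)
        with pytest.raises(ValidationError, match="dedup"):
            build_paired_cohort(m, smap)

    def test_permutation_invariance(self, rng):
        """Row/column order of the input matrix never changes calls."""
        cohort = _expression_cohort(rng, n_pairs=10, n_null=30)
        calls = score_expression(cohort)
        perm_genes = rng.permutation(cohort.tumor.feature_ids).tolist()
        perm_t = rng.permutation(cohort.tumor.sample_ids).tolist()
        shuffled = PairedCohort(
            OmicsMatrix(cohort.tumor.values.loc[perm_genes, perm_t], "expression"),
            OmicsMatrix(cohort.normal.values.loc[perm_genes], "expression"),
            cohort.pairs,
        )
        calls2 = score_expression(shuffled)
        pd.testing.assert_frame_equal(
            calls.frame.sort_index(), calls2.frame.sort_index()
        )


def _cn_setup(shift, n_pairs=200, rho_sign=1.0):
    """One gene: constant shift with tiny distinct jitter, expression
    perfectly (anti)monotone in tumor CN."""
    jit = 0.01 * (2 * np.arange(n_pairs) / (n_pairs - 1) - 1)
    tumor = (shift + jit)[None, :]
    normal = np.zeros((1, n_pairs))
    cn = make_matrix(np.hstack([tumor, normal]), ["G"], n_pairs, n_pairs, tag="cna")
    cohort = build_paired_cohort(cn, make_paired_map(n_pairs))
    expr = OmicsMatrix(
        pd.DataFrame(rho_sign * tumor, index=["G"], columns=cohort.tumor.sample_ids),
        "expression",
    )
    return cohort, expr


class TestCopyNumber:
    def test_gain_with_positive_correlation_flagged(self):
        cohort, expr = _cn_setup(0.15)
        calls = score_copy_number(cohort, expr)
        assert calls.frame.loc["G", "activating"]

    def test_shift_exactly_at_gate_unflagged(self):
        cohort, expr = _cn_setup(0.10)
        calls = score_copy_number(cohort, expr)
        assert not calls.frame.loc["G", ["activating", "inactivating"]].any()

    def test_negative_correlation_blocks_flag(self):
        cohort, expr = _cn_setup(0.5, rho_sign=-1.0)
        calls = score_copy_number(cohort, expr)
        assert not calls.frame.loc["G", ["activating", "inactivating"]].any()

    def test_loss_flagged_inactivating(self):
        cohort, expr = _cn_setup(-0.3)
        calls = score_copy_number(cohort, expr)
        assert calls.frame.loc["G", "inactivating"]

    def test_gene_missing_from_expression_unavailable(self):
        cohort, expr = _cn_setup(0.5)
        other = OmicsMatrix(
            pd.DataFrame(expr.values.to_numpy(), index=["OTHER"],
                         columns=expr.sample_ids),
            "expression",
        )
        calls = score_copy_number(cohort, other)
        assert not calls.frame.loc["G", "available"]

    def test_infinite_gate_flags_nothing(self):
        cohort, expr = _cn_setup(0.5)
        cfg = ScoringConfig(min_cn_diff=np.inf)
        calls = score_copy_number(cohort, expr, cfg)
        assert not calls.frame[["activating", "inactivating"]].to_numpy().any()


def _meth_setup(beta_shift, region="body", corr_sign=1.0, n=100):
    jit = 0.01 * (2 * np.arange(n) / (n - 1) - 1)
    tumor_cols = [f"T{i:03d}" for i in range(n)]
    normal_cols = [f"N{i:03d}" for i in range(n)]
    tumor = pd.DataFrame([0.4 + beta_shift + jit], index=["cg1"], columns=tumor_cols)
    normal = pd.DataFrame(0.4, index=["cg1"], columns=normal_cols)
    expr = OmicsMatrix(
        pd.DataFrame(corr_sign * tumor.to_numpy(), index=["G"], columns=tumor_cols),
        "expression",
    )
    annot = ProbeAnnotation(
        pd.DataFrame({"probe_id": ["cg1"], "gene": ["G"], "region": [region]})
    )
    return (
        OmicsMatrix(tumor, "methylation"),
        OmicsMatrix(normal, "methylation"),
        annot,
        expr,
    )


class TestMethylation:
    def test_body_hyper_positive_corr_activating(self):
        calls, _ = score_methylation(*_meth_setup(0.2, "body", corr_sign=1.0))
        assert calls.frame.loc["G", "activating"]
        assert not calls.frame.loc["G", "inactivating"]

    def test_other_hyper_negative_corr_inactivating(self):
        calls, _ = score_methylation(*_meth_setup(0.2, "other", corr_sign=-1.0))
        assert calls.frame.loc["G", "inactivating"]
        assert not calls.frame.loc["G", "activating"]

    def test_body_hypo_positive_corr_inactivating(self):
        calls, _ = score_methylation(*_meth_setup(-0.2, "body", corr_sign=1.0))
        assert calls.frame.loc["G", "inactivating"]

    def test_both_flags_from_two_probes(self):
        """A gene with one OG-style and one TS-style probe gets both."""
        n = 100
        jit = 0.01 * (2 * np.arange(n) / (n - 1) - 1)
        tumor_cols = [f"T{i:03d}" for i in range(n)]
        normal_cols = [f"N{i:03d}" for i in range(n)]
        tumor = pd.DataFrame(
            [0.6 + jit, 0.6 + jit], index=["cg_body", "cg_prom"], columns=tumor_cols
        )
        normal = pd.DataFrame(0.4, index=["cg_body", "cg_prom"], columns=normal_cols)
        annot = ProbeAnnotation(
            pd.DataFrame(
                {
                    "probe_id": ["cg_body", "cg_prom"],
                    "gene": ["G", "G"],
                    "region": ["body", "other"],
                }
            )
        )
        # expression positively follows the body probe, i.e. negatively
        # nothing: use two genes? no - single gene: expression correlates
        # positively with cg_body and (same values) positively with
        # cg_prom, so make the promoter probe anti-correlated instead
        tumor.loc["cg_prom"] = 0.6 - jit
        expr = OmicsMatrix(
            pd.DataFrame([0.6 + jit], index=["G"], columns=tumor_cols), "expression"
        )
        calls, _ = score_methylation(
            OmicsMatrix(tumor, "methylation"),
            OmicsMatrix(normal, "methylation"),
            annot,
            expr,
        )
        assert calls.frame.loc["G", "activating"]
        assert calls.frame.loc["G", "inactivating"]

    def test_shift_at_gate_unflagged(self):
        calls, _ = score_methylation(*_meth_setup(0.1, "body"))
        assert not calls.frame.loc["G", ["activating", "inactivating"]].any()

    def test_gene_without_expression_skipped(self):
        tm, nm, annot, expr = _meth_setup(0.2, "body")
        empty_expr = OmicsMatrix(
            pd.DataFrame(index=pd.Index([], dtype=object),
                         columns=expr.sample_ids, dtype=float),
            "expression",
        )
        calls, _ = score_methylation(tm, nm, annot, empty_expr)
        assert not calls.frame.loc["G", "available"]
        assert not calls.frame.loc["G", ["activating", "inactivating"]].any()


class TestGeneRemovalMonotonicity:
    def test_removing_a_gene_keeps_other_flags(self, rng):
        """With every other gene far from the threshold, dropping one
        gene only perturbs BH q-values, not directions."""
        cohort = _expression_cohort(rng, n_pairs=20, n_null=100)
        full = score_expression(cohort)
        drop = cohort.tumor.feature_ids[5]
        keep = [g for g in cohort.tumor.feature_ids if g != drop]
        reduced_cohort = PairedCohort(
            cohort.tumor.subset_features(keep),
            cohort.normal.subset_features(keep),
            cohort.pairs,
        )
        reduced = score_expression(reduced_cohort)
        pd.testing.assert_series_equal(
            full.frame.loc[keep, "activating"], reduced.frame["activating"]
        )
        pd.testing.assert_series_equal(
            full.frame.loc[keep, "inactivating"], reduced.frame["inactivating"]
        )
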