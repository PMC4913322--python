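"""Matrix-based aberration scorers: expression, copy number, methylation.

Each scorer compares tumor against normal samples and emits an
:class:`~oncoscape.types.AberrationCalls` set.  Expression uses paired
signed-rank tests with BH correction (FDR < 0.05).  Copy number adds a
strict mean-difference gate (> 0.1 log-ratio units) and requires a
significant positive Spearman correlation between copy number and
expression across tumor samples.  Methylation is probe-wise (unpaired
rank-sum, beta-difference gate > 0.1) with probe-expression correlation
gating and gene-body vs other-region logic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .types import (
    AberrationCalls,
    OmicsMatrix,
    ProbeAnnotation,
    SampleMap,
    ScoringConfig,
    ValidationError,
    empty_calls,
)


@dataclass
class PairedCohort:
    """Tumor/normal slices of one data type plus the patient pairing.

    ``tumor`` may contain more samples than appear in ``pairs`` (unpaired
    tumors participate in correlation stages but not in paired tests).
    """

    tumor: OmicsMatrix
    normal: OmicsMatrix
    pairs: list[tuple[str, str, str]]  # (tumor_sample, normal_sample, patient)

    def __post_init__(self) -> None:
        tcols = set(self.tumor.sample_ids)
        ncols = set(self.normal.sample_ids)
        patients = [p for _, _, p in self.pairs]
        if len(set(patients)) != len(patients):
            raise ValidationError("more than one pair for the same patient")
        for t, n, _ in self.pairs:
            if t not in tcols or n not in ncols:
                raise ValidationError(f"pair ({t}, {n}) not covered by slices")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def paired_values(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        t = self.tumor.values.loc[gene, [p[0] for p in self.pairs]].to_numpy(float)
        n = self.normal.values.loc[gene, [p[1] for p in self.pairs]].to_numpy(float)
        return t, n


def build_paired_cohort(
    matrix: OmicsMatrix, smap: SampleMap, cancer_type: str | None = None
) -> PairedCohort:
    """Slice ``matrix`` into tumor/normal parts and derive patient pairs.

    Requires a deduplicated sample map.  All primary tumor samples present
    in the matrix enter the tumor slice; pairs are the patients with both
    a primary tumor and a normal sample measured.
    """
    if not smap.deduplicated:
        raise ValidationError("sample map must be deduplicated before scoring")
    if cancer_type is not None:
        smap = smap.subset_cancer_type(cancer_type)
    cols = set(matrix.sample_ids)
    rec = smap.records
    tumors = [s for s in rec.loc[rec.sample_class == "tumor_primary", "sample_id"] if s in cols]
    normals = [s for s in rec.loc[rec.sample_class == "normal", "sample_id"] if s in cols]
    by_patient: dict[str, dict[str, str]] = {}
    for _, row in rec.iterrows():
        if row.sample_id not in cols:
            continue
        by_patient.setdefault(row.patient_id, {})[row.sample_class] = row.sample_id
    pairs = [
        (d["tumor_primary"], d["normal"], patient)
        for patient, d in sorted(by_patient.items())
        if "tumor_primary" in d and "normal" in d
    ]
    return PairedCohort(
        matrix.subset_samples(tumors), matrix.subset_samples(normals), pairs
    )


def map_segments_to_genes(
    seg: pd.DataFrame, genes: pd.DataFrame
) -> OmicsMatrix:
    """Collapse segmented copy number to gene-level log-ratios.

    ``seg`` columns: sample, chrom, start, end, seg_mean (1-based
    inclusive).  ``genes`` columns: gene, chrom, start, end.  Per gene and
    sample the overlap-length-weighted mean of ``seg_mean`` over all
    intersecting segments; genes with no overlapping segment are missing.
    """
    if (genes["end"] < genes["start"]).any():
        bad = genes[genes["end"] < genes["start"]].iloc[0]
        raise ValidationError(f"malformed gene interval for {bad['gene']!r}")
    samples = sorted(seg["sample"].unique())
    gene_ids = genes["gene"].tolist()
    out = np.full((len(gene_ids), len(samples)), np.nan)
    # 0-based half-open internally
    g0 = genes["start"].to_numpy(int) - 1
    g1 = genes["end"].to_numpy(int)
    gchrom = genes["chrom"].to_numpy(str)
    for j, sample in enumerate(samples):
        ssub = seg[seg["sample"] == sample]
        by_chrom = {c: t for c, t in ssub.groupby("chrom")}
        for i in range(len(gene_ids)):
            segs = by_chrom.get(gchrom[i])
            if segs is None:
                continue
            s0 = segs["start"].to_numpy(int) - 1
            s1 = segs["end"].to_numpy(int)
            overlap = np.minimum(g1[i], s1) - np.maximum(g0[i], s0)
            hit = overlap > 0
            if not hit.any():
                continue
            w = overlap[hit].astype(float)
            out[i, j] = float(np.average(segs["seg_mean"].to_numpy(float)[hit], weights=w))
    values = pd.DataFrame(out, index=gene_ids, columns=samples)
    return OmicsMatrix(values, "cna")


def _paired_tests(
    cohort: PairedCohort, cfg: ScoringConfig
) -> pd.DataFrame:
    """Per-gene paired signed-rank tests over the cohort's pairs.

    Returns a frame indexed by gene with columns p, effect (mean tumor -
    mean normal over pairs), n_pairs and available.
    """
    tcols = [p[0] for p in cohort.pairs]
    ncols = [p[1] for p in cohort.pairs]
    t = cohort.tumor.values[tcols].to_numpy(float) if tcols else np.empty((len(cohort.tumor.feature_ids), 0))
    n = cohort.normal.values[ncols].to_numpy(float) if ncols else np.empty((len(cohort.normal.feature_ids), 0))
    genes = cohort.tumor.feature_ids
    rows = []
    for i, gene in enumerate(genes):
        tv, nv = t[i], n[i]
        complete = np.isfinite(tv) & np.isfinite(nv)
        if complete.sum() < cfg.min_pairs:
            rows.append((gene, np.nan, np.nan, int(complete.sum()), False))
            continue
        res = stats.wilcoxon_signed_rank(tv[complete], nv[complete])
        effect = float(tv[complete].mean() - nv[complete].mean())
        rows.append((gene, res.p_two_sided, effect, int(complete.sum()), True))
    return pd.DataFrame(
        rows, columns=["gene", "p", "effect", "n_pairs", "available"]
    ).set_index("gene")


def score_expression(cohort: PairedCohort, cfg: ScoringConfig | None = None) -> AberrationCalls:
    """Flag genes differentially expressed between tumors and matched
    normals (paired signed-rank, BH across all tested genes, q < FDR
    threshold).  Higher in tumor -> activating, lower -> inactivating."""
    cfg = cfg or ScoringConfig()
    if cohort.n_pairs == 0:
        return empty_calls("expression", cohort.tumor.feature_ids)
    frame = _paired_tests(cohort, cfg)
    frame["q"] = stats.bh_adjust(frame["p"].to_numpy())
    sig = frame["available"] & (frame["q"] < cfg.fdr_threshold)
    frame["activating"] = sig & (frame["effect"] > 0)
    frame["inactivating"] = sig & (frame["effect"] < 0)
    return AberrationCalls(
        "expression",
        frame[["activating", "inactivating", "available", "p", "q", "effect", "n_pairs"]],
    )


def _tumor_correlations(
    values: pd.DataFrame,
    tumor_expr: OmicsMatrix,
    links: list[tuple[str, str]],
    tumor_samples: list[str],
) -> pd.DataFrame:
    """Spearman correlation of each (feature, gene) link across tumor
    samples carrying both measurements."""
    expr_cols = set(tumor_expr.sample_ids)
    shared = [s for s in tumor_samples if s in expr_cols]
    rows = []
    for feature, gene in links:
        if gene not in tumor_expr.values.index:
            rows.append((feature, gene, np.nan, np.nan, 0, True))
            continue
        x = values.loc[feature, shared].to_numpy(float)
        y = tumor_expr.values.loc[gene, shared].to_numpy(float)
        res = stats.spearman(x, y)
        rows.append((feature, gene, res.rho, res.p_two_sided, res.n, res.degenerate))
    return pd.DataFrame(
        rows, columns=["feature", "gene", "rho", "rho_p", "rho_n", "degenerate"]
    )


def score_copy_number(
    cohort: PairedCohort,
    tumor_expr: OmicsMatrix,
    cfg: ScoringConfig | None = None,
) -> AberrationCalls:
    """Flag copy-number-aberrated genes.

    A gene is called only if (1) its tumor-normal paired signed-rank test
    is significant after BH (q < FDR threshold) with an absolute mean
    log-ratio difference strictly greater than ``min_cn_diff`` and (2) its
    copy number is significantly positively Spearman-correlated with its
    expression across tumor samples (BH over the genes passing stage 1).
    Gain -> activating, loss -> inactivating.  Genes without expression
    data are unavailable (the correlation requirement cannot be met).
    """
    cfg = cfg or ScoringConfig()
    if cohort.n_pairs == 0:
        return empty_calls("cna", cohort.tumor.feature_ids)
    frame = _paired_tests(cohort, cfg)
    frame["q"] = stats.bh_adjust(frame["p"].to_numpy())
    in_expr = frame.index.isin(tumor_expr.values.index)
    frame["available"] = frame["available"] & in_expr
    # round at machine-noise precision so an effect equal to the gate up
    # to float error does not slip past the strict inequality
    stage1 = (
        frame["available"]
        & (frame["q"] < cfg.fdr_threshold)
        & (frame["effect"].abs().round(12) > cfg.min_cn_diff)
    )
    frame["rho"] = np.nan
    frame["rho_q"] = np.nan
    frame["activating"] = False
    frame["inactivating"] = False
    candidates = list(frame.index[stage1])
    if candidates:
        corr = _tumor_correlations(
            cohort.tumor.values,
            tumor_expr,
            [(g, g) for g in candidates],
            cohort.tumor.sample_ids,
        ).set_index("gene")
        corr["rho_q"] = stats.bh_adjust(
            np.where(corr["degenerate"], np.nan, corr["rho_p"])
        )
        frame.loc[candidates, "rho"] = corr["rho"]
        frame.loc[candidates, "rho_q"] = corr["rho_q"]
        passed = (
            ~corr["degenerate"]
            & (corr["rho_q"] < cfg.fdr_threshold)
            & (corr["rho"] > 0)
        )
        ok = corr.index[passed]
        frame.loc[ok, "activating"] = frame.loc[ok, "effect"] > 0
        frame.loc[ok, "inactivating"] = frame.loc[ok, "effect"] < 0
    cols = ["activating", "inactivating", "available", "p", "q", "effect", "rho", "rho_q", "n_pairs"]
    return AberrationCalls("cna", frame[cols])


def score_methylation(
    tumor_meth: OmicsMatrix,
    normal_meth: OmicsMatrix,
    annot: ProbeAnnotation,
    tumor_expr: OmicsMatrix,
    cfg: ScoringConfig | None = None,
    min_group: int = 3,
) -> tuple[AberrationCalls, pd.DataFrame]:
    """Flag methylation-aberrated genes via probe-level evidence.

    Probe stage: unpaired rank-sum tumor vs normal per probe, BH across
    all tested probes; a probe is eligible if q < FDR threshold and its
    absolute mean beta difference is strictly greater than
    ``min_beta_diff``.  Link stage: Spearman correlation of eligible-probe
    beta with the expression of each annotated gene across tumor samples,
    BH across those links; the correlation must be significant (q < FDR
    threshold).  A gene is flagged

    * inactivating if >= 1 probe is (gene body, lower in tumors, positive
      correlation) or (other region, higher in tumors, negative
      correlation);
    * activating if >= 1 probe is (gene body, higher in tumors, positive
      correlation) or (other region, lower in tumors, negative
      correlation).

    Both flags may co-occur.  Returns the gene-level calls and the
    per-link diagnostics table.
    """
    cfg = cfg or ScoringConfig()
    probes = [p for p in tumor_meth.feature_ids if p in set(normal_meth.feature_ids)]
    annotated = set(annot.records["probe_id"])
    probes = [p for p in probes if p in annotated]
    tvals = tumor_meth.values
    nvals = normal_meth.values
    rows = []
    for probe in probes:
        tv = tvals.loc[probe].to_numpy(float)
        nv = nvals.loc[probe].to_numpy(float)
        tv = tv[np.isfinite(tv)]
        nv = nv[np.isfinite(nv)]
        if tv.size < min_group or nv.size < min_group:
            rows.append((probe, np.nan, np.nan, False))
            continue
        res = stats.wilcoxon_rank_sum(tv, nv)
        rows.append((probe, res.p_two_sided, float(tv.mean() - nv.mean()), True))
    probe_frame = pd.DataFrame(
        rows, columns=["probe_id", "p", "beta_diff", "tested"]
    ).set_index("probe_id")
    genes = sorted(set(annot.records["gene"]))
    if not len(probe_frame):
        return empty_calls("methylation", genes), pd.DataFrame(
            columns=["probe_id", "gene", "region", "p", "q", "beta_diff",
                     "rho", "rho_q", "og_hit", "ts_hit"]
        )
    probe_frame["q"] = stats.bh_adjust(probe_frame["p"].to_numpy())
    eligible = (
        probe_frame["tested"]
        & (probe_frame["q"] < cfg.fdr_threshold)
        & (probe_frame["beta_diff"].abs().round(12) > cfg.min_beta_diff)
    )
    links_df = annot.records[annot.records["probe_id"].isin(probe_frame.index[eligible])]
    links_df = links_df[links_df["gene"].isin(tumor_expr.values.index)]
    link_rows = _tumor_correlations(
        tvals,
        tumor_expr,
        list(zip(links_df["probe_id"], links_df["gene"])),
        tumor_meth.sample_ids,
    )
    link_rows["region"] = links_df["region"].to_numpy() if len(links_df) else []
    if len(link_rows):
        link_rows["rho_q"] = stats.bh_adjust(
            np.where(link_rows["degenerate"], np.nan, link_rows["rho_p"])
        )
        link_rows = link_rows.merge(
            probe_frame[["p", "q", "beta_diff"]],
            left_on="feature",
            right_index=True,
        )
        corr_sig = ~link_rows["degenerate"] & (link_rows["rho_q"] < cfg.fdr_threshold)
        body = link_rows["region"] == "body"
        higher = link_rows["beta_diff"] > 0
        pos = link_rows["rho"] > 0
        link_rows["og_hit"] = corr_sig & (
            (body & higher & pos) | (~body & ~higher & ~pos)
        )
        link_rows["ts_hit"] = corr_sig & (
            (body & ~higher & pos) | (~body & higher & ~pos)
        )
    else:
        link_rows = pd.DataFrame(
            columns=["feature", "gene", "rho", "rho_p", "rho_n", "degenerate",
                     "region", "rho_q", "p", "q", "beta_diff", "og_hit", "ts_hit"]
        )
    # gene availability: at least one tested probe link with expression data
    tested_links = annot.records[
        annot.records["probe_id"].isin(probe_frame.index[probe_frame["tested"]])
    ]
    tested_links = tested_links[tested_links["gene"].isin(tumor_expr.values.index)]
    available_genes = set(tested_links["gene"])
    frame = pd.DataFrame(
        {
            "activating": False,
            "inactivating": False,
            "available": [g in available_genes for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    if len(link_rows):
        og_genes = set(link_rows.loc[link_rows["og_hit"], "gene"])
        ts_genes = set(link_rows.loc[link_rows["ts_hit"], "gene"])
        frame["activating"] = [g in og_genes for g in genes]
        frame["inactivating"] = [g in ts_genes for g in genes]
    diag_cols = ["probe_id", "gene", "region", "p", "q", "beta_diff",
                 "rho", "rho_q", "og_hit", "ts_hit"]
    diagnostics = link_rows.rename(columns={"feature": "probe_id"}).reindex(
        columns=diag_cols
    )
    return AberrationCalls("methylation", frame), diagnostics
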