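"""Fuse per-data-type calls into gene score cards and derived summaries.

Per gene and cancer type the oncogene score is the number of data types
with an activating aberration and the tumor suppressor score the number
with an inactivating aberration (each data type contributes at most +1 per
direction).  The overall score is their difference (positive = oncogene-
like) and the aberration score their sum (direction-blind).  On top of the
cards: rankings, dual-role gene detection across cancer types, pathway
mean scores, affected-sample fractions and tumor-vs-cell-line pathway
correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    DATA_TYPES,
    AberrationCalls,
    OmicsMatrix,
    PathwayCollection,
    ValidationError,
)


def combine_scores(
    calls: list[AberrationCalls],
    cancer_type: str,
    genes=None,
) -> pd.DataFrame:
    """Combine call sets (at most one per data type) into score cards.

    Returns a frame with one row per gene: the four scores, the data-
    availability count and per-data-type flag columns.  ``genes`` fixes
    the gene universe; by default it is the union of all call sets.
    Unavailable data types contribute nothing and do not count towards
    ``n_data_types_available``.
    """
    tags = [c.tag for c in calls]
    if len(set(tags)) != len(tags):
        dup = sorted({t for t in tags if tags.count(t) > 1})
        raise ValidationError(f"duplicate call set for data type(s): {dup}")
    if genes is None:
        universe: list[str] = sorted(set().union(*[set(c.frame.index) for c in calls])) if calls else []
    else:
        universe = list(genes)
    cards = pd.DataFrame({"gene": universe, "cancer_type": cancer_type})
    og = np.zeros(len(universe), dtype=int)
    ts = np.zeros(len(universe), dtype=int)
    n_avail = np.zeros(len(universe), dtype=int)
    for tag in DATA_TYPES:
        matching = [c for c in calls if c.tag == tag]
        if not matching:
            continue
        frame = matching[0].frame.reindex(universe)

        def _flags(col: str) -> np.ndarray:
            raw = frame[col].to_numpy(dtype=object)
            return np.array([bool(v) if not pd.isna(v) else False for v in raw])

        act = _flags("activating")
        inact = _flags("inactivating")
        avail = _flags("available")
        og += act
        ts += inact
        n_avail += avail
        cards[f"{tag}_activating"] = act
        cards[f"{tag}_inactivating"] = inact
        cards[f"{tag}_available"] = avail
    cards.insert(2, "og_score", og)
    cards.insert(3, "ts_score", ts)
    cards.insert(4, "overall_score", og - ts)
    cards.insert(5, "aberration_score", og + ts)
    cards.insert(6, "n_data_types_available", n_avail)
    check_score_identities(cards)
    return cards


def check_score_identities(cards: pd.DataFrame) -> None:
    """Assert the structural score identities on a card table."""
    og = cards["og_score"].to_numpy()
    ts = cards["ts_score"].to_numpy()
    if not np.array_equal(cards["overall_score"].to_numpy(), og - ts):
        raise ValidationError("overall_score != og_score - ts_score")
    if not np.array_equal(cards["aberration_score"].to_numpy(), og + ts):
        raise ValidationError("aberration_score != og_score + ts_score")
    if (og < 0).any() or (ts < 0).any():
        raise ValidationError("negative directional score")
    n_avail = cards["n_data_types_available"].to_numpy()
    if (og > n_avail).any() or (ts > n_avail).any():
        raise ValidationError("directional score exceeds available data types")


_RANK_KEYS = {
    "og": "og_score",
    "ts": "ts_score",
    "overall": "overall_score",
    "aberration": "aberration_score",
}


def rank_genes(cards: pd.DataFrame, by: str = "aberration", descending: bool = True) -> list[str]:
    """Order genes by one of the four scores; ties break alphabetically."""
    if by not in _RANK_KEYS:
        raise ValidationError(f"rank key must be one of {sorted(_RANK_KEYS)}")
    col = _RANK_KEYS[by]
    ordered = cards.sort_values(
        [col, "gene"], ascending=[not descending, True], kind="stable"
    )
    return ordered["gene"].tolist()


def dual_role_genes(cards: pd.DataFrame, min_data_types: int = 2) -> list[str]:
    """Genes scoring oncogene-like in one cancer type and tumor-
    suppressor-like in a *different* one, each backed by at least
    ``min_data_types`` data types."""
    out = []
    for gene, grp in cards.groupby("gene", sort=True):
        og_types = set(grp.loc[grp["og_score"] >= min_data_types, "cancer_type"])
        ts_types = set(grp.loc[grp["ts_score"] >= min_data_types, "cancer_type"])
        if not og_types or not ts_types:
            continue
        # need an oncogene-like cancer type different from a tumor-
        # suppressor-like one
        if len(og_types | ts_types) >= 2:
            out.append(gene)
    return out


def pathway_scores(cards: pd.DataFrame, pathways: PathwayCollection) -> pd.DataFrame:
    """Mean overall score per pathway over member genes present in the
    scored universe; absent genes are excluded and counted."""
    overall = cards.set_index("gene")["overall_score"]
    rows = []
    for pid in sorted(pathways.gene_sets):
        members = pathways.gene_sets[pid]
        present = [g for g in members if g in overall.index]
        mean = float(overall.loc[present].mean()) if present else np.nan
        rows.append(
            {
                "pathway_id": pid,
                "mean_overall": mean,
                "n_genes_scored": len(present),
                "n_missing": len(members) - len(present),
            }
        )
    return pd.DataFrame(rows)


def affected_fractions(
    tumor: OmicsMatrix,
    normal: OmicsMatrix,
    pairs: list[tuple[str, str, str]] | None = None,
) -> pd.DataFrame:
    """Per gene, the fraction of tumor samples affected up or down.

    Paired mode (``pairs`` given): the difference vector is tumor minus
    matched normal.  Unpaired mode: tumor minus the mean over all normal
    samples.  A sample is affected if its difference lies strictly more
    than one sample standard deviation (n-1 denominator) from the mean of
    the difference distribution.
    """
    genes = tumor.feature_ids
    rows = []
    for gene in genes:
        if pairs is not None:
            t = tumor.values.loc[gene, [p[0] for p in pairs]].to_numpy(float)
            n = normal.values.loc[gene, [p[1] for p in pairs]].to_numpy(float)
            keep = np.isfinite(t) & np.isfinite(n)
            d = t[keep] - n[keep]
        else:
            t = tumor.values.loc[gene].to_numpy(float)
            t = t[np.isfinite(t)]
            if gene in normal.values.index:
                nvals = normal.values.loc[gene].to_numpy(float)
                nvals = nvals[np.isfinite(nvals)]
            else:
                nvals = np.array([])
            if nvals.size == 0:
                rows.append({"gene": gene, "frac_up": np.nan, "frac_down": np.nan, "n": 0})
                continue
            d = t - nvals.mean()
        if d.size < 2:
            rows.append({"gene": gene, "frac_up": np.nan, "frac_down": np.nan, "n": int(d.size)})
            continue
        mu = d.mean()
        sd = d.std(ddof=1)
        if sd == 0:
            frac_up = frac_down = 0.0
        else:
            frac_up = float(np.mean(d - mu > sd))
            frac_down = float(np.mean(d - mu < -sd))
        rows.append({"gene": gene, "frac_up": frac_up, "frac_down": frac_down, "n": int(d.size)})
    return pd.DataFrame(rows)


def compare_cohorts(
    pathway_scores_a: pd.DataFrame, pathway_scores_b: pd.DataFrame
) -> float:
    """Pearson correlation of two pathway-score tables over shared,
    non-missing pathways (e.g. tumor cohort vs cell-line panel)."""
    a = pathway_scores_a.set_index("pathway_id")["mean_overall"]
    b = pathway_scores_b.set_index("pathway_id")["mean_overall"]
    joined = pd.concat([a, b], axis=1, join="inner", keys=["a", "b"]).dropna()
    if len(joined) < 3:
        raise ValidationError(
            f"need >= 3 shared pathways with scores, got {len(joined)}"
        )
    return float(np.corrcoef(joined["a"], joined["b"])[0, 1])
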