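"""Somatic-mutation scoring after the 20/20 rule.

Mutations are split into oncogene-class (missense, in-frame indels) and
tumor-suppressor-class (frameshift indels, nonsense, splice site); anything
else (e.g. silent) stays in the denominator only.  Per gene:

    OGMR = 1 - (# distinct oncogene-class mutations) / (# total mutations)
    TSMR = (# distinct tumor-suppressor-class mutations) / (# total mutations)

A recurrently hit site keeps OGMR high (few distinct changes among many
records); broadly scattered truncating mutations push TSMR up.  A gene is
called activating if OGMR > 0.2 and TSMR < 0.05, inactivating if
TSMR > 0.2 or (OGMR > 0.2 and TSMR > 0.05); each call additionally
requires at least five mutations of the corresponding class.  All
inequalities are strict, which makes the two flags mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .types import AberrationCalls, MutationTable

OG_CLASSES = frozenset({"missense", "in_frame_ins", "in_frame_del"})
TS_CLASSES = frozenset({"frame_shift_ins", "frame_shift_del", "nonsense", "splice_site"})

OGMR_THRESHOLD = 0.2
TSMR_UPPER = 0.2
TSMR_LOWER = 0.05


def classify_mutation(variant_class: str) -> str:
    """Map a variant class onto {oncogene, tumor_suppressor, other}."""
    if variant_class in OG_CLASSES:
        return "oncogene"
    if variant_class in TS_CLASSES:
        return "tumor_suppressor"
    return "other"


@dataclass(frozen=True)
class MutationRates:
    gene: str
    n_total: int
    n_og: int
    n_ts: int
    n_og_distinct: int
    n_ts_distinct: int
    ogmr: float
    tsmr: float


def mutation_rates(records: pd.DataFrame) -> MutationRates:
    """Compute per-gene mutation counts and the OGMR/TSMR rates.

    ``records`` holds all mutation records of one gene.  Distinct identity
    is the genomic change (chrom, pos, ref, alt, variant_class); the
    denominator counts every record, including other-class mutations.
    """
    if len(records) == 0:
        raise ValueError("mutation_rates requires at least one record")
    genes = records["gene"].unique()
    if len(genes) != 1:
        raise ValueError(f"records span several genes: {sorted(genes)}")
    cls = records["variant_class"].map(classify_mutation)
    identity = ["chrom", "pos", "ref", "alt", "variant_class"]
    n_total = len(records)
    og = records[cls == "oncogene"]
    ts = records[cls == "tumor_suppressor"]
    n_og_distinct = len(og.drop_duplicates(identity))
    n_ts_distinct = len(ts.drop_duplicates(identity))
    return MutationRates(
        gene=str(genes[0]),
        n_total=n_total,
        n_og=len(og),
        n_ts=len(ts),
        n_og_distinct=n_og_distinct,
        n_ts_distinct=n_ts_distinct,
        ogmr=1.0 - n_og_distinct / n_total,
        tsmr=n_ts_distinct / n_total,
    )


def score_mutations(
    table: MutationTable, min_class_count: int = 5
) -> tuple[AberrationCalls, pd.DataFrame]:
    """Apply the 20/20-rule thresholds per gene.

    Returns the call set and a per-gene rates table (counts, OGMR, TSMR,
    flags).  Genes absent from the table are simply not listed
    (unavailable downstream).
    """
    rows = []
    for gene, grp in table.records.groupby("gene", sort=True):
        r = mutation_rates(grp)
        activating = (
            r.ogmr > OGMR_THRESHOLD
            and r.tsmr < TSMR_LOWER
            and r.n_og >= min_class_count
        )
        inactivating = (
            r.tsmr > TSMR_UPPER
            or (r.ogmr > OGMR_THRESHOLD and r.tsmr > TSMR_LOWER)
        ) and r.n_ts >= min_class_count
        rows.append(
            {
                "gene": gene,
                "n_total": r.n_total,
                "n_og": r.n_og,
                "n_ts": r.n_ts,
                "n_og_distinct": r.n_og_distinct,
                "n_ts_distinct": r.n_ts_distinct,
                "ogmr": r.ogmr,
                "tsmr": r.tsmr,
                "activating": activating,
                "inactivating": inactivating,
            }
        )
    rates = pd.DataFrame(
        rows,
        columns=[
            "gene", "n_total", "n_og", "n_ts", "n_og_distinct",
            "n_ts_distinct", "ogmr", "tsmr", "activating", "inactivating",
        ],
    )
    frame = rates.set_index("gene")[
        ["activating", "inactivating", "ogmr", "tsmr", "n_og", "n_ts"]
    ].copy()
    frame.insert(2, "available", True)
    return AberrationCalls("mutation", frame), rates
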