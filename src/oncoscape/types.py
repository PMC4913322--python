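"""Core domain types for multi-omics gene prioritization.

The central containers are :class:`OmicsMatrix` (one feature x sample
measurement matrix per data type), :class:`SampleMap` (patient/sample/
cancer-type bookkeeping), :class:`MutationTable` (somatic mutation records),
:class:`AberrationCalls` (per-data-type activating/inactivating flags) and
the per-gene score cards produced by aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Recognised data-type tags for OmicsMatrix.
MATRIX_TAGS = ("expression", "cna", "methylation", "shrna")

#: Data types that can contribute to gene scores (at most one call set each).
DATA_TYPES = ("expression", "cna", "methylation", "mutation", "shrna")

#: Closed vocabulary of sample classes.
SAMPLE_CLASSES = ("tumor_primary", "tumor_recurrent_or_met", "normal")

#: Closed vocabulary of mutation variant classes.
VARIANT_CLASSES = (
    "missense",
    "in_frame_ins",
    "in_frame_del",
    "frame_shift_ins",
    "frame_shift_del",
    "nonsense",
    "splice_site",
    "other",
)

#: Closed vocabulary of methylation probe regions.
PROBE_REGIONS = ("body", "other")

#: Data types whose activating/inactivating flags are mutually exclusive.
EXCLUSIVE_FLAG_TAGS = ("expression", "cna", "mutation")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_unique(values, what: str) -> None:
    s = pd.Index(values)
    if s.has_duplicates:
        dup = s[s.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {', '.join(map(str, dup[:5]))}")


@dataclass
class OmicsMatrix:
    """A feature x sample numeric matrix carrying a data-type tag.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are features (gene symbols or probe ids), columns are sample
        ids.  Units depend on ``tag``: log2 expression, copy-number
        log-ratio, methylation beta in [0, 1], or shRNA viability score.
        Missing values are NaN.
    tag : str
        One of ``expression``, ``cna``, ``methylation``, ``shrna``.
    """

    values: pd.DataFrame
    tag: str

    def __post_init__(self) -> None:
        if self.tag not in MATRIX_TAGS:
            raise ValidationError(
                f"unknown matrix tag {self.tag!r}; expected one of {MATRIX_TAGS}"
            )
        _check_unique(self.values.index, "feature id")
        _check_unique(self.values.columns, "sample id")
        vals = self.values.to_numpy(dtype=float)
        if self.tag == "methylation":
            bad = np.where((vals < 0) | (vals > 1))
            if bad[0].size:
                r, c = bad[0][0], bad[1][0]
                raise ValidationError(
                    "methylation beta value outside [0, 1] at "
                    f"feature {self.values.index[r]!r}, sample "
                    f"{self.values.columns[c]!r}: {vals[r, c]}"
                )
        # normalise dtype so downstream arithmetic never sees object columns
        self.values = self.values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        """Return a new matrix restricted to ``sample_ids`` (order kept)."""
        keep = [s for s in sample_ids if s in self.values.columns]
        return OmicsMatrix(self.values.loc[:, keep], self.tag)

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        keep = [f for f in feature_ids if f in self.values.index]
        return OmicsMatrix(self.values.loc[keep, :], self.tag)


@dataclass
class SampleMap:
    """Patient <-> sample links with sample class and cancer type.

    ``records`` has columns ``patient_id``, ``sample_id``, ``sample_class``
    and ``cancer_type``.  ``deduplicated`` marks that the per-patient
    deduplication rules have been applied; downstream scoring requires it.
    """

    records: pd.DataFrame
    deduplicated: bool = False

    def __post_init__(self) -> None:
        required = ["patient_id", "sample_id", "sample_class", "cancer_type"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValidationError(f"sample map missing columns: {missing}")
        self.records = self.records[required].reset_index(drop=True)
        _check_unique(self.records["sample_id"], "sample_id")
        bad = set(self.records["sample_class"]) - set(SAMPLE_CLASSES)
        if bad:
            raise ValidationError(
                f"unknown sample_class {sorted(bad)}; expected one of {SAMPLE_CLASSES}"
            )
        if self.deduplicated:
            prim = self.records[self.records["sample_class"] == "tumor_primary"]
            if prim["patient_id"].duplicated().any():
                raise ValidationError(">1 primary sample per patient after dedup")
            if (self.records["sample_class"] == "tumor_recurrent_or_met").any():
                raise ValidationError("recurrent/metastatic samples after dedup")

    def __len__(self) -> int:
        return len(self.records)

    def deduplicate(self) -> "SampleMap":
        """Apply the per-patient sample retention rules.

        Recurrent/metastatic samples are dropped (only primary samples are
        analysed).  Patients with two or more primary samples are removed
        entirely, including their normal samples.  Idempotent.
        """
        rec = self.records
        prim = rec[rec["sample_class"] == "tumor_primary"]
        counts = prim["patient_id"].value_counts()
        multi = set(counts[counts >= 2].index)
        keep = (~rec["patient_id"].isin(multi)) & (
            rec["sample_class"] != "tumor_recurrent_or_met"
        )
        return SampleMap(rec[keep].reset_index(drop=True), deduplicated=True)

    def subset_cancer_type(self, cancer_type: str) -> "SampleMap":
        rec = self.records[self.records["cancer_type"] == cancer_type]
        return SampleMap(rec.reset_index(drop=True), deduplicated=self.deduplicated)

    def samples_of_class(self, sample_class: str) -> list[str]:
        if sample_class not in SAMPLE_CLASSES:
            raise ValidationError(f"unknown sample_class {sample_class!r}")
        rec = self.records
        return rec.loc[rec["sample_class"] == sample_class, "sample_id"].tolist()

    @property
    def cancer_types(self) -> list[str]:
        return sorted(self.records["cancer_type"].unique())


@dataclass
class MutationTable:
    """Per-mutation records: gene, sample, variant class, genomic identity.

    ``records`` has columns ``gene``, ``sample_id``, ``variant_class``,
    ``chrom``, ``pos`` (1-based), ``ref``, ``alt``.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene", "sample_id", "variant_class", "chrom", "pos", "ref", "alt"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValidationError(f"mutation table missing columns: {missing}")
        self.records = self.records[required].reset_index(drop=True)
        bad = set(self.records["variant_class"]) - set(VARIANT_CLASSES)
        if bad:
            raise ValidationError(
                f"unknown variant_class {sorted(bad)}; expected one of {VARIANT_CLASSES}"
            )
        if len(self.records) and (self.records["pos"].astype(int) < 1).any():
            raise ValidationError("mutation position must be >= 1 (1-based)")
        self.records["pos"] = self.records["pos"].astype(int)

    def __len__(self) -> int:
        return len(self.records)

    def subset_samples(self, sample_ids) -> "MutationTable":
        keep = self.records["sample_id"].isin(set(sample_ids))
        return MutationTable(self.records[keep].reset_index(drop=True))

    @property
    def genes(self) -> list[str]:
        return sorted(self.records["gene"].unique())


@dataclass
class ProbeAnnotation:
    """Methylation probe -> gene links with a binary region label.

    One row per (probe, gene) link; ``region`` is ``body`` for probes in
    the transcribed gene body and ``other`` for every other context
    (promoter, UTR, ...).  A probe annotated to several genes contributes
    one row per gene.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["probe_id", "gene", "region"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValidationError(f"probe annotation missing columns: {missing}")
        self.records = self.records[required].reset_index(drop=True)
        if self.records.duplicated(["probe_id", "gene"]).any():
            dup = self.records[self.records.duplicated(["probe_id", "gene"])]
            raise ValidationError(
                f"duplicate (probe_id, gene) pair: {dup.iloc[0].tolist()[:2]}"
            )
        bad = set(self.records["region"]) - set(PROBE_REGIONS)
        if bad:
            raise ValidationError(
                f"unknown probe region {sorted(bad)}; expected one of {PROBE_REGIONS}"
            )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PathwayCollection:
    """Named gene sets (pathway id -> set of gene symbols)."""

    gene_sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, genes in self.gene_sets.items():
            if not genes:
                raise ValidationError(f"pathway {pid!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.gene_sets)

    def __getitem__(self, pid: str) -> set[str]:
        return self.gene_sets[pid]


# columns every AberrationCalls frame carries; extra stat columns are free-form
CALL_COLUMNS = ("activating", "inactivating", "available")


@dataclass
class AberrationCalls:
    """Per-gene activating/inactivating flags for one data type.

    ``frame`` is indexed by gene symbol and carries boolean columns
    ``activating``, ``inactivating``, ``available`` plus any supporting
    statistics (``p``, ``q``, ``effect``, ``rho`` ... as applicable).
    Genes that were not evaluable keep ``available=False`` and both flags
    False.  For expression, copy-number and mutation calls the two flags
    are mutually exclusive; methylation and shRNA calls may set both.
    """

    tag: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.tag not in DATA_TYPES:
            raise ValidationError(f"unknown data type tag {self.tag!r}")
        for col in CALL_COLUMNS:
            if col not in self.frame.columns:
                raise ValidationError(f"call frame missing column {col!r}")
        _check_unique(self.frame.index, "gene")
        f = self.frame
        unavailable = ~f["available"].astype(bool)
        if (f.loc[unavailable, ["activating", "inactivating"]].to_numpy()).any():
            raise ValidationError(f"{self.tag}: flags set on unavailable gene")
        if self.tag in EXCLUSIVE_FLAG_TAGS:
            both = f["activating"].astype(bool) & f["inactivating"].astype(bool)
            if both.any():
                raise ValidationError(
                    f"{self.tag}: activating and inactivating both set for "
                    f"{f.index[both][0]!r}"
                )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def activating_genes(self) -> list[str]:
        return list(self.frame.index[self.frame["activating"].astype(bool)])

    @property
    def inactivating_genes(self) -> list[str]:
        return list(self.frame.index[self.frame["inactivating"].astype(bool)])


def empty_calls(tag: str, genes=()) -> AberrationCalls:
    """All-unavailable call set for ``genes`` under data type ``tag``."""
    frame = pd.DataFrame(
        {
            "activating": False,
            "inactivating": False,
            "available": False,
        },
        index=pd.Index(genes, name="gene"),
    )
    return AberrationCalls(tag, frame)


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds shared by the per-data-type scorers.

    fdr_threshold
        BH-adjusted significance cut-off for every test stage (default 0.05).
    min_cn_diff
        Minimum absolute tumor-normal mean copy-number log-ratio difference
        (strict, default 0.1) required for a copy-number call.
    min_beta_diff
        Minimum absolute tumor-normal mean methylation beta difference
        (strict, default 0.1) required for a probe to be eligible.
    min_pairs
        Minimum number of complete tumor-normal pairs for a paired test.
    min_mutation_count
        Minimum number of oncogene- resp. tumor-suppressor-class mutations
        required to call a gene from mutation data.
    shrna_fraction
        Fraction of a cancer type's cell lines that must lie beyond the
        global quartiles for an shRNA call (inclusive, default 0.25).
    """

    fdr_threshold: float = 0.05
    min_cn_diff: float = 0.1
    min_beta_diff: float = 0.1
    min_pairs: int = 3
    min_mutation_count: int = 5
    shrna_fraction: float = 0.25

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "min_cn_diff", "min_beta_diff", "shrna_fraction"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def replace(self, **kwargs) -> "ScoringConfig":
        return replace(self, **kwargs)
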