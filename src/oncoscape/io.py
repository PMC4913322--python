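"""Readers and writers for the plain-text exchange formats.

All files are UTF-8, tab-delimited, LF line endings.  Matrices have feature
ids in the first column and sample ids in the header row; ``NA`` or empty
cells are missing.  Mutation input is the standard MAF column subset,
segmented copy number the SEG format, gene sets the GMT format.
"""

from __future__ import annotations

import pandas as pd

from .types import (
    MutationTable,
    OmicsMatrix,
    PathwayCollection,
    ProbeAnnotation,
    SampleMap,
    ValidationError,
)

_NA = ["", "NA", "NaN", "nan"]

# MAF Variant_Classification -> closed vocabulary; anything unmapped -> other
MAF_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "In_Frame_Ins": "in_frame_ins",
    "In_Frame_Del": "in_frame_del",
    "Frame_Shift_Ins": "frame_shift_ins",
    "Frame_Shift_Del": "frame_shift_del",
    "Nonsense_Mutation": "nonsense",
    "Splice_Site": "splice_site",
}

MAF_COLUMNS = [
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
]


def read_matrix(path, tag: str, sep: str = "\t") -> OmicsMatrix:
    """Read a feature x sample TSV into a validated :class:`OmicsMatrix`."""
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=_NA, keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return OmicsMatrix(df.astype(float), tag)
    except ValueError as exc:
        if isinstance(exc, ValidationError):
            raise
        raise ValidationError(f"non-numeric value in matrix {path}: {exc}") from exc


def write_matrix(path, matrix: OmicsMatrix, sep: str = "\t") -> None:
    matrix.values.to_csv(path, sep=sep, na_rep="NA", lineterminator="\n")


def read_sample_map(path, sep: str = "\t") -> SampleMap:
    """Read a patient/sample/class/cancer-type TSV (pre-deduplication)."""
    df = pd.read_csv(path, sep=sep, dtype=str, na_values=_NA, keep_default_na=False)
    return SampleMap(df)


def write_sample_map(path, smap: SampleMap, sep: str = "\t") -> None:
    smap.records.to_csv(path, sep=sep, index=False, lineterminator="\n")


def read_mutations(path, sep: str = "\t") -> MutationTable:
    """Read the MAF column subset, mapping variant classes onto the
    closed vocabulary (unmapped classes such as ``Silent`` become
    ``other``)."""
    df = pd.read_csv(path, sep=sep, dtype=str, na_values=_NA, keep_default_na=False)
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"MAF file {path} missing required columns: {missing}")
    out = pd.DataFrame(
        {
            "gene": df["Hugo_Symbol"],
            "sample_id": df["Tumor_Sample_Barcode"],
            "variant_class": df["Variant_Classification"]
            .map(MAF_CLASS_MAP)
            .fillna("other"),
            "chrom": df["Chromosome"],
            "pos": df["Start_Position"].astype(int),
            "ref": df["Reference_Allele"],
            "alt": df["Tumor_Seq_Allele2"],
        }
    )
    return MutationTable(out)


def write_mutations(path, table: MutationTable, sep: str = "\t") -> None:
    inv = {v: k for k, v in MAF_CLASS_MAP.items()}
    rec = table.records
    out = pd.DataFrame(
        {
            "Hugo_Symbol": rec["gene"],
            "Tumor_Sample_Barcode": rec["sample_id"],
            "Variant_Classification": rec["variant_class"].map(
                lambda c: inv.get(c, "Silent")
            ),
            "Chromosome": rec["chrom"],
            "Start_Position": rec["pos"],
            "Reference_Allele": rec["ref"],
            "Tumor_Seq_Allele2": rec["alt"],
        }
    )
    out.to_csv(path, sep=sep, index=False, lineterminator="\n")


def read_seg(path, sep: str = "\t") -> pd.DataFrame:
    """Read segmented copy number (SEG): sample, chrom, start, end,
    optional num_mark, seg_mean.  Coordinates are 1-based inclusive."""
    df = pd.read_csv(path, sep=sep, na_values=_NA, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    required = ["sample", "chrom", "start", "end", "seg_mean"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValidationError(f"SEG file {path} missing columns: {missing}")
    out = pd.DataFrame(
        {
            "sample": df[cols["sample"]].astype(str),
            "chrom": df[cols["chrom"]].astype(str),
            "start": df[cols["start"]].astype(int),
            "end": df[cols["end"]].astype(int),
            "seg_mean": df[cols["seg_mean"]].astype(float),
        }
    )
    if (out["end"] < out["start"]).any():
        bad = out[out["end"] < out["start"]].iloc[0]
        raise ValidationError(
            f"malformed SEG interval (end < start): {bad['sample']} "
            f"{bad['chrom']}:{bad['start']}-{bad['end']}"
        )
    return out


def read_gene_intervals(path, sep: str = "\t") -> pd.DataFrame:
    """Read gene intervals TSV with columns gene, chrom, start, end
    (1-based inclusive)."""
    df = pd.read_csv(path, sep=sep, na_values=_NA, keep_default_na=False)
    missing = [c for c in ["gene", "chrom", "start", "end"] if c not in df.columns]
    if missing:
        raise ValidationError(f"gene interval file {path} missing columns: {missing}")
    df = df.copy()
    df["gene"] = df["gene"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df[["start", "end"]] = df[["start", "end"]].astype(int)
    if (df["end"] <= df["start"] - 1).any():
        raise ValidationError("malformed gene interval (end < start)")
    return df


def read_gmt(path) -> PathwayCollection:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    gene_sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"GMT line {lineno}: expected name, description and >=1 gene"
                )
            name, desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise ValidationError(f"GMT line {lineno}: empty gene set {name!r}")
            if name in gene_sets:
                raise ValidationError(f"GMT line {lineno}: duplicate pathway {name!r}")
            gene_sets[name] = set(genes)
            descriptions[name] = desc
    return PathwayCollection(gene_sets, descriptions)


def write_gmt(path, pathways: PathwayCollection) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for pid, genes in pathways.gene_sets.items():
            desc = pathways.descriptions.get(pid, "")
            fh.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


# Illumina region contexts collapse onto the binary body/other vocabulary:
# only gene-body probes behave distinctly in the scoring rules.
REGION_MAP = {
    "body": "body",
    "other": "other",
    "tss200": "other",
    "tss1500": "other",
    "5'utr": "other",
    "3'utr": "other",
    "1stexon": "other",
    "exonbnd": "other",
    "igr": "other",
}


def read_probe_annotation(path, sep: str = "\t") -> ProbeAnnotation:
    df = pd.read_csv(path, sep=sep, dtype=str, na_values=_NA, keep_default_na=False)
    if "region" in df.columns:
        df = df.copy()
        mapped = df["region"].str.lower().map(REGION_MAP)
        if mapped.isna().any():
            bad = df.loc[mapped.isna(), "region"].iloc[0]
            raise ValidationError(f"unknown probe region token {bad!r}")
        df["region"] = mapped
    return ProbeAnnotation(df)


def write_probe_annotation(path, annot: ProbeAnnotation, sep: str = "\t") -> None:
    annot.records.to_csv(path, sep=sep, index=False, lineterminator="\n")


SCORE_COLUMNS = [
    "gene",
    "cancer_type",
    "og_score",
    "ts_score",
    "overall_score",
    "aberration_score",
    "n_data_types_available",
]


def write_scores(path, cards: pd.DataFrame, sep: str = "\t") -> None:
    """Write a gene score table (one row per gene x cancer type) with the
    four scores and the per-data-type flag columns."""
    missing = [c for c in SCORE_COLUMNS if c not in cards.columns]
    if missing:
        raise ValidationError(f"score table missing columns: {missing}")
    flag_cols = [c for c in cards.columns if c not in SCORE_COLUMNS]
    cards[SCORE_COLUMNS + flag_cols].to_csv(
        path, sep=sep, index=False, na_rep="NA", lineterminator="\n"
    )


def read_scores(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, na_values=_NA, keep_default_na=False)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"score table {path} missing columns: {missing}")
    for col in SCORE_COLUMNS[2:]:
        df[col] = df[col].astype(int)
    for col in df.columns:
        if col not in SCORE_COLUMNS and col.endswith(
            ("_activating", "_inactivating", "_available")
        ):
            df[col] = df[col].astype(bool)
    return df
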