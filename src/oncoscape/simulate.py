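"""Seeded synthetic multi-omics cohorts with planted driver genes.

:func:`generate_cohort` builds a complete cohort — expression, copy-number,
methylation, mutation and optionally shRNA data plus sample map, probe
annotation and a truth table — in which a chosen number of genes carry
oncogene- or tumor-suppressor-style aberrations and the rest are
exchangeable noise.  Planted oncogenes are up-regulated, gained in copy
number (with the gain coupled to expression through a shared per-sample
dosage latent), hypermethylated at a gene-body probe (again coupled to
expression), recurrently hit by missense mutations at a single site, and,
if the screen is enabled, strongly depleted on knock-down in the target
cancer type's cell lines.  Tumor suppressors carry the mirrored effects
(body-probe hypomethylation with positive expression coupling, distinct
truncating mutations, viability gain on knock-down).

:func:`boundary_fixture` emits the small deterministic inputs that probe
each decision threshold of the scoring rules exactly.

All randomness flows from the single integer ``seed`` of the
:class:`CohortSpec` through one :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as osio
from .shrna import ShrnaScreen
from .types import (
    MutationTable,
    OmicsMatrix,
    ProbeAnnotation,
    SampleMap,
    ValidationError,
)


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Effect sizes are deliberately large by default (an expression shift of
    two noise SDs, a 0.4 copy-number log-ratio gain/loss against 0.05
    noise, a 0.25 beta shift, eight recurrent missense or six distinct
    truncating mutations) so that planted drivers sit far from every
    decision threshold; the nulls calibrate the false-positive side.
    """

    n_genes: int = 1000
    n_pairs: int = 50
    n_extra_tumors: int = 0
    n_probes_per_gene: int = 2
    n_oncogenes: int = 20
    n_tumor_suppressors: int = 20
    cancer_type: str = "SYNTH"
    data_types: tuple[str, ...] = ("expression", "cna", "methylation", "mutation")
    # expression
    expr_shift: float = 2.0  # in units of expr_noise_sd
    expr_noise_sd: float = 1.0
    dosage_weight: float = 1.0  # shared latent -> expression
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 2.0
    # copy number
    cn_shift: float = 0.4
    cn_noise_sd: float = 0.05
    cn_dosage_weight: float = 0.15
    # methylation
    beta_shift: float = 0.25
    beta_noise_sd: float = 0.02
    beta_dosage_weight: float = 0.03
    # mutations
    n_recurrent_missense: int = 8
    n_distinct_truncating: int = 6
    background_mutation_rate: float = 0.5  # Poisson mean per null gene
    # shRNA screen
    n_cell_lines: int = 100
    n_type_lines: int = 20
    viability_noise_sd: float = 1.0
    viability_shift: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 3:
            raise ValidationError("n_pairs must be >= 3")
        if self.n_oncogenes + self.n_tumor_suppressors > self.n_genes:
            raise ValidationError("more planted genes than genes")
        unknown = set(self.data_types) - {
            "expression", "cna", "methylation", "mutation", "shrna"
        }
        if unknown:
            raise ValidationError(f"unknown data types: {sorted(unknown)}")


@dataclass
class SyntheticCohort:
    """A generated dataset bundle plus its ground truth."""

    spec: CohortSpec
    expression: OmicsMatrix | None
    cna: OmicsMatrix | None
    methylation: OmicsMatrix | None
    probe_annotation: ProbeAnnotation | None
    mutations: MutationTable | None
    shrna: ShrnaScreen | None
    sample_map: SampleMap
    truth: pd.DataFrame  # gene, role, per-data-type planted flags

    def to_dir(self, outdir) -> None:
        """Write every component in the package's external text formats."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        osio.write_sample_map(outdir / "sample_map.tsv", self.sample_map)
        if self.expression is not None:
            osio.write_matrix(outdir / "expression.tsv", self.expression)
        if self.cna is not None:
            osio.write_matrix(outdir / "copy_number.tsv", self.cna)
        if self.methylation is not None:
            osio.write_matrix(outdir / "methylation.tsv", self.methylation)
        if self.probe_annotation is not None:
            osio.write_probe_annotation(
                outdir / "probe_annotation.tsv", self.probe_annotation
            )
        if self.mutations is not None:
            osio.write_mutations(outdir / "mutations.maf.tsv", self.mutations)
        if self.shrna is not None:
            osio.write_matrix(outdir / "shrna_viability.tsv", self.shrna.viability)
            self.shrna.gene_solution_count.rename("n_solutions").to_frame().to_csv(
                outdir / "gene_solutions.tsv", sep="\t",
                index_label="gene", lineterminator="\n",
            )
            self.shrna.line_type.rename("cancer_type").to_frame().to_csv(
                outdir / "line_types.tsv", sep="\t",
                index_label="cell_line", lineterminator="\n",
            )
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False,
                          lineterminator="\n")


def _clip_beta(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.001, 0.999)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full cohort bundle from a :class:`CohortSpec`."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:04d}" for i in range(1, spec.n_genes + 1)]
    roles = np.array(["null"] * spec.n_genes, dtype=object)
    planted_idx = rng.choice(
        spec.n_genes, size=spec.n_oncogenes + spec.n_tumor_suppressors, replace=False
    )
    roles[planted_idx[: spec.n_oncogenes]] = "oncogene"
    roles[planted_idx[spec.n_oncogenes:]] = "tumor_suppressor"
    sign = np.where(roles == "oncogene", 1.0, np.where(roles == "tumor_suppressor", -1.0, 0.0))

    n_pairs = spec.n_pairs
    n_tumors = n_pairs + spec.n_extra_tumors
    patients = [f"P{i:04d}" for i in range(1, n_tumors + 1)]
    tumor_ids = [f"{p}-T" for p in patients]
    normal_ids = [f"{p}-N" for p in patients[:n_pairs]]
    smap = SampleMap(
        pd.DataFrame(
            {
                "patient_id": patients + patients[:n_pairs],
                "sample_id": tumor_ids + normal_ids,
                "sample_class": ["tumor_primary"] * n_tumors + ["normal"] * n_pairs,
                "cancer_type": spec.cancer_type,
            }
        )
    ).deduplicate()

    # shared per-(gene, tumor sample) dosage latent couples CN and
    # methylation to expression in planted genes
    z = rng.standard_normal((spec.n_genes, n_tumors))

    expression = None
    if "expression" in spec.data_types:
        base = rng.normal(spec.expr_baseline_mean, spec.expr_baseline_sd, spec.n_genes)
        normal_vals = base[:, None] + rng.normal(
            0, spec.expr_noise_sd, (spec.n_genes, n_pairs)
        )
        tumor_vals = (
            base[:, None]
            + sign[:, None] * spec.expr_shift * spec.expr_noise_sd
            + np.where(sign[:, None] != 0, spec.dosage_weight * z, 0.0)
            + rng.normal(0, spec.expr_noise_sd, (spec.n_genes, n_tumors))
        )
        values = pd.DataFrame(
            np.hstack([tumor_vals, normal_vals]),
            index=genes,
            columns=tumor_ids + normal_ids,
        )
        expression = OmicsMatrix(values, "expression")

    cna = None
    if "cna" in spec.data_types:
        normal_vals = rng.normal(0, spec.cn_noise_sd, (spec.n_genes, n_pairs))
        tumor_vals = (
            sign[:, None] * spec.cn_shift
            + np.where(sign[:, None] != 0, spec.cn_dosage_weight * z, 0.0)
            + rng.normal(0, spec.cn_noise_sd, (spec.n_genes, n_tumors))
        )
        values = pd.DataFrame(
            np.hstack([tumor_vals, normal_vals]),
            index=genes,
            columns=tumor_ids + normal_ids,
        )
        cna = OmicsMatrix(values, "cna")

    methylation = None
    probe_annotation = None
    if "methylation" in spec.data_types:
        k = spec.n_probes_per_gene
        probe_ids = [f"cg{g[1:]}_{j}" for g in genes for j in range(1, k + 1)]
        annot = pd.DataFrame(
            {
                "probe_id": probe_ids,
                "gene": np.repeat(genes, k),
                # first probe of every gene sits in the gene body
                "region": ["body" if j == 0 else "other" for _ in genes for j in range(k)],
            }
        )
        probe_base = rng.uniform(0.2, 0.6, len(probe_ids))
        n_probes = len(probe_ids)
        normal_vals = probe_base[:, None] + rng.normal(
            0, spec.beta_noise_sd, (n_probes, n_pairs)
        )
        tumor_vals = probe_base[:, None] + rng.normal(
            0, spec.beta_noise_sd, (n_probes, n_tumors)
        )
        # plant the shift + dosage coupling on the body probe only
        body_rows = np.arange(0, n_probes, k)
        tumor_vals[body_rows] += sign[:, None] * spec.beta_shift
        tumor_vals[body_rows] += np.where(
            sign[:, None] != 0, spec.beta_dosage_weight * z, 0.0
        )
        values = pd.DataFrame(
            _clip_beta(np.hstack([tumor_vals, normal_vals])),
            index=probe_ids,
            columns=tumor_ids + normal_ids,
        )
        methylation = OmicsMatrix(values, "methylation")
        probe_annotation = ProbeAnnotation(annot)

    mutations = None
    if "mutation" in spec.data_types:
        rows = []
        for i, gene in enumerate(genes):
            chrom = str(1 + i % 22)
            base_pos = 1 + i * 100_000
            if roles[i] == "oncogene":
                hit = rng.choice(n_tumors, spec.n_recurrent_missense, replace=False)
                for s in hit:
                    rows.append((gene, tumor_ids[s], "missense", chrom, base_pos, "A", "G"))
            elif roles[i] == "tumor_suppressor":
                hit = rng.choice(n_tumors, spec.n_distinct_truncating, replace=False)
                for j, s in enumerate(hit):
                    rows.append(
                        (gene, tumor_ids[s], "nonsense", chrom, base_pos + j * 3, "C", "T")
                    )
            n_bg = rng.poisson(spec.background_mutation_rate)
            for j in range(n_bg):
                s = rng.integers(n_tumors)
                vc = "missense" if rng.random() < 0.7 else "other"
                rows.append(
                    (gene, tumor_ids[s], vc, chrom, base_pos + 50_000 + j * 7, "G", "A")
                )
        mutations = MutationTable(
            pd.DataFrame(
                rows,
                columns=["gene", "sample_id", "variant_class", "chrom", "pos", "ref", "alt"],
            )
        )

    screen = None
    if "shrna" in spec.data_types:
        lines = [f"CL{i:03d}" for i in range(1, spec.n_cell_lines + 1)]
        line_type = pd.Series(
            [spec.cancer_type] * spec.n_type_lines
            + ["OTHER"] * (spec.n_cell_lines - spec.n_type_lines),
            index=lines,
        )
        viab = rng.normal(0, spec.viability_noise_sd, (spec.n_genes, spec.n_cell_lines))
        type_cols = np.arange(spec.n_type_lines)
        # knock-down of a planted oncogene kills dependent lines (low
        # viability); knocking down a planted suppressor relieves growth
        viab[:, type_cols] += -sign[:, None] * spec.viability_shift
        screen = ShrnaScreen(
            OmicsMatrix(pd.DataFrame(viab, index=genes, columns=lines), "shrna"),
            pd.Series(1, index=pd.Index(genes, name="gene")),
            line_type,
        )

    truth = pd.DataFrame({"gene": genes, "role": roles})
    for tag in spec.data_types:
        truth[f"{tag}_planted"] = roles != "null"
    return SyntheticCohort(
        spec=spec,
        expression=expression,
        cna=cna,
        methylation=methylation,
        probe_annotation=probe_annotation,
        mutations=mutations,
        shrna=screen,
        sample_map=smap,
        truth=truth,
    )


def spec_from_dict(d: dict) -> CohortSpec:
    d = dict(d)
    if "data_types" in d:
        d["data_types"] = tuple(d["data_types"])
    return CohortSpec(**d)


def spec_to_dict(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["data_types"] = list(d["data_types"])
    return d


# ---------------------------------------------------------------------------
# deterministic boundary fixtures


BOUNDARY_CASES = (
    "cn_gate",
    "beta_gate",
    "ogmr_gate",
    "tsmr_gate",
    "min_five",
    "shrna_quartile",
    "affected_sd",
    "unit_score",
)


def _symmetric_jitter(n: int, amplitude: float) -> np.ndarray:
    """Deterministic zero-mean jitter with distinct values."""
    return amplitude * (2 * np.arange(n) / (n - 1) - 1)


def _maf_frame(rows) -> MutationTable:
    return MutationTable(
        pd.DataFrame(
            rows, columns=["gene", "sample_id", "variant_class", "chrom", "pos", "ref", "alt"]
        )
    )


def boundary_fixture(case_id: str, seed: int = 0) -> dict:
    """Deterministic inputs probing one decision threshold.

    Each fixture bundles several probes of the same rule (e.g. one gene
    per copy-number shift on the sweep grid) so a single scorer run reads
    out the whole boundary.  Returns a dict of the inputs the relevant
    scorer consumes plus the sweep bookkeeping under ``sweep``.
    """
    if case_id not in BOUNDARY_CASES:
        raise ValidationError(
            f"unknown boundary case {case_id!r}; valid ids: {', '.join(BOUNDARY_CASES)}"
        )
    if case_id == "cn_gate":
        shifts = [0.05, 0.10, 0.15]
        n = 200
        tumor_ids = [f"P{i:03d}-T" for i in range(n)]
        normal_ids = [f"P{i:03d}-N" for i in range(n)]
        jit = _symmetric_jitter(n, 0.01)
        genes = [f"CN_{s:.2f}" for s in shifts]
        tumor = pd.DataFrame(
            [s + jit for s in shifts], index=genes, columns=tumor_ids
        )
        normal = pd.DataFrame(0.0, index=genes, columns=normal_ids)
        cna = OmicsMatrix(pd.concat([tumor, normal], axis=1), "cna")
        expr = OmicsMatrix(tumor.copy(), "expression")  # expression == tumor CN
        smap = SampleMap(
            pd.DataFrame(
                {
                    "patient_id": [f"P{i:03d}" for i in range(n)] * 2,
                    "sample_id": tumor_ids + normal_ids,
                    "sample_class": ["tumor_primary"] * n + ["normal"] * n,
                    "cancer_type": "BOUND",
                }
            )
        ).deduplicate()
        return {"cna": cna, "tumor_expr": expr, "sample_map": smap,
                "sweep": dict(zip(genes, shifts))}
    if case_id == "beta_gate":
        shifts = [0.05, 0.10, 0.15]
        n = 100
        tumor_ids = [f"T{i:03d}" for i in range(n)]
        normal_ids = [f"N{i:03d}" for i in range(n)]
        jit = _symmetric_jitter(n, 0.01)
        genes = [f"ME_{s:.2f}" for s in shifts]
        probes = [f"cg_{g}" for g in genes]
        tumor = pd.DataFrame(
            [0.4 + s + jit for s in shifts], index=probes, columns=tumor_ids
        )
        normal = pd.DataFrame(0.4, index=probes, columns=normal_ids)
        expr = OmicsMatrix(
            pd.DataFrame(tumor.to_numpy(), index=genes, columns=tumor_ids),
            "expression",
        )  # expression monotone in probe beta
        annot = ProbeAnnotation(
            pd.DataFrame({"probe_id": probes, "gene": genes, "region": "body"})
        )
        return {
            "tumor_meth": OmicsMatrix(tumor, "methylation"),
            "normal_meth": OmicsMatrix(normal, "methylation"),
            "annot": annot,
            "tumor_expr": expr,
            "sweep": dict(zip(genes, shifts)),
        }
    if case_id == "ogmr_gate":
        # 20 missense each, d distinct sites, d = 20..14 -> OGMR 0 .. 0.30
        rows = []
        sweep = {}
        for d in range(20, 13, -1):
            gene = f"OG_D{d:02d}"
            sweep[gene] = 1 - d / 20
            for i in range(20):
                pos = 1000 + min(i, d - 1) * 3
                rows.append((gene, f"S{i:02d}", "missense", "1", pos, "A", "G"))
        return {"mutations": _maf_frame(rows), "sweep": sweep}
    if case_id == "tsmr_gate":
        # 40 distinct mutations, k nonsense + (40-k) missense, k = 5..12
        rows = []
        sweep = {}
        for k in range(5, 13):
            gene = f"TS_K{k:02d}"
            sweep[gene] = k / 40
            for i in range(40):
                vc = "nonsense" if i < k else "missense"
                rows.append((gene, f"S{i:02d}", vc, "2", 5000 + i * 3, "C", "T"))
        return {"mutations": _maf_frame(rows), "sweep": sweep}
    if case_id == "min_five":
        # 1..10 distinct nonsense mutations in one gene each
        rows = []
        sweep = {}
        for m in range(1, 11):
            gene = f"MIN_{m:02d}"
            sweep[gene] = m
            for i in range(m):
                rows.append((gene, f"S{i:02d}", "nonsense", "3", 9000 + i * 3, "G", "A"))
        return {"mutations": _maf_frame(rows), "sweep": sweep}
    if case_id == "shrna_quartile":
        lines = [f"CL{i:03d}" for i in range(1, 101)]
        type_lines = lines[:20]
        line_type = pd.Series(["TYPE"] * 20 + ["OTHER"] * 80, index=lines)
        rows = {}
        sweep_low = {}

        def _assemble(displaced: np.ndarray) -> np.ndarray:
            """Exact integer partition of 1..100: displaced type lines,
            remaining type lines between the quartiles, the rest to the
            other 80 lines.  The pooled distribution is always a
            permutation of 1..100, so Q1 = 25.75 and Q3 = 75.25."""
            mid_pool = np.setdiff1d(np.arange(26, 76), displaced)
            mid = mid_pool[: 20 - displaced.size]
            others = np.setdiff1d(
                np.arange(1, 101), np.concatenate([displaced, mid])
            )
            return np.concatenate([displaced, mid, others]).astype(float)

        # below-Q1 sweep: gene_k has exactly k type lines at 1..k, the
        # rest of the type between the quartiles
        for k in range(1, 21):
            gene = f"SH_LOW_{k:02d}"
            sweep_low[gene] = k / 20
            rows[gene] = _assemble(np.arange(1, k + 1))
        # above-percentile sweep: 5 type lines just above candidate
        # global percentiles
        sweep_high = {}
        for pct in (50, 75, 90):
            gene = f"SH_HIGH_{pct:02d}"
            sweep_high[gene] = pct
            rows[gene] = _assemble(pct + np.arange(1, 6))
        viability = pd.DataFrame(rows, index=lines).T
        screen = ShrnaScreen(
            OmicsMatrix(viability, "shrna"),
            pd.Series(1, index=viability.index),
            line_type,
        )
        return {"screen": screen, "cancer_type": "TYPE",
                "sweep_low": sweep_low, "sweep_high": sweep_high}
    if case_id == "affected_sd":
        tumor = pd.DataFrame(
            {f"T{i}": [v] for i, v in enumerate([-2.0, -1.0, 0.0, 1.0, 2.0])},
            index=["AFF"],
        )
        normal = pd.DataFrame(
            {f"N{i}": [0.0] for i in range(5)}, index=["AFF"]
        )
        pairs = [(f"T{i}", f"N{i}", f"P{i}") for i in range(5)]
        return {
            "tumor": OmicsMatrix(tumor, "expression"),
            "normal": OmicsMatrix(normal, "expression"),
            "pairs": pairs,
        }
    # unit_score: 20 pairs, one gene shifted +2, 999 exchangeable nulls
    rng = np.random.default_rng(seed)
    n_genes, n_pairs = 1000, 20
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    tumor_ids = [f"P{i:02d}-T" for i in range(n_pairs)]
    normal_ids = [f"P{i:02d}-N" for i in range(n_pairs)]
    normal = rng.normal(8, 1, (n_genes, n_pairs))
    tumor = rng.normal(8, 1, (n_genes, n_pairs))
    tumor[0] = normal[0] + 2.0  # the planted gene
    values = pd.DataFrame(
        np.hstack([tumor, normal]), index=genes, columns=tumor_ids + normal_ids
    )
    smap = SampleMap(
        pd.DataFrame(
            {
                "patient_id": [f"P{i:02d}" for i in range(n_pairs)] * 2,
                "sample_id": tumor_ids + normal_ids,
                "sample_class": ["tumor_primary"] * n_pairs + ["normal"] * n_pairs,
                "cancer_type": "BOUND",
            }
        )
    ).deduplicate()
    return {
        "expression": OmicsMatrix(values, "expression"),
        "sample_map": smap,
        "target_gene": genes[0],
    }
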