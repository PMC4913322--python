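"""Model/Results interface tying the per-data-type scorers together.

:class:`OncoScape` is constructed from whatever data types are available
for one cancer type; :meth:`OncoScape.fit` runs every applicable scorer,
aggregates the calls into gene score cards and returns an
:class:`OncoScapeResults` carrying the cards, the per-data-type call sets
and diagnostics, with a ``summary()`` table and TSV export.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import aggregate, io as osio, mutations as mut, scoring, shrna as sh
from .types import (
    AberrationCalls,
    MutationTable,
    OmicsMatrix,
    ProbeAnnotation,
    SampleMap,
    ScoringConfig,
    ValidationError,
)


class OncoScape:
    """Multi-omics aberration scoring model for one cancer type.

    Parameters
    ----------
    sample_map : SampleMap, optional
        Patient/sample bookkeeping; deduplicated automatically.  Required
        for expression, copy-number and methylation scoring.
    expression, copy_number, methylation : OmicsMatrix, optional
        Feature x sample matrices holding tumor and normal columns; the
        sample map decides which is which.
    probe_annotation : ProbeAnnotation, optional
        Required alongside ``methylation``.
    mutations : MutationTable, optional
        Somatic mutations; restricted to the cancer type's tumor samples
        when sample ids overlap the map.
    shrna : ShrnaScreen, optional
        Knock-down screen across cell lines (multi-solution genes are
        filtered out before scoring).
    cancer_type : str, optional
        Label written into the score cards; defaults to the single type
        present in the sample map.
    config : ScoringConfig, optional
        Thresholds; defaults follow the published rules (FDR 0.05, 0.1
        effect gates, five class mutations, 25%/quartile screen rule).
    """

    def __init__(
        self,
        sample_map: SampleMap | None = None,
        expression: OmicsMatrix | None = None,
        copy_number: OmicsMatrix | None = None,
        methylation: OmicsMatrix | None = None,
        probe_annotation: ProbeAnnotation | None = None,
        mutations: MutationTable | None = None,
        shrna: sh.ShrnaScreen | None = None,
        cancer_type: str | None = None,
        config: ScoringConfig | None = None,
    ) -> None:
        if not any(
            x is not None for x in (expression, copy_number, methylation, mutations, shrna)
        ):
            raise ValidationError("at least one data type must be provided")
        if methylation is not None and probe_annotation is None:
            raise ValidationError("methylation scoring requires a probe annotation")
        needs_map = any(x is not None for x in (expression, copy_number, methylation))
        if needs_map and sample_map is None:
            raise ValidationError(
                "expression/copy-number/methylation scoring requires a sample map"
            )
        if sample_map is not None and not sample_map.deduplicated:
            sample_map = sample_map.deduplicate()
        if cancer_type is None:
            if sample_map is not None and len(sample_map.cancer_types) == 1:
                cancer_type = sample_map.cancer_types[0]
            else:
                raise ValidationError("cancer_type must be given")
        if sample_map is not None:
            sample_map = sample_map.subset_cancer_type(cancer_type)
        self.sample_map = sample_map
        self.expression = expression
        self.copy_number = copy_number
        self.methylation = methylation
        self.probe_annotation = probe_annotation
        self.mutations = mutations
        self.shrna = shrna
        self.cancer_type = cancer_type
        self.config = config or ScoringConfig()

    # -- helpers ----------------------------------------------------------

    def _tumor_expression(self) -> OmicsMatrix | None:
        if self.expression is None or self.sample_map is None:
            return None
        tumors = self.sample_map.samples_of_class("tumor_primary")
        return self.expression.subset_samples(tumors)

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "OncoScapeResults":
        """Run every available scorer and aggregate the calls."""
        cfg = self.config
        calls: list[AberrationCalls] = []
        diagnostics: dict[str, pd.DataFrame] = {}
        cohorts: dict[str, scoring.PairedCohort] = {}
        tumor_expr = self._tumor_expression()

        if self.expression is not None:
            cohort = scoring.build_paired_cohort(self.expression, self.sample_map)
            cohorts["expression"] = cohort
            c = scoring.score_expression(cohort, cfg)
            calls.append(c)
            diagnostics["expression"] = c.frame

        if self.copy_number is not None:
            cohort = scoring.build_paired_cohort(self.copy_number, self.sample_map)
            cohorts["cna"] = cohort
            if tumor_expr is None:
                c = scoring.score_copy_number(
                    cohort,
                    OmicsMatrix(pd.DataFrame(index=[], columns=[], dtype=float), "expression"),
                    cfg,
                )
            else:
                c = scoring.score_copy_number(cohort, tumor_expr, cfg)
            calls.append(c)
            diagnostics["cna"] = c.frame

        if self.methylation is not None:
            tumors = self.sample_map.samples_of_class("tumor_primary")
            normals = self.sample_map.samples_of_class("normal")
            expr = tumor_expr if tumor_expr is not None else OmicsMatrix(
                pd.DataFrame(index=[], columns=[], dtype=float), "expression"
            )
            c, links = scoring.score_methylation(
                self.methylation.subset_samples(tumors),
                self.methylation.subset_samples(normals),
                self.probe_annotation,
                expr,
                cfg,
            )
            calls.append(c)
            diagnostics["methylation"] = links

        if self.mutations is not None:
            table = self.mutations
            if self.sample_map is not None:
                tumors = set(self.sample_map.samples_of_class("tumor_primary"))
                if tumors & set(table.records["sample_id"]):
                    table = table.subset_samples(tumors)
            c, rates = mut.score_mutations(table, cfg.min_mutation_count)
            calls.append(c)
            diagnostics["mutation"] = rates

        if self.shrna is not None:
            screen = sh.filter_single_solution(self.shrna)
            c = sh.score_shrna(screen, self.cancer_type, cfg.shrna_fraction)
            calls.append(c)
            diagnostics["shrna"] = c.frame

        cards = aggregate.combine_scores(calls, self.cancer_type)
        return OncoScapeResults(self, cards, {c.tag: c for c in calls}, diagnostics, cohorts)


class OncoScapeResults:
    """Fitted scoring results: score cards, calls and diagnostics."""

    def __init__(
        self,
        model: OncoScape,
        score_cards: pd.DataFrame,
        calls: dict[str, AberrationCalls],
        diagnostics: dict[str, pd.DataFrame],
        cohorts: dict[str, scoring.PairedCohort],
    ) -> None:
        self.model = model
        self.score_cards = score_cards
        self.calls = calls
        self.diagnostics = diagnostics
        self._cohorts = cohorts

    # -- derived quantities ----------------------------------------------

    def rank(self, by: str = "aberration", descending: bool = True) -> list[str]:
        return aggregate.rank_genes(self.score_cards, by, descending)

    def pathway_scores(self, pathways) -> pd.DataFrame:
        return aggregate.pathway_scores(self.score_cards, pathways)

    def affected_fractions(self, data_type: str) -> pd.DataFrame:
        """Affected-sample fractions for one of the paired data types."""
        cohort = self._cohorts.get(data_type)
        if cohort is None:
            raise ValidationError(f"no cohort data for data type {data_type!r}")
        return aggregate.affected_fractions(cohort.tumor, cohort.normal, cohort.pairs)

    # -- reporting ---------------------------------------------------------

    def summary(self, top: int = 10) -> str:
        cards = self.score_cards
        lines = [
            f"OncoScape results: cancer type {self.model.cancer_type}",
            f"  genes scored:        {len(cards)}",
            f"  data types:          {', '.join(sorted(self.calls))}",
            f"  oncogene calls:      {(cards['og_score'] > 0).sum()}",
            f"  tumor suppressor:    {(cards['ts_score'] > 0).sum()}",
            f"  aberration >= 3:     {(cards['aberration_score'] >= 3).sum()}",
            "",
            f"Top {top} genes by aberration score:",
        ]
        head = cards.sort_values(
            ["aberration_score", "gene"], ascending=[False, True]
        ).head(top)
        lines.append(
            head[
                ["gene", "og_score", "ts_score", "overall_score", "aberration_score",
                 "n_data_types_available"]
            ].to_string(index=False)
        )
        return "\n".join(lines)

    def to_dir(self, outdir) -> dict:
        """Write the score table, diagnostics and a run manifest; returns
        the manifest (which includes a content hash for rerun checks)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        osio.write_scores(outdir / "gene_scores.tsv", self.score_cards)
        for tag, diag in self.diagnostics.items():
            diag.to_csv(
                outdir / f"diagnostics_{tag}.tsv", sep="\t", na_rep="NA",
                lineterminator="\n",
                index=not isinstance(diag.index, pd.RangeIndex),
            )
        digest = hashlib.sha256()
        for path in sorted(outdir.glob("*.tsv")):
            digest.update(path.read_bytes())
        manifest = {
            "cancer_type": self.model.cancer_type,
            "data_types": sorted(self.calls),
            "config": {
                "fdr_threshold": self.model.config.fdr_threshold,
                "min_cn_diff": self.model.config.min_cn_diff,
                "min_beta_diff": self.model.config.min_beta_diff,
                "min_mutation_count": self.model.config.min_mutation_count,
                "shrna_fraction": self.model.config.shrna_fraction,
            },
            "n_genes": int(len(self.score_cards)),
            "output_sha256": digest.hexdigest(),
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return manifest
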