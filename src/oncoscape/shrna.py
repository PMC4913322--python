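"""shRNA knock-down viability scoring per cancer type.

Screens provide one consolidated viability score per gene and cell line
("gene solution"); only genes with a single gene solution are used.  For
each gene the 25th and 75th percentile of viability across *all* screened
cell lines define the global quartiles.  Within one cancer type, a gene is
a potential oncogene if at least 25% of that type's lines fall strictly
below the global lower quartile (knock-down kills the lines), and a
potential tumor suppressor if at least 25% fall strictly above the global
upper quartile.  Both flags may co-occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .types import AberrationCalls, OmicsMatrix, ValidationError


@dataclass
class ShrnaScreen:
    """Viability matrix (genes x cell lines) with per-gene solution counts
    and a cell-line -> cancer-type map."""

    viability: OmicsMatrix
    gene_solution_count: pd.Series  # gene -> int
    line_type: pd.Series  # cell line -> cancer type

    def __post_init__(self) -> None:
        if self.viability.tag != "shrna":
            raise ValidationError("screen matrix must carry tag 'shrna'")
        missing = [s for s in self.viability.sample_ids if s not in self.line_type.index]
        if missing:
            raise ValidationError(f"cell lines without type label: {missing[:5]}")
        counts = self.gene_solution_count.dropna()
        if (counts < 1).any():
            raise ValidationError("gene_solution_count must be >= 1")

    def lines_of_type(self, cancer_type: str) -> list[str]:
        lines = self.line_type.index[self.line_type == cancer_type]
        return [s for s in self.viability.sample_ids if s in set(lines)]


def filter_single_solution(screen: ShrnaScreen) -> ShrnaScreen:
    """Keep only genes with exactly one gene solution."""
    counts = screen.gene_solution_count
    keep = [
        g
        for g in screen.viability.feature_ids
        if g in counts.index and counts[g] == 1
    ]
    return ShrnaScreen(
        screen.viability.subset_features(keep),
        counts.loc[keep],
        screen.line_type,
    )


def score_shrna(
    screen: ShrnaScreen, cancer_type: str, fraction: float = 0.25
) -> AberrationCalls:
    """Score one cancer type's cell lines against the global quartiles.

    ``fraction`` is the minimum fraction of the type's lines beyond a
    quartile (inclusive); the quartile comparisons themselves are strict.
    """
    type_lines = screen.lines_of_type(cancer_type)
    if not type_lines:
        raise ValidationError(f"no cell lines for cancer type {cancer_type!r}")
    vals = screen.viability.values
    rows = []
    for gene in screen.viability.feature_ids:
        all_v = vals.loc[gene].to_numpy(float)
        all_v = all_v[np.isfinite(all_v)]
        type_v = vals.loc[gene, type_lines].to_numpy(float)
        type_v = type_v[np.isfinite(type_v)]
        if all_v.size == 0 or type_v.size == 0:
            rows.append((gene, False, False, False, np.nan, np.nan, np.nan, np.nan))
            continue
        q1 = stats.quantile(all_v, 0.25)
        q3 = stats.quantile(all_v, 0.75)
        frac_low = float(np.mean(type_v < q1))
        frac_high = float(np.mean(type_v > q3))
        rows.append(
            (gene, frac_low >= fraction, frac_high >= fraction, True,
             q1, q3, frac_low, frac_high)
        )
    frame = pd.DataFrame(
        rows,
        columns=["gene", "activating", "inactivating", "available",
                 "q1", "q3", "frac_below_q1", "frac_above_q3"],
    ).set_index("gene")
    return AberrationCalls("shrna", frame)
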