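"""Phosphoprotein-bias curves.

For a bait-vs-control contrast, the curve reports — at each fold-change
threshold t — how many quantified proteins exceed t and what fraction of
them are annotated as potential phosphoproteins. A bait whose recruitment is
driven by phosphotyrosine binding shows a rising fraction with threshold;
comparing two baits' curves (signed difference and the area between them)
quantifies differential phospho-dependence of their interactomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import ContrastResult
from .io import AnnotationTable

#: default threshold grid, log2 fold-change units
DEFAULT_THRESHOLDS = np.arange(0.0, 5.0 + 1e-9, 0.25)

PHOSPHO_LABEL = "has_pTyr_site"


@dataclass
class BiasCurve:
    """Counts and phospho fraction above each log2fc threshold."""

    thresholds: np.ndarray
    n_proteins: np.ndarray
    n_phospho: np.ndarray
    contrast: str = ""

    @property
    def fraction(self) -> np.ndarray:
        """n_phospho / n_proteins; NaN where no protein exceeds the threshold."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.n_proteins > 0, self.n_phospho / self.n_proteins, np.nan
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "n_proteins": self.n_proteins,
                "n_phospho": self.n_phospho,
                "fraction": self.fraction,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def phospho_fraction_curve(
    result: ContrastResult,
    annotations: AnnotationTable,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
    label: str = PHOSPHO_LABEL,
) -> BiasCurve:
    """Phosphoprotein fraction among proteins with log2fc strictly above each threshold.

    Proteins absent from the annotation table count as not phospho-annotated.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim != 1 or len(thresholds) == 0:
        raise ValueError("thresholds must be a non-empty 1-D grid")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    lfc = result.table["log2fc"].to_numpy()
    is_phospho = np.array(
        [annotations.has(pid, label) for pid in result.table.index], dtype=bool
    )
    n_proteins = np.array([(lfc > t).sum() for t in thresholds])
    n_phospho = np.array([(is_phospho & (lfc > t)).sum() for t in thresholds])
    return BiasCurve(thresholds, n_proteins, n_phospho, contrast=result.label)


def compare_bias_curves(
    curve_a: BiasCurve, curve_b: BiasCurve
) -> tuple[np.ndarray, float]:
    """Signed per-threshold fraction difference (A − B) and its trapezoidal area.

    A positive area means curve A is more phospho-enriched than B over the
    shared grid. Both curves must be computed on identical threshold grids.
    """
    if len(curve_a.thresholds) != len(curve_b.thresholds) or not np.allclose(
        curve_a.thresholds, curve_b.thresholds
    ):
        raise ValueError("bias curves computed on different threshold grids")
    diff = curve_a.fraction - curve_b.fraction
    area = float(np.trapezoid(diff, curve_a.thresholds))
    return diff, area
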