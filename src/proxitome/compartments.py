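"""Compartment-level statistics on proximity-labeling contrasts.

Four complementary views of where a bait's labeling signal sits:

* ``compartment_shift`` — does a labeled protein class (e.g. mitochondrial)
  show systematically higher bait-over-control fold-changes than the rest of
  the quantified proteome? One-sided Mann–Whitney U.
* ``complex_hit_counts`` — how many members of each respiratory-chain
  complex are enrichment hits, with complex I split into core / accessory /
  assembly subunit classes.
* ``submito_profile`` — mean fold-change of matrix-resident vs
  intermembrane-space-resident proteins per variant; the difference locates
  the bait's labeling within the organelle.
* ``overrepresentation`` — generic hypergeometric gene-set ORA with
  Benjamini–Hochberg adjustment, the background being the quantified
  proteins of the contrast (proximity-labeling detectability defines the
  sampling frame).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import ContrastResult, HitSet
from .io import AnnotationTable, GeneSetCollection

logger = logging.getLogger("proxitome")

#: complex I subunit classes reported separately when annotated
COMPLEX_I_CLASSES = ("complex_I_core", "complex_I_accessory", "complex_I_assembly")


@dataclass
class CompartmentShift:
    """One-sided rank test of labeled proteins' log2fc against the background."""

    label: str
    contrast: str
    condition: str
    n_in_label: int
    n_background: int
    u_statistic: float
    p_value: float
    median_label: float
    median_background: float

    @property
    def median_shift(self) -> float:
        return self.median_label - self.median_background


def compartment_shift(
    result: ContrastResult,
    annotations: AnnotationTable,
    label: str,
) -> CompartmentShift:
    """Mann–Whitney U test: labeled proteins' log2fc > background log2fc.

    The background is every quantified protein in the contrast not carrying
    the label. An exact null distribution is used for small tie-free inputs
    (scipy's default policy).
    """
    if label not in annotations.vocabulary:
        raise ValueError(f"label {label!r} not in the annotation vocabulary")
    lfc = result.table["log2fc"]
    in_label = np.array([annotations.has(pid, label) for pid in lfc.index], dtype=bool)
    if not in_label.any():
        raise ValueError(f"no quantified protein carries label {label!r}")
    if in_label.all():
        raise ValueError(f"label {label!r} covers every quantified protein: empty background")
    labeled = lfc.to_numpy()[in_label]
    background = lfc.to_numpy()[~in_label]
    u, p = stats.mannwhitneyu(labeled, background, alternative="greater")
    return CompartmentShift(
        label=label,
        contrast=result.label,
        condition=result.condition,
        n_in_label=int(in_label.sum()),
        n_background=int((~in_label).sum()),
        u_statistic=float(u),
        p_value=float(p),
        median_label=float(np.median(labeled)),
        median_background=float(np.median(background)),
    )


def complex_hit_counts(
    hitset: HitSet,
    annotations: AnnotationTable,
    complexes: list[str],
) -> pd.DataFrame:
    """Number of hit proteins per respiratory-complex label.

    Any complex I subunit-class labels present in the vocabulary are counted
    separately in addition to the labels requested.
    """
    labels = list(complexes)
    for cls in COMPLEX_I_CLASSES:
        if cls in annotations.vocabulary and cls not in labels:
            labels.append(cls)
    rows = []
    for label in labels:
        members = annotations.with_label(label)  # raises on unknown label
        rows.append(
            {
                "label": label,
                "n_members": len(members),
                "n_hits": len(members & set(hitset.proteins)),
            }
        )
    return pd.DataFrame(rows)


def submito_profile(
    results: list[ContrastResult],
    annotations: AnnotationTable,
    matrix_label: str = "matrix",
    ims_label: str = "intermembrane_space",
) -> pd.DataFrame:
    """Per-variant mean log2fc of matrix vs intermembrane-space proteins.

    The difference (matrix − IMS) is an indicator of sub-mitochondrial
    position of the bait's labeling signal. A sub-compartment with no
    quantified member yields NaN with a logged warning.
    """
    matrix_proteins = annotations.with_label(matrix_label)
    ims_proteins = annotations.with_label(ims_label)
    rows = []
    for result in results:
        lfc = result.table["log2fc"]
        means = {}
        for name, members in (("matrix", matrix_proteins), ("ims", ims_proteins)):
            present = lfc.index.intersection(sorted(members))
            if len(present) == 0:
                logger.warning(
                    "%s: no quantified %s-labeled protein; reporting NaN",
                    result.label,
                    name,
                )
                means[name] = np.nan
            else:
                means[name] = float(lfc.loc[present].mean())
        rows.append(
            {
                "contrast": result.label,
                "mean_matrix": means["matrix"],
                "mean_ims": means["ims"],
                "matrix_minus_ims": means["matrix"] - means["ims"],
            }
        )
    return pd.DataFrame(rows)


def overrepresentation(
    hitset: HitSet,
    background: set[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in the hit set.

    For a background of M quantified proteins of which n belong to the gene
    set, and N hits, the p-value is the upper tail
    P(overlap >= k) under the hypergeometric distribution. BH adjustment is
    applied across all tested sets; rows are sorted by p.
    """
    hits = set(hitset.proteins)
    stray = hits - background
    if stray:
        raise ValueError(
            f"hit proteins absent from the background: {sorted(stray)[:5]}"
        )
    M, N = len(background), len(hits)
    rows = []
    for s in sets:
        members = set(s.members) & background
        k = len(members & hits)
        # upper tail P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), N))
        rows.append(
            {
                "set_name": s.name,
                "overlap": k,
                "set_size": len(members),
                "hit_size": N,
                "background_size": M,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values(["p_value", "set_name"]).reset_index(drop=True)
    return out
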