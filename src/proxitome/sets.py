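"""Set algebra over interactome hit sets.

Covers the three consensus constructions used when comparing bait variants:
exact pairwise overlaps, the k-of-n "core interactome" (proteins called as
hits for at least k of n variants), and a relaxed pairwise overlap that
applies both cutoffs to the first variant but only one of the two to the
second — a sparsity-tolerant overlap measure. All operations are exact
enumeration; proteins absent from a contrast table count as non-hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .enrichment import ContrastResult, HitSet, call_hits


@dataclass
class OverlapMatrix:
    """Pairwise shared-hit counts and per-protein membership for a hit-set family."""

    membership: pd.DataFrame  # proteins × set labels, boolean
    pairwise: pd.DataFrame  # labels × labels, shared-protein counts
    condition: str

    @property
    def per_protein_counts(self) -> pd.Series:
        """Number of hit sets containing each protein."""
        return self.membership.sum(axis=1)


def _check_same_condition(hitsets: list[HitSet]) -> str:
    conditions = {h.condition for h in hitsets}
    if len(conditions) > 1:
        raise ValueError(f"hit sets span multiple conditions: {sorted(conditions)}")
    return next(iter(conditions)) if conditions else ""


def overlap_matrix(hitsets: list[HitSet]) -> OverlapMatrix:
    """Exact pairwise overlap counts among hit sets from one condition."""
    if not hitsets:
        raise ValueError("no hit sets given")
    condition = _check_same_condition(hitsets)
    labels = [h.variant for h in hitsets]
    if len(labels) != len(set(labels)):
        raise ValueError(f"duplicate variant labels: {labels}")
    universe = sorted(set().union(*(h.proteins for h in hitsets)))
    membership = pd.DataFrame(
        {h.variant: [p in h.proteins for p in universe] for h in hitsets},
        index=pd.Index(universe, name="protein_id"),
        dtype=bool,
    )
    m = membership.to_numpy(dtype=int)
    pairwise = pd.DataFrame(m.T @ m, index=labels, columns=labels)
    return OverlapMatrix(membership=membership, pairwise=pairwise, condition=condition)


def core_interactome(hitsets: list[HitSet], k: int) -> set[str]:
    """Proteins hit in at least ``k`` of the given hit sets.

    k=1 is the union, k=len(hitsets) the intersection; the result shrinks
    monotonically in k.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(hitsets):
        raise ValueError(f"k={k} exceeds the number of hit sets ({len(hitsets)})")
    _check_same_condition(hitsets)
    counts: dict[str, int] = {}
    for h in hitsets:
        for pid in h.proteins:
            counts[pid] = counts.get(pid, 0) + 1
    return {pid for pid, c in counts.items() if c >= k}


def relaxed_pairwise_overlap(
    result_a: ContrastResult,
    result_b: ContrastResult,
    lfc_cut: float = 1.0,
    p_cut: float = 0.05,
) -> set[str]:
    """Overlap applying both cutoffs to A but only one of the two to B.

    A protein is included when it passes log2fc > lfc_cut AND p < p_cut in
    contrast A, and passes log2fc > lfc_cut OR p < p_cut in contrast B. The
    operation is intentionally asymmetric in (A, B). Proteins missing from
    either table are treated as failing that table's cutoffs.
    """
    strict_a = call_hits(result_a, lfc_cut, p_cut).proteins
    tb = result_b.table
    relaxed_b = set(
        tb.index[(tb["log2fc"] > lfc_cut) | (tb["p_value"] < p_cut)]
    )
    return set(strict_a) & relaxed_b


def membership_table(hitsets: list[HitSet]) -> pd.DataFrame:
    """Boolean protein × variant membership table (upset-style)."""
    return overlap_matrix(hitsets).membership
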