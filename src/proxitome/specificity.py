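"""SH2-domain binding specificity from degenerate phosphopeptide screens.

A degenerate library of peptides with a fixed central phosphotyrosine
(written as lowercase ``y``) is panned against an SH2 domain; deep-sequencing
counts of the input and selected pools give, per flanking position and
residue, a log2 enrichment weight:

    w(p, a) = log2( f_sel(p, a) / f_in(p, a) )

with a Laplace count pseudocount inside each positional frequency and weights
zero-centered per position, so a uniform peptide scores 0. A phosphosite
window is scored by summing the weights of its flanking residues (additive
PSSM convention); padding positions beyond the protein termini contribute 0.
Percentile ranks over a scored site collection identify predicted tight
binders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

#: the 20 proteinogenic amino acids, one-letter code
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: fixed central phosphotyrosine placeholder in peptide sequences
CENTER_CHAR = "y"

#: padding character for windows extending past protein termini
PADDING_CHAR = "-"


def flank_positions(half_width: int) -> list[int]:
    """Positions −h…+h excluding the central 0 (the phosphotyrosine)."""
    return [p for p in range(-half_width, half_width + 1) if p != 0]


@dataclass
class ScreenCounts:
    """Input and selected read counts per library peptide.

    ``table`` columns: sequence (odd length, central residue the
    phosphotyrosine placeholder), input_count, selected_count.
    """

    table: pd.DataFrame
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        required = {"sequence", "input_count", "selected_count"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"screen counts missing columns {sorted(missing)}")
        seqs = self.table["sequence"].astype(str)
        lengths = seqs.str.len().unique()
        if len(lengths) != 1:
            raise ValueError(f"peptides have mixed lengths: {sorted(lengths)}")
        length = int(lengths[0])
        if length % 2 == 0:
            raise ValueError("peptide length must be odd (central phosphotyrosine)")
        center = length // 2
        if not (seqs.str[center] == CENTER_CHAR).all():
            bad = seqs[seqs.str[center] != CENTER_CHAR].iloc[0]
            raise ValueError(
                f"central residue must be {CENTER_CHAR!r} (phosphotyrosine): {bad!r}"
            )
        allowed = set(self.alphabet)
        for seq in seqs:
            flank = seq[:center] + seq[center + 1 :]
            outside = set(flank) - allowed
            if outside:
                raise ValueError(
                    f"residues {sorted(outside)} in sequence {seq!r} are outside "
                    f"the declared alphabet"
                )
        if (self.table[["input_count", "selected_count"]] < 0).any().any():
            raise ValueError("negative read counts")
        self.length = length
        self.half_width = center

    @property
    def positions(self) -> list[int]:
        return flank_positions(self.half_width)

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, alphabet: str = AMINO_ACIDS) -> "ScreenCounts":
        df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
        df["input_count"] = df["input_count"].astype(int)
        df["selected_count"] = df["selected_count"].astype(int)
        return cls(df, alphabet=alphabet)


@dataclass
class SpecificityMatrix:
    """Position × residue log2-enrichment weights for one SH2 domain."""

    domain: str
    weights: pd.DataFrame  # index = residues, columns = integer positions
    pseudocount: float = 1.0
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        self.weights = self.weights.astype(float)
        if list(self.weights.index) != list(self.alphabet):
            raise ValueError("weight rows must enumerate the alphabet in order")
        if 0 in self.weights.columns:
            raise ValueError("position 0 (the phosphotyrosine) must be excluded")

    @property
    def positions(self) -> list[int]:
        return list(self.weights.columns)

    @property
    def half_width(self) -> int:
        return max(abs(p) for p in self.positions)

    def write(self, tsv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        out = self.weights.copy()
        out.index.name = "residue"
        out.to_csv(tsv_path, sep="\t")
        if sidecar_path is None:
            sidecar_path = Path(tsv_path).with_suffix(".json")
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "domain": self.domain,
                    "pseudocount": self.pseudocount,
                    "alphabet": self.alphabet,
                },
                fh,
                indent=2,
            )
            fh.write("\n")

    @classmethod
    def read(
        cls, tsv_path: str | Path, sidecar_path: str | Path | None = None
    ) -> "SpecificityMatrix":
        weights = pd.read_csv(tsv_path, sep="\t", index_col=0)
        weights.columns = [int(c) for c in weights.columns]
        if sidecar_path is None:
            sidecar_path = Path(tsv_path).with_suffix(".json")
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        return cls(
            domain=meta["domain"],
            weights=weights,
            pseudocount=meta["pseudocount"],
            alphabet=meta["alphabet"],
        )


def _positional_counts(
    seqs: pd.Series, weights: np.ndarray, alphabet: str, half_width: int
) -> np.ndarray:
    """Sum read counts per (flanking position, residue). Vectorized over peptides."""
    lookup = np.full(128, -1, dtype=np.int64)
    for i, a in enumerate(alphabet):
        lookup[ord(a)] = i
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(seqs), 2 * half_width + 1)
    flank = np.delete(arr, half_width, axis=1)  # drop the central pY
    idx = lookup[flank]  # n_pep × n_positions
    n_pos = flank.shape[1]
    counts = np.zeros((n_pos, len(alphabet)))
    for p in range(n_pos):
        counts[p] = np.bincount(idx[:, p], weights=weights, minlength=len(alphabet))
    return counts


def build_matrix(
    counts: ScreenCounts, pseudocount: float = 1.0, domain: str = "SH2"
) -> SpecificityMatrix:
    """Estimate the specificity matrix from screen counts.

    Per flanking position p and residue a,
    ``w(p,a) = log2(f_sel(p,a) / f_in(p,a))`` with positional frequencies
    smoothed by a Laplace pseudocount (``pseudocount`` reads added to every
    (position, residue) cell before normalizing); weights are then centered
    to zero mean within each position.
    """
    seqs = counts.table["sequence"].astype(str)
    in_reads = counts.table["input_count"].to_numpy(dtype=float)
    sel_reads = counts.table["selected_count"].to_numpy(dtype=float)
    if in_reads.sum() <= 0 or sel_reads.sum() <= 0:
        raise ValueError("both input and selected pools need nonzero total reads")
    A = len(counts.alphabet)
    c_in = _positional_counts(seqs, in_reads, counts.alphabet, counts.half_width)
    c_sel = _positional_counts(seqs, sel_reads, counts.alphabet, counts.half_width)
    f_in = (c_in + pseudocount) / (c_in.sum(axis=1, keepdims=True) + pseudocount * A)
    f_sel = (c_sel + pseudocount) / (c_sel.sum(axis=1, keepdims=True) + pseudocount * A)
    w = np.log2(f_sel / f_in)
    w = w - w.mean(axis=1, keepdims=True)  # zero-center per position
    weights = pd.DataFrame(
        w.T, index=list(counts.alphabet), columns=counts.positions
    )
    return SpecificityMatrix(
        domain=domain, weights=weights, pseudocount=pseudocount,
        alphabet=counts.alphabet,
    )


def score_window(matrix: SpecificityMatrix, window: str) -> float:
    """Additive PSSM score of one phosphosite window.

    The window must span the matrix positions plus the central
    phosphotyrosine (length 2h+1); padding characters contribute 0.
    """
    h = matrix.half_width
    if len(window) != 2 * h + 1:
        raise ValueError(
            f"window {window!r} has length {len(window)}, expected {2 * h + 1}"
        )
    score = 0.0
    w = matrix.weights
    for pos in matrix.positions:
        residue = window[pos + h]
        if residue == PADDING_CHAR:
            continue
        if residue not in matrix.alphabet:
            raise ValueError(
                f"residue {residue!r} at position {pos} of {window!r} is outside "
                f"the alphabet"
            )
        score += float(w.at[residue, pos])
    return score


def _score_many(matrix: SpecificityMatrix, windows: pd.Series) -> np.ndarray:
    return np.array([score_window(matrix, w) for w in windows.astype(str)])


def score_proteome(
    matrix_n: SpecificityMatrix,
    matrix_c: SpecificityMatrix,
    sites: pd.DataFrame,
) -> pd.DataFrame:
    """Score every phosphosite window with both SH2 matrices.

    Returns a table with per-domain scores and percentile ranks over the full
    scored set, ordered deterministically: best (max-domain) score first,
    ties broken by protein_id then position.
    """
    out = sites[["protein_id", "position", "window"]].copy()
    out["score_N"] = _score_many(matrix_n, out["window"])
    out["score_C"] = _score_many(matrix_c, out["window"])
    n = len(out)
    for col in ("score_N", "score_C"):
        # percentile rank on a 0..100 scale: the best site scores 100, the
        # worst 0; a lone site ranks 100. Ties share the larger rank.
        if n > 1:
            pct = (out[col].rank(method="max") - 1) / (n - 1) * 100.0
        else:
            pct = pd.Series(100.0, index=out.index)
        out[col.replace("score", "percentile")] = pct
    out["_best"] = out[["score_N", "score_C"]].max(axis=1)
    out = out.sort_values(
        ["_best", "protein_id", "position"], ascending=[False, True, True]
    ).drop(columns="_best")
    return out.reset_index(drop=True)


def tight_binders(
    scores: pd.DataFrame,
    percentile_cut: float = 99.0,
    proteins: set[str] | None = None,
) -> pd.DataFrame:
    """Sites whose better domain percentile is at or above the cutoff.

    Optionally restricted to proteins in a hit set (e.g. a bait interactome).
    """
    if not 0 <= percentile_cut <= 100:
        raise ValueError("percentile_cut must be in [0, 100]")
    best = scores[["percentile_N", "percentile_C"]].max(axis=1)
    keep = best >= percentile_cut
    if proteins is not None:
        keep &= scores["protein_id"].isin(proteins)
    return scores[keep].reset_index(drop=True)


class ScreenSpecificityModel(BaseEstimator):
    """Estimator facade: fit a specificity matrix from screen counts, score windows.

    Parameters
    ----------
    pseudocount : float, default 1.0
        Laplace count added per (position, residue) cell.
    domain : str
        Label carried into the fitted matrix (e.g. ``"N-SH2"``).
    """

    def __init__(self, pseudocount: float = 1.0, domain: str = "SH2"):
        self.pseudocount = pseudocount
        self.domain = domain

    def fit(self, counts: ScreenCounts, y=None):
        self.matrix_ = build_matrix(
            counts, pseudocount=self.pseudocount, domain=self.domain
        )
        return self

    def score_windows(self, windows) -> np.ndarray:
        return _score_many(self.matrix_, pd.Series(list(windows)))
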