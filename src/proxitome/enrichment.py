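"""Normalization, missing-value imputation, two-group testing and hit calling.

The workflow mirrors standard label-free proximity-labeling practice:

1. median-shift normalization of each sample column;
2. per-sample down-shifted normal imputation of missing values
   (missing-not-at-random: unquantified proteins are presumed low-abundance);
3. a two-sided Welch t-test per protein on the completed matrix;
4. dual-cutoff hit calling — log2 fold-change strictly greater than
   ``lfc_cut`` and p-value strictly below ``p_cut``. No multiple-testing
   correction is applied by default; a Benjamini–Hochberg column can be
   requested but does not drive the hit flag.

The transformer/estimator classes follow scikit-learn conventions
(rows = samples, columns = proteins) so they compose with sklearn pipelines;
the module-level functions operating on :class:`~proxitome.io.IntensityTable`
are thin wrappers over them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils import check_random_state
from statsmodels.stats.multitest import multipletests

from .io import IntensityTable

logger = logging.getLogger("proxitome")

#: smallest positive float — the p→0 convention for zero-variance separations
P_FLOOR = float(np.finfo(float).tiny)

CONTRAST_COLUMNS = (
    "protein_id",
    "log2fc",
    "p_value",
    "n_obs_A",
    "n_obs_B",
    "n_imputed_A",
    "n_imputed_B",
    "is_hit",
)


# ----------------------------------------------------------------------
# sklearn-style estimators
# ----------------------------------------------------------------------


class MedianShiftNormalizer(TransformerMixin, BaseEstimator):
    """Shift each sample (row) so its median equals the grand median.

    The grand median is the median of per-sample medians, computed over
    observed (non-NaN) entries at ``fit`` time. NaNs are passed through.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D samples × proteins matrix")
        n_obs = np.sum(~np.isnan(X), axis=1)
        if np.any(n_obs == 0):
            raise ValueError(
                f"samples with zero observed values: rows {list(np.flatnonzero(n_obs == 0))}"
            )
        medians = np.nanmedian(X, axis=1)
        self.target_median_ = float(np.median(medians))
        self.offsets_ = medians - self.target_median_
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X - self.offsets_[:, None]


class DownshiftImputer(TransformerMixin, BaseEstimator):
    """Fill NaNs per sample from a down-shifted narrow normal.

    For each sample (row) with observed mean m and standard deviation s,
    missing cells are drawn from N(m − shift_sd·s, (width_sd·s)²). Samples
    with fewer than two observed values fall back to the global mean/sd with
    a logged warning.

    Parameters
    ----------
    shift_sd : float, default 1.8
        Down-shift of the imputation distribution, in units of the sample sd.
    width_sd : float, default 0.3
        Width of the imputation distribution, in units of the sample sd.
    random_state : int, RandomState or None
        Seed for reproducible draws.
    """

    def __init__(self, shift_sd: float = 1.8, width_sd: float = 0.3, random_state=None):
        self.shift_sd = shift_sd
        self.width_sd = width_sd
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D samples × proteins matrix")
        obs = ~np.isnan(X)
        global_mean = float(np.nanmean(X)) if obs.any() else 0.0
        global_sd = float(np.nanstd(X, ddof=1)) if obs.sum() > 1 else 1.0
        means = np.empty(X.shape[0])
        sds = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            row = X[i, obs[i]]
            if row.size < 2:
                logger.warning(
                    "sample row %d has %d observed values; imputing from "
                    "global statistics",
                    i,
                    row.size,
                )
                means[i], sds[i] = global_mean, global_sd
            else:
                means[i], sds[i] = row.mean(), row.std(ddof=1)
        self.impute_means_ = means - self.shift_sd * sds
        self.impute_sds_ = self.width_sd * sds
        return self

    def transform(self, X):
        X = np.array(X, dtype=float, copy=True)
        rng = check_random_state(self.random_state)
        self.imputed_mask_ = np.isnan(X)
        for i in range(X.shape[0]):
            miss = self.imputed_mask_[i]
            if miss.any():
                X[i, miss] = rng.normal(
                    self.impute_means_[i], self.impute_sds_[i], size=int(miss.sum())
                )
        return X


class GroupContrast(BaseEstimator):
    """Per-feature Welch t contrast between two groups of samples.

    ``fit(X, y)`` takes a complete samples × proteins matrix and a binary
    group label vector; fitted attributes are ``log2fc_`` (mean of group A
    minus mean of group B) and ``p_value_`` (two-sided Welch t-test).

    Degenerate features with zero variance in both groups get p = 1 when the
    means agree and the machine-minimum p otherwise (perfect separation; the
    event is logged).
    """

    def __init__(self, group_a=1, group_b=0):
        self.group_a = group_a
        self.group_b = group_b

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        a = X[y == self.group_a]
        b = X[y == self.group_b]
        if a.shape[0] < 2 or b.shape[0] < 2:
            raise ValueError("both groups need at least two samples")
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValueError("contrast input must be complete; impute first")
        self.log2fc_ = a.mean(axis=0) - b.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
        degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
        if degenerate.any():
            n_sep = int((degenerate & (self.log2fc_ != 0)).sum())
            if n_sep:
                logger.info(
                    "%d features with zero variance in both groups and unequal "
                    "means; p set to machine minimum",
                    n_sep,
                )
            p = np.where(degenerate, np.where(self.log2fc_ == 0, 1.0, P_FLOOR), p)
        p = np.where(p == 0, P_FLOOR, p)
        self.p_value_ = p
        return self


# ----------------------------------------------------------------------
# Domain-level results
# ----------------------------------------------------------------------


@dataclass
class ContrastResult:
    """One two-group comparison: per-protein log2fc, p-value and provenance."""

    table: pd.DataFrame  # index protein_id; log2fc, p_value, n_obs_*, n_imputed_*
    label: str = "contrast"
    condition: str = ""
    lfc_cut: float = 1.0
    p_cut: float = 0.05
    direction: str = "up"

    def __post_init__(self) -> None:
        self._flag_hits()

    def _flag_hits(self) -> None:
        t = self.table
        if self.direction == "up":
            t["is_hit"] = (t["log2fc"] > self.lfc_cut) & (t["p_value"] < self.p_cut)
        elif self.direction == "down":
            t["is_hit"] = (t["log2fc"] < -self.lfc_cut) & (t["p_value"] < self.p_cut)
        else:
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")

    @property
    def proteins(self) -> list[str]:
        return list(self.table.index)

    @property
    def hits(self) -> set[str]:
        return set(self.table.index[self.table["is_hit"]])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.reset_index()
        out = out.rename(columns={out.columns[0]: "protein_id"})
        return out[list(CONTRAST_COLUMNS)]

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class HitSet:
    """Proteins passing the dual enrichment cutoff for one variant/condition."""

    variant: str
    condition: str
    proteins: frozenset = field(default_factory=frozenset)
    lfc_cut: float = 1.0
    p_cut: float = 0.05
    direction: str = "up"

    def __len__(self) -> int:
        return len(self.proteins)

    def __contains__(self, pid: str) -> bool:
        return pid in self.proteins


# ----------------------------------------------------------------------
# IntensityTable-level operations
# ----------------------------------------------------------------------


def normalize_intensities(table: IntensityTable) -> IntensityTable:
    """Median-shift normalize every sample column (see MedianShiftNormalizer)."""
    X = table.values.to_numpy().T  # samples × proteins
    n_obs = np.sum(~np.isnan(X), axis=1)
    if np.any(n_obs == 0):
        bad = [table.sample_ids[i] for i in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"samples with zero observed values: {bad}")
    norm = MedianShiftNormalizer().fit(X)
    values = pd.DataFrame(
        norm.transform(X).T, index=table.values.index, columns=table.values.columns
    )
    return IntensityTable(values, table.metadata.copy(), table.imputed.copy())


def impute_missing(
    table: IntensityTable,
    shift_sd: float = 1.8,
    width_sd: float = 0.3,
    seed: int | None = None,
) -> IntensityTable:
    """Impute missing cells per sample from a down-shifted normal.

    Returns a complete table whose ``imputed`` mask records every filled cell.
    Observed values are untouched.
    """
    X = table.values.to_numpy().T
    imp = DownshiftImputer(shift_sd=shift_sd, width_sd=width_sd, random_state=seed)
    filled = imp.fit(X).transform(X)
    values = pd.DataFrame(
        filled.T, index=table.values.index, columns=table.values.columns
    )
    new_mask = pd.DataFrame(
        imp.imputed_mask_.T, index=table.values.index, columns=table.values.columns
    )
    return IntensityTable(values, table.metadata.copy(), table.imputed | new_mask)


def test_contrast(
    table: IntensityTable,
    group_a: list[str],
    group_b: list[str],
    *,
    label: str = "contrast",
    condition: str = "",
    lfc_cut: float = 1.0,
    p_cut: float = 0.05,
    min_observed: int = 2,
    add_bh: bool = False,
) -> ContrastResult:
    """Welch t contrast of group A over group B on an imputed table.

    Proteins observed (pre-imputation) in fewer than ``min_observed`` samples
    across the whole contrast are dropped before testing, so no test is
    driven purely by imputed values on both sides.
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValueError(f"groups overlap: {sorted(set_a & set_b)}")
    unknown = (set_a | set_b) - set(table.sample_ids)
    if unknown:
        raise ValueError(f"unknown samples: {sorted(unknown)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least two samples")

    cols = list(group_a) + list(group_b)
    sub = table.values[cols]
    if sub.isna().any().any():
        raise ValueError("contrast input contains missing values; impute first")
    observed = table.observed_mask[cols]
    keep = observed.sum(axis=1) >= min_observed
    if (~keep).any():
        logger.info(
            "%s: dropping %d proteins observed in < %d samples",
            label,
            int((~keep).sum()),
            min_observed,
        )
    sub = sub.loc[keep]

    X = sub.to_numpy().T  # samples × proteins
    y = np.array([1] * len(group_a) + [0] * len(group_b))
    est = GroupContrast().fit(X, y)

    imput = table.imputed.loc[keep]
    obs = table.observed_mask.loc[keep]
    out = pd.DataFrame(
        {
            "log2fc": est.log2fc_,
            "p_value": est.p_value_,
            "n_obs_A": obs[list(group_a)].sum(axis=1).to_numpy(),
            "n_obs_B": obs[list(group_b)].sum(axis=1).to_numpy(),
            "n_imputed_A": imput[list(group_a)].sum(axis=1).to_numpy(),
            "n_imputed_B": imput[list(group_b)].sum(axis=1).to_numpy(),
        },
        index=sub.index,
    )
    if add_bh:
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return ContrastResult(
        out, label=label, condition=condition, lfc_cut=lfc_cut, p_cut=p_cut
    )


def call_hits(
    result: ContrastResult,
    lfc_cut: float = 1.0,
    p_cut: float = 0.05,
    *,
    variant: str | None = None,
    direction: str = "up",
) -> HitSet:
    """Apply the dual cutoff (log2fc strictly > lfc_cut, p strictly < p_cut).

    ``direction='down'`` collects depletion hits (log2fc < −lfc_cut) instead;
    enrichment and depletion are always reported as separate sets.
    """
    updated = replace(
        result, table=result.table, lfc_cut=lfc_cut, p_cut=p_cut, direction=direction
    )
    result.table = updated.table
    result.lfc_cut, result.p_cut, result.direction = lfc_cut, p_cut, direction
    return HitSet(
        variant=variant if variant is not None else result.label,
        condition=result.condition,
        proteins=frozenset(updated.hits),
        lfc_cut=lfc_cut,
        p_cut=p_cut,
        direction=direction,
    )
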