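import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proxitome import (
    AnnotationTable,
    GeneSet,
    GeneSetCollection,
    HitSet,
    SimConfig,
    compartment_shift,
    complex_hit_counts,
    impute_missing,
    normalize_intensities,
    overrepresentation,
    simulate_turboid,
    submito_profile,
)
from proxitome import test_contrast as welch_contrast

from conftest import contrast_from_stats


def _result_with_lfc(lfc_by_protein):
    return contrast_from_stats({p: (v, 0.5) for p, v in lfc_by_protein.items()})


def _exact_mw_p(labeled, background):
    """One-sided Mann–Whitney p by exhaustive relabeling (tie-free inputs)."""
    pooled = list(labeled) + list(background)
    n1 = len(labeled)

    def u_stat(group1, group2):
        return sum(1 for x in group1 for y in group2 if x > y)

    observed = u_stat(labeled, background)
    count = total = 0
    for combo in combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in combo]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in combo]
        if u_stat(g1, g2) >= observed:
            count += 1
        total += 1
    return count / total


class TestCompartmentShift:
    def test_label_covering_everything_is_degenerate(self):
        res = _result_with_lfc({"P1": 1.0, "P2": 2.0})
        ann = AnnotationTable({"P1": {"mitochondrial"}, "P2": {"mitochondrial"}})
        with pytest.raises(ValueError, match="background"):
            compartment_shift(res, ann, "mitochondrial")

    def test_unknown_label_rejected(self, toy_annotations):
        res = _result_with_lfc({"P1": 1.0, "P2": 2.0})
        with pytest.raises(ValueError, match="vocabulary"):
            compartment_shift(res, toy_annotations, "nucleolus")

    def test_exact_enumeration_small_case(self):
        # labeled (3,4,5) vs background (0,1,2): U = 9, exact one-sided
        # p = 1/C(6,3) = 0.05
        res = _result_with_lfc(
            {"L1": 3.0, "L2": 4.0, "L3": 5.0, "B1": 0.0, "B2": 1.0, "B3": 2.0}
        )
        ann = AnnotationTable({p: {"mitochondrial"} for p in ("L1", "L2", "L3")})
        shift = compartment_shift(res, ann, "mitochondrial")
        assert shift.u_statistic == 9.0
        assert shift.p_value == pytest.approx(0.05)
        assert shift.median_shift == pytest.approx(3.0)

    def test_matches_enumeration_oracle_at_small_n(self, rng):
        for _ in range(20):
            n1 = int(rng.integers(2, 5))
            n2 = int(rng.integers(2, 9 - n1))
            values = rng.permutation(20)[: n1 + n2].astype(float)
            labeled, background = values[:n1], values[n1:]
            mapping = {f"L{i}": v for i, v in enumerate(labeled)}
            mapping.update({f"B{i}": v for i, v in enumerate(background)})
            res = _result_with_lfc(mapping)
            ann = AnnotationTable({p: {"mitochondrial"} for p in mapping if p[0] == "L"})
            shift = compartment_shift(res, ann, "mitochondrial")
            assert shift.p_value == pytest.approx(
                _exact_mw_p(labeled, background), rel=1e-12
            )

    def test_mito_biased_bait_detected(self):
        pvals, medians = [], []
        for seed in range(10):
            cfg = SimConfig(
                n_proteins=600,
                variants=("mito_bait",),
                egf_states=("-",),
                frac_mitochondrial=0.15,
                interactor_bias={"mito_bait": ("mitochondrial", 40.0)},
                seed=seed,
            )
            table, truth = simulate_turboid(cfg)
            table = impute_missing(normalize_intensities(table), seed=seed)
            res = welch_contrast(
                table, table.samples_for("mito_bait"), table.samples_for("control")
            )
            shift = compartment_shift(res, truth.to_annotations(), "mitochondrial")
            pvals.append(shift.p_value)
            medians.append(shift.median_shift)
        assert np.median(medians) > 0
        assert np.median(pvals) < 0.05


class TestComplexHitCounts:
    def test_empty_hitset_gives_zeros(self, toy_annotations):
        hs = HitSet(variant="WT", condition="", proteins=frozenset())
        out = complex_hit_counts(hs, toy_annotations, ["complex_IV"])
        assert (out["n_hits"] == 0).all()

    def test_toy_counts(self, toy_annotations):
        hs = HitSet(variant="WT", condition="", proteins=frozenset({"P5", "P7", "P9"}))
        out = complex_hit_counts(hs, toy_annotations, ["complex_IV"])
        row = out[out["label"] == "complex_IV"].iloc[0]
        assert row["n_members"] == 3 and row["n_hits"] == 2

    def test_random_hitsets_match_intersection_oracle(self, rng):
        proteins = [f"P{i}" for i in range(200)]
        labels = {}
        complex_labels = ["complex_II", "complex_III", "complex_IV", "complex_V",
                         "complex_I_core", "complex_I_accessory", "complex_I_assembly"]
        for pid in proteins:
            if rng.random() < 0.4:
                labels[pid] = {complex_labels[int(rng.integers(len(complex_labels)))]}
        ann = AnnotationTable(labels)
        for _ in range(20):
            hits = set(rng.choice(proteins, size=30, replace=False))
            hs = HitSet(variant="V", condition="", proteins=frozenset(hits))
            out = complex_hit_counts(hs, ann, complex_labels[:4])
            for _, row in out.iterrows():
                members = {p for p, ls in labels.items() if row["label"] in ls}
                assert row["n_hits"] == len(members & hits)


class TestSubmitoProfile:
    def test_identical_lfc_gives_zero_difference(self, toy_annotations):
        res = _result_with_lfc({f"P{i}": 1.5 for i in range(1, 8)})
        out = submito_profile([res], toy_annotations)
        assert out["matrix_minus_ims"].iloc[0] == pytest.approx(0.0)

    def test_toy_difference(self, toy_annotations):
        lfc = {f"P{i}": 0.0 for i in range(1, 8)}
        lfc["P3"] = 2.0  # matrix
        lfc["P4"] = 1.0  # intermembrane space
        out = submito_profile([_result_with_lfc(lfc)], toy_annotations)
        row = out.iloc[0]
        assert row["mean_matrix"] == pytest.approx(2.0)
        assert row["mean_ims"] == pytest.approx(1.0)
        assert row["matrix_minus_ims"] == pytest.approx(1.0)

    def test_empty_subcompartment_reports_nan(self, caplog):
        ann = AnnotationTable({"P1": {"matrix"}})
        res = _result_with_lfc({"P1": 1.0, "P2": 0.0})
        with caplog.at_level("WARNING", logger="proxitome"):
            out = submito_profile([res], ann)
        assert np.isnan(out["mean_ims"].iloc[0])

    def test_matrix_biased_variant_exceeds_neutral(self):
        diffs = []
        for seed in range(10):
            cfg = SimConfig(
                n_proteins=600,
                variants=("matrix_bait", "neutral"),
                egf_states=("-",),
                frac_mitochondrial=0.25,
                interactor_bias={"matrix_bait": ("matrix", 40.0)},
                seed=100 + seed,
            )
            table, truth = simulate_turboid(cfg)
            table = impute_missing(normalize_intensities(table), seed=seed)
            ctrl = table.samples_for("control")
            results = [
                welch_contrast(
                    table, table.samples_for(v), ctrl, label=v
                )
                for v in ("matrix_bait", "neutral")
            ]
            out = submito_profile(results, truth.to_annotations())
            by = out.set_index("contrast")["matrix_minus_ims"]
            diffs.append(by["matrix_bait"] - by["neutral"])
        assert np.mean(diffs) > 0


class TestOverrepresentation:
    def _universe(self, n=10):
        return {f"P{i}" for i in range(n)}

    def test_complete_overlap_closed_form(self):
        hits = {"P0", "P1", "P2"}
        background = self._universe(6)
        sets = GeneSetCollection([GeneSet("s", "", sorted(hits))])
        out = overrepresentation(
            HitSet(variant="V", condition="", proteins=frozenset(hits)),
            background,
            sets,
        )
        # P(overlap = 3) when both set and hits have 3 of 6: 1 / C(6,3)
        assert out["p_value"].iloc[0] == pytest.approx(1 / math.comb(6, 3))

    def test_disjoint_set_gives_p_one(self):
        background = self._universe(10)
        sets = GeneSetCollection([GeneSet("s", "", ["P7", "P8", "P9"])])
        out = overrepresentation(
            HitSet(variant="V", condition="", proteins=frozenset({"P0", "P1"})),
            background,
            sets,
        )
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_exhaustive_enumeration_on_five_protein_universe(self):
        background = {f"P{i}" for i in range(5)}
        gene_set = {"P0", "P1", "P2"}
        hits = {"P0", "P1", "P3"}
        k_obs = len(gene_set & hits)
        # enumerate every possible hit draw of the same size
        n_hits = len(hits)
        total = better = 0
        for combo in combinations(sorted(background), n_hits):
            total += 1
            if len(set(combo) & gene_set) >= k_obs:
                better += 1
        exact = better / total
        out = overrepresentation(
            HitSet(variant="V", condition="", proteins=frozenset(hits)),
            background,
            GeneSetCollection([GeneSet("s", "", sorted(gene_set))]),
        )
        assert out["p_value"].iloc[0] == pytest.approx(exact, rel=1e-12)

    def test_hit_outside_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            overrepresentation(
                HitSet(variant="V", condition="", proteins=frozenset({"X"})),
                self._universe(5),
                GeneSetCollection([GeneSet("s", "", ["P0"])]),
            )

    def test_bh_is_monotone_in_p(self, rng):
        background = {f"P{i}" for i in range(100)}
        sets = []
        for i in range(20):
            members = sorted(rng.choice(sorted(background), 15, replace=False))
            sets.append(GeneSet(f"s{i}", "", members))
        hits = frozenset(rng.choice(sorted(background), 20, replace=False))
        out = overrepresentation(
            HitSet(variant="V", condition="", proteins=hits),
            background,
            GeneSetCollection(sets),
        )
        assert (out["q_value"] >= out["p_value"] - 1e-15).all()
        # sorted by p, q never inverts the ordering
        assert (out["q_value"].diff().dropna() >= -1e-12).all()
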