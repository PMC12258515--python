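import numpy as np
import pandas as pd
import pytest

from proxitome import (
    ScreenCounts,
    ScreenSpecificityModel,
    SpecificityMatrix,
    build_matrix,
    make_true_matrix,
    score_proteome,
    score_window,
    simulate_screen,
    tight_binders,
)
from proxitome.specificity import AMINO_ACIDS, flank_positions


def _counts_from_pairs(pairs, alphabet=AMINO_ACIDS):
    """pairs: list of (sequence, input_count, selected_count)."""
    return ScreenCounts(
        pd.DataFrame(pairs, columns=["sequence", "input_count", "selected_count"]),
        alphabet=alphabet,
    )


def _zero_matrix(half_width=2, domain="SH2"):
    positions = flank_positions(half_width)
    weights = pd.DataFrame(
        0.0, index=list(AMINO_ACIDS), columns=positions
    )
    return SpecificityMatrix(domain=domain, weights=weights)


class TestScreenCountsValidation:
    def test_center_must_be_phosphotyrosine(self):
        with pytest.raises(ValueError, match="phosphotyrosine"):
            _counts_from_pairs([("AAAAA", 1, 1)])

    def test_residue_outside_alphabet_named(self):
        with pytest.raises(ValueError, match="AZyAA"):
            _counts_from_pairs([("AZyAA", 1, 1)])


class TestBuildMatrix:
    def test_null_screen_gives_zero_weights(self, rng):
        seqs = [
            "".join(rng.choice(list(AMINO_ACIDS), 2)) + "y"
            + "".join(rng.choice(list(AMINO_ACIDS), 2))
            for _ in range(500)
        ]
        counts = _counts_from_pairs([(s, 10, 10) for s in seqs])
        m = build_matrix(counts)
        assert np.allclose(m.weights.to_numpy(), 0.0, atol=1e-12)

    def test_doubled_residue_frequency_gives_log2_weight(self):
        # position -1 enumerates all residues uniformly in the input;
        # Glu peptides double their reads in the selected pool
        pairs = []
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                sel = 200 if a == "E" else 100
                pairs.append((f"{a}y{b}", 100, sel))
        counts = _counts_from_pairs(pairs)
        m = build_matrix(counts, pseudocount=1.0)
        # independent frequency arithmetic: input f=1/20; selected
        # f = 4000/42000; pseudocount shifts both slightly
        n_in, n_sel = 20 * 20 * 100, 42000
        f_in = (20 * 100 + 1) / (n_in + 20)
        f_sel = (20 * 200 + 1) / (n_sel + 20)
        expected_uncentered = np.log2(f_sel / f_in)
        centering = m.weights[-1].mean()  # zero after centering by definition
        assert centering == pytest.approx(0.0, abs=1e-12)
        others = [
            np.log2(((20 * 100 + 1) / (n_sel + 20)) / f_in) for _ in range(19)
        ]
        mean_uncentered = (expected_uncentered + sum(others)) / 20
        assert m.weights.at["E", -1] == pytest.approx(
            expected_uncentered - mean_uncentered, abs=1e-9
        )
        # and the headline effect is close to log2(2) = 1
        assert expected_uncentered == pytest.approx(1.0, abs=0.12)

    def test_zero_reads_rejected(self):
        counts = _counts_from_pairs([("AyA", 0, 0)])
        with pytest.raises(ValueError, match="reads"):
            build_matrix(counts)

    def test_scale_invariance(self, rng):
        seqs = [
            "".join(rng.choice(list(AMINO_ACIDS), 2)) + "y"
            + "".join(rng.choice(list(AMINO_ACIDS), 2))
            for _ in range(300)
        ]
        base = [
            (s, int(rng.integers(50, 200)), int(rng.integers(50, 200)))
            for s in seqs
        ]
        scaled = [(s, 10 * i, 10 * j) for s, i, j in base]
        w1 = build_matrix(_counts_from_pairs(base)).weights.to_numpy()
        w2 = build_matrix(_counts_from_pairs(scaled)).weights.to_numpy()
        assert np.abs(w1 - w2).max() < 1e-2  # pseudocount-level perturbation

    def test_round_trip_through_files(self, tmp_path, rng):
        m = make_true_matrix(half_width=3, seed=8, domain="N-SH2")
        m.write(tmp_path / "pwm.tsv")
        back = SpecificityMatrix.read(tmp_path / "pwm.tsv")
        assert back.domain == "N-SH2"
        assert np.allclose(back.weights.to_numpy(), m.weights.to_numpy())
        assert back.positions == m.positions


class TestScoreWindow:
    def test_zero_matrix_scores_zero(self):
        m = _zero_matrix()
        assert score_window(m, "ACyDE") == 0.0

    def test_hand_summed_toy_matrix(self):
        # weights only at positions -1, +1, +2: +1, -0.5, +2 for the
        # window's residues -> score 2.5
        positions = [-2, -1, 1, 2]
        weights = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=positions)
        weights.at["C", -1] = 1.0
        weights.at["D", 1] = -0.5
        weights.at["E", 2] = 2.0
        m = SpecificityMatrix(domain="toy", weights=weights)
        assert score_window(m, "ACyDE") == pytest.approx(2.5)

    def test_fully_padded_window_scores_zero(self, rng):
        m = make_true_matrix(half_width=2, seed=1)
        assert score_window(m, "--y--") == 0.0

    def test_partial_padding_contributes_zero(self, rng):
        m = make_true_matrix(half_width=2, seed=1)
        full = score_window(m, "ACyDE")
        left_pad = score_window(m, "--yDE")
        expected = full - float(m.weights.at["A", -2]) - float(m.weights.at["C", -1])
        assert left_pad == pytest.approx(expected)

    def test_window_length_mismatch(self):
        m = _zero_matrix(half_width=2)
        with pytest.raises(ValueError, match="length"):
            score_window(m, "AyA")

    def test_non_alphabet_residue_rejected(self):
        m = _zero_matrix(half_width=1)
        with pytest.raises(ValueError, match="'Z'"):
            score_window(m, "ZyA")

    def test_additivity_over_positions(self, rng):
        m = make_true_matrix(half_width=3, seed=4)
        window = "ACDyEFG"
        total = score_window(m, window)
        parts = 0.0
        for i, pos in enumerate(m.positions):
            single = ["-"] * 7
            idx = pos + 3
            single[idx] = window[idx]
            single[3] = "y"
            parts += score_window(m, "".join(single))
        assert total == pytest.approx(parts)


class TestScoreProteome:
    def _sites(self, windows):
        return pd.DataFrame(
            {
                "protein_id": [f"P{i}" for i in range(len(windows))],
                "position": list(range(10, 10 + len(windows))),
                "window": windows,
            }
        )

    def test_single_site_ranks_100(self):
        m = make_true_matrix(half_width=2, seed=0)
        out = score_proteome(m, m, self._sites(["ACyDE"]))
        assert out["percentile_N"].iloc[0] == 100.0
        assert out["percentile_C"].iloc[0] == 100.0

    def test_rescoring_is_bitwise_identical(self, rng):
        m_n = make_true_matrix(half_width=2, seed=1)
        m_c = make_true_matrix(half_width=2, seed=2)
        windows = [
            "".join(rng.choice(list(AMINO_ACIDS), 2)) + "y"
            + "".join(rng.choice(list(AMINO_ACIDS), 2))
            for _ in range(100)
        ]
        sites = self._sites(windows)
        out1 = score_proteome(m_n, m_c, sites)
        out2 = score_proteome(m_n, m_c, sites)
        pd.testing.assert_frame_equal(out1, out2)

    def test_deterministic_ordering(self, rng):
        m_n = make_true_matrix(half_width=2, seed=1)
        m_c = make_true_matrix(half_width=2, seed=2)
        out = score_proteome(m_n, m_c, self._sites(["AAyAA", "CCyCC", "DDyDD"]))
        best = out[["score_N", "score_C"]].max(axis=1)
        assert list(best) == sorted(best, reverse=True)


class TestTightBinders:
    def _scored(self, n=20):
        # distinct descending scores -> distinct percentiles
        scores = np.arange(n, 0, -1, dtype=float)
        return pd.DataFrame(
            {
                "protein_id": [f"P{i}" for i in range(n)],
                "position": range(n),
                "window": ["AAyAA"] * n,
                "score_N": scores,
                "score_C": scores - 100.0,
                "percentile_N": (np.argsort(np.argsort(scores)) / (n - 1)) * 100,
                "percentile_C": np.zeros(n),
            }
        )

    def test_cut_zero_keeps_all(self):
        scored = self._scored()
        assert len(tight_binders(scored, 0.0)) == len(scored)

    def test_cut_100_keeps_top(self):
        out = tight_binders(self._scored(), 100.0)
        assert list(out["protein_id"]) == ["P0"]

    def test_cut_90_matches_sort_and_slice_oracle(self):
        scored = self._scored(20)
        out = tight_binders(scored, 90.0)
        oracle = scored.sort_values("score_N", ascending=False).head(2)
        assert set(out["protein_id"]) == set(oracle["protein_id"])

    def test_hitset_restriction(self):
        scored = self._scored()
        out = tight_binders(scored, 0.0, proteins={"P3", "P5"})
        assert set(out["protein_id"]) == {"P3", "P5"}


def test_estimator_facade_fit_and_score(rng):
    true = make_true_matrix(half_width=2, seed=3)
    counts = simulate_screen(
        true, n_library=2000, n_reads_input=50_000, n_reads_selected=50_000, seed=1
    )
    model = ScreenSpecificityModel(domain="N-SH2").fit(counts)
    assert model.matrix_.domain == "N-SH2"
    scores = model.score_windows(["AAyAA", "CCyCC"])
    assert scores[0] == pytest.approx(score_window(model.matrix_, "AAyAA"))
    # sklearn param plumbing
    assert model.get_params()["pseudocount"] == 1.0
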