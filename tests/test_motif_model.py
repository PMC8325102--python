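"""Motif model: PWM construction, scoring, analytic identities."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinasecall import (
    ALPHABET,
    PAD,
    PositionWeightMatrix,
    SequenceWindow,
    ValidationError,
    build_pwm,
    compute_background,
    extract_window,
    score_sites,
    score_window,
    uniform_background,
)


def brute_force_pwm(windows, background, alphabet):
    """Independent re-derivation of the PWM formulas with plain loops.

    Pad mass at a column is redistributed by the background, matching the
    package's terminus convention; for pad-free columns this is exactly
    p(x,i) = (f + p(x)*eps) / (N + eps), w = log2(p(x,i)/p(x)).
    """
    L = len(windows[0])
    n = len(windows)
    eps = math.sqrt(n)
    weights = {}
    for i in range(L):
        counts = {x: 0 for x in alphabet}
        n_pad = 0
        for w in windows:
            if w[i] in alphabet:
                counts[w[i]] += 1
            else:
                n_pad += 1
        for x in alphabet:
            p_xi = (counts[x] + background[x] * (eps + n_pad)) / (n + eps)
            weights[(x, i + 1)] = math.log2(p_xi / background[x])
    return weights


class TestToyOracle:
    def test_counts_and_epsilon(self, toy_pwm):
        assert toy_pwm.n_sequences == 4
        assert toy_pwm.epsilon == 2.0

    def test_weights_match_hand_arithmetic(self, toy_pwm):
        assert toy_pwm.weight("A", 1) == pytest.approx(math.log2(5 / 3), abs=1e-12)
        assert toy_pwm.weight("A", 2) == pytest.approx(math.log2(4 / 3), abs=1e-12)
        assert toy_pwm.weight("R", 2) == pytest.approx(math.log2(2 / 3), abs=1e-12)

    def test_scores_match_hand_arithmetic(self, toy_pwm):
        assert score_window(toy_pwm, "AA").lam == pytest.approx(
            math.log2(5 / 3) + math.log2(4 / 3), abs=1e-12
        )
        assert score_window(toy_pwm, "RR").lam == pytest.approx(
            -math.log2(3) - math.log2(3 / 2), abs=1e-12
        )


class TestBackground:
    def test_equal_counts_give_uniform(self):
        proteome = {"P1": ALPHABET * 3}
        bg = compute_background(proteome)
        assert np.allclose(bg, 0.05, atol=1e-15)
        assert bg.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_count_residue_gets_floor(self, caplog):
        proteome = {"P1": "A" * 100}
        with caplog.at_level("WARNING"):
            bg = compute_background(proteome)
        assert (bg > 0).all()
        assert bg.sum() == pytest.approx(1.0, abs=1e-12)
        assert bg["A"] == pytest.approx((100) / (100 + 19), rel=1e-12)
        assert "floor" in caplog.text

    def test_nonstandard_residues_excluded(self):
        bg_plain = compute_background({"P1": ALPHABET})
        bg_with_x = compute_background({"P1": ALPHABET + "XXXXUUB"})
        pd.testing.assert_series_equal(bg_plain, bg_with_x)

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValidationError):
            compute_background({})


class TestExtractWindow:
    def test_position_one_has_seven_left_pads(self):
        win = extract_window("MKSPQRSTVWYLAND", 1)
        assert win.flanks[:7] == PAD * 7
        assert win.center_residue == "M"

    def test_interior_position_has_no_pads(self):
        win = extract_window("MKSPQRSTVWYLAND", 8)  # 15-mer, center
        assert PAD not in win.flanks
        assert win.flanks == "MKSPQRS" + "VWYLAND"

    def test_near_terminus_read_off(self):
        win = extract_window("MKSPQRSTVWYLAND", 3)
        assert win.center_residue == "S"
        assert win.flanks[:7] == PAD * 5 + "MK"
        assert win.flanks[7:] == "PQRSTVW"

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError, match="out of bounds"):
            extract_window("MKS", 4, protein_id="P1")
        with pytest.raises(ValidationError):
            extract_window("MKS", 0)


class TestBuildPwm:
    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            build_pwm([], uniform_background())

    def test_wrong_length_window_rejected(self):
        bg = pd.Series(0.5, index=["A", "R"])
        with pytest.raises(ValidationError, match="1"):
            build_pwm(["AA", "AAA"], bg)

    def test_column_at_background_gives_zero_weights(self):
        # every column has exactly the background composition -> p(x,i)=p(x)
        bg = pd.Series(0.5, index=["A", "R"])
        pwm = build_pwm(["AA", "AR", "RA", "RR"], bg)
        assert np.allclose(pwm.weights.to_numpy(), 0.0, atol=1e-15)
        assert score_window(pwm, "AR").lam == pytest.approx(0.0, abs=1e-15)

    def test_epsilon_is_sqrt_n(self):
        wins = ["A" * 15] * 100
        pwm = build_pwm(wins, uniform_background())
        assert pwm.epsilon == 10.0

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        """Random small training sets (N<=50, mixed padding) match the
        independently coded formulas within 1e-9."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 51))
        letters = list(ALPHABET)
        wins = []
        for _ in range(n):
            chars = [letters[i] for i in rng.integers(0, 20, size=15)]
            n_left = int(rng.integers(0, 4))
            n_right = int(rng.integers(0, 4))
            w = PAD * n_left + "".join(chars[n_left : 15 - n_right]) + PAD * n_right
            wins.append(w)
        bg = uniform_background()
        pwm = build_pwm(wins, bg)
        oracle = brute_force_pwm(wins, bg, ALPHABET)
        for off in pwm.offsets:
            # oracle columns are 1..15 over the raw string; center is column 8
            raw_col = off + 8
            for x in ALPHABET:
                assert pwm.weight(x, off) == pytest.approx(
                    oracle[(x, raw_col)], abs=1e-9
                )

    @pytest.mark.parametrize("seed", range(8))
    def test_column_normalization_and_finiteness(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(1, 51))
        wins = []
        letters = list(ALPHABET)
        for _ in range(n):
            chars = "".join(letters[i] for i in rng.integers(0, 20, size=15))
            pad = int(rng.integers(0, 6))
            wins.append(PAD * pad + chars[pad:])
        pwm = build_pwm(wins, uniform_background())
        sums = pwm.probs.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert np.isfinite(pwm.weights.to_numpy()).all()
        assert pwm.epsilon == math.sqrt(n)


class TestScoreWindow:
    def test_all_pad_window_scores_zero(self, toy_pwm):
        pwm = build_pwm(["A" * 15] * 4, uniform_background())
        win = SequenceWindow("P", 1, "S", PAD * 14)
        ms = score_window(pwm, win)
        assert ms.lam == 0.0
        assert ms.n_scored_positions == 0

    def test_pad_positions_contribute_zero(self):
        bg = uniform_background()
        wins = ["ACDEFGHSKLMNPQR"] * 9
        pwm = build_pwm(wins, bg)
        full = score_window(pwm, "ACDEFGHSKLMNPQR").lam
        left_padded = score_window(pwm, PAD * 3 + "EFGHSKLMNPQR").lam
        # removing the first three positions removes exactly their weights
        removed = sum(pwm.weight(r, o) for r, o in zip("ACD", [-7, -6, -5]))
        assert left_padded == pytest.approx(full - removed, abs=1e-12)

    def test_nonalphabet_flank_skipped_with_warning(self, caplog):
        pwm = build_pwm(["ACDEFGHSKLMNPQR"] * 4, uniform_background())
        with caplog.at_level("WARNING"):
            ms = score_window(pwm, "XCDEFGHSKLMNPQR")
        assert ms.n_scored_positions == 13
        with pytest.raises(ValidationError):
            score_window(pwm, "XCDEFGHSKLMNPQR", unknown_policy="error")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_additivity_single_substitution(self, seed):
        """Mutating one flank residue changes lambda by w(alt)-w(ref)."""
        rng = np.random.default_rng(seed)
        letters = list(ALPHABET)
        wins = [
            "".join(letters[i] for i in rng.integers(0, 20, size=15)) for _ in range(20)
        ]
        pwm = build_pwm(wins, uniform_background())
        win = SequenceWindow.from_string(
            "".join(letters[i] for i in rng.integers(0, 20, size=15))
        )
        offs = [o for o in win.offsets]
        off = offs[int(rng.integers(0, len(offs)))]
        ref = win.residue_at(off)
        alt = letters[int(rng.integers(0, 20))]
        mutated = win.substitute(off, alt)
        delta = score_window(pwm, mutated).lam - score_window(pwm, win).lam
        assert delta == pytest.approx(
            pwm.weight(alt, off) - pwm.weight(ref, off), abs=1e-12
        )


class TestScoreSites:
    def test_empty_site_table(self, toy_pwm, small_proteome):
        pwm = build_pwm(["ACDEFGHSKLMNPQR"] * 4, uniform_background())
        sites = pd.DataFrame(columns=["site_id", "protein_id", "position", "residue"])
        scores, errors = score_sites(pwm, sites, small_proteome)
        assert scores.empty and errors.empty

    def test_mismatched_row_excluded_and_reported(self, small_proteome):
        pwm = build_pwm(["ACDEFGHSKLMNPQR"] * 4, uniform_background())
        pid = next(iter(small_proteome))
        seq = small_proteome[pid]
        pos = 20
        good_res = seq[pos - 1]
        bad_res = "S" if good_res != "S" else "T"
        sites = pd.DataFrame(
            {
                "site_id": ["ok", "bad"],
                "protein_id": [pid, pid],
                "position": [pos, pos],
                "residue": [good_res, bad_res],
            }
        )
        scores, errors = score_sites(pwm, sites, small_proteome)
        assert len(scores) == 1 and scores["site_id"].iloc[0] == "ok"
        assert len(errors) == 1 and "mismatch" in errors["reason"].iloc[0]

    def test_ordering_matches_input(self, small_proteome):
        pwm = build_pwm(["ACDEFGHSKLMNPQR"] * 4, uniform_background())
        rows = []
        for pid, seq in list(small_proteome.items())[:5]:
            rows.append((f"{pid}_x", pid, 10, seq[9]))
        sites = pd.DataFrame(rows, columns=["site_id", "protein_id", "position", "residue"])
        scores, _ = score_sites(pwm, sites, small_proteome)
        assert list(scores["site_id"]) == list(sites["site_id"])


class TestSerialization:
    def test_tsv_round_trip_lossless(self, tmp_path):
        rng = np.random.default_rng(3)
        letters = list(ALPHABET)
        wins = [
            PAD * (i % 3) + "".join(letters[j] for j in rng.integers(0, 20, size=15))[i % 3 :]
            for i in range(25)
        ]
        bg = compute_background({"P": "".join(letters[j] for j in rng.integers(0, 20, size=5000))})
        pwm = build_pwm(wins, bg)
        path = tmp_path / "pwm.tsv"
        pwm.to_tsv(path)
        loaded = PositionWeightMatrix.from_tsv(path)
        assert loaded.n_sequences == pwm.n_sequences
        assert loaded.epsilon == pwm.epsilon
        pd.testing.assert_frame_equal(loaded.counts, pwm.counts)
        assert np.allclose(loaded.weights.to_numpy(), pwm.weights.to_numpy(), atol=0, rtol=0)
        assert np.allclose(loaded.background.to_numpy(), pwm.background.to_numpy(), atol=0, rtol=0)
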