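"""Synthetic generators: determinism, frequency consistency, truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from kinasecall import (
    ALPHABET,
    GroundTruthMotif,
    SyntheticTruthLabels,
    ValidationError,
    acidophilic_motif,
    build_pwm,
    generate_proteome,
    human_background,
    plant_substrates,
    sample_training_windows,
    score_window,
    simulate_bioid_matrix,
    simulate_mutations,
    simulate_perturbation_table,
    uniform_background,
)
from kinasecall.synth import FLANK_OFFSETS


def empty_truth(seed=0):
    return SyntheticTruthLabels(set(), set(), 0.0, seed)


class TestGenerateProteome:
    def test_contract_single_protein(self):
        prot = generate_proteome(1, mean_length=30, residue_freqs=uniform_background(), seed=7)
        assert len(prot) == 1
        seq = next(iter(prot.values()))
        assert len(seq) >= 30
        assert set(seq) <= set(ALPHABET)

    def test_determinism(self):
        a = generate_proteome(100, seed=1)
        b = generate_proteome(100, seed=1)
        assert a == b
        c = generate_proteome(100, seed=2)
        assert a != c

    def test_empirical_frequencies_match_input(self):
        prot = generate_proteome(500, mean_length=400, residue_freqs=human_background(), seed=3)
        counts = pd.Series(list("".join(prot.values()))).value_counts(normalize=True)
        for aa, f in human_background().items():
            assert abs(counts.get(aa, 0.0) - f) < 0.01

    def test_unnormalized_freqs_rejected_naming_sum(self):
        bad = human_background() * 1.1
        with pytest.raises(ValidationError, match="sum"):
            generate_proteome(10, residue_freqs=bad, seed=0)

    def test_n_zero_rejected(self):
        with pytest.raises(ValidationError):
            generate_proteome(0, seed=0)


class TestTrainingWindows:
    def test_degenerate_column_fixed_residue(self):
        motif = GroundTruthMotif.from_anchors({-3: {"R": 1.0}}, background=uniform_background())
        wins = sample_training_windows(motif, 10, seed=5)
        assert all(w[4] == "R" for w in wins)  # offset -3 is string index 4
        assert all(len(w) == 15 for w in wins)
        assert all(w[7] in motif.center_residues for w in wins)

    def test_n_zero_rejected(self):
        with pytest.raises(ValidationError):
            sample_training_windows(acidophilic_motif(), 0)

    def test_empty_center_residues_rejected(self):
        with pytest.raises(ValidationError):
            GroundTruthMotif(acidophilic_motif().position_probs, center_residues="")

    def test_position_probs_must_normalize(self):
        probs = acidophilic_motif().position_probs.copy()
        probs.iloc[0, 0] += 0.01
        with pytest.raises(ValidationError, match="sum"):
            GroundTruthMotif(probs)

    def test_empirical_position_frequencies(self):
        motif = acidophilic_motif()
        wins = sample_training_windows(motif, 2000, seed=11)
        arr = np.array([list(w) for w in wins])
        flank_cols = list(range(7)) + list(range(8, 15))
        for col, off in zip(flank_cols, FLANK_OFFSETS):
            freqs = pd.Series(arr[:, col]).value_counts(normalize=True)
            for aa in ALPHABET:
                assert abs(freqs.get(aa, 0.0) - motif.position_probs.at[off, aa]) < 0.03

    def test_determinism(self):
        m = acidophilic_motif()
        assert sample_training_windows(m, 50, seed=9) == sample_training_windows(m, 50, seed=9)


@pytest.fixture(scope="module")
def proteome():
    return generate_proteome(80, mean_length=300, seed=21)


@pytest.fixture(scope="module")
def pert_sites():
    return pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(400)],
            "protein_id": [f"P{i % 40}" for i in range(400)],
            "position": 50,
            "residue": "S",
        }
    )


@pytest.fixture(scope="module")
def mut_scenario():
    prot = generate_proteome(40, mean_length=250, seed=31)
    return plant_substrates(prot, acidophilic_motif(), n_true=10, n_decoy=60, seed=31)


class TestPlantSubstrates:
    def test_no_true_sites(self, proteome):
        res = plant_substrates(proteome, acidophilic_motif(), n_true=0, n_decoy=40, seed=2)
        assert res.labels.true_substrate_sites == set()
        assert len(res.sites) == 40
        assert res.proteome == proteome  # nothing overwritten

    def test_bookkeeping_true_and_decoy_disjoint(self, proteome):
        res = plant_substrates(proteome, acidophilic_motif(), n_true=20, n_decoy=200, seed=2)
        true = res.labels.true_substrate_sites
        assert len(true) == 20
        assert len(res.sites) == 220
        decoys = set(res.sites["site_id"]) - true
        assert len(decoys) == 200 and not (true & decoys)
        # consistent truth: hosts of true sites are the interactors
        hosts = set(res.sites[res.sites["site_id"].isin(true)]["protein_id"])
        assert res.labels.true_interactors == hosts

    def test_site_table_matches_proteome(self, proteome):
        res = plant_substrates(proteome, acidophilic_motif(), n_true=15, n_decoy=100, seed=4)
        for row in res.sites.itertuples(index=False):
            assert res.proteome[row.protein_id][row.position - 1] == row.residue

    def test_true_sites_outscore_decoys(self, proteome):
        motif = acidophilic_motif()
        res = plant_substrates(proteome, motif, n_true=25, n_decoy=300, seed=6)
        # PWM trained on an independent motif sample
        pwm = build_pwm(sample_training_windows(motif, 1000, seed=999), human_background())
        from kinasecall.motif import extract_window

        def mean_score(ids):
            rows = res.sites[res.sites["site_id"].isin(ids)]
            lams = []
            for r in rows.itertuples(index=False):
                win = extract_window(res.proteome[r.protein_id], r.position)
                lams.append(score_window(pwm, win).lam)
            return np.mean(lams)

        true = res.labels.true_substrate_sites
        decoy = set(res.sites["site_id"]) - true
        assert mean_score(true) > mean_score(decoy) + 2

    def test_insufficient_positions_sized_error(self):
        tiny = {"P1": "MKSA"}  # too short for any interior window
        with pytest.raises(ValidationError, match="decoy|true"):
            plant_substrates(tiny, acidophilic_motif(), n_true=0, n_decoy=5, seed=0)


class TestBioidMatrix:
    def test_no_detection_limit_means_no_missing(self):
        qm = simulate_bioid_matrix(
            [f"P{i}" for i in range(50)], empty_truth(),
            detection_limit_log2=-np.inf, seed=1,
        )
        assert qm.n_missing == 0

    def test_planted_effect_recovered_in_means(self):
        proteins = [f"P{i}" for i in range(200)]
        truth = SyntheticTruthLabels(set(proteins[:50]), set(), 0.0, 9)
        qm = simulate_bioid_matrix(
            proteins, truth, effect_log2=2.0, rep_sd=0.3,
            detection_limit_log2=-np.inf, n_reps=3, seed=9,
        )
        log2 = qm.log2()
        bait = log2[qm.columns_of("bait")].mean(axis=1)
        ctrl = log2[qm.columns_of("control")].mean(axis=1)
        diff = (bait - ctrl)[proteins[:50]]
        se = 2 * 0.3 * np.sqrt(2 / 3) / np.sqrt(50)
        assert abs(diff.mean() - 2.0) < 2 * se + 0.05

    def test_missingness_is_truncation_at_limit(self):
        qm = simulate_bioid_matrix(
            [f"P{i}" for i in range(300)], empty_truth(), detection_limit_log2=24.0, seed=3
        )
        assert qm.n_missing > 0
        observed = qm.log2().to_numpy()
        assert np.nanmin(observed) >= 24.0

    def test_negative_effect_logs_warning(self, caplog):
        with caplog.at_level("WARNING"):
            simulate_bioid_matrix(["P1", "P2"], empty_truth(), effect_log2=-1.0, seed=0)
        assert "depletion" in caplog.text

    def test_determinism(self):
        a = simulate_bioid_matrix(["P1", "P2", "P3"], empty_truth(), seed=5)
        b = simulate_bioid_matrix(["P1", "P2", "P3"], empty_truth(), seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestPerturbationTable:
    def test_direction_validated(self, pert_sites):
        with pytest.raises(ValidationError, match="direction"):
            simulate_perturbation_table(pert_sites, empty_truth(), direction="sideways")

    def test_all_multiphospho_leaves_nothing_mono(self, pert_sites):
        from kinasecall import select_monophospho

        tab = simulate_perturbation_table(
            pert_sites, empty_truth(), frac_multiphospho=1.0, seed=2
        )
        assert select_monophospho(tab).empty

    def test_true_sites_centered_at_planted_effect(self, pert_sites):
        truth = SyntheticTruthLabels(set(), set(pert_sites["site_id"][:150]), -1.5, 4)
        tab = simulate_perturbation_table(
            pert_sites, truth, direction="down", effect_log2=1.5, noise_sd=0.2, seed=4
        )
        rcols = [c for c in tab.columns if c.startswith("ratio_")]
        true_rows = tab[tab["site_id"].isin(truth.true_substrate_sites)]
        m = true_rows[rcols].to_numpy().mean()
        se = 0.2 / np.sqrt(true_rows.shape[0] * len(rcols))
        assert abs(m - (-1.5)) < 2 * se + 0.01
        null_rows = tab[~tab["site_id"].isin(truth.true_substrate_sites)]
        assert abs(null_rows[rcols].to_numpy().mean()) < 0.05

    def test_null_effect_indistinguishable(self, pert_sites):
        from scipy import stats

        truth = SyntheticTruthLabels(set(), set(pert_sites["site_id"][:200]), 0.0, 8)
        tab = simulate_perturbation_table(pert_sites, truth, effect_log2=0.0, seed=8)
        rcols = [c for c in tab.columns if c.startswith("ratio_")]
        a = tab[tab["site_id"].isin(truth.true_substrate_sites)][rcols].to_numpy().ravel()
        b = tab[~tab["site_id"].isin(truth.true_substrate_sites)][rcols].to_numpy().ravel()
        assert stats.mannwhitneyu(a, b).pvalue > 0.01

    def test_loc_prob_in_unit_interval(self, pert_sites):
        tab = simulate_perturbation_table(pert_sites, empty_truth(), seed=1)
        assert tab["loc_prob"].between(0, 1).all()
        assert (tab["phospho_count"] >= 1).all()


class TestSimulateMutations:
    def test_reference_residue_matches_proteome(self, mut_scenario):
        muts = simulate_mutations(mut_scenario.sites, mut_scenario.proteome, 20, 20, seed=6)
        for m in muts.itertuples(index=False):
            assert mut_scenario.proteome[m.protein_id][m.position - 1] == m.ref
            assert m.alt != m.ref

    def test_outside_mutations_clear_all_windows(self, mut_scenario):
        muts = simulate_mutations(mut_scenario.sites, mut_scenario.proteome, 0, 25, seed=7)
        assert len(muts) == 25
        site_pos = mut_scenario.sites.groupby("protein_id")["position"].apply(list)
        for m in muts.itertuples(index=False):
            for sp in site_pos.get(m.protein_id, []):
                assert abs(m.position - sp) > 7

    def test_inside_mutations_hit_some_window(self, mut_scenario):
        muts = simulate_mutations(mut_scenario.sites, mut_scenario.proteome, 30, 0, seed=8)
        assert len(muts) == 30
        site_pos = mut_scenario.sites.groupby("protein_id")["position"].apply(list)
        for m in muts.itertuples(index=False):
            offsets = [abs(m.position - sp) for sp in site_pos.get(m.protein_id, [])]
            assert any(1 <= o <= 7 for o in offsets)

    def test_empty_site_table_rejected(self, mut_scenario):
        empty = mut_scenario.sites.iloc[0:0]
        with pytest.raises(ValidationError):
            simulate_mutations(empty, mut_scenario.proteome, 1, 1, seed=0)
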