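"""Call kinase-proximal proteins from a simulated BioID pulldown.

Simulates a label-free bait-vs-control intensity matrix with 40 true
interactors among 400 proteins (bait shift 2 log2 units, MNAR dropout at
the detection limit), then runs the volcano procedure: replicate-presence
filter, downshifted-normal imputation, Welch's t-test, fold-change/p cutoff.
"""

from kinasecall import (
    SyntheticTruthLabels,
    call_interactors,
    filter_replicate_presence,
    impute_missing,
    simulate_bioid_matrix,
)

proteins = [f"P{i:05d}" for i in range(1, 401)]
truth = SyntheticTruthLabels(set(proteins[:40]), set(), 0.0, seed=5)
matrix = simulate_bioid_matrix(proteins, truth, effect_log2=2.0, rep_sd=0.3,
                               detection_limit_log2=22.0, n_reps=3, seed=5)
print("matrix:", matrix.data.shape[0], "proteins x", matrix.data.shape[1],
      "samples;", matrix.n_missing, "missing cells (below detection limit)")

present = filter_replicate_presence(matrix, min_present=2, scope="bait-group")
print("quantified in >=2/3 bait replicates:", len(present.data), "proteins")

complete = impute_missing(present, shift_sd=1.8, width_sd=0.3, seed=5)
calls = call_interactors(complete, fc_cutoff=2.0, p_cutoff=0.05)
passed = calls[calls["passed"]]
tp = passed["protein_id"].isin(truth.true_interactors).sum()
print(f"interactors called: {len(passed)} (fold change >= 2 and p < 0.05)")
print(f"of which planted true interactors: {tp} / {len(truth.true_interactors)}")
print("-> log2_ratio is mean(log2 bait) - mean(log2 control); the volcano axes")
print("   are log2_ratio vs -log10 p, as exported by volcano_table()")
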