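"""Train a pseudocount-regularized PWM and score candidate phosphosites.

Builds the two-letter worked example first (so every number can be checked
by hand), then a realistic 20-letter PWM from simulated kinase-substrate
windows, and scores motif-true vs background windows.
"""

import numpy as np
import pandas as pd

from kinasecall import (
    GroundTruthMotif,
    acidophilic_motif,
    build_pwm,
    human_background,
    sample_training_windows,
    score_window,
)

# --- hand-checkable example: alphabet {A,R}, N=4 training windows
bg = pd.Series(0.5, index=["A", "R"])
pwm = build_pwm(["AA", "AA", "AA", "AR"], bg)
print("worked example: N =", pwm.n_sequences, " epsilon = sqrt(N) =", pwm.epsilon)
print("w(A,1) = log2(5/6 / 1/2) =", round(pwm.weight("A", 1), 4))
print("w(R,2) = log2(1/3 / 1/2) =", round(pwm.weight("R", 2), 4))
print("lambda('AA') =", round(score_window(pwm, "AA").lam, 4),
      " lambda('RR') =", round(score_window(pwm, "RR").lam, 4))
print("-> positive lambda: window looks like the training motif; negative: it does not\n")

# --- 20-letter PWM from a CK2-like acidophilic motif (acidic +1..+3)
background = human_background()
motif = acidophilic_motif(background)
train = sample_training_windows(motif, 2000, seed=1)
pwm = build_pwm(train, background)
print("acidophilic PWM trained on", pwm.n_sequences, "windows; epsilon =", round(pwm.epsilon, 3))
print("strongest weights at offset +1:",
      pwm.weights[1].sort_values(ascending=False).head(3).round(2).to_dict())

true_scores = [score_window(pwm, w).lam for w in sample_training_windows(motif, 200, seed=2)]
null_motif = GroundTruthMotif.background_motif(background)
null_scores = [score_window(pwm, w).lam for w in sample_training_windows(null_motif, 200, seed=3)]
print("mean lambda, motif-true windows:", round(float(np.mean(true_scores)), 2))
print("mean lambda, background windows:", round(float(np.mean(null_scores)), 2))
print("-> the substrate criterion used downstream is lambda > 2 (strict)")
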