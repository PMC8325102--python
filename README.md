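# kinasecall

Calling **endogenous kinase substrates** by intersecting three independent
layers of evidence:

1. **Proximity (BioID interactome).** A promiscuous biotin ligase fused to
   the kinase biotinylates proteins within ~10 nm; streptavidin pulldown and
   label-free quantification give a bait-vs-control intensity matrix.
   Proteins enriched in the bait channel (Welch's t-test + fold-change
   cutoff on a volcano plot) are the kinase-proximal candidates — including
   the transient, unstable kinase–substrate contacts that conventional
   AP-MS misses.
2. **Regulation (kinase-perturbed phosphoproteome).** Treating cells with a
   kinase inhibitor (or activator) and quantifying phosphosites in
   triplicate identifies sites whose phosphorylation responds in the
   expected direction (≥2-fold mean change, p < 0.05).
3. **Specificity (phosphorylation motif).** A position weight matrix
   trained on known in vitro substrate windows scores the ±7 residues
   flanking each candidate site; sites with motif score λ > 2 match the
   kinase's linear specificity.

A site is called a substrate only when it passes **all three** filters:
proximity removes downstream-kinase artifacts, regulation removes inert
proximal proteins, and the motif removes indirectly regulated sites. The
package also scores how **missense mutations** near substrate phosphosites
disrupt the motif, and ships a synthetic-data generator with planted ground
truth so the whole cascade is testable end to end.

For computational proteomics users working in Python: everything is a
library call on pandas tables (see `examples/`), with a thin `kinasecall`
CLI for shell pipelines.

## The motif model

Given `N` training windows, the probability of residue `x` at flanking
offset `i` is pseudocount-regularized:

    p(x,i) = (f(x,i) + c(x)) / (N + ε),   c(x) = p(x)·ε,   ε = √N

where `f(x,i)` is the observed count and `p(x)` the proteome-wide
background probability. Log-odds weights `w(x,i) = log2(p(x,i)/p(x))` are
always finite, and a candidate window scores

    λ = Σᵢ w(qᵢ, i)

over its non-pad flanking positions. Because λ is additive, a single
substitution at offset `i` changes it by exactly `w(alt,i) − w(ref,i)` —
the quantity used for mutation-impact classification. The in vitro assay
statistic is `phosphorylation ratio (%) = (1 − area_with/area_without) × 100`.

## Worked example

The PWM arithmetic on a two-letter alphabet {A, R} with uniform background
(p = 0.5 each) and training windows `AA, AA, AA, AR` (so N = 4, ε = 2,
c(A) = c(R) = 1):

```python
>>> import pandas as pd
>>> from kinasecall import build_pwm, score_window
>>> pwm = build_pwm(["AA", "AA", "AA", "AR"], pd.Series(0.5, index=["A", "R"]))
>>> round(pwm.weight("A", 1), 4)   # log2((4+1)/(4+2) / 0.5) = log2(5/3)
0.737
>>> round(pwm.weight("R", 2), 4)   # log2((1+1)/(4+2) / 0.5) = log2(2/3)
-0.585
>>> round(score_window(pwm, "AA").lam, 4)   # w(A,1) + w(A,2)
1.152
>>> round(score_window(pwm, "RR").lam, 4)
-2.1699
```

Running the full benchmark (`python examples/04_end_to_end.py`) prints:

```
final substrate calls (I and R and M): 42
recovery vs planted truth: sensitivity=0.84 precision=1.00 F1=0.91
```

i.e. of 50 substrate sites planted among 2950 decoys, 42 are recovered by
the triple intersection with no false calls; the Venn breakdown shows the
sites each single filter would have wrongly admitted (453 proximal-only
sites, 72 motif-only look-alikes, ...).

## Layout

- `src/kinasecall/motif.py` — PWM construction, window extraction, λ scoring
- `src/kinasecall/bioid.py` — presence filter, MNAR imputation, Welch test, interactor calls
- `src/kinasecall/perturb.py` — monophospho/localization filters, site aggregation, regulated calls
- `src/kinasecall/integrate.py` — three-way intersection, Venn counts, recovery metrics
- `src/kinasecall/mutation.py` — mutation/site matching, Δλ scoring, assay ratio
- `src/kinasecall/synth.py` — proteome/motif/matrix/table/mutation simulators with ground truth
- `src/kinasecall/{io,config,pipeline,cli}.py` — TSV/FASTA IO, TOML config, orchestration, CLI
- `docs/methods.md` — model assumptions, parameter defaults, design choices, limitations
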