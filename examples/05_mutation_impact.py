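"""Score how missense mutations near phosphosites disrupt the kinase motif.

Plants substrate sites, simulates mutations inside and outside the +-7
windows, and reports the motif-score change delta = lambda_mut - lambda_wt,
which for a single substitution equals w(alt, offset) - w(ref, offset)
exactly. Also shows the in vitro assay statistic.
"""

from kinasecall import (
    acidophilic_motif,
    build_pwm,
    generate_proteome,
    human_background,
    match_mutations_to_sites,
    phosphorylation_ratio,
    plant_substrates,
    sample_training_windows,
    score_mutation_impacts,
    simulate_mutations,
)

motif = acidophilic_motif()
proteome = generate_proteome(60, mean_length=300, seed=14)
planted = plant_substrates(proteome, motif, n_true=15, n_decoy=50, seed=14)
pwm = build_pwm(sample_training_windows(motif, 2000, seed=15), human_background())

mutations = simulate_mutations(planted.sites, planted.proteome,
                               n_inside=25, n_outside=25, seed=16)
pairs, rejected = match_mutations_to_sites(mutations, planted.sites, planted.proteome)
print(f"{len(mutations)} mutations -> {len(pairs)} mutation/site pairs within +-7 "
      f"({len(rejected)} rejected)")

impacts = score_mutation_impacts(pwm, pairs, planted.proteome, score_threshold=2.0)
print("impact classes:", impacts["class"].value_counts().to_dict())
worst = impacts.dropna(subset=["delta"]).nsmallest(3, "delta")
worst = worst.rename(columns={"class": "impact_class"})
for row in worst.itertuples(index=False):
    print(f"  {row.site_id}: {row.ref}->{row.alt} at offset {row.offset:+d}: "
          f"lambda {row.lambda_wt:.2f} -> {row.lambda_mut:.2f} "
          f"(delta {row.delta:.2f}, {row.impact_class})")
print("-> 'loss' = large score drop or a passing site pushed below the threshold;")
print("   acceptor mutations (offset 0, alt not S/T/Y) are flagged acceptor_loss")

print()
print("in vitro assay: phosphorylation ratio (%) = (1 - area_with/area_without) x 100")
for wo, wi in [(4.0, 1.0), (4.0, 4.0), (4.0, 0.0)]:
    print(f"  areas without/with kinase {wo}/{wi} -> {phosphorylation_ratio(wo, wi):.0f}%")
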