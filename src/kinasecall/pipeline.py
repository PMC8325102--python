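"""End-to-end orchestration: simulate -> PWM -> score -> filters -> integrate.

A run is driven by a :class:`~kinasecall.config.RunConfig`; every stage
derives its own seed from the run seed, writes its table into the run
directory, and contributes a row-count entry to the manifest.  Rerunning
with an identical config produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .bioid import call_interactors, filter_replicate_presence, impute_missing, volcano_table
from .config import RunConfig, SimParams, derive_seed
from .integrate import VennCounts, call_substrates, evaluate_recovery, map_sites_to_interactors
from .io import (
    read_bioid_matrix,
    read_fasta,
    read_table,
    read_windows,
    write_bioid_matrix,
    write_fasta,
    write_table,
    write_truth,
    write_windows,
)
from .motif import ValidationError, build_pwm, compute_background, score_sites
from .mutation import match_mutations_to_sites, score_mutation_impacts
from .perturb import (
    aggregate_to_sites,
    call_regulated,
    filter_localization,
    select_monophospho,
)
from .synth import (
    GroundTruthMotif,
    SyntheticTruthLabels,
    acidophilic_motif,
    basophilic_motif,
    generate_proteome,
    plant_substrates,
    sample_training_windows,
    simulate_bioid_matrix,
    simulate_mutations,
    simulate_perturbation_table,
)

logger = logging.getLogger(__name__)


@dataclass
class ScenarioData:
    """In-memory bundle of one simulated scenario."""

    proteome: dict[str, str]
    windows: list[str]
    sites: pd.DataFrame
    labels: SyntheticTruthLabels
    matrix: "object"
    perturb: pd.DataFrame
    mutations: pd.DataFrame


def _motif_for(sim: SimParams) -> GroundTruthMotif:
    if sim.motif == "acidophilic":
        return acidophilic_motif()
    if sim.motif == "basophilic":
        return basophilic_motif()
    raise ValidationError(f"unknown motif kind {sim.motif!r}")


def simulate_scenario(sim: SimParams, seed: int) -> ScenarioData:
    """Generate one full scenario with planted ground truth."""
    motif = _motif_for(sim)
    proteome = generate_proteome(
        sim.n_proteins, sim.mean_length, seed=derive_seed(seed, "proteome")
    )
    windows = sample_training_windows(
        motif, sim.n_train_windows, seed=derive_seed(seed, "train-windows")
    )
    plant = plant_substrates(
        proteome,
        motif,
        n_true=sim.n_true,
        n_decoy=sim.n_decoy,
        seed=derive_seed(seed, "plant"),
        consistent_truth=sim.consistent_truth,
        n_extra_interactors=sim.n_extra_interactors,
    )
    labels = plant.labels
    labels.planted_effect_log2 = sim.perturb_effect_log2
    matrix = simulate_bioid_matrix(
        list(plant.proteome),
        labels,
        baseline_log2=sim.baseline_log2,
        protein_sd=sim.protein_sd,
        effect_log2=sim.bioid_effect_log2,
        rep_sd=sim.bioid_rep_sd,
        detection_limit_log2=sim.detection_limit_log2,
        n_reps=sim.bioid_n_reps,
        seed=derive_seed(seed, "bioid"),
    )
    perturb = simulate_perturbation_table(
        plant.sites,
        labels,
        direction=sim.direction,
        effect_log2=sim.perturb_effect_log2,
        noise_sd=sim.perturb_noise_sd,
        n_reps=sim.perturb_n_reps,
        frac_multiphospho=sim.frac_multiphospho,
        loc_prob_alpha=sim.loc_prob_alpha,
        loc_prob_beta=sim.loc_prob_beta,
        extra_peptide_rate=sim.extra_peptide_rate,
        seed=derive_seed(seed, "perturb"),
    )
    mutations = simulate_mutations(
        plant.sites,
        plant.proteome,
        n_inside=sim.n_mut_inside,
        n_outside=sim.n_mut_outside,
        seed=derive_seed(seed, "mutations"),
    )
    return ScenarioData(
        proteome=plant.proteome,
        windows=windows,
        sites=plant.sites,
        labels=labels,
        matrix=matrix,
        perturb=perturb,
        mutations=mutations,
    )


def write_scenario(data: ScenarioData, outdir) -> dict[str, str]:
    """Write a scenario's files into ``outdir``; returns name -> path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": out / "proteome.fasta",
        "windows": out / "training_windows.txt",
        "sites": out / "sites.tsv",
        "bioid_matrix": out / "bioid_matrix.tsv",
        "perturb_table": out / "perturbation.tsv",
        "mutations": out / "mutations.tsv",
        "truth": out / "truth.tsv",
    }
    write_fasta(data.proteome, paths["proteome"])
    write_windows(data.windows, paths["windows"])
    write_table(data.sites, paths["sites"])
    write_bioid_matrix(data.matrix, paths["bioid_matrix"])
    write_table(data.perturb, paths["perturb_table"])
    write_table(data.mutations, paths["mutations"])
    write_truth(data.labels, paths["truth"])
    return {k: str(v) for k, v in paths.items()}


@dataclass
class PipelineResult:
    """Outputs of one pipeline run (also written to the run directory)."""

    pwm: "object"
    scores: pd.DataFrame
    interactors: pd.DataFrame
    regulated: pd.DataFrame
    calls: pd.DataFrame
    venn: VennCounts
    impacts: pd.DataFrame | None
    manifest: dict


def run_pipeline(
    config: RunConfig,
    data: ScenarioData | None = None,
    sites: pd.DataFrame | None = None,
) -> PipelineResult:
    """Execute the full filter cascade.

    Inputs come either from ``data`` (an in-memory scenario) or from the
    paths in ``config``.  Outputs (PWM, per-stage tables, Venn counts,
    manifest) are written under ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": str(config.seed)}
    counts: dict[str, int] = {}

    if data is not None:
        proteome = data.proteome
        windows = data.windows
        sites = data.sites
        matrix = data.matrix
        perturb = data.perturb
        mutations = data.mutations if len(data.mutations) else None
    else:
        proteome = read_fasta(config.proteome_path)
        windows = read_windows(config.windows_path)
        if sites is None:
            raise ValidationError("run_pipeline needs a site table when run from paths")
        matrix = read_bioid_matrix(config.bioid_matrix_path)
        perturb = read_table(config.perturb_table_path, schema="site-quant")
        mutations = (
            read_table(config.mutations_path, schema="mutations")
            if config.mutations_path
            else None
        )

    # --- stage 1: motif model
    background = compute_background(proteome)
    pwm = build_pwm(windows, background, include_center=config.include_center)
    pwm.to_tsv(out / "pwm.tsv")
    counts["training_windows"] = len(windows)

    scores, score_errors = score_sites(pwm, sites, proteome, half_width=config.half_width)
    write_table(scores, out / "motif_scores.tsv", metadata=meta)
    if len(score_errors):
        write_table(score_errors, out / "motif_score_errors.tsv", metadata=meta)
    counts["scored_sites"] = len(scores)

    # --- stage 2: BioID interactome filter
    present = filter_replicate_presence(
        matrix, min_present=config.min_present, scope=config.presence_scope
    )
    counts["bioid_proteins_quantified"] = len(present.data)
    complete = impute_missing(
        present,
        shift_sd=config.impute_shift_sd,
        width_sd=config.impute_width_sd,
        seed=derive_seed(config.seed, "impute"),
        scope=config.impute_scope,
    )
    interactors = call_interactors(
        complete, fc_cutoff=config.bioid_fc_cutoff, p_cutoff=config.bioid_p_cutoff
    )
    write_table(interactors, out / "interactors.tsv", metadata=meta)
    write_table(volcano_table(interactors), out / "bioid_volcano.tsv", metadata=meta)
    counts["interactors_passed"] = int(interactors["passed"].sum())

    # --- stage 3: perturbation filter
    records = perturb
    if config.monophospho_only:
        records = select_monophospho(records)
    records = filter_localization(records, min_prob=config.min_loc_prob)
    site_vectors = aggregate_to_sites(records)
    counts["perturb_sites_quantified"] = len(site_vectors)
    regulated = call_regulated(
        site_vectors,
        direction=config.direction,
        fc_cutoff=config.perturb_fc_cutoff,
        p_cutoff=config.perturb_p_cutoff,
    )
    write_table(regulated, out / "regulated_sites.tsv", metadata=meta)
    counts["regulated_passed"] = int(regulated["passed"].sum())

    # --- stage 4: integration
    interactor_ids = set(interactors.loc[interactors["passed"], "protein_id"])
    flagged = map_sites_to_interactors(sites, interactor_ids)
    # evaluated universe: perturbation-quantified sites on BioID-quantified proteins
    universe = flagged["site_id"].isin(set(site_vectors["site_id"])) & flagged[
        "protein_id"
    ].isin(set(present.data.index))
    flagged = flagged[universe].reset_index(drop=True)
    calls, venn = call_substrates(
        flagged, regulated, scores, score_threshold=config.score_threshold
    )
    write_table(calls, out / "substrate_calls.tsv", metadata=meta)
    write_table(venn.to_frame(), out / "venn_counts.tsv", metadata=meta)
    counts["final_calls"] = int(calls["final"].sum())
    counts["substrate_proteins"] = calls.loc[calls["final"], "protein_id"].nunique()

    # --- stage 5 (optional): mutation impact
    impacts = None
    if mutations is not None:
        pairs, rejected = match_mutations_to_sites(
            mutations, sites, proteome, half_width=config.half_width
        )
        impacts = score_mutation_impacts(
            pwm, pairs, proteome,
            half_width=config.half_width, score_threshold=config.score_threshold,
        )
        write_table(impacts, out / "mutation_impacts.tsv", metadata=meta)
        if len(rejected):
            write_table(rejected, out / "mutation_rejects.tsv", metadata=meta)
        counts["mutation_pairs_scored"] = len(impacts)

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": counts,
        "mutation_stage": "run" if mutations is not None else "skipped",
    }
    with open(out / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(
        pwm=pwm,
        scores=scores,
        interactors=interactors,
        regulated=regulated,
        calls=calls,
        venn=venn,
        impacts=impacts,
        manifest=manifest,
    )


def run_reference(seed: int, outdir: str) -> tuple[PipelineResult, ScenarioData, dict]:
    """Simulate the reference scenario, run the pipeline, evaluate recovery."""
    config = RunConfig(seed=seed, outdir=outdir)
    data = simulate_scenario(config.sim, seed=seed)
    write_scenario(data, Path(outdir) / "inputs")
    result = run_pipeline(config, data=data)
    metrics = evaluate_recovery(result.calls, data.labels)
    with open(Path(outdir) / "recovery.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result, data, metrics
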