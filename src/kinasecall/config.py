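"""Run configuration: thresholds, paths, simulation parameters, TOML IO.

A single TOML file drives a reproducible run; one top-level seed feeds every
stage through stable per-stage derived seeds, so stages can be rerun in
isolation with identical results.
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed (< 2^31) from the run seed and a stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class SimParams:
    """Parameters of the synthetic reference scenario.

    Defaults describe the shipped consistent-truth benchmark: 50 true
    substrate sites planted on 50 true-interactor proteins (plus 50
    nonsubstrate proximal proteins) among 2950 decoy sites; BioID bait shift
    of 2 log2 units with replicate noise 0.3; perturbation effect of 1.5
    log2 units downward with replicate noise 0.2.
    """

    n_proteins: int = 500
    mean_length: int = 450
    motif: str = "acidophilic"  # or "basophilic"
    n_train_windows: int = 2000
    n_true: int = 50
    n_decoy: int = 2950
    n_extra_interactors: int = 50
    consistent_truth: bool = True
    # BioID matrix
    baseline_log2: float = 25.0
    protein_sd: float = 2.0
    bioid_effect_log2: float = 2.0
    bioid_rep_sd: float = 0.3
    detection_limit_log2: float = 22.0
    bioid_n_reps: int = 3
    # perturbation table
    direction: str = "down"
    perturb_effect_log2: float = 1.5
    perturb_noise_sd: float = 0.2
    perturb_n_reps: int = 3
    frac_multiphospho: float = 0.1
    loc_prob_alpha: float = 12.0
    loc_prob_beta: float = 1.0
    extra_peptide_rate: float = 0.5
    # mutations
    n_mut_inside: int = 40
    n_mut_outside: int = 40


@dataclass
class RunConfig:
    """Everything a pipeline run needs: seed, thresholds, paths, simulation."""

    seed: int = 1
    outdir: str = "runs/reference"
    # motif
    half_width: int = 7
    include_center: bool = False
    score_threshold: float = 2.0
    # BioID filter
    bioid_fc_cutoff: float = 2.0
    bioid_p_cutoff: float = 0.05
    min_present: int = 2
    presence_scope: str = "bait-group"
    impute_shift_sd: float = 1.8
    impute_width_sd: float = 0.3
    impute_scope: str = "column"
    # perturbation filter
    direction: str = "down"
    perturb_fc_cutoff: float = 2.0
    perturb_p_cutoff: float = 0.05
    min_loc_prob: float = 0.75
    monophospho_only: bool = True
    # input paths (empty string = not provided)
    proteome_path: str = ""
    windows_path: str = ""
    bioid_matrix_path: str = ""
    perturb_table_path: str = ""
    mutations_path: str = ""
    sim: SimParams = field(default_factory=SimParams)

    # ------------------------------------------------------------- TOML IO

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim = SimParams(**raw.pop("sim", {}))
        known = {f.name for f in fields(cls)} - {"sim"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(sim=sim, **raw)

    def to_toml(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(self.to_toml_str())

    def to_toml_str(self) -> str:
        d = asdict(self)
        sim = d.pop("sim")
        lines = [_toml_kv(k, v) for k, v in d.items()]
        lines.append("")
        lines.append("[sim]")
        lines.extend(_toml_kv(k, v) for k, v in sim.items())
        return "\n".join(lines) + "\n"

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output directory is
        excluded so reruns into different directories compare byte-identical)."""
        d = asdict(self)
        d.pop("outdir")
        sim = d.pop("sim")
        canonical = [f"{k}={v!r}" for k, v in sorted(d.items())]
        canonical += [f"sim.{k}={v!r}" for k, v in sorted(sim.items())]
        return hashlib.sha256("\n".join(canonical).encode()).hexdigest()[:16]

    def outpath(self, name: str) -> Path:
        return Path(self.outdir) / name


def _toml_kv(key: str, value) -> str:
    if isinstance(value, bool):
        return f"{key} = {'true' if value else 'false'}"
    if isinstance(value, (int, float)):
        return f"{key} = {value!r}"
    if isinstance(value, str):
        escaped = value.replace("\\", "\\\\").replace('"', '\\"')
        return f'{key} = "{escaped}"'
    raise TypeError(f"cannot serialize config value of type {type(value)} for {key!r}")
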