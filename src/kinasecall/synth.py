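"""Synthetic data with planted ground truth for the substrate-calling pipeline.

Every downstream stage (motif scoring, BioID interactome filtering,
perturbation-phosphoproteome filtering, integration, mutation impact) is
exercised against data produced here, where the true interactors, true
substrate sites and planted effect sizes are known exactly.

What is emulated, and how:

* a background proteome of i.i.d. residues (geometric length distribution,
  minimum 30 residues);
* substrate flanking windows drawn from a ground-truth motif (per-position
  residue probabilities over the 14 flanking offsets, center from S/T/Y);
* a BioID streptavidin-pulldown intensity matrix: protein-level log2
  abundances with normal replicate noise, a bait-channel shift for true
  interactors, and missing-not-at-random dropout via hard truncation at a
  detection limit;
* a TMT-style perturbation table: peptide-level rows with per-replicate
  treated/control log2 ratios centered at the planted effect for true sites
  and 0 otherwise, phospho-counts, and beta-distributed localization
  probabilities;
* missense mutations placed inside or strictly outside the ±7 windows of
  the planted sites.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motif import ACCEPTORS, ALPHABET, ValidationError

logger = logging.getLogger(__name__)

#: Amino-acid frequencies of the human proteome (UniProt/SwissProt order of
#: magnitude; rounded, renormalized).  Used as the default residue model.
HUMAN_AA_FREQS: dict[str, float] = {
    "A": 0.0702, "C": 0.0230, "D": 0.0474, "E": 0.0710, "F": 0.0365,
    "G": 0.0658, "H": 0.0263, "I": 0.0433, "K": 0.0572, "L": 0.0996,
    "M": 0.0213, "N": 0.0359, "P": 0.0631, "Q": 0.0477, "R": 0.0564,
    "S": 0.0833, "T": 0.0536, "V": 0.0597, "W": 0.0122, "Y": 0.0266,
}
_total = sum(HUMAN_AA_FREQS.values())
HUMAN_AA_FREQS = {k: v / _total for k, v in HUMAN_AA_FREQS.items()}

FLANK_OFFSETS: tuple[int, ...] = tuple(list(range(-7, 0)) + list(range(1, 8)))


def human_background() -> pd.Series:
    """The default residue probability table as a Series over the alphabet."""
    return pd.Series(HUMAN_AA_FREQS).reindex(list(ALPHABET))


def uniform_background() -> pd.Series:
    return pd.Series(1 / 20, index=list(ALPHABET))


@dataclass(frozen=True)
class GroundTruthMotif:
    """Generator-side truth for a kinase's linear sequence specificity.

    ``position_probs``: offsets (−7..−1, +1..+7) × 20 residues, rows sum to 1.
    ``center_residues``: allowed phosphoacceptors.
    """

    position_probs: pd.DataFrame
    center_residues: str = "ST"

    def __post_init__(self) -> None:
        if tuple(self.position_probs.index) != FLANK_OFFSETS:
            raise ValidationError("position_probs must index exactly the 14 flanking offsets")
        sums = self.position_probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            bad = sums[(sums - 1).abs() > 1e-12]
            raise ValidationError(f"position probabilities must sum to 1; offending sums: {bad.to_dict()}")
        if (self.position_probs.to_numpy() < 0).any():
            raise ValidationError("position probabilities must be nonnegative")
        if not self.center_residues:
            raise ValidationError("center_residues must be non-empty")
        if not set(self.center_residues) <= set(ACCEPTORS):
            raise ValidationError(f"center_residues must be a subset of {ACCEPTORS}")

    @classmethod
    def from_anchors(
        cls,
        anchors: dict[int, dict[str, float]],
        background: pd.Series | None = None,
        center_residues: str = "ST",
    ) -> "GroundTruthMotif":
        """Background motif with enriched residues at anchor offsets.

        ``anchors`` maps an offset to residue→probability; the residual mass
        at that offset is spread over the remaining residues in proportion to
        the background.
        """
        bg = (background if background is not None else human_background()).reindex(list(ALPHABET))
        rows = {}
        for off in FLANK_OFFSETS:
            row = bg.copy()
            if off in anchors:
                spec = anchors[off]
                mass = sum(spec.values())
                if mass > 1:
                    raise ValidationError(f"anchor mass at offset {off} exceeds 1")
                rest = bg.drop(list(spec)).copy()
                rest *= (1 - mass) / rest.sum()
                row = pd.concat([pd.Series(spec), rest]).reindex(list(ALPHABET))
            rows[off] = row / row.sum()
        probs = pd.DataFrame(rows).T.reindex(list(FLANK_OFFSETS))
        return cls(position_probs=probs, center_residues=center_residues)

    @classmethod
    def background_motif(cls, background: pd.Series | None = None, center_residues: str = "STY") -> "GroundTruthMotif":
        """A motif with no positional information (pure background)."""
        return cls.from_anchors({}, background=background, center_residues=center_residues)


def acidophilic_motif(background: pd.Series | None = None) -> GroundTruthMotif:
    """A CK2-like acidophilic motif: acidic residues dominate +1..+3."""
    acidic = {"E": 0.55, "D": 0.35}
    return GroundTruthMotif.from_anchors(
        {1: dict(acidic), 2: dict(acidic), 3: dict(acidic)},
        background=background,
        center_residues="ST",
    )


def basophilic_motif(background: pd.Series | None = None) -> GroundTruthMotif:
    """A PKA-like basophilic motif: R/K dominate −3 and −2."""
    basic = {"R": 0.6, "K": 0.3}
    return GroundTruthMotif.from_anchors(
        {-3: dict(basic), -2: dict(basic)}, background=background, center_residues="ST"
    )


@dataclass
class SyntheticTruthLabels:
    """Ground-truth bookkeeping threaded through a simulation scenario."""

    true_interactors: set[str]
    true_substrate_sites: set[str]
    planted_effect_log2: float
    seed: int
    consistent_truth: bool = True


def _check_freqs(residue_freqs: pd.Series) -> pd.Series:
    freqs = residue_freqs.reindex(list(ALPHABET))
    if freqs.isna().any():
        raise ValidationError("residue_freqs must cover the 20-letter alphabet")
    s = float(freqs.sum())
    if abs(s - 1.0) > 1e-9:
        raise ValidationError(f"residue_freqs must sum to 1 (got {s!r})")
    return freqs / s


def generate_proteome(
    n_proteins: int,
    mean_length: int = 450,
    residue_freqs: pd.Series | None = None,
    seed: int = 0,
    min_length: int = 30,
) -> dict[str, str]:
    """I.i.d.-residue proteome; lengths are geometric shifted to ``min_length``.

    Returns an ordered mapping protein_id -> sequence (ids P00001, P00002, …).
    """
    if n_proteins < 1:
        raise ValidationError("n_proteins must be >= 1")
    freqs = _check_freqs(residue_freqs if residue_freqs is not None else human_background())
    rng = np.random.default_rng(seed)
    p = 1.0 / max(mean_length - min_length + 1, 1)
    lengths = min_length + rng.geometric(p, size=n_proteins) - 1
    letters = np.array(list(ALPHABET))
    proteome: dict[str, str] = {}
    for i, L in enumerate(lengths, start=1):
        seq = rng.choice(letters, size=int(L), p=freqs.to_numpy())
        proteome[f"P{i:05d}"] = "".join(seq)
    return proteome


def sample_training_windows(motif: GroundTruthMotif, n: int, seed: int = 0) -> list[str]:
    """Draw ``n`` 15-character substrate windows from the ground-truth motif."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(ALPHABET))
    centers = np.array(list(motif.center_residues))
    cols = {}
    for off in FLANK_OFFSETS:
        cols[off] = rng.choice(letters, size=n, p=motif.position_probs.loc[off].to_numpy())
    cidx = rng.integers(0, len(centers), size=n)
    windows = []
    for k in range(n):
        left = "".join(cols[o][k] for o in range(-7, 0))
        right = "".join(cols[o][k] for o in range(1, 8))
        windows.append(left + centers[cidx[k]] + right)
    return windows


def _site_id(protein_id: str, residue: str, position: int) -> str:
    return f"{protein_id}_{residue}{position}"


@dataclass
class PlantResult:
    """Output of :func:`plant_substrates`: sites, labels and the (modified) proteome."""

    sites: pd.DataFrame
    labels: SyntheticTruthLabels
    proteome: dict[str, str]


def plant_substrates(
    proteome: dict[str, str],
    motif: GroundTruthMotif,
    n_true: int,
    n_decoy: int,
    seed: int = 0,
    consistent_truth: bool = True,
    n_extra_interactors: int = 0,
    half_width: int = 7,
) -> PlantResult:
    """Plant true substrate sites (motif-sampled windows) and decoy sites.

    True sites have their ±half_width flanking sequence overwritten by a
    fresh motif sample; decoy sites keep the native background sequence at
    existing S/T/Y positions.  When ``consistent_truth`` is set the hosts of
    the true sites become the true interactors, optionally joined by
    ``n_extra_interactors`` proteins carrying no true site (nonsubstrate
    proximal proteins).  Sites are at least ``half_width+1`` residues from
    both termini so each window is pad-free.
    """
    rng = np.random.default_rng(seed)
    proteome = dict(proteome)
    ids = list(proteome)
    h = half_width

    # --- true sites: one per host protein when possible
    true_rows = []
    planted: dict[str, list[int]] = {}
    hosts: list[str] = []
    if n_true > 0:
        order = list(rng.permutation(ids))
        for pid in order:
            if len(hosts) == n_true:
                break
            L = len(proteome[pid])
            lo, hi = h + 1, L - h  # 1-based positions with full windows
            if hi < lo:
                continue
            pos = int(rng.integers(lo, hi + 1))
            win = sample_training_windows(motif, 1, seed=int(rng.integers(0, 2**31)))[0]
            seq = proteome[pid]
            proteome[pid] = seq[: pos - h - 1] + win + seq[pos + h :]
            res = win[h]
            true_rows.append((_site_id(pid, res, pos), pid, pos, res))
            planted.setdefault(pid, []).append(pos)
            hosts.append(pid)
        if len(hosts) < n_true:
            raise ValidationError(
                f"could not place {n_true} true sites: only {len(hosts)} proteins "
                f"have an interior position (need length >= {2 * h + 1})"
            )

    # --- decoy sites: native S/T/Y positions clear of planted windows
    eligible = []
    for pid, seq in proteome.items():
        taken = planted.get(pid, [])
        for pos in range(h + 1, len(seq) - h + 1):
            if seq[pos - 1] in ACCEPTORS and all(abs(pos - t) > 2 * h for t in taken):
                eligible.append((pid, pos))
    if len(eligible) < n_decoy:
        raise ValidationError(
            f"insufficient eligible decoy positions: need {n_decoy}, found {len(eligible)}"
        )
    pick = rng.choice(len(eligible), size=n_decoy, replace=False) if n_decoy else []
    decoy_rows = []
    for k in sorted(int(i) for i in np.atleast_1d(pick)):
        pid, pos = eligible[k]
        res = proteome[pid][pos - 1]
        decoy_rows.append((_site_id(pid, res, pos), pid, pos, res))

    sites = pd.DataFrame(
        true_rows + decoy_rows, columns=["site_id", "protein_id", "position", "residue"]
    )
    interactors = set(hosts) if consistent_truth else set()
    if n_extra_interactors:
        pool = [p for p in ids if p not in interactors]
        extra = rng.choice(pool, size=min(n_extra_interactors, len(pool)), replace=False)
        interactors |= set(str(p) for p in extra)
    labels = SyntheticTruthLabels(
        true_interactors=interactors,
        true_substrate_sites={r[0] for r in true_rows},
        planted_effect_log2=float("nan"),
        seed=seed,
        consistent_truth=consistent_truth,
    )
    return PlantResult(sites=sites, labels=labels, proteome=proteome)


def simulate_bioid_matrix(
    proteins: list[str],
    truth: SyntheticTruthLabels,
    baseline_log2: float = 25.0,
    protein_sd: float = 2.0,
    effect_log2: float = 2.0,
    rep_sd: float = 0.3,
    detection_limit_log2: float = 22.0,
    n_reps: int = 3,
    seed: int = 0,
) -> "QuantMatrix":
    """Label-free BioID pulldown matrix (linear intensities, NaN = missing).

    Each protein gets a latent log2 abundance ~ Normal(baseline, protein_sd);
    bait-channel means of true interactors are shifted by ``effect_log2``;
    replicate noise is Normal(0, rep_sd); any log2 intensity below the
    detection limit is recorded as missing (MNAR hard truncation).
    """
    from .bioid import QuantMatrix

    if n_reps < 2:
        raise ValidationError("n_reps must be >= 2")
    if rep_sd <= 0:
        raise ValidationError("rep_sd must be > 0")
    if effect_log2 < 0:
        logger.warning("simulate_bioid_matrix: negative effect_log2 (%.3g) models depletion", effect_log2)
    rng = np.random.default_rng(seed)
    n = len(proteins)
    base = rng.normal(baseline_log2, protein_sd, size=n)
    is_true = np.array([p in truth.true_interactors for p in proteins])
    cols = {}
    for grp, shift in (("bait", effect_log2), ("control", 0.0)):
        for r in range(1, n_reps + 1):
            mean = base + np.where(is_true, shift if grp == "bait" else 0.0, 0.0)
            vals = mean + rng.normal(0.0, rep_sd, size=n)
            vals = np.where(vals < detection_limit_log2, np.nan, vals)
            cols[f"{grp}_{r}"] = np.power(2.0, vals)
    data = pd.DataFrame(cols, index=list(proteins))
    data.index.name = "protein_id"
    groups = {c: c.rsplit("_", 1)[0] for c in data.columns}
    return QuantMatrix(data=data, groups=groups)


def simulate_perturbation_table(
    sites: pd.DataFrame,
    truth: SyntheticTruthLabels,
    direction: str = "down",
    effect_log2: float = 1.5,
    noise_sd: float = 0.2,
    n_reps: int = 3,
    frac_multiphospho: float = 0.1,
    loc_prob_alpha: float = 12.0,
    loc_prob_beta: float = 1.0,
    extra_peptide_rate: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Peptide-level perturbation quantification table.

    One site is covered by ``1 + Poisson(extra_peptide_rate)`` peptide rows
    (missed-cleavage / modified forms).  Each row carries per-replicate
    treated/control log2 ratios centered at ±effect_log2 for true substrate
    sites (sign per ``direction``) and 0 otherwise, a phospho-count that is 1
    except for a ``frac_multiphospho`` share of rows (then 2 or 3), and a
    localization probability drawn from Beta(alpha, beta).
    """
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    if n_reps < 2:
        raise ValidationError("n_reps must be >= 2")
    if not 0.0 <= frac_multiphospho <= 1.0:
        raise ValidationError("frac_multiphospho must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sign = -1.0 if direction == "down" else 1.0
    rows = []
    for row in sites.itertuples(index=False):
        center = sign * effect_log2 if row.site_id in truth.true_substrate_sites else 0.0
        n_pep = 1 + int(rng.poisson(extra_peptide_rate))
        for k in range(1, n_pep + 1):
            multi = rng.random() < frac_multiphospho
            count = int(rng.integers(2, 4)) if multi else 1
            loc = float(rng.beta(loc_prob_alpha, loc_prob_beta))
            ratios = center + rng.normal(0.0, noise_sd, size=n_reps)
            rows.append(
                (row.site_id, row.protein_id, row.position, row.residue,
                 f"{row.site_id}_pep{k}", count, loc, *ratios)
            )
    cols = ["site_id", "protein_id", "position", "residue", "peptide_id",
            "phospho_count", "loc_prob"] + [f"ratio_{r}" for r in range(1, n_reps + 1)]
    return pd.DataFrame(rows, columns=cols)


def simulate_mutations(
    sites: pd.DataFrame,
    proteome: dict[str, str],
    n_inside: int,
    n_outside: int,
    seed: int = 0,
    half_width: int = 7,
    max_tries: int = 200,
) -> pd.DataFrame:
    """Missense mutations inside / strictly outside the ±half_width windows.

    Inside mutations land at a nonzero offset within ``half_width`` of some
    site; outside mutations are farther than ``half_width`` from every site
    of their protein.  Reference residues always match the proteome; the
    alternate differs from the reference.  Placements that cannot be
    satisfied after ``max_tries`` draws are skipped with a logged count.
    """
    if sites.empty:
        raise ValidationError("site table is empty")
    rng = np.random.default_rng(seed)
    letters = list(ALPHABET)
    site_pos: dict[str, list[int]] = {}
    for row in sites.itertuples(index=False):
        site_pos.setdefault(row.protein_id, []).append(int(row.position))
    rows = []
    skipped = 0

    site_records = list(sites.itertuples(index=False))
    for _ in range(n_inside):
        placed = False
        for _try in range(max_tries):
            s = site_records[int(rng.integers(0, len(site_records)))]
            off = int(rng.integers(1, half_width + 1)) * (1 if rng.random() < 0.5 else -1)
            pos = int(s.position) + off
            seq = proteome[s.protein_id]
            if not 1 <= pos <= len(seq):
                continue
            ref = seq[pos - 1]
            alt = letters[int(rng.integers(0, 20))]
            while alt == ref:
                alt = letters[int(rng.integers(0, 20))]
            rows.append((s.protein_id, pos, ref, alt))
            placed = True
            break
        if not placed:
            skipped += 1

    pids = list(proteome)
    for _ in range(n_outside):
        placed = False
        for _try in range(max_tries):
            pid = pids[int(rng.integers(0, len(pids)))]
            seq = proteome[pid]
            pos = int(rng.integers(1, len(seq) + 1))
            if any(abs(pos - sp) <= half_width for sp in site_pos.get(pid, [])):
                continue
            ref = seq[pos - 1]
            alt = letters[int(rng.integers(0, 20))]
            while alt == ref:
                alt = letters[int(rng.integers(0, 20))]
            rows.append((pid, pos, ref, alt))
            placed = True
            break
        if not placed:
            skipped += 1
    if skipped:
        logger.warning("simulate_mutations: skipped %d unplaceable mutation(s)", skipped)
    return pd.DataFrame(rows, columns=["protein_id", "position", "ref", "alt"])
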