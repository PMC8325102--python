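"""Motif impact of missense mutations near phosphosites.

A substitution within ±7 residues of a phosphosite changes the site's motif
score by exactly the difference of two PWM weights (the score is additive
over positions):

    delta = lambda_mut − lambda_wt = w(alt, offset) − w(ref, offset).

Mutations of the acceptor residue itself (offset 0) abolish the site when
the alternate is not phosphorylatable and are flagged ``acceptor_loss``
rather than delta-scored; substitutions farther than 7 residues never change
the score.  The module also computes the in vitro kinase-assay statistic

    phosphorylation ratio (%) = (1 − area_with / area_without) × 100,

the fraction of the nonphosphopeptide consumed by the kinase reaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .motif import (
    ACCEPTORS,
    PositionWeightMatrix,
    SequenceWindow,
    ValidationError,
    score_window,
)

logger = logging.getLogger(__name__)

#: Default classification thresholds (config keys; conventions, see docs).
LOSS_DELTA = -1.0
GAIN_DELTA = 1.0
NO_CHANGE_BAND = 0.5


def match_mutations_to_sites(
    mutations: pd.DataFrame,
    sites: pd.DataFrame,
    proteome: dict[str, str],
    half_width: int = 7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair each mutation with every phosphosite within ``half_width`` residues.

    Returns (pairs, rejected).  A pair row has the site, the mutation and the
    signed offset (mutation position − site position); offset 0 pairs are
    flagged ``acceptor_site`` (acceptor-loss when alt is not S/T/Y).
    Mutations whose reference residue disagrees with the proteome are
    rejected with a reason.
    """
    pairs = []
    rejected = []
    by_protein: dict[str, list] = {}
    for s in sites.itertuples(index=False):
        by_protein.setdefault(s.protein_id, []).append(s)
    for m in mutations.itertuples(index=False):
        seq = proteome.get(m.protein_id)
        if seq is None:
            rejected.append((m.protein_id, m.position, m.ref, m.alt, "protein not in proteome"))
            continue
        if not 1 <= m.position <= len(seq):
            rejected.append((m.protein_id, m.position, m.ref, m.alt, "position out of bounds"))
            continue
        if seq[m.position - 1] != m.ref:
            rejected.append(
                (m.protein_id, m.position, m.ref, m.alt,
                 f"ref mismatch: proteome has {seq[m.position - 1]}")
            )
            continue
        if m.ref == m.alt:
            rejected.append((m.protein_id, m.position, m.ref, m.alt, "ref == alt"))
            continue
        for s in by_protein.get(m.protein_id, []):
            offset = int(m.position) - int(s.position)
            if abs(offset) > half_width:
                continue
            acceptor = offset == 0
            acceptor_loss = acceptor and m.alt not in ACCEPTORS
            pairs.append(
                (s.site_id, s.protein_id, s.position, m.position, offset,
                 m.ref, m.alt, acceptor, acceptor_loss)
            )
    if rejected:
        logger.warning("match_mutations_to_sites: rejected %d mutation(s)", len(rejected))
    pair_df = pd.DataFrame(
        pairs,
        columns=["site_id", "protein_id", "site_position", "mut_position", "offset",
                 "ref", "alt", "acceptor_site", "acceptor_loss"],
    )
    rej_df = pd.DataFrame(
        rejected, columns=["protein_id", "position", "ref", "alt", "reason"]
    )
    return pair_df, rej_df


@dataclass(frozen=True)
class MutationImpact:
    """Motif-score change of a single substitution near one phosphosite."""

    site_id: str
    ref: str
    alt: str
    offset: int
    lambda_wt: float
    lambda_mut: float
    delta: float
    impact_class: str


def classify_delta(
    delta: float,
    lambda_wt: float,
    lambda_mut: float,
    score_threshold: float = 2.0,
    loss_delta: float = LOSS_DELTA,
    gain_delta: float = GAIN_DELTA,
    no_change_band: float = NO_CHANGE_BAND,
) -> str:
    """Loss / no_change / gain / indeterminate classification of a delta.

    Loss: delta ≤ loss_delta, or the mutation pushes a passing site
    (lambda_wt > threshold) below the threshold.  No-change: |delta| within
    the band.  Gain: delta ≥ gain_delta.  Anything else: indeterminate.
    """
    if delta <= loss_delta or (lambda_wt > score_threshold and lambda_mut <= score_threshold):
        return "loss"
    if abs(delta) < no_change_band:
        return "no_change"
    if delta >= gain_delta:
        return "gain"
    return "indeterminate"


def delta_motif_score(
    pwm: PositionWeightMatrix,
    window_wt: SequenceWindow,
    offset: int,
    ref: str,
    alt: str,
    score_threshold: float = 2.0,
) -> MutationImpact:
    """Score a substitution at a flanking offset of a phosphosite window.

    ``lambda_mut`` is computed on the substituted window; additivity
    guarantees it differs from ``lambda_wt`` by w(alt) − w(ref) at the
    offset, which is asserted.
    """
    if not 1 <= abs(offset) <= window_wt.half_width:
        raise ValidationError(f"offset must satisfy 1 <= |offset| <= {window_wt.half_width}")
    have = window_wt.residue_at(offset)
    if have != ref:
        raise ValidationError(
            f"window residue at offset {offset} is {have!r}, mutation says {ref!r}"
        )
    lam_wt = score_window(pwm, window_wt).lam
    window_mut = window_wt.substitute(offset, alt)
    lam_mut = score_window(pwm, window_mut).lam
    delta = lam_mut - lam_wt
    expected = pwm.weight(alt, offset) - pwm.weight(ref, offset)
    if abs(delta - expected) > 1e-9:
        raise AssertionError(
            f"additivity violated: delta={delta!r}, weight difference={expected!r}"
        )
    return MutationImpact(
        site_id=(
            f"{window_wt.protein_id}_{window_wt.center_residue}{window_wt.position}"
            if window_wt.protein_id
            else ""
        ),
        ref=ref,
        alt=alt,
        offset=offset,
        lambda_wt=lam_wt,
        lambda_mut=lam_mut,
        delta=delta,
        impact_class=classify_delta(delta, lam_wt, lam_mut, score_threshold),
    )


def score_mutation_impacts(
    pwm: PositionWeightMatrix,
    pairs: pd.DataFrame,
    proteome: dict[str, str],
    half_width: int = 7,
    score_threshold: float = 2.0,
) -> pd.DataFrame:
    """Delta-score every mutation/site pair from :func:`match_mutations_to_sites`.

    Acceptor-position pairs are carried through with class ``acceptor_loss``
    (alt not phosphorylatable) or ``acceptor_swap`` and no delta.  The
    wild-type window is extracted from the proteome around the site.
    """
    from .motif import extract_window

    rows = []
    for p in pairs.itertuples(index=False):
        seq = proteome[p.protein_id]
        win = extract_window(seq, int(p.site_position), half_width=half_width, protein_id=p.protein_id)
        lam_wt = score_window(pwm, win).lam
        if p.acceptor_site:
            cls = "acceptor_loss" if p.acceptor_loss else "acceptor_swap"
            rows.append(
                (p.site_id, p.ref, p.alt, p.offset, lam_wt, float("nan"), float("nan"), cls)
            )
            continue
        impact = delta_motif_score(
            pwm, win, int(p.offset), p.ref, p.alt, score_threshold=score_threshold
        )
        rows.append(
            (p.site_id, p.ref, p.alt, p.offset, impact.lambda_wt,
             impact.lambda_mut, impact.delta, impact.impact_class)
        )
    return pd.DataFrame(
        rows,
        columns=["site_id", "ref", "alt", "offset", "lambda_wt", "lambda_mut", "delta", "class"],
    )


def phosphorylation_ratio(area_without: float, area_with: float) -> float:
    """In vitro assay statistic: (1 − area_with/area_without) × 100 (percent).

    ``area_without`` is the nonphosphopeptide peak area without kinase,
    ``area_with`` the same peptide's area after the kinase reaction; 100%
    means complete consumption.  Negative values (area_with > area_without)
    are returned as-is and flagged by the caller.
    """
    if area_without <= 0:
        raise ValidationError("area_without must be > 0")
    if area_with < 0:
        raise ValidationError("area_with must be >= 0")
    return (1.0 - area_with / area_without) * 100.0
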