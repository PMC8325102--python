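"""Three-way evidence intersection: interactome × perturbation × motif.

A phosphosite is called a substrate only when (i) it lies on a protein
proximal to the kinase (interactor filter), (ii) its phosphorylation level
responds to kinase perturbation in the expected direction (regulated
filter), and (iii) its flanking sequence matches the kinase's motif
(lambda strictly greater than the score threshold).  The module also
reports the seven-region Venn decomposition of the three evidence sets and
recovery metrics against synthetic ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motif import ValidationError
from .synth import SyntheticTruthLabels

logger = logging.getLogger(__name__)


def map_sites_to_interactors(sites: pd.DataFrame, interactor_ids) -> pd.DataFrame:
    """Flag each site whose protein is in the interactor set (no rows dropped)."""
    ids = set(interactor_ids)
    out = sites.copy()
    out["on_interactor"] = out["protein_id"].isin(ids)
    return out


@dataclass(frozen=True)
class VennCounts:
    """Counts of the 7 nonempty regions of the three evidence sets.

    I = interactor-site set, R = regulated set, M = motif-pass set;
    e.g. ``i_only`` counts sites with only the interactor flag.
    """

    i_only: int
    r_only: int
    m_only: int
    ir_only: int
    im_only: int
    rm_only: int
    irm: int

    @property
    def total_flagged(self) -> int:
        return sum(
            (self.i_only, self.r_only, self.m_only,
             self.ir_only, self.im_only, self.rm_only, self.irm)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": ["I_only", "R_only", "M_only", "IR_only", "IM_only", "RM_only", "IRM"],
                "count": [self.i_only, self.r_only, self.m_only,
                          self.ir_only, self.im_only, self.rm_only, self.irm],
            }
        )


def call_substrates(
    flagged_sites: pd.DataFrame,
    regulated: pd.DataFrame,
    motif_scores: pd.DataFrame,
    score_threshold: float = 2.0,
) -> tuple[pd.DataFrame, VennCounts]:
    """Final substrate calls = interactor ∧ regulated ∧ (lambda > threshold).

    ``flagged_sites`` must carry ``on_interactor`` (see
    :func:`map_sites_to_interactors`); ``regulated`` is the regulated-site
    call table (``passed`` column); ``motif_scores`` carries ``lambda``.
    The evaluated universe is the site universe of ``flagged_sites``; motif
    scores for unknown sites are logged and ignored.  The motif threshold
    is strict (a score exactly at the threshold does not pass).
    """
    if not np.isfinite(score_threshold):
        raise ValidationError("score_threshold must be finite")
    universe = flagged_sites["site_id"]
    if universe.duplicated().any():
        raise ValidationError("duplicate site_id in site universe")
    stray = set(motif_scores["site_id"]) - set(universe)
    if stray:
        logger.warning(
            "call_substrates: %d motif score(s) for sites outside the universe ignored", len(stray)
        )
    reg_pass = set(regulated.loc[regulated["passed"], "site_id"])
    lam = motif_scores.set_index("site_id")["lambda"]

    out = flagged_sites.copy()
    out["regulated"] = out["site_id"].isin(reg_pass)
    out["lambda"] = out["site_id"].map(lam)
    out["motif_pass"] = out["lambda"] > score_threshold
    out["motif_pass"] = out["motif_pass"].fillna(False).astype(bool)
    out["final"] = out["on_interactor"] & out["regulated"] & out["motif_pass"]
    # protein-level rollup: a substrate protein is any protein with a final site
    substrate_proteins = set(out.loc[out["final"], "protein_id"])
    out["substrate_protein"] = out["protein_id"].isin(substrate_proteins)

    i = out["on_interactor"].to_numpy()
    r = out["regulated"].to_numpy()
    m = out["motif_pass"].to_numpy()
    venn = VennCounts(
        i_only=int((i & ~r & ~m).sum()),
        r_only=int((~i & r & ~m).sum()),
        m_only=int((~i & ~r & m).sum()),
        ir_only=int((i & r & ~m).sum()),
        im_only=int((i & ~r & m).sum()),
        rm_only=int((~i & r & m).sum()),
        irm=int((i & r & m).sum()),
    )
    logger.info(
        "substrate calling (lambda > %g): %d final calls on %d proteins out of %d sites",
        score_threshold, int(out["final"].sum()), len(substrate_proteins), len(out),
    )
    return out, venn


def evaluate_recovery(
    calls: pd.DataFrame, truth: SyntheticTruthLabels
) -> dict[str, float]:
    """Sensitivity / precision / F1 of final calls against planted truth.

    Sensitivity = TP/(TP+FN) over planted true sites; precision = TP/(TP+FP)
    over final calls (NaN when there are no calls); F1 harmonic mean (NaN
    when undefined).  Counts are included for context.
    """
    if not truth.true_substrate_sites:
        raise ValidationError("truth labels contain no true substrate sites")
    final = set(calls.loc[calls["final"], "site_id"])
    true = truth.true_substrate_sites
    tp = len(final & true)
    fp = len(final - true)
    fn = len(true - final)
    sensitivity = tp / (tp + fn)
    precision = tp / (tp + fp) if final else float("nan")
    if np.isnan(precision) or (precision + sensitivity) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "sensitivity": sensitivity, "precision": precision, "f1": f1,
    }
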