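"""Regulated-phosphosite calling from a kinase-perturbation experiment.

Input is a peptide-level table of treated/control log2 ratios (TMT-style
triplicates).  The cascade: keep monophosphopeptides only (so each ratio is
attributable to a single site), keep confidently localized sites
(localization probability strictly > 0.75 by default), average peptide
ratios to sites per replicate, then call sites whose replicate-mean log2
ratio clears a direction-aware fold-change cutoff (down for a kinase
inhibitor, up for an activator) with a significant one-sample t-test
against zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .motif import ValidationError

logger = logging.getLogger(__name__)

SITE_META = ["site_id", "protein_id", "position", "residue"]


def ratio_columns(records: pd.DataFrame) -> list[str]:
    cols = [c for c in records.columns if c.startswith("ratio_")]
    if len(cols) < 2:
        raise ValidationError("need >= 2 replicate ratio_* columns")
    return cols


def select_monophospho(records: pd.DataFrame) -> pd.DataFrame:
    """Keep rows with exactly one phosphate (phospho_count == 1)."""
    out = records[records["phospho_count"] == 1].copy()
    logger.info("monophospho filter: %d -> %d rows", len(records), len(out))
    return out


def filter_localization(records: pd.DataFrame, min_prob: float = 0.75) -> pd.DataFrame:
    """Keep rows with localization probability strictly greater than ``min_prob``."""
    if not 0.0 <= min_prob <= 1.0:
        raise ValidationError("min_prob must be in [0, 1]")
    out = records[records["loc_prob"] > min_prob].copy()
    logger.info("localization filter (> %g): %d -> %d rows", min_prob, len(records), len(out))
    return out


def aggregate_to_sites(records: pd.DataFrame) -> pd.DataFrame:
    """Average peptide-level log2 ratios to sites, per replicate.

    Returns one row per site with the site metadata, ``n_peptides`` and the
    replicate ratio columns.  A site whose peptides disagree on protein,
    position or residue is an input error.
    """
    rcols = ratio_columns(records)
    if records.empty:
        return pd.DataFrame(columns=SITE_META + ["n_peptides"] + rcols)
    meta_nunique = records.groupby("site_id")[SITE_META[1:]].nunique()
    bad = meta_nunique[(meta_nunique > 1).any(axis=1)].index.tolist()
    if bad:
        raise ValidationError(f"inconsistent site metadata for site(s): {bad}")
    grouped = records.groupby("site_id", sort=False)
    out = grouped[rcols].mean()
    out.insert(0, "n_peptides", grouped.size())
    meta = grouped[SITE_META[1:]].first()
    out = meta.join(out).reset_index()
    return out[SITE_META + ["n_peptides"] + rcols]


def call_regulated(
    site_table: pd.DataFrame,
    direction: str,
    fc_cutoff: float = 2.0,
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Direction-aware regulated-site calls on aggregated site vectors.

    ``mean_log2_ratio`` is the mean over replicates; ``p_value`` is a
    two-tailed one-sample t-test of the replicate ratios against 0.
    ``passed`` requires mean ≤ −log2(fc) (direction="down") or
    mean ≥ +log2(fc) (direction="up") and p < p_cutoff.  Zero replicate
    variance makes a site untestable (never passed).
    """
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    if fc_cutoff <= 1 and not np.isinf(fc_cutoff):
        raise ValidationError("fc_cutoff must be > 1")
    if not 0 < p_cutoff < 1:
        raise ValidationError("p_cutoff must be in (0, 1)")
    rcols = ratio_columns(site_table)
    vals = site_table[rcols].to_numpy(dtype=float)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    untestable = sd == 0
    t = np.full(len(vals), np.nan)
    p = np.full(len(vals), np.nan)
    ok = ~untestable
    if ok.any():
        res = stats.ttest_1samp(vals[ok], popmean=0.0, axis=1)
        t[ok], p[ok] = res.statistic, res.pvalue
    thr = np.log2(fc_cutoff)
    sign_ok = mean <= -thr if direction == "down" else mean >= thr
    passed = ok & sign_ok & (p < p_cutoff)
    out = site_table[SITE_META + (["n_peptides"] if "n_peptides" in site_table else [])].copy()
    out["mean_log2_ratio"] = mean
    out["t_stat"] = t
    out["p_value"] = p
    out["untestable"] = untestable
    out["direction"] = direction
    out["passed"] = passed
    logger.info(
        "regulated-site calling (direction=%s, fc>=%g, p<%g): %d/%d sites passed",
        direction, fc_cutoff, p_cutoff, int(passed.sum()), len(out),
    )
    return out


def regulated_pipeline(
    records: pd.DataFrame,
    direction: str,
    fc_cutoff: float = 2.0,
    p_cutoff: float = 0.05,
    min_loc_prob: float = 0.75,
    monophospho_only: bool = True,
) -> pd.DataFrame:
    """Full cascade: monophospho → localization → aggregate → call."""
    out = select_monophospho(records) if monophospho_only else records
    out = filter_localization(out, min_prob=min_loc_prob)
    out = aggregate_to_sites(out)
    return call_regulated(out, direction=direction, fc_cutoff=fc_cutoff, p_cutoff=p_cutoff)
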