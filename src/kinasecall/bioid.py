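"""Interactor calling from a label-free BioID pulldown intensity matrix.

The procedure mirrors the standard proximity-labeling volcano analysis:
proteins quantified in too few replicates are dropped, remaining missing
values (missing-not-at-random dropouts near the detection limit) are imputed
from a downshifted normal distribution on the log2 scale, a two-tailed
Welch's t-test compares bait to control per protein, and interactors are
called by a fold-change / p-value cutoff pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .motif import ValidationError

logger = logging.getLogger(__name__)


class DegenerateDataError(ValueError):
    """Raised when a statistical test is undefined (e.g. both variances zero)."""


@dataclass
class QuantMatrix:
    """Protein × sample intensity table with group labels.

    ``data``: linear-scale intensities (> 0 where present), NaN = missing,
    index = unique protein ids.  ``groups``: sample column -> "bait"/"control".
    """

    data: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.groups.values()) - {"bait", "control"}
        if unknown:
            raise ValidationError(f"unknown group label(s): {sorted(unknown)}")
        for grp in ("bait", "control"):
            if len(self.columns_of(grp)) < 2:
                raise ValidationError(f"need >= 2 replicates in group {grp!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein ids: {dups[:5]}")
        with np.errstate(invalid="ignore"):
            if (self.data.to_numpy() <= 0).any():
                raise ValidationError("intensities must be positive where present")

    def columns_of(self, group: str) -> list[str]:
        return [c for c, g in self.groups.items() if g == group]

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def log2(self) -> pd.DataFrame:
        return np.log2(self.data)


def filter_replicate_presence(
    matrix: QuantMatrix, min_present: int = 2, scope: str = "bait-group"
) -> QuantMatrix:
    """Keep proteins observed in at least ``min_present`` replicates.

    ``scope``: "bait-group" (default) counts presence within the bait columns;
    "any-group" keeps a protein if either group meets the threshold.
    """
    if scope not in ("bait-group", "any-group"):
        raise ValidationError(f"scope must be 'bait-group' or 'any-group', got {scope!r}")
    bait = matrix.columns_of("bait")
    ctrl = matrix.columns_of("control")
    if min_present > max(len(bait), len(ctrl)):
        raise ValidationError(
            f"min_present={min_present} exceeds replicate count"
        )
    present_bait = matrix.data[bait].notna().sum(axis=1)
    if scope == "bait-group":
        keep = present_bait >= min_present
    else:
        present_ctrl = matrix.data[ctrl].notna().sum(axis=1)
        keep = (present_bait >= min_present) | (present_ctrl >= min_present)
    out = matrix.data.loc[keep]
    logger.info(
        "replicate-presence filter (scope=%s, min_present=%d): %d -> %d proteins",
        scope, min_present, len(matrix.data), len(out),
    )
    return QuantMatrix(data=out.copy(), groups=dict(matrix.groups))


def impute_missing(
    matrix: QuantMatrix,
    shift_sd: float = 1.8,
    width_sd: float = 0.3,
    seed: int = 0,
    scope: str = "column",
) -> QuantMatrix:
    """Impute missing intensities from a downshifted normal on the log2 scale.

    Per sample column (or globally with ``scope='global'``), missing log2
    intensities are drawn from Normal(mean − shift_sd·sd, (width_sd·sd)²)
    where mean and sd are computed over the observed log2 values.  This
    places imputed values around the detection limit, matching the MNAR
    dropout mechanism.  Observed values are untouched; deterministic per seed.
    """
    if shift_sd <= 0 or width_sd <= 0:
        raise ValidationError("shift_sd and width_sd must be > 0")
    if scope not in ("column", "global"):
        raise ValidationError(f"scope must be 'column' or 'global', got {scope!r}")
    log2 = matrix.log2()
    rng = np.random.default_rng(seed)
    out = log2.copy()
    if scope == "global":
        obs = log2.to_numpy()
        obs = obs[~np.isnan(obs)]
        if obs.size < 2:
            raise ValidationError("fewer than 2 observed values in matrix")
        mu, sd = float(np.mean(obs)), float(np.std(obs, ddof=1))
        arr = out.to_numpy(copy=True)
        mask = np.isnan(arr)
        arr[mask] = rng.normal(mu - shift_sd * sd, width_sd * sd, size=int(mask.sum()))
        out = pd.DataFrame(arr, index=out.index, columns=out.columns)
    else:
        for col in log2.columns:
            vals = log2[col]
            obs = vals.dropna()
            if len(obs) < 2:
                raise ValidationError(f"column {col!r} has fewer than 2 observed values")
            mu, sd = float(obs.mean()), float(obs.std(ddof=1))
            miss = vals.isna()
            if miss.any():
                out.loc[miss, col] = rng.normal(
                    mu - shift_sd * sd, width_sd * sd, size=int(miss.sum())
                )
    data = np.power(2.0, out)
    return QuantMatrix(data=data, groups=dict(matrix.groups))


def welch_test(group_a, group_b) -> tuple[float, float, float]:
    """Two-tailed Welch's t-test; returns (t, df, p).

    ``t = (mean_a − mean_b) / sqrt(s²_a/n_a + s²_b/n_b)`` with
    Welch–Satterthwaite degrees of freedom.  Raises
    :class:`DegenerateDataError` when both sample variances are zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise DegenerateDataError("both group variances are zero")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def call_interactors(
    matrix: QuantMatrix, fc_cutoff: float = 2.0, p_cutoff: float = 0.05
) -> pd.DataFrame:
    """Volcano-style interactor calls on a complete (post-imputation) matrix.

    Per protein: log2_ratio = mean(log2 bait) − mean(log2 control), Welch's
    t-test on the log2 intensities, and
    ``passed = (log2_ratio >= log2(fc_cutoff)) & (p < p_cutoff)``.
    Degenerate rows (both variances zero, unequal means) are marked
    untestable and never pass.
    """
    if fc_cutoff <= 1 and not np.isinf(fc_cutoff):
        raise ValidationError("fc_cutoff must be > 1")
    if not 0 < p_cutoff < 1:
        raise ValidationError("p_cutoff must be in (0, 1)")
    if matrix.data.empty:
        logger.warning("call_interactors: empty matrix")
        return pd.DataFrame(
            columns=["protein_id", "log2_ratio", "t_stat", "df", "p_value", "untestable", "passed"]
        )
    if matrix.n_missing:
        raise ValidationError(
            f"matrix has {matrix.n_missing} missing cells; impute before calling"
        )
    log2 = matrix.log2()
    bait = log2[matrix.columns_of("bait")].to_numpy()
    ctrl = log2[matrix.columns_of("control")].to_numpy()
    rows = []
    log2_fc = np.log2(fc_cutoff)
    for pid, a, b in zip(matrix.data.index, bait, ctrl):
        ratio = float(np.mean(a) - np.mean(b))
        try:
            t, df, p = welch_test(a, b)
            untestable = False
        except DegenerateDataError:
            t, df, p = np.nan, np.nan, np.nan
            untestable = True
        passed = (not untestable) and ratio >= log2_fc and p < p_cutoff
        rows.append((pid, ratio, t, df, p, untestable, passed))
    out = pd.DataFrame(
        rows, columns=["protein_id", "log2_ratio", "t_stat", "df", "p_value", "untestable", "passed"]
    )
    logger.info(
        "interactor calling (fc>=%g, p<%g): %d/%d proteins passed",
        fc_cutoff, p_cutoff, int(out["passed"].sum()), len(out),
    )
    return out


def volcano_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot export: x = log2 ratio, y = −log10 p."""
    out = calls[["protein_id", "log2_ratio"]].copy()
    out["neg_log10_p"] = -np.log10(calls["p_value"])
    out["passed"] = calls["passed"]
    return out
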