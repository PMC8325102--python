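"""Pseudocount-regularized position weight matrices for phosphosite motifs.

The motif model is a per-position log-odds table over the ±7 residues
flanking a phosphoacceptor (S/T/Y).  Given ``N`` training windows, the
probability of residue ``x`` at flanking offset ``i`` is

    p(x, i) = (f(x, i) + c(x)) / (N + eps),    c(x) = p(x) * eps,
    eps     = sqrt(N),

where ``f(x, i)`` is the observed count and ``p(x)`` the background
(proteome-wide) residue probability.  The pseudocount ``c(x)`` keeps every
probability strictly positive, so the log-odds weight

    w(x, i) = log2(p(x, i) / p(x))

is always finite.  A candidate window scores

    lambda = sum_i w(q_i, i)

over its non-pad flanking positions; windows near a protein terminus carry
pad symbols that contribute zero weight.

Terminus convention: a pad observation at column ``i`` carries no residue
information, so its unit of count mass is redistributed over the alphabet in
proportion to the background:

    p(x, i) = (f(x, i) + p(x) * (eps + n_pad_i)) / (N + eps).

For pad-free columns this reduces exactly to the formula above; every column
sums to one analytically either way, and a fully-padded column collapses to
the background (all weights zero).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter codes.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

#: Phosphoacceptor residues.
ACCEPTORS: str = "STY"

#: Pad symbol used beyond protein termini.
PAD: str = "-"


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def flank_offsets(half_width: int = 7, include_center: bool = False) -> tuple[int, ...]:
    """Ordered offsets -half_width..+half_width, with 0 only if center-inclusive."""
    offs = list(range(-half_width, 0)) + ([0] if include_center else []) + list(
        range(1, half_width + 1)
    )
    return tuple(offs)


@dataclass(frozen=True)
class SequenceWindow:
    """A phosphosite with its centered flanking sequence.

    ``flanks`` maps one character per flanking offset (ordered
    -half_width..-1, +1..+half_width); positions beyond the protein termini
    hold the pad symbol.  ``position`` is the 1-based protein coordinate of
    the center residue, matching site names like "S1377".
    """

    protein_id: str
    position: int
    center_residue: str
    flanks: str
    half_width: int = 7

    def __post_init__(self) -> None:
        if len(self.flanks) != 2 * self.half_width:
            raise ValidationError(
                f"flanks must have length {2 * self.half_width}, got {len(self.flanks)}"
            )

    @property
    def offsets(self) -> tuple[int, ...]:
        return flank_offsets(self.half_width)

    def residue_at(self, offset: int) -> str:
        """Residue at a flanking offset (or the center for offset 0)."""
        if offset == 0:
            return self.center_residue
        offs = self.offsets
        return self.flanks[offs.index(offset)]

    def full_window(self) -> str:
        """The (2*half_width+1)-character window including the center."""
        h = self.half_width
        return self.flanks[:h] + self.center_residue + self.flanks[h:]

    @classmethod
    def from_string(cls, window: str, protein_id: str = "", position: int = 0) -> "SequenceWindow":
        """Build from an odd-length centered window string (e.g. a 15-mer)."""
        if len(window) % 2 == 0 or len(window) < 3:
            raise ValidationError(
                f"centered window must have odd length >= 3, got {len(window)}"
            )
        h = len(window) // 2
        return cls(
            protein_id=protein_id,
            position=position,
            center_residue=window[h],
            flanks=window[:h] + window[h + 1 :],
            half_width=h,
        )

    def substitute(self, offset: int, residue: str) -> "SequenceWindow":
        """Return a copy with the residue at ``offset`` replaced."""
        if offset == 0:
            return SequenceWindow(
                self.protein_id, self.position, residue, self.flanks, self.half_width
            )
        offs = self.offsets
        i = offs.index(offset)
        flanks = self.flanks[:i] + residue + self.flanks[i + 1 :]
        return SequenceWindow(
            self.protein_id, self.position, self.center_residue, flanks, self.half_width
        )


@dataclass(frozen=True)
class MotifScore:
    """Summed log2-odds score of one window against a PWM."""

    protein_id: str
    position: int
    lam: float
    n_scored_positions: int


def extract_window(
    sequence: str, position: int, half_width: int = 7, protein_id: str = ""
) -> SequenceWindow:
    """Extract the ±half_width window around a 1-based position.

    Offsets beyond the sequence bounds become pad symbols, so windows at the
    termini are well defined (position 1 has ``half_width`` left pads).
    """
    n = len(sequence)
    if not 1 <= position <= n:
        raise ValidationError(
            f"position {position} out of bounds for protein {protein_id!r} of length {n}"
        )
    chars = []
    for off in flank_offsets(half_width):
        j = position + off  # 1-based
        chars.append(sequence[j - 1] if 1 <= j <= n else PAD)
    return SequenceWindow(
        protein_id=protein_id,
        position=position,
        center_residue=sequence[position - 1],
        flanks="".join(chars),
        half_width=half_width,
    )


def compute_background(
    records: Mapping[str, str] | Iterable, alphabet: str = ALPHABET
) -> pd.Series:
    """Proteome-wide residue probabilities p(x).

    ``records`` may be a mapping id -> sequence or an iterable of Biopython
    SeqRecords.  Residues outside ``alphabet`` are excluded from both the
    numerator and the denominator.  A residue absent from the proteome gets a
    floor of one pseudo-observation (then renormalized) so that p(x) > 0
    everywhere — p(x) appears in denominators downstream.
    """
    if hasattr(records, "values"):
        seqs = list(records.values())
    else:
        seqs = [str(getattr(r, "seq", r)) for r in records]
    if not seqs:
        raise ValidationError("proteome is empty")
    counts = pd.Series(0.0, index=list(alphabet))
    for s in seqs:
        vc = pd.Series(list(str(s).upper())).value_counts()
        common = vc.index.intersection(counts.index)
        counts[common] += vc[common]
    total = counts.sum()
    if total == 0:
        raise ValidationError("proteome contains no standard residues")
    zero = counts[counts == 0].index
    if len(zero) > 0:
        logger.warning(
            "background: %d residue(s) absent from proteome (%s); applying floor 1/%d",
            len(zero),
            "".join(zero),
            int(total),
        )
        counts[zero] = 1.0
    p = counts / counts.sum()
    return p


@dataclass
class PositionWeightMatrix:
    """Counts, probabilities and log2 weights for a flanking-residue motif.

    ``counts`` is residues × offsets (integer, pads excluded); ``pad_counts``
    holds per-offset pad totals; ``probs`` and ``weights`` are derived per the
    module formulas.  ``offsets`` may be signed flank offsets (centered mode)
    or 1-based column indices (positional mode, used for non-centered training
    windows such as toy examples).
    """

    alphabet: str
    offsets: tuple[int, ...]
    counts: pd.DataFrame
    n_sequences: int
    background: pd.Series
    centered: bool = True
    include_center: bool = False
    pad_counts: pd.Series = field(default=None)  # type: ignore[assignment]
    epsilon: float = field(init=False)
    probs: pd.DataFrame = field(init=False)
    weights: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        if self.pad_counts is None:
            self.pad_counts = pd.Series(0, index=list(self.offsets))
        self.epsilon = math.sqrt(self.n_sequences)
        self._derive()

    def _derive(self) -> None:
        N, eps = self.n_sequences, self.epsilon
        bg = self.background.reindex(list(self.alphabet))
        pseudo = np.outer(bg.to_numpy(), eps + self.pad_counts.to_numpy())
        probs = (self.counts.to_numpy() + pseudo) / (N + eps)
        self.probs = pd.DataFrame(
            probs, index=list(self.alphabet), columns=list(self.offsets)
        )
        self.weights = np.log2(self.probs.div(bg, axis=0))

    def weight(self, residue: str, offset: int) -> float:
        """w(residue, offset); pad or non-alphabet residues contribute 0."""
        if residue not in self.alphabet or offset not in self.offsets:
            return 0.0
        return float(self.weights.at[residue, offset])

    # ------------------------------------------------------------------ IO

    def to_tsv(self, path) -> None:
        """Serialize as TSV: # metadata lines, then count/prob/weight blocks."""
        lines = ["# kinasecall-pwm\tv1"]
        lines.append(f"# N\t{self.n_sequences}")
        lines.append(f"# epsilon\t{self.epsilon!r}")
        lines.append(f"# centered\t{int(self.centered)}")
        lines.append(f"# include_center\t{int(self.include_center)}")
        lines.append("# alphabet\t" + self.alphabet)
        lines.append(
            "# background\t"
            + "\t".join(f"{r}={float(self.background[r])!r}" for r in self.alphabet)
        )
        lines.append(
            "# pad_counts\t"
            + "\t".join(str(int(v)) for v in self.pad_counts.to_numpy())
        )
        header = "block\tresidue\t" + "\t".join(str(o) for o in self.offsets)
        lines.append(header)
        for block, df in (
            ("count", self.counts),
            ("prob", self.probs),
            ("weight", self.weights),
        ):
            for r in self.alphabet:
                vals = "\t".join(
                    repr(float(v)) if block != "count" else str(int(v)) for v in df.loc[r]
                )
                lines.append(f"{block}\t{r}\t{vals}")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "PositionWeightMatrix":
        meta: dict[str, str] = {}
        rows: list[list[str]] = []
        offsets: tuple[int, ...] = ()
        bg_items: dict[str, float] = {}
        pad_vals: list[int] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("# "):
                    parts = line[2:].split("\t")
                    key = parts[0]
                    if key == "background":
                        for item in parts[1:]:
                            r, v = item.split("=")
                            bg_items[r] = float(v)
                    elif key == "pad_counts":
                        pad_vals = [int(v) for v in parts[1:]]
                    else:
                        meta[key] = parts[1] if len(parts) > 1 else ""
                elif line.startswith("block\t"):
                    offsets = tuple(int(o) for o in line.split("\t")[2:])
                else:
                    rows.append(line.split("\t"))
        alphabet = meta["alphabet"]
        counts = pd.DataFrame(
            0, index=list(alphabet), columns=list(offsets), dtype=int
        )
        for parts in rows:
            if parts[0] == "count":
                counts.loc[parts[1]] = [int(v) for v in parts[2:]]
        pwm = cls(
            alphabet=alphabet,
            offsets=offsets,
            counts=counts,
            n_sequences=int(meta["N"]),
            background=pd.Series(bg_items).reindex(list(alphabet)),
            centered=bool(int(meta.get("centered", "1"))),
            include_center=bool(int(meta.get("include_center", "0"))),
            pad_counts=pd.Series(pad_vals, index=list(offsets)),
        )
        return pwm


def build_pwm(
    training_windows: Sequence,
    background: pd.Series,
    include_center: bool = False,
    alphabet: str | None = None,
) -> PositionWeightMatrix:
    """Build the PWM from training windows.

    Windows may be :class:`SequenceWindow` objects or raw strings.  Odd-length
    strings (>= 3) are treated as centered windows; even-length strings are
    positional (columns 1..L, no center — convenient for worked examples).
    Pad symbols and non-standard residues are excluded from the counts; their
    column mass is redistributed by the background (module docstring).
    """
    if len(training_windows) == 0:
        raise ValidationError("training set is empty")
    alphabet = alphabet or "".join(background.index)
    first = training_windows[0]
    if isinstance(first, SequenceWindow):
        half = first.half_width
        centered = True
        offsets = flank_offsets(half, include_center)
    else:
        L = len(first)
        centered = L % 2 == 1 and L >= 3
        if centered:
            half = L // 2
            offsets = flank_offsets(half, include_center)
        else:
            offsets = tuple(range(1, L + 1))

    counts = pd.DataFrame(0, index=list(alphabet), columns=list(offsets), dtype=int)
    pad_counts = pd.Series(0, index=list(offsets))
    n_nonstd = 0
    all_strings = all(not isinstance(w, SequenceWindow) for w in training_windows)
    if all_strings:
        L = len(first)
        for idx, win in enumerate(training_windows):
            if len(win) != L:
                raise ValidationError(
                    f"window {idx} has length {len(win)}, expected {L}"
                )
        arr = np.array([list(str(w)) for w in training_windows])
        for off in offsets:
            col_idx = (off + (L // 2)) if centered else (off - 1)
            residues, col_counts = np.unique(arr[:, col_idx], return_counts=True)
            for r, c in zip(residues, col_counts):
                if r in alphabet:
                    counts.at[r, off] += int(c)
                else:
                    if r != PAD:
                        n_nonstd += int(c)
                    pad_counts[off] += int(c)
    else:
        for idx, win in enumerate(training_windows):
            if not isinstance(win, SequenceWindow):
                win = SequenceWindow.from_string(str(win))
            if win.half_width != half:
                raise ValidationError(f"window {idx} has mismatched geometry")
            for off in offsets:
                r = win.residue_at(off)
                if r in alphabet:
                    counts.at[r, off] += 1
                else:
                    if r != PAD:
                        n_nonstd += 1
                    pad_counts[off] += 1
    if n_nonstd:
        logger.warning("build_pwm: skipped %d non-standard residue(s) in training", n_nonstd)
    return PositionWeightMatrix(
        alphabet=alphabet,
        offsets=offsets,
        counts=counts,
        n_sequences=len(training_windows),
        background=background,
        centered=centered,
        include_center=include_center,
        pad_counts=pad_counts,
    )


def score_window(
    pwm: PositionWeightMatrix,
    window: "SequenceWindow | str",
    unknown_policy: str = "skip",
) -> MotifScore:
    """Score one window: lambda = sum of w over non-pad positions.

    Pad positions contribute exactly 0; a non-alphabet residue at a flank
    position contributes 0 with a logged warning (``unknown_policy='skip'``,
    default) or raises (``'error'``).
    """
    if isinstance(window, str):
        if pwm.centered:
            window = SequenceWindow.from_string(window)
        else:
            lam = 0.0
            n_scored = 0
            for off in pwm.offsets:
                r = window[off - 1]
                if r in pwm.alphabet:
                    lam += pwm.weight(r, off)
                    n_scored += 1
                elif r != PAD:
                    _handle_unknown(r, off, unknown_policy)
            return MotifScore("", 0, lam, n_scored)
    lam = 0.0
    n_scored = 0
    for off in pwm.offsets:
        r = window.residue_at(off)
        if r in pwm.alphabet:
            lam += pwm.weight(r, off)
            n_scored += 1
        elif r != PAD:
            _handle_unknown(r, off, unknown_policy)
    return MotifScore(window.protein_id, window.position, lam, n_scored)


def _handle_unknown(residue: str, offset: int, policy: str) -> None:
    if policy == "error":
        raise ValidationError(f"residue {residue!r} at offset {offset} not in alphabet")
    logger.warning("scoring: residue %r at offset %d not in alphabet; contributes 0", residue, offset)


def score_sites(
    pwm: PositionWeightMatrix,
    sites: pd.DataFrame,
    proteome: Mapping[str, str],
    half_width: int = 7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every site of a table against the PWM.

    ``sites`` needs columns ``site_id, protein_id, position, residue``.
    Rows whose protein is missing from the proteome or whose stated residue
    disagrees with the sequence are excluded and reported in the second
    (error) frame; output ordering matches input ordering.
    """
    scores = []
    errors = []
    for row in sites.itertuples(index=False):
        pid, pos = row.protein_id, int(row.position)
        seq = proteome.get(pid)
        if seq is None:
            errors.append((row.site_id, pid, pos, "protein not in proteome"))
            continue
        if not 1 <= pos <= len(seq):
            errors.append((row.site_id, pid, pos, f"position out of bounds (len {len(seq)})"))
            continue
        if seq[pos - 1] != row.residue:
            errors.append(
                (row.site_id, pid, pos, f"residue mismatch: table {row.residue}, proteome {seq[pos - 1]}")
            )
            continue
        win = extract_window(seq, pos, half_width=half_width, protein_id=pid)
        ms = score_window(pwm, win)
        scores.append((row.site_id, pid, pos, row.residue, ms.lam, ms.n_scored_positions))
    if errors:
        logger.warning("score_sites: excluded %d row(s) with errors", len(errors))
    score_df = pd.DataFrame(
        scores, columns=["site_id", "protein_id", "position", "residue", "lambda", "n_scored"]
    )
    err_df = pd.DataFrame(errors, columns=["site_id", "protein_id", "position", "reason"])
    return score_df, err_df
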