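"""Readers and writers for the pipeline's file formats.

All tables are UTF-8, LF, tab-separated; metadata travels in ``#``-prefixed
header comment lines.  FASTA goes through Biopython.  Empty cells in
intensity columns are explicit missing values.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif import ValidationError

logger = logging.getLogger(__name__)

from . import __version__ as _VERSION

#: Required columns and dtypes per named table schema.
SCHEMAS: dict[str, dict[str, type]] = {
    "sites": {"site_id": str, "protein_id": str, "position": int, "residue": str},
    "site-quant": {
        "site_id": str, "protein_id": str, "position": int, "residue": str,
        "peptide_id": str, "phospho_count": int, "loc_prob": float,
    },
    "mutations": {"protein_id": str, "position": int, "ref": str, "alt": str},
    "truth": {"kind": str, "id": str},
    "scores": {"site_id": str, "protein_id": str, "position": int, "residue": str,
               "lambda": float},
    "interactors": {"protein_id": str, "log2_ratio": float, "p_value": float,
                    "passed": bool},
    "regulated": {"site_id": str, "mean_log2_ratio": float, "p_value": float,
                  "passed": bool},
    "calls": {"site_id": str, "protein_id": str, "final": bool},
}


def read_fasta(path) -> dict[str, str]:
    """Ordered mapping id -> uppercased sequence; duplicate ids are an error."""
    records: dict[str, str] = {}
    dups = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            dups.append(rec.id)
        records[rec.id] = str(rec.seq).upper()
    if dups:
        raise ValidationError(f"duplicate FASTA ids: {sorted(set(dups))}")
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    return records


def write_fasta(proteome: Mapping[str, str], path, width: int = 60) -> None:
    recs = [SeqRecord(Seq(s), id=pid, description="") for pid, s in proteome.items()]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(recs, fh, "fasta")


def _header_lines(extra: Mapping[str, str] | None = None) -> list[str]:
    lines = [f"# kinasecall {_VERSION}"]
    for k, v in (extra or {}).items():
        lines.append(f"# {k}\t{v}")
    return lines


def write_table(df: pd.DataFrame, path, metadata: Mapping[str, str] | None = None) -> None:
    """Write a TSV with ``#`` header comment lines; NaN becomes an empty cell."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(_header_lines(metadata)) + "\n")
        # repr gives the shortest exact decimal, so floats round-trip losslessly
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n",
                  float_format=lambda v: repr(float(v)))


def read_table(path, schema: str | None = None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`; validate against a schema.

    Schema validation checks required columns, coerces dtypes, and reports
    non-numeric cells with their row number.  Unknown extra columns are
    preserved with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if schema is not None:
        spec = SCHEMAS.get(schema)
        if spec is None:
            raise ValidationError(f"unknown schema {schema!r}")
        missing = [c for c in spec if c not in df.columns]
        if missing:
            raise ValidationError(
                f"missing required column(s) {missing} for schema {schema!r} in {path}"
            )
        extra = [c for c in df.columns if c not in spec and not c.startswith(("ratio_", "bait_", "control_"))]
        if extra:
            logger.warning("read_table(%s): extra column(s) preserved: %s", schema, extra)
    out = {}
    spec = SCHEMAS.get(schema, {}) if schema else {}
    for col in df.columns:
        want = spec.get(col)
        if want is None and (col.startswith("ratio_") or col.startswith(("bait_", "control_"))):
            want = float
        if want is bool:
            mapping = {"True": True, "False": False, "true": True, "false": False,
                       "1": True, "0": False}
            bad = ~df[col].isin(mapping)
            if bad.any():
                rows = (df.index[bad] + 2).tolist()[:5]
                raise ValidationError(
                    f"non-boolean value(s) in column {col!r} of {path}, file row(s) {rows}"
                )
            out[col] = df[col].map(mapping)
        elif want in (int, float):
            try:
                # astype(float) is correctly rounded, so written reprs
                # round-trip exactly (pd.to_numeric is not)
                coerced = df[col].replace("", "nan").astype(float)
            except ValueError:
                probe = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
                bad = probe.isna() & (df[col] != "")
                rows = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-basing
                raise ValidationError(
                    f"non-numeric value(s) in column {col!r} of {path}, file row(s) {rows}"
                ) from None
            if want is int:
                coerced = coerced.astype("int64")
            out[col] = coerced
        else:
            out[col] = df[col]
    return pd.DataFrame(out)


def write_bioid_matrix(matrix, path, metadata: Mapping[str, str] | None = None) -> None:
    """QuantMatrix -> TSV (protein_id, then <group>_<rep> columns; empty = missing)."""
    df = matrix.data.reset_index()
    write_table(df, path, metadata=metadata)


def read_bioid_matrix(path):
    """TSV -> QuantMatrix; groups are parsed from ``<group>_<rep>`` column names."""
    from .bioid import QuantMatrix

    df = pd.read_csv(path, sep="\t", comment="#")
    if "protein_id" not in df.columns:
        raise ValidationError(f"missing required column ['protein_id'] for schema 'bioid-matrix' in {path}")
    df = df.set_index("protein_id")
    groups = {}
    for c in df.columns:
        grp = c.rsplit("_", 1)[0]
        if grp not in ("bait", "control"):
            raise ValidationError(f"sample column {c!r} must be named <group>_<rep> with group bait/control")
        groups[c] = grp
        df[c] = pd.to_numeric(df[c], errors="raise")
    return QuantMatrix(data=df, groups=groups)


def write_windows(windows: list[str], path) -> None:
    """One training window per line."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(windows) + "\n")


def read_windows(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        wins = [line.strip().upper() for line in fh if line.strip() and not line.startswith("#")]
    if not wins:
        raise ValidationError(f"no windows in {path}")
    lengths = {len(w) for w in wins}
    if len(lengths) > 1:
        raise ValidationError(f"windows of mixed lengths {sorted(lengths)} in {path}")
    return wins


def write_truth(labels, path) -> None:
    rows = [("interactor", pid) for pid in sorted(labels.true_interactors)]
    rows += [("substrate_site", sid) for sid in sorted(labels.true_substrate_sites)]
    df = pd.DataFrame(rows, columns=["kind", "id"])
    write_table(df, path, metadata={"seed": str(labels.seed),
                                    "planted_effect_log2": repr(labels.planted_effect_log2)})


def read_truth(path):
    from .synth import SyntheticTruthLabels

    df = read_table(path, schema="truth")
    effect = float("nan")
    seed = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].strip().split("\t")
            if parts[0] == "seed":
                seed = int(parts[1])
            elif parts[0] == "planted_effect_log2":
                effect = float(parts[1])
    return SyntheticTruthLabels(
        true_interactors=set(df.loc[df["kind"] == "interactor", "id"]),
        true_substrate_sites=set(df.loc[df["kind"] == "substrate_site", "id"]),
        planted_effect_log2=effect,
        seed=seed,
    )
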