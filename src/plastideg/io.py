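"""Readers and writers for the delimited-text and FASTA formats.

One fixed unit system is enforced at the boundary: lengths in cm, thickness
in um, masses in g (BOD readings in mg O2), time in days. Comma- or
tab-delimited files are distinguished by extension (``.tsv`` -> tab,
anything else -> comma). Lines starting with ``#`` are header/comment lines
and are skipped by every reader; writers emit a provenance header (package
version, seed, config hash) so a rerun with identical inputs and seed
produces identical bytes.
"""

from __future__ import annotations

import csv
import hashlib
import io as _io
import json
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .errors import InvalidInputError, RowParseError, SchemaError
from .kinetics import SpecimenGeometry, SpecimenRecord
from .residues import NONSTANDARD_SYMBOLS, STANDARD_RESIDUES

__all__ = [
    "read_measurement_table",
    "read_thickness_series",
    "attach_thickness",
    "read_fasta_proteins",
    "read_orf_table",
    "read_bod_readings",
    "read_formula_table",
    "read_asv_counts",
    "read_table",
    "write_table",
    "write_fasta",
]

MEASUREMENT_COLUMNS = (
    "id",
    "polymer",
    "site",
    "days",
    "w_initial_g",
    "w_final_g",
    "length_cm",
    "width_cm",
    "thickness_um",
    "form",
)
_NUMERIC_MEASUREMENT = ("days", "w_initial_g", "w_final_g", "length_cm", "width_cm", "thickness_um")


def _delimiter(path: str | Path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, text) for non-comment, non-blank lines."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            yield lineno, line


def read_measurement_table(path: str | Path) -> list[SpecimenRecord]:
    """Read specimen measurements into typed records.

    Mandatory columns: id, polymer, site, days, w_initial_g, w_final_g,
    length_cm, width_cm, thickness_um, form. Unknown columns are preserved
    in each record's ``metadata``. Row-level parse failures (including
    locale-style decimal commas) are collected and raised together.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    rows = list(_data_lines(path))
    if not rows:
        raise SchemaError(f"{path}: empty file")
    delim = _delimiter(path)
    header = next(csv.reader([rows[0][1]], delimiter=delim))
    header = [h.strip() for h in header]
    missing = [c for c in MEASUREMENT_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}", missing=missing)
    extra = [c for c in header if c not in MEASUREMENT_COLUMNS]
    records: list[SpecimenRecord] = []
    errors: list[tuple[int, str]] = []
    for lineno, line in rows[1:]:
        cells = next(csv.reader([line], delimiter=delim))
        if len(cells) != len(header):
            errors.append((lineno, f"expected {len(header)} fields, got {len(cells)}"))
            continue
        raw = dict(zip(header, (c.strip() for c in cells)))
        values: dict[str, float] = {}
        bad = False
        for col in _NUMERIC_MEASUREMENT:
            try:
                values[col] = float(raw[col])
            except ValueError:
                errors.append((lineno, f"non-numeric value {raw[col]!r} in column {col!r}"))
                bad = True
        if bad:
            continue
        try:
            geometry = SpecimenGeometry(
                form=raw["form"],
                length_cm=values["length_cm"],
                width_cm=values["width_cm"],
                thickness_um=values["thickness_um"],
            )
            records.append(
                SpecimenRecord(
                    id=raw["id"],
                    polymer=raw["polymer"],
                    site=raw["site"],
                    deployment_days=values["days"],
                    w_initial_g=values["w_initial_g"],
                    w_final_g=values["w_final_g"],
                    geometry=geometry,
                    metadata={k: raw[k] for k in extra},
                )
            )
        except InvalidInputError as exc:
            errors.append((lineno, str(exc)))
    if errors:
        raise RowParseError(errors)
    return records


def read_thickness_series(path: str | Path) -> pd.DataFrame:
    """Read a long-format thickness series (id, day, thickness_um)."""
    df = read_table(path)
    missing = [c for c in ("id", "day", "thickness_um") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}", missing=missing)
    return df


def attach_thickness(records: Sequence[SpecimenRecord], series: pd.DataFrame) -> None:
    """Attach thickness time series to matching specimen records in place."""
    grouped = series.sort_values("day").groupby("id")
    by_id = {sid: list(zip(g["day"], g["thickness_um"])) for sid, g in grouped}
    for record in records:
        record.thickness_series = by_id.get(record.id, record.thickness_series)


def read_fasta_proteins(path: str | Path) -> dict[str, dict[str, int]]:
    """Residue counts per protein from a FASTA file.

    Sequences are case-folded to upper case; counts cover the 20 standard
    residues, with ambiguity/rare symbols tallied under ``nonstandard``.
    Duplicate identifiers and empty sequences are errors.
    """
    counts: dict[str, dict[str, int]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in counts:
            raise SchemaError(f"{path}: duplicate FASTA identifier {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise SchemaError(f"{path}: empty sequence for {rec.id!r}")
        tally = Counter(seq)
        entry = {r: tally.get(r, 0) for r in STANDARD_RESIDUES}
        entry["nonstandard"] = sum(tally[s] for s in tally if s not in STANDARD_RESIDUES)
        unknown = {
            s for s in tally if s not in STANDARD_RESIDUES and s not in NONSTANDARD_SYMBOLS
        }
        if unknown:
            raise SchemaError(
                f"{path}: sequence {rec.id!r} contains unrecognised symbol(s) {sorted(unknown)}"
            )
        counts[rec.id] = entry
    if not counts:
        raise SchemaError(f"{path}: no FASTA records")
    return counts


def read_orf_table(
    path: str | Path, fasta_path: str | Path | None = None
) -> pd.DataFrame:
    """Read ORF metadata, optionally merging residue counts from a FASTA file.

    Mandatory columns: orf_id, scaffold_id, coverage, length, class, genus,
    is_rpsC. With ``fasta_path``, per-residue count columns are joined by
    orf_id; ORFs without a sequence get zero counts.
    """
    df = read_table(path)
    mandatory = ("orf_id", "scaffold_id", "coverage", "length", "class", "genus", "is_rpsC")
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}", missing=missing)
    df["is_rpsC"] = (
        df["is_rpsC"].astype(str).str.strip().str.lower().isin(("1", "true", "yes", "y"))
    )
    if fasta_path is not None:
        counts = read_fasta_proteins(fasta_path)
        count_df = pd.DataFrame.from_dict(counts, orient="index")
        count_df.index.name = "orf_id"
        stale = [c for c in count_df.columns if c in df.columns]
        df = df.drop(columns=stale).merge(count_df, on="orf_id", how="left")
        fill_cols = list(STANDARD_RESIDUES) + ["nonstandard"]
        df[fill_cols] = df[fill_cols].fillna(0).astype(int)
    return df


def read_bod_readings(path: str | Path) -> pd.DataFrame:
    """Long-format BOD table: sample_id, day, bod_mg, is_blank."""
    df = read_table(path)
    missing = [c for c in ("sample_id", "day", "bod_mg", "is_blank") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}", missing=missing)
    df["is_blank"] = (
        df["is_blank"].astype(str).str.strip().str.lower().isin(("1", "true", "yes", "y"))
    )
    return df


def read_formula_table(path: str | Path) -> pd.DataFrame:
    """Monomer formula table: sample_id, formula, M (g/mol), w_mg."""
    df = read_table(path)
    missing = [c for c in ("sample_id", "formula", "M", "w_mg") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}", missing=missing)
    return df


def read_asv_counts(path: str | Path) -> pd.DataFrame:
    """Samples x taxa count matrix with the first column as sample_id index."""
    df = read_table(path)
    df = df.set_index(df.columns[0])
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric ASV counts ({exc})") from exc
    if not np.allclose(values, np.round(values)):
        raise SchemaError(f"{path}: non-integer ASV counts")
    df = values.astype(int)
    if (df.values < 0).any():
        raise SchemaError(f"{path}: negative ASV counts")
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    """Generic delimited read honouring the comment-header convention."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    return pd.read_csv(path, sep=_delimiter(path), comment="#")


def _config_hash(config: dict | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
    index: bool = False,
) -> Path:
    """Write a delimited table with a provenance header.

    The header records the package version, the seed governing any
    randomness, and a short hash of the run configuration; given identical
    inputs, seed and config the output bytes are identical. An empty frame
    yields a header-only file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"# plastideg {__version__}\n"
        f"# seed: {'none' if seed is None else seed}\n"
        f"# config: {_config_hash(config)}\n"
    )
    buf = _io.StringIO()
    if df.empty:
        buf.write("# warning: empty result\n")
    else:
        df.to_csv(buf, sep=_delimiter(path), index=index)
    path.write_text(header + buf.getvalue(), encoding="utf-8")
    return path


def write_fasta(sequences: dict[str, str], path: str | Path) -> Path:
    """Write protein sequences as FASTA, 60 columns per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return path
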