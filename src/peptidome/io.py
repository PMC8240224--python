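"""Readers and writers for the interchange formats.

PSM tables are TSV (or CSV) with a header naming every
:data:`~peptidome.model.PSM_COLUMNS` field; modifications are serialized
as semicolon-joined ``pos:type`` tokens.  Result tables round-trip:
integers bit-exactly, reals to 12 significant digits.
"""

from __future__ import annotations

import csv
import math
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .model import (
    AMINO_ACIDS,
    FREQUENCY_COLUMNS,
    PSM_COLUMNS,
    FrequencyRecord,
    PSMRecord,
    SchemaError,
    ValidationError,
)

_SEPS = {"tsv": "\t", "csv": ","}


def _sep(dialect: str) -> str:
    try:
        return _SEPS[dialect]
    except KeyError:
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}") from None


def parse_modifications(token: str):
    """Parse a semicolon-joined ``pos:type`` modification string."""
    token = (token or "").strip()
    if not token:
        return frozenset()
    mods = set()
    for part in token.split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            pos_s, mtype = part.split(":", 1)
            pos = int(pos_s)
        except ValueError:
            raise ValidationError(f"unparsable modification token {part!r}") from None
        mods.add((pos, mtype.strip()))
    return frozenset(mods)


def format_modifications(mods) -> str:
    return ";".join(f"{pos}:{mtype}" for pos, mtype in sorted(mods))


def read_psm_table(path, dialect: str = "tsv") -> list[PSMRecord]:
    """Read and validate a PSM table; row order is preserved.

    Raises :class:`SchemaError` naming any missing column and
    :class:`ValidationError` carrying the 1-based data-row line number
    for malformed rows.
    """
    sep = _sep(dialect)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        header = reader.fieldnames or []
        missing = [c for c in PSM_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"PSM table {path} is missing columns: {missing}")
        records = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    PSMRecord(
                        spectrum_id=row["spectrum_id"],
                        sample_id=row["sample_id"],
                        fraction=row["fraction"],
                        treatment_id=int(row["treatment_id"]),
                        peptide=row["peptide"],
                        modifications=parse_modifications(row["modifications"]),
                        charge=int(row["charge"]),
                        engine=row["engine"],
                        score=float(row["score"]),
                        precursor_intensity=float(row["precursor_intensity"]),
                        protein_accession=row["protein_accession"],
                        gene_symbol=row["gene_symbol"],
                    )
                )
            except (ValidationError, ValueError, KeyError) as exc:
                raise ValidationError(f"{path} line {lineno}: {exc}") from exc
    return records


def write_psm_table(records: Iterable[PSMRecord], path, dialect: str = "tsv") -> None:
    sep = _sep(dialect)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(PSM_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.spectrum_id,
                    r.sample_id,
                    r.fraction,
                    r.treatment_id,
                    r.peptide,
                    format_modifications(r.modifications),
                    r.charge,
                    r.engine,
                    _fmt_real(r.score),
                    _fmt_real(r.precursor_intensity),
                    r.protein_accession,
                    r.gene_symbol,
                ]
            )


def _fmt_real(x: float) -> str:
    # 17 significant digits round-trips any IEEE double exactly.
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    return f"{x:.17g}"


def write_frequency_table(records: Iterable[FrequencyRecord], path) -> None:
    """Write frequency-comparison rows as TSV in fixed column order.

    ``(gene_symbol, stream)`` is the primary key; duplicates are
    rejected.
    """
    seen = set()
    rows = []
    for r in records:
        key = (r.gene_symbol, r.stream)
        if key in seen:
            raise ValidationError(f"duplicate (gene_symbol, stream) row: {key}")
        seen.add(key)
        rows.append(r)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(FREQUENCY_COLUMNS)
        for r in rows:
            writer.writerow(
                [
                    r.gene_symbol,
                    r.stream,
                    r.count_case,
                    r.count_control,
                    _fmt_real(r.corrected_control),
                    _fmt_real(r.delta),
                    _fmt_real(r.chi2),
                    _fmt_real(r.pvalue),
                    _fmt_real(r.qvalue),
                ]
            )


def read_frequency_table(path) -> list[FrequencyRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in FREQUENCY_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise SchemaError(f"frequency table {path} is missing columns: {missing}")
        out = []
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    FrequencyRecord(
                        gene_symbol=row["gene_symbol"],
                        stream=row["stream"],
                        count_case=int(row["count_case"]),
                        count_control=int(row["count_control"]),
                        corrected_control=float(row["corrected_control"]),
                        delta=float(row["delta"]),
                        chi2=float(row["chi2"]),
                        pvalue=float(row["pvalue"]),
                        qvalue=float(row["qvalue"]),
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path} line {lineno}: {exc}") from exc
    return out


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{accession: uppercased sequence}``.

    The accession is the first whitespace-delimited token after ``>``.
    Duplicate accessions, empty sequences, and gap/stop or other
    non-amino-acid characters are rejected.
    """
    mapping: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        seq = str(rec.seq).upper()
        if acc in mapping:
            raise ValidationError(f"duplicate accession {acc!r} in {path}")
        if not seq:
            raise ValidationError(f"empty sequence for accession {acc!r} in {path}")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"sequence {acc!r} contains illegal characters {sorted(bad)}"
            )
        mapping[acc] = seq
    return mapping


def read_edge_list(path) -> list[tuple[str, str]]:
    """Read a two-column TSV undirected edge list."""
    edges = []
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(
                    f"{path} line {lineno}: expected two tab-separated columns"
                )
            edges.append((parts[0], parts[1]))
    return edges


def frequency_frame(records: Iterable[FrequencyRecord]) -> pd.DataFrame:
    """Convenience view of FrequencyRecords as a DataFrame."""
    return pd.DataFrame([r.__dict__ for r in records], columns=list(FREQUENCY_COLUMNS))
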