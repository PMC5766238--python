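"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions
-----------
* GTF is 1-based inclusive on disk and converted to 0-based half-open
  coordinates on read (and back on write).
* BED6 is 0-based half-open, as usual.
* PFM files follow the JASPAR text layout: a ``>ID NAME`` header followed
  by four rows of counts (A, C, G, T), with or without the ``A [ ... ]``
  bracket decoration.
* Matrices travel as TSV with a header row, row ids in the first column
  and ``NA`` as the missing code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .intervals import GenomicInterval


class FormatError(ValueError):
    """Malformed record in an input file."""

    def __init__(self, path: str | Path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an in-memory mapping (synthetic genomes are small)."""
    fa = Fasta(str(path), sequence_always_upper=True, rebuild=True)
    out = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return out


# ---------------------------------------------------------------------------
# GTF


@dataclass
class GtfRecord:
    """One GTF line with coordinates converted to 0-based half-open."""

    chrom: str
    source: str
    feature: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


def _format_attributes(attrs: Mapping[str, str]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in attrs.items())


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def write_gtf(records: Iterable[GtfRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.chrom,
                        rec.source,
                        rec.feature,
                        str(rec.start + 1),  # back to 1-based inclusive
                        str(rec.end),
                        ".",
                        rec.strand,
                        ".",
                        _format_attributes(rec.attributes),
                    ]
                )
                + "\n"
            )


def read_gtf(path: str | Path) -> list[GtfRecord]:
    records: list[GtfRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(path, line_no, f"expected 9 fields, got {len(fields)}")
            chrom, source, feature, start, end, _, strand, _, attr_text = fields
            try:
                start0 = int(start) - 1
                end0 = int(end)
            except ValueError:
                raise FormatError(path, line_no, f"non-integer coordinates {start}/{end}")
            if start0 < 0 or start0 >= end0:
                raise FormatError(path, line_no, f"invalid span {start}-{end}")
            records.append(
                GtfRecord(chrom, source, feature, start0, end0, strand, _parse_attributes(attr_text))
            )
    return records


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals: Iterable[tuple[GenomicInterval, str]], path: str | Path) -> None:
    """Write (interval, name) pairs as BED6 with score 0."""
    with open(path, "w") as fh:
        for iv, name in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(path, line_no, "BED needs at least 3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"feature_{line_no}"
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
            if start < 0 or start >= end:
                raise FormatError(path, line_no, f"invalid BED span {start}-{end}")
            out.append((GenomicInterval(chrom, start, end, strand), name))
    return out


# ---------------------------------------------------------------------------
# JASPAR PFM

_PFM_ROWS = "ACGT"


def write_pfm(counts: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write motifs as JASPAR-style PFM text (``A [ ... ]`` rows)."""
    with open(path, "w") as fh:
        for motif_id, matrix in counts.items():
            matrix = np.asarray(matrix)
            if matrix.shape[0] != 4:
                raise ValueError(f"motif {motif_id}: expected 4 rows, got {matrix.shape[0]}")
            fh.write(f">{motif_id} {motif_id}\n")
            for row, base in enumerate(_PFM_ROWS):
                values = " ".join(f"{v:.0f}" if float(v).is_integer() else f"{v:g}" for v in matrix[row])
                fh.write(f"{base} [ {values} ]\n")


def read_pfm(path: str | Path) -> dict[str, np.ndarray]:
    """Parse JASPAR PFM text, accepting bracketed and bare count rows."""
    motifs: dict[str, np.ndarray] = {}
    current_id: str | None = None
    rows: list[list[float]] = []

    def flush(line_no: int) -> None:
        nonlocal current_id, rows
        if current_id is None:
            return
        if len(rows) != 4:
            raise FormatError(path, line_no, f"motif {current_id}: expected 4 count rows, got {len(rows)}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise FormatError(path, line_no, f"motif {current_id}: ragged count rows")
        motifs[current_id] = np.array(rows, dtype=float)
        current_id, rows = None, []

    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                current_id = line[1:].split()[0]
                continue
            if current_id is None:
                raise FormatError(path, line_no, "count row before any motif header")
            text = line
            if text[0] in "ACGTacgt" and (len(text) == 1 or not text[1].isdigit()):
                text = text[1:]
            text = text.replace("[", " ").replace("]", " ")
            try:
                rows.append([float(tok) for tok in text.split()])
            except ValueError:
                raise FormatError(path, line_no, f"unparseable count row: {line!r}")
    flush(line_no if "line_no" in dir() else 0)
    return motifs


# ---------------------------------------------------------------------------
# TSV matrices and JSON reports


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
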