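"""Readers and writers for every on-disk format the pipeline touches.

All tables are tab-separated UTF-8 with a single header row; missing values
are encoded as the empty string; dates are ISO-8601; coverage intervals are
0-based half-open.  Schemas are documented in ``docs/schemas.md`` and
enforced on read.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("halovir")

FASTA_WIDTH = 70


class SchemaError(ValueError):
    """Table does not match its documented schema."""


class DuplicateIdError(ValueError):
    """A FASTA file contains the same identifier twice."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContigRecord:
    """A contig plus its sample of origin.

    ``base_name`` strips any predictor trim-suffix (``<base><delim><coords>``)
    so full-length and trimmed variants of one assembly contig share it.
    """

    contig_id: str
    sequence: str
    sample_id: str
    site: str
    date: datetime.date
    fraction: str = "viral"

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def base_name(self, delimiter: str = "||") -> str:
        return strip_trim_suffix(self.contig_id, delimiter)


def strip_trim_suffix(contig_id: str, delimiter: str = "||") -> str:
    """Drop a trim-coordinate suffix appended by a provirus-trimming tool."""
    return contig_id.split(delimiter, 1)[0]


def parse_contig_id(contig_id: str, delimiter: str = "||") -> tuple[str, str, datetime.date]:
    """Recover ``(sample_id, site, date)`` from an id like ``LOC_2020-05-01_c00003``."""
    base = strip_trim_suffix(contig_id, delimiter)
    site, date_s, _ = base.split("_", 2)
    return f"{site}_{date_s}", site, datetime.date.fromisoformat(date_s)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> uppercase sequence mapping (insertion-ordered).

    An empty file yields an empty mapping; a duplicated identifier is an
    error naming the offending id.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise DuplicateIdError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else list(seqs)
    ids = [i for i, _ in items] if not isinstance(seqs, dict) else list(seqs)
    if len(ids) != len(set(ids)):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise DuplicateIdError(f"duplicate FASTA id {dup!r}")
    records = (SeqRecord(Seq(s), id=i, description="") for i, s in items)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WIDTH)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# tabular schemas
# ---------------------------------------------------------------------------

#: schema name -> ordered {column: dtype}; dtype is a pandas-compatible type.
TABLE_SCHEMAS: dict[str, dict[str, type]] = {
    "metadata": {
        "site": str, "date": str, "season": str, "temp_C": float,
        "do_mg_per_L": float, "salinity_ppt": float, "pH": float,
        "nh4_uM": float, "no3_uM": float, "no2_uM": float,
        "autofluor_cells_per_mL": float, "is_pulse": int, "is_freeze": int,
    },
    "predictor_calls": {"contig_id": str, "predictor": str, "called_length_bp": int},
    "read_counts": {"sample_id": str, "contig_id": str, "reads": int},
    "coverage": {"sample_id": str, "contig_id": str, "start": int, "end": int},
    "sample_depths": {"sample_id": str, "total_reads": int},
    "gene_taxonomy": {
        "contig_id": str, "gene_id": str, "realm": str, "kingdom": str,
        "phylum": str, "class": str, "order": str, "family": str,
        "environment": str,
    },
    "amg": {"contig_id": str, "gene_id": str, "kegg_pathway": str},
    "host_predictions": {"virus_id": str, "host_genome": str, "score": float},
    "mags": {
        "mag_id": str, "completion": float, "contamination": float,
        "domain": str, "phylum": str, "class": str, "order": str,
        "length_bp": int, "relative_abundance": float,
    },
    "votu_assignment": {"contig_id": str, "votu_id": str, "viral": int},
    "temporal_cluster": {"votu_id": str, "cluster_id": str},
}

#: numeric columns whose values must be non-negative
_NONNEGATIVE = {
    "metadata": ["salinity_ppt", "autofluor_cells_per_mL"],
    "coverage": ["start", "end"],
    "read_counts": ["reads"],
    "sample_depths": ["total_reads"],
    "mags": ["completion", "contamination", "length_bp"],
}


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read a TSV, validating it against the named schema.

    Missing required columns raise a :class:`SchemaError` listing them; an
    unparseable cell raises with its (1-based, header-exclusive) row number;
    unknown extra columns are preserved with a warning; a header-only file
    yields an empty, correctly-typed table.
    """
    if schema_name not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    schema = TABLE_SCHEMAS[schema_name]
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                     keep_default_na=False)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing} for schema {schema_name!r}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        logger.warning("%s: extra columns preserved: %s", path, extra)
    for col, typ in schema.items():
        if typ is str:
            continue
        converted = pd.to_numeric(df[col].replace("", pd.NA), errors="coerce")
        bad = converted.isna() & (df[col] != "")
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise SchemaError(
                f"{path}: unparseable {col!r} value {df[col][bad.idxmax()]!r} at row {row}")
        df[col] = converted.astype(float if typ is float else "int64" if not converted.isna().any() else "Int64")
    for col in _NONNEGATIVE.get(schema_name, []):
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals.dropna() < 0).any():
            raise SchemaError(f"{path}: column {col!r} must be non-negative")
    return df


def write_table(df: pd.DataFrame, path: str | Path, header_comments: Sequence[str] = ()) -> None:
    """Write a TSV with optional ``#`` comment lines before the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# the study's printed abiotic-conditions table
# ---------------------------------------------------------------------------

def load_field_metadata() -> pd.DataFrame:
    """The transcribed field table of abiotic conditions (16 site-month rows).

    Columns follow the ``metadata`` schema; nutrient values are the printed
    means (the printed plus/minus SDs are not retained).
    """
    with resources.as_file(resources.files("halovir.data") / "field_metadata.tsv") as p:
        return read_table(p, "metadata")
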