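"""Tabular and genomic I/O: insertion tables, gene models, model archives.

Factor tables are strict TSV with a mandatory header. Genomic inputs are BED6
(0-based half-open) for insertions and GTF (1-based closed) for gene models;
all internal arithmetic uses the 0-based half-open convention.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

FAMILIES = ("IAP", "ETnMusD")
ORIENTATIONS = ("sense", "antisense")
LABELS = ("positive", "negative", "unknown")

TABLE_COLUMNS = ["id", "family", "orientation", "intron_size_bp", "exon_distance_bp", "label"]

ARCHIVE_FORMAT_VERSION = 1


class TableFormatError(ValueError):
    """A factor table violates the schema; the message names the row/field."""


@dataclass
class ErvInsertion:
    """One intronic ERV insertion with its four raw factors.

    ``coords`` (chrom, start, end, strand) are 0-based half-open and only
    present when the record came from genomic inputs rather than a table.
    """

    id: str
    family: str
    orientation: str
    intron_size_bp: int
    exon_distance_bp: int
    label: Optional[str] = None
    gene_id: Optional[str] = None
    coords: Optional[tuple] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"record {self.id!r}: family must be one of {FAMILIES}, got {self.family!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"record {self.id!r}: orientation must be one of {ORIENTATIONS}, got {self.orientation!r}"
            )
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"record {self.id!r}: label must be one of {LABELS}, got {self.label!r}")
        if self.intron_size_bp <= 0:
            raise ValueError(f"record {self.id!r}: intron_size_bp must be positive, got {self.intron_size_bp}")
        if self.exon_distance_bp < 0:
            raise ValueError(
                f"record {self.id!r}: exon_distance_bp must be non-negative, got {self.exon_distance_bp}"
            )
        if self.exon_distance_bp > self.intron_size_bp:
            raise ValueError(
                f"record {self.id!r}: exon_distance_bp ({self.exon_distance_bp}) exceeds "
                f"intron_size_bp ({self.intron_size_bp})"
            )


@dataclass
class GeneModel:
    """Flattened (union-of-exons) model of one gene.

    Exons are merged, sorted, 0-based half-open intervals; introns are the
    gaps between consecutive exons, ordered by genomic coordinate.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list  # list of (start, end)

    @property
    def introns(self) -> list:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]


def _parse_int(value, row_num: int, column: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise TableFormatError(f"row {row_num}: column {column!r} has unparseable integer {value!r}") from None


def read_insertion_table(path, require_labels: bool = False) -> list[ErvInsertion]:
    """Read a TSV factor table into validated records, in file order.

    Rows are numbered from 1 (first data row) in error messages. With
    ``require_labels`` every row must carry a positive/negative label,
    as needed for training tables.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    has_label = "label" in df.columns
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        label = row.get("label", "") if has_label else ""
        label = label.strip() or None
        if require_labels and label not in ("positive", "negative"):
            raise TableFormatError(f"row {i}: training table requires label positive/negative, got {label!r}")
        try:
            rec = ErvInsertion(
                id=row["id"],
                family=row["family"],
                orientation=row["orientation"],
                intron_size_bp=_parse_int(row["intron_size_bp"], i, "intron_size_bp"),
                exon_distance_bp=_parse_int(row["exon_distance_bp"], i, "exon_distance_bp"),
                label=label,
                gene_id=(row.get("gene_id") or None),
            )
        except ValueError as exc:
            if isinstance(exc, TableFormatError):
                raise
            raise TableFormatError(f"row {i}: {exc}") from None
        records.append(rec)
    return records


def write_insertion_table(records: Sequence[ErvInsertion], path) -> None:
    """Write records to TSV using the canonical column order."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "family": r.family,
                "orientation": r.orientation,
                "intron_size_bp": r.intron_size_bp,
                "exon_distance_bp": r.exon_distance_bp,
                "label": r.label or "",
                "gene_id": r.gene_id or "",
            }
        )
    pd.DataFrame(rows, columns=TABLE_COLUMNS + ["gene_id"]).to_csv(path, sep="\t", index=False)


def write_predictions(ids, likelihoods, calls, tau: float, path) -> None:
    """Write per-record predictions (id, likelihood, call, threshold) as TSV."""
    df = pd.DataFrame(
        {
            "id": list(ids),
            "likelihood": np.asarray(likelihoods, dtype=float),
            "call": ["positive" if c else "negative" for c in calls],
            "threshold": tau,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _merge_intervals(intervals):
    """Merge overlapping/adjacent intervals; returns (merged, had_overlap)."""
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    overlap = False
    for s, e in ivs[1:]:
        if s < merged[-1][1]:
            overlap = True
            merged[-1][1] = max(merged[-1][1], e)
        elif s == merged[-1][1]:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged], overlap


def read_gene_models(path) -> dict[str, GeneModel]:
    """Read gene models from a GTF file, flattening each gene to a union of exons.

    Overlapping exons within one gene are merged with a warning. GTF
    coordinates (1-based closed) are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_gene: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        gene_ids = exon.attributes.get("gene_id")
        if not gene_ids:
            raise ValueError(f"exon at {exon.seqid}:{exon.start}-{exon.end} lacks a gene_id attribute")
        gid = gene_ids[0]
        entry = per_gene.setdefault(gid, {"chrom": exon.seqid, "strand": exon.strand, "exons": []})
        # gffutils keeps GTF 1-based closed coordinates; convert here.
        entry["exons"].append((exon.start - 1, exon.end))
    genes = {}
    for gid, entry in per_gene.items():
        merged, overlap = _merge_intervals(entry["exons"])
        if overlap:
            warnings.warn(f"gene {gid}: overlapping exons merged", stacklevel=2)
        genes[gid] = GeneModel(gene_id=gid, chrom=entry["chrom"], strand=entry["strand"], exons=merged)
    return genes


def read_bed_insertions(path) -> list[dict]:
    """Read BED6 insertion intervals (chrom, start, end, name, score, strand)."""
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"{path} line {i}: BED6 requires 6 columns, got {len(fields)}")
        chrom, start, end, name, _score, strand = fields[:6]
        if strand not in ("+", "-"):
            raise ValueError(f"{path} line {i}: strand must be + or -, got {strand!r}")
        rows.append({"chrom": chrom, "start": int(start), "end": int(end), "name": name, "strand": strand})
    return rows


@dataclass
class ModelArchive:
    """Serializable container for a trained ensemble.

    ``members`` is a list of dicts, one per trained network, each holding the
    19 parameters at full precision plus split and reinit provenance.
    """

    format_version: int = ARCHIVE_FORMAT_VERSION
    members: list = field(default_factory=list)
    cv_plan_digest: str = ""
    training_config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)


def save_model_archive(archive: ModelArchive, path) -> None:
    """Write the archive as self-describing JSON; floats keep full precision."""
    payload = {
        "format_version": archive.format_version,
        "cv_plan_digest": archive.cv_plan_digest,
        "training_config": archive.training_config,
        "seeds": archive.seeds,
        "members": archive.members,
    }
    Path(path).write_text(json.dumps(payload))


def load_model_archive(path) -> ModelArchive:
    """Load a JSON archive; rejects unknown versions and truncated files."""
    text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: truncated or corrupt model archive ({exc})") from None
    version = payload.get("format_version")
    if version != ARCHIVE_FORMAT_VERSION:
        raise ValueError(f"{path}: unknown archive format_version {version!r}, expected {ARCHIVE_FORMAT_VERSION}")
    return ModelArchive(
        format_version=version,
        members=payload["members"],
        cv_plan_digest=payload.get("cv_plan_digest", ""),
        training_config=payload.get("training_config", {}),
        seeds=payload.get("seeds", {}),
    )
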