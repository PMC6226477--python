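"""File readers and writers: FASTA, counts TSV + sample sheet CSV, result tables.

Conventions: counts and result tables are TSV with the gene id in the
first column; sample sheets are CSV with columns
``sample_id,condition,assay,replicate``; sequences are FASTA wrapped at 60
columns; floating point output uses 6 significant digits.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import CountsMatrix, EnrichmentTable
from .motifs import TranscriptRecord, features_table
from .simulate import SimulationTruth

FLOAT_FORMAT = "%.6g"
SAMPLE_SHEET_COLUMNS = ["condition", "assay", "replicate"]


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs; duplicate ids are rejected."""
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append((rec.id, str(rec.seq)))
    return out


def write_fasta(records: Iterable[TranscriptRecord | tuple[str, str]], path) -> None:
    """Write records (TranscriptRecord or (id, seq) pairs) as 60-column FASTA."""
    seq_records = []
    for rec in records:
        if isinstance(rec, TranscriptRecord):
            rid, seq = rec.id, rec.sequence
        else:
            rid, seq = rec
        seq_records.append(SeqRecord(Seq(seq), id=rid, description=""))
    target = path if hasattr(path, "write") else str(path)
    SeqIO.write(seq_records, target, "fasta")


def read_counts(counts_path, samples_path) -> CountsMatrix:
    """Read a gene x sample counts TSV and its sample sheet CSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = "gene_id"
    samples = pd.read_csv(samples_path, index_col="sample_id")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample sheet {samples_path} lacks columns {missing}")
    return CountsMatrix(counts=counts, samples=samples)


def write_counts(cm: CountsMatrix, counts_path, samples_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.samples.to_csv(samples_path)


def write_features(records: Sequence[TranscriptRecord], path) -> None:
    features_table(records).to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_enrichment_table(table: EnrichmentTable | pd.DataFrame, path) -> None:
    frame = table.frame if isinstance(table, EnrichmentTable) else table
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_enrichment_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_truth(truth: SimulationTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
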