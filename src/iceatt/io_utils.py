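"""Shared readers and writers: FASTA, BED6, TSV tables, configs, manifests.

All tabular outputs carry headers and round-trip through the module's own
readers. Coordinates in BED output are 0-based, half-open; scan hits use
name = mismatch count and score = 17 - mismatches so that better matches
score higher.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .attsite import CORE_LENGTH, InsertionRecord, ScanHit

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_bed6",
    "read_bed6",
    "read_catalog",
    "write_catalog",
    "read_cq_table",
    "read_dilution_series",
    "read_config",
    "write_manifest",
    "file_checksum",
]


class FastaParseError(ValueError):
    pass


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into an order-preserving {id: sequence} dict.

    Sequences are uppercased; CRLF line endings and arbitrary line wrapping
    are tolerated. Raises on an empty file, a duplicate identifier, or
    content before the first header.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FastaParseError(f"{path}: empty FASTA file")
    first = text.lstrip().splitlines()[0]
    if not first.startswith(">"):
        raise FastaParseError(f"{path}: line 1: expected '>' header, got {first[:30]!r}")
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise FastaParseError(f"{path}: duplicate sequence id {record.id!r}")
        out[record.id] = str(record.seq).upper()
    if not out:
        raise FastaParseError(f"{path}: no records parsed")
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, *, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq.upper()), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_bed6(hits: Iterable[ScanHit], path: str | Path) -> None:
    """Write scan hits as BED6: name = mismatch count, score = 17 - mismatches."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.contig}\t{h.start}\t{h.end}\t{h.mismatches}\t"
                f"{CORE_LENGTH - h.mismatches}\t{h.strand}\n"
            )


def read_bed6(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig", "start", "end", "name", "score", "strand"],
    )


def read_catalog(path: str | Path) -> list[InsertionRecord]:
    """Read an insertion catalog TSV with columns locus, orientation,
    occurrences and optionally core_sequence, mismatches."""
    df = pd.read_csv(path, sep="\t")
    required = {"locus", "orientation", "occurrences"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog {path} is missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        from .attsite import AttSiteCore

        core = None
        if "core_sequence" in df.columns and isinstance(row.get("core_sequence"), str):
            core = AttSiteCore(row["core_sequence"])
        mm = None
        if "mismatches" in df.columns and pd.notna(row.get("mismatches")):
            mm = int(row["mismatches"])
        records.append(
            InsertionRecord(
                locus=str(row["locus"]),
                orientation=str(row["orientation"]),  # type: ignore[arg-type]
                occurrences=int(row["occurrences"]),
                core=core,
                mismatches=mm,
            )
        )
    return records


def write_catalog(records: Iterable[InsertionRecord], path: str | Path) -> None:
    rows = [
        {
            "locus": r.locus,
            "orientation": r.orientation,
            "occurrences": r.occurrences,
            "core_sequence": r.core.sequence if r.core else "",
            "mismatches": r.mismatches if r.mismatches is not None else "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cq_table(path: str | Path) -> pd.DataFrame:
    """Read a Cq table TSV with columns sample_id, target, replicate, cq."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "target", "replicate", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Cq table {path} is missing columns: {sorted(missing)}")
    return df


def read_dilution_series(path: str | Path) -> pd.DataFrame:
    """Read a dilution-series TSV with columns target, log10_copies, cq."""
    df = pd.read_csv(path, sep="\t")
    required = {"target", "log10_copies", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dilution series {path} is missing columns: {sorted(missing)}")
    return df


def read_config(path: str | Path) -> dict:
    """Read a key-value (YAML) run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: str | Path, manifest: Mapping) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
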