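"""Format readers/writers: FASTA, FASTQ (Phred+33), TSV; gzip transparent."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reads import FastqRead

__all__ = [
    "read_fasta",
    "read_fasta_descriptions",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_tsv",
    "write_tsv",
]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode, newline="" if "w" in mode else None)


def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> sequence; raises on malformed input naming the file."""
    out: dict[str, str] = {}
    try:
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                if rec.id in out:
                    raise ValueError(f"duplicate id {rec.id!r}")
                out[rec.id] = str(rec.seq).upper()
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return out


def read_fasta_descriptions(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            out[rec.id] = desc
    return out


def write_fasta(
    path: str | Path,
    sequences: dict[str, str],
    descriptions: dict[str, str] | None = None,
) -> None:
    records = [
        SeqRecord(
            Seq(seq),
            id=name,
            description=(descriptions or {}).get(name, ""),
        )
        for name, seq in sequences.items()
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fastq(path: str | Path) -> list[FastqRead]:
    """Parse Phred+33 FASTQ; malformed records raise with file context."""
    reads = []
    try:
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                reads.append(
                    FastqRead(
                        id=rec.id,
                        sequence=str(rec.seq).upper(),
                        qualities=tuple(rec.letter_annotations["phred_quality"]),
                    )
                )
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FASTQ record: {exc}") from exc
    return reads


def write_fastq(path: str | Path, reads: Iterable[FastqRead]) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Header-row TSV; CRLF input accepted."""
    return pd.read_csv(path, sep="\t")


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
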