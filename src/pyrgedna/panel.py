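"""Reference panel of named COI haplotypes with known localities."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .iupac import ConcreteSequence

__all__ = ["ReferenceRecord", "ReferencePanel"]


@dataclass(frozen=True)
class ReferenceRecord:
    id: str
    taxon: str
    sequence: str
    #: known localities as (lat, lon) WGS84 decimal degrees; may be empty
    localities: tuple[tuple[float, float], ...] = ()


def _check_coord(lat: float, lon: float) -> None:
    if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
        raise ValueError(f"invalid coordinates ({lat}, {lon})")


@dataclass
class ReferencePanel:
    records: list[ReferenceRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reference ids")
        for r in self.records:
            ConcreteSequence(r.sequence)  # validates
            for lat, lon in r.localities:
                _check_coord(lat, lon)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, ref_id: str) -> ReferenceRecord:
        for r in self.records:
            if r.id == ref_id:
                return r
        raise KeyError(ref_id)

    @property
    def sequences(self) -> dict[str, str]:
        return {r.id: r.sequence for r in self.records}

    # ------------------------------------------------------------------ io

    def write(self, fasta_path: str | Path, localities_path: str | Path) -> None:
        from .io import write_fasta, write_tsv

        write_fasta(
            fasta_path,
            {r.id: r.sequence for r in self.records},
            descriptions={r.id: r.taxon for r in self.records},
        )
        rows = [
            {"reference_id": r.id, "taxon": r.taxon, "latitude": lat, "longitude": lon}
            for r in self.records
            for lat, lon in r.localities
        ]
        write_tsv(
            localities_path,
            pd.DataFrame(rows, columns=["reference_id", "taxon", "latitude", "longitude"]),
        )

    @classmethod
    def read(
        cls, fasta_path: str | Path, localities_path: str | Path | None = None
    ) -> "ReferencePanel":
        from .io import read_fasta, read_fasta_descriptions, read_tsv

        seqs = read_fasta(fasta_path)
        taxa = read_fasta_descriptions(fasta_path)
        locs: dict[str, list[tuple[float, float]]] = {k: [] for k in seqs}
        if localities_path is not None:
            df = read_tsv(localities_path)
            for _, row in df.iterrows():
                rid = str(row["reference_id"])
                if rid in locs:
                    locs[rid].append(
                        (float(row["latitude"]), float(row["longitude"]))
                    )
        records = [
            ReferenceRecord(
                id=rid,
                taxon=taxa.get(rid, rid) or rid,
                sequence=seq,
                localities=tuple(locs[rid]),
            )
            for rid, seq in seqs.items()
        ]
        return cls(records)
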