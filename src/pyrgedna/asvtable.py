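"""ASV table container: sequences x samples read counts plus sample metadata."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .iupac import ConcreteSequence

__all__ = ["AsvTable", "assign_asv_ids"]


def assign_asv_ids(totals: dict[str, int]) -> dict[str, str]:
    """Map sequence -> ASV id, ordered by total count descending.

    Ties break lexicographically by sequence so ids are stable across runs.
    """
    ordered = sorted(totals, key=lambda s: (-totals[s], s))
    return {seq: f"ASV_{i + 1}" for i, seq in enumerate(ordered)}


@dataclass
class AsvTable:
    """ASV sequences with a per-sample read-count matrix.

    ``sequences`` maps ASV id -> concrete sequence; ``counts`` is an
    integer frame indexed by ASV id with one column per sample; ``samples``
    (optional) is indexed by sample id with ``site`` and ``batch`` columns.
    """

    sequences: dict[str, str]
    counts: pd.DataFrame
    samples: pd.DataFrame | None = None
    _site_cache: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if set(self.sequences) != set(self.counts.index):
            raise ValueError("sequence ids and count-matrix rows disagree")
        if len(set(self.sequences.values())) != len(self.sequences):
            raise ValueError("duplicate ASV sequences")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")
        if self.samples is not None:
            missing = set(self.counts.columns) - set(self.samples.index)
            if missing:
                raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def site_of(self, sample: str) -> str:
        if self.samples is None:
            raise ValueError("no sample metadata attached")
        return str(self.samples.loc[sample, "site"])

    def site_counts(self) -> pd.DataFrame:
        """Counts aggregated to sites (ASV x site)."""
        if self.samples is None:
            raise ValueError("no sample metadata attached")
        if self._site_cache is None:
            mapping = self.samples["site"]
            object.__setattr__(
                self,
                "_site_cache",
                self.counts.T.groupby(self.counts.columns.map(mapping)).sum().T,
            )
        return self._site_cache

    def invalidate_cache(self) -> None:
        self._site_cache = None

    def detections(self) -> list[tuple[str, str, int]]:
        """All (asv_id, site, reads) triples with reads > 0."""
        sc = self.site_counts()
        out = []
        for asv in sc.index:
            row = sc.loc[asv]
            for site in sc.columns:
                n = int(row[site])
                if n > 0:
                    out.append((asv, str(site), n))
        return out

    def drop_empty(self) -> "AsvTable":
        keep = self.counts.sum(axis=1) > 0
        counts = self.counts.loc[keep]
        return AsvTable(
            sequences={a: self.sequences[a] for a in counts.index},
            counts=counts,
            samples=self.samples,
        )

    # ------------------------------------------------------------------ io

    def write(self, fasta_path: str | Path, counts_path: str | Path) -> None:
        from .io import write_fasta, write_tsv

        write_fasta(fasta_path, self.sequences)
        df = self.counts.copy()
        df.index.name = "asv_id"
        write_tsv(counts_path, df.reset_index())

    @classmethod
    def read(
        cls,
        fasta_path: str | Path,
        counts_path: str | Path,
        samples: pd.DataFrame | None = None,
    ) -> "AsvTable":
        from .io import read_fasta, read_tsv

        seqs = {k: str(ConcreteSequence(v)) for k, v in read_fasta(fasta_path).items()}
        df = read_tsv(counts_path).set_index("asv_id")
        df = df.astype(int)
        return cls(sequences=seqs, counts=df, samples=samples)
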