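"""Minimal aligned/unaligned sequence containers with FASTA I/O."""

from __future__ import annotations

import io

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP_CHARS = set("-.")


class Alignment:
    """An ordered set of equal-length sequences."""

    def __init__(self, ids: list[str], seqs: list[str]):
        if len(ids) != len(seqs):
            raise ValueError("ids and seqs length mismatch")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids")
        if seqs and len({len(s) for s in seqs}) > 1:
            raise ValueError("sequences are not aligned (unequal lengths)")
        self.ids = list(ids)
        self.seqs = [s.upper() for s in seqs]

    # -- basic accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def to_dict(self) -> dict[str, str]:
        return dict(zip(self.ids, self.seqs))

    def column(self, j: int) -> str:
        return "".join(s[j] for s in self.seqs)

    def gap_fraction(self, j: int) -> float:
        col = self.column(j)
        return sum(c in GAP_CHARS for c in col) / len(col)

    def matrix(self) -> np.ndarray:
        return np.array([list(s) for s in self.seqs])

    # -- transforms ----------------------------------------------------------

    def take_columns(self, idx) -> "Alignment":
        idx = list(idx)
        return Alignment(
            self.ids, ["".join(s[j] for j in idx) for s in self.seqs]
        )

    def subset(self, ids) -> "Alignment":
        want = set(ids)
        keep = [(i, s) for i, s in zip(self.ids, self.seqs) if i in want]
        return Alignment([i for i, _ in keep], [s for _, s in keep])

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_fasta(cls, source) -> "Alignment":
        if isinstance(source, str) and source.startswith(">"):
            handle = io.StringIO(source)
        else:
            handle = source
        recs = list(SeqIO.parse(handle, "fasta"))
        return cls([r.id for r in recs], [str(r.seq) for r in recs])

    def write_fasta(self, path_or_handle) -> None:
        recs = [
            SeqRecord(Seq(s), id=i, description="") for i, s in zip(self.ids, self.seqs)
        ]
        SeqIO.write(recs, path_or_handle, "fasta")


def read_fasta_dict(path) -> dict[str, str]:
    """Read a (possibly unaligned) FASTA file as an id -> sequence dict."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta_dict(seqs: dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    SeqIO.write(recs, path, "fasta")
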