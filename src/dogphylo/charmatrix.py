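"""Binary detection matrices and concatenated amino-acid supermatrices.

The supermatrix workflow mirrors the standard phylogenomic recipe: trim
each family alignment to well-aligned blocks, concatenate over the full
taxon set (taxa lacking a family contribute all-gap rows), then drop
columns observed in fewer than a minimum number of taxa.  All public
coordinates are 1-based inclusive; internal indexing is 0-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqs import GAP_CHARS, Alignment


class PresenceMatrix:
    """Taxa x families binary detection/non-detection characters."""

    def __init__(self, taxa: list[str], family_ids: list[str], cells: np.ndarray):
        cells = np.asarray(cells, dtype=np.int8)
        if cells.shape != (len(taxa), len(family_ids)):
            raise ValueError("cell matrix shape does not match taxa x families")
        if ((cells != 0) & (cells != 1)).any():
            raise ValueError("cells must be 0/1")
        if (cells.sum(axis=0) == 0).any():
            raise ValueError("all-zero family column (unobservable family)")
        self.taxa = list(taxa)
        self.family_ids = list(family_ids)
        self.cells = cells

    def to_binary_sequences(self) -> dict[str, str]:
        return {
            t: "".join(map(str, self.cells[i])) for i, t in enumerate(self.taxa)
        }

    def row_sums(self) -> dict[str, int]:
        return {t: int(self.cells[i].sum()) for i, t in enumerate(self.taxa)}

    # -- NEXUS (restriction data) -------------------------------------------

    def write_nexus(self, path: str) -> None:
        pad = max(len(t) for t in self.taxa) + 2
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(
                f"    DIMENSIONS NTAX={len(self.taxa)} NCHAR={len(self.family_ids)};\n"
            )
            fh.write(
                '    FORMAT DATATYPE=RESTRICTION MISSING=? GAP=- SYMBOLS="01";\n'
            )
            fh.write("    MATRIX\n")
            for t, row in zip(self.taxa, self.cells):
                fh.write(f"    {t:<{pad}}{''.join(map(str, row))}\n")
            fh.write("    ;\nEND;\n")

    @classmethod
    def read_nexus(cls, path: str) -> "PresenceMatrix":
        taxa, rows = [], []
        in_matrix = False
        with open(path) as fh:
            for line in fh:
                s = line.strip()
                if s.upper().startswith("MATRIX"):
                    in_matrix = True
                    continue
                if in_matrix:
                    if s.startswith(";"):
                        break
                    if not s:
                        continue
                    name, chars = s.split(None, 1)
                    taxa.append(name)
                    rows.append([int(c) for c in chars.strip()])
        cells = np.array(rows, dtype=np.int8)
        fam = [f"char{i + 1}" for i in range(cells.shape[1])]
        return cls(taxa, fam, cells)


def build_binary_matrix(membership, taxa: list[str]) -> PresenceMatrix:
    """Presence matrix from a DOG membership table.

    ``membership`` is a DataFrame (or records) with columns
    family_id / taxon / seq_id.  cell(t, f) = 1 iff taxon t has a member
    in family f.
    """
    df = pd.DataFrame(membership)
    if not {"family_id", "taxon"}.issubset(df.columns):
        raise ValueError("membership needs family_id and taxon columns")
    fams = sorted(df["family_id"].unique())
    t_idx = {t: i for i, t in enumerate(taxa)}
    f_idx = {f: j for j, f in enumerate(fams)}
    cells = np.zeros((len(taxa), len(fams)), dtype=np.int8)
    for _, row in df.iterrows():
        if row["taxon"] not in t_idx:
            raise ValueError(f"taxon {row['taxon']!r} not in taxa list")
        cells[t_idx[row["taxon"]], f_idx[row["family_id"]]] = 1
    return PresenceMatrix(taxa, fams, cells)


# ---------------------------------------------------------------------------
# Trimming


@dataclass
class TrimConfig:
    """Conserved-block and occupancy filter settings."""

    min_conserved_fraction: float = 0.5  # mode residue must exceed this
    min_block_length: int = 5
    max_contiguous_nonconserved: int = 8
    occupancy_min: int = 10

    def __post_init__(self):
        if self.occupancy_min < 1:
            raise ValueError("occupancy_min must be >= 1")


def _conserved_columns(aln: Alignment, cfg: TrimConfig) -> np.ndarray:
    """A column is conserved when its most frequent residue occurs in more
    than ``min_conserved_fraction`` of the sequences (strictly: at least
    floor(n/2)+1 at the 0.5 default) and gaps are under half the column."""
    m = aln.matrix()
    n = len(aln)
    out = np.zeros(aln.n_sites, dtype=bool)
    need = int(np.floor(n * cfg.min_conserved_fraction)) + 1
    for j in range(aln.n_sites):
        col = m[:, j]
        gaps = np.isin(col, list(GAP_CHARS)).sum()
        if gaps / n >= 0.5:
            continue
        vals, counts = np.unique(col[~np.isin(col, list(GAP_CHARS))], return_counts=True)
        if len(counts) and counts.max() >= need:
            out[j] = True
    return out


def trim_blocks(aln: Alignment, cfg: TrimConfig | None = None) -> tuple[Alignment, list[int]]:
    """Keep blocks of conserved columns; drop poorly aligned regions.

    A block starts and ends on conserved columns, may contain internal
    non-conserved runs of at most ``max_contiguous_nonconserved`` columns,
    and must span at least ``min_block_length`` columns.  Returns the
    trimmed alignment and the retained original column indices (0-based).
    """
    cfg = cfg or TrimConfig()
    if len(aln) == 0 or aln.n_sites == 0:
        raise ValueError("empty alignment")
    cons = _conserved_columns(aln, cfg)
    kept: list[int] = []
    j = 0
    n = aln.n_sites
    while j < n:
        if not cons[j]:
            j += 1
            continue
        # extend a block starting at conserved column j
        block = [j]
        k = j + 1
        gap_run = 0
        last_cons = j
        while k < n:
            if cons[k]:
                block.extend(range(last_cons + 1, k + 1))
                last_cons = k
                gap_run = 0
            else:
                gap_run += 1
                if gap_run > cfg.max_contiguous_nonconserved:
                    break
            k += 1
        if len(block) >= cfg.min_block_length:
            kept.extend(block)
        j = last_cons + 1 if last_cons + 1 > j else j + 1
    if not kept:
        raise ValueError("trimming removed every column")
    return aln.take_columns(kept), kept


# ---------------------------------------------------------------------------
# Supermatrix


class SuperAlignment:
    """Concatenated alignment over a taxa universe with a partition map."""

    def __init__(
        self,
        taxa: list[str],
        rows: dict[str, str],
        partitions: dict[str, tuple[int, int]],  # family -> 1-based inclusive
        dropped: list[str] | None = None,
    ):
        self.taxa = list(taxa)
        self.alignment = Alignment(self.taxa, [rows[t] for t in self.taxa])
        self.partitions = dict(partitions)
        self.dropped = list(dropped or [])
        n = self.alignment.n_sites
        covered = sorted(self.partitions.values())
        pos = 1
        for a, b in covered:
            if a != pos or b < a:
                raise ValueError("partition intervals must tile the columns")
            pos = b + 1
        if covered and pos != n + 1:
            raise ValueError("partition intervals must cover all columns")

    @property
    def n_sites(self) -> int:
        return self.alignment.n_sites

    def gap_mask(self) -> np.ndarray:
        return np.isin(self.alignment.matrix(), list(GAP_CHARS))

    def column_occupancy(self) -> np.ndarray:
        return (~self.gap_mask()).sum(axis=0)

    def missing_fraction(self) -> float:
        mask = self.gap_mask()
        return float(mask.mean()) if mask.size else 0.0

    def _filter_columns(self, keep: np.ndarray) -> "SuperAlignment":
        if not keep.any():
            raise ValueError("occupancy filter removed every column")
        col_fam = np.empty(self.n_sites, dtype=object)
        for fam, (a, b) in self.partitions.items():
            col_fam[a - 1 : b] = fam
        new_rows = {
            t: "".join(np.array(list(s))[keep])
            for t, s in zip(self.alignment.ids, self.alignment.seqs)
        }
        parts: dict[str, tuple[int, int]] = {}
        dropped = list(self.dropped)
        pos = 1
        for fam in self.partitions:  # preserves insertion (column) order
            a, b = self.partitions[fam]
            width = int(keep[a - 1 : b].sum())
            if width == 0:
                dropped.append(fam)
                continue
            parts[fam] = (pos, pos + width - 1)
            pos += width
        return SuperAlignment(self.taxa, new_rows, parts, dropped)

    # -- I/O -----------------------------------------------------------------

    def write_phylip(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)} {self.n_sites}\n")
            for t, s in zip(self.alignment.ids, self.alignment.seqs):
                fh.write(f"{t}  {s}\n")

    def write_fasta(self, path: str) -> None:
        self.alignment.write_fasta(path)

    def write_partitions(self, path: str, model_name: str = "WAG") -> None:
        with open(path, "w") as fh:
            for fam, (a, b) in self.partitions.items():
                fh.write(f"{model_name}, {fam} = {a}-{b}\n")

    def write_manifest(self, path: str) -> None:
        mask = self.gap_mask()
        with open(path, "w") as fh:
            fh.write("family\tstart\tend\tlength\tmissing_fraction\n")
            for fam, (a, b) in self.partitions.items():
                sub = mask[:, a - 1 : b]
                fh.write(f"{fam}\t{a}\t{b}\t{b - a + 1}\t{sub.mean():.6f}\n")
            for fam in self.dropped:
                fh.write(f"{fam}\tNA\tNA\t0\tNA\n")

    @classmethod
    def read_phylip(cls, phylip_path: str, partition_path: str) -> "SuperAlignment":
        with open(phylip_path) as fh:
            header = fh.readline().split()
            ntax, nchar = int(header[0]), int(header[1])
            rows: dict[str, str] = {}
            taxa: list[str] = []
            for line in fh:
                if not line.strip():
                    continue
                name, seq = line.split(None, 1)
                taxa.append(name)
                rows[name] = seq.strip()
        if len(taxa) != ntax or any(len(s) != nchar for s in rows.values()):
            raise ValueError("PHYLIP dimensions disagree with matrix")
        parts: dict[str, tuple[int, int]] = {}
        pat = re.compile(r"^\s*\S+\s*,\s*(\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*$")
        with open(partition_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                m = pat.match(line)
                if not m:
                    raise ValueError(f"bad partition line: {line!r}")
                parts[m.group(1)] = (int(m.group(2)), int(m.group(3)))
        return cls(taxa, rows, parts)


def concatenate(
    family_alignments: dict[str, Alignment],
    taxa_universe: list[str],
    occupancy_min: int = 10,
) -> SuperAlignment:
    """Concatenate per-family alignments over ``taxa_universe``.

    Missing taxa receive all-gap rows per family, then columns with fewer
    than ``occupancy_min`` non-gap characters are removed; partitions are
    reported in post-trim coordinates.  Families losing every column are
    recorded in ``dropped`` rather than raising.
    """
    rows = {t: [] for t in taxa_universe}
    partitions: dict[str, tuple[int, int]] = {}
    pos = 1
    for fam, aln in family_alignments.items():
        extra = set(aln.ids) - set(taxa_universe)
        if extra:
            raise ValueError(f"{fam}: taxa {sorted(extra)} not in the taxa universe")
        d = aln.to_dict()
        width = aln.n_sites
        for t in taxa_universe:
            rows[t].append(d.get(t, "-" * width))
        partitions[fam] = (pos, pos + width - 1)
        pos += width
    sa = SuperAlignment(
        taxa_universe, {t: "".join(chunks) for t, chunks in rows.items()}, partitions
    )
    keep = sa.column_occupancy() >= occupancy_min
    return sa._filter_columns(keep)


def missing_fraction(super_aln: SuperAlignment) -> float:
    return super_aln.missing_fraction()


def stringent_filter(
    super_aln: SuperAlignment, occupancy_fraction: float
) -> SuperAlignment:
    """Keep columns observed in >= ceil(fraction * n_taxa) taxa."""
    if not 0.0 < occupancy_fraction <= 1.0:
        raise ValueError("occupancy_fraction must be in (0, 1]")
    need = int(np.ceil(occupancy_fraction * len(super_aln.taxa)))
    keep = super_aln.column_occupancy() >= need
    return super_aln._filter_columns(keep)
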