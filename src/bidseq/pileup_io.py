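"""Reference handling, deletion-signature pileup and count-table I/O.

Bisulfite treatment converts pseudouridine (Ψ) into an adduct that reverse
transcriptase reads through as a deletion, so a Ψ site shows up in an
alignment as reads whose CIGAR deletes the reference position.  This module
turns a SAM alignment into per-position (coverage, deletion) counts — the raw
material for stoichiometry calibration and site calling — together with the
reference 5-mer context (NNUNN) around every counted position.

Coordinate convention: 0-based half-open everywhere in code; 1-based only in
human-facing reports produced elsewhere.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

__all__ = [
    "ReferenceSet",
    "SiteCount",
    "CountTable",
    "load_reference",
    "extract_motif",
    "pileup_deletions",
    "read_count_table",
    "write_count_table",
]

COUNT_COLUMNS = [
    "ref_name",
    "pos",
    "ref_base",
    "coverage",
    "del_count",
    "motif5",
    "library_label",
]

# CIGAR operation codes (pysam numeric encoding)
_CIGAR_ALIGNED = {0, 7, 8}  # M, =, X : consume query and reference
_CIGAR_DEL = 2              # D      : consumes reference only
_CIGAR_SKIP = 3             # N      : reference skip (no coverage)


class ReferenceSet:
    """Named reference sequences with a U/T-agnostic alphabet.

    Sequences are stored uppercase with T normalized to U, so lookups against
    RNA (U) or DNA (T) references behave identically.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"reference {name!r} is empty")
            self._seqs[name] = str(seq).upper().replace("T", "U")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSet":
        seqs: dict[str, str] = {}
        n = 0
        for rec in SeqIO.parse(str(path), "fasta"):
            n += 1
            if rec.id in seqs:
                raise ValueError(f"duplicate reference name {rec.id!r} in {path}")
            seqs[rec.id] = str(rec.seq)
        if n == 0:
            raise ValueError(f"no FASTA records in {path}")
        return cls(seqs)

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def sequence(self, name: str) -> str:
        return self._seqs[name]

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def base(self, name: str, pos: int) -> str:
        seq = self._seqs[name]
        if not 0 <= pos < len(seq):
            raise IndexError(f"position {pos} outside reference {name!r} (length {len(seq)})")
        return seq[pos]

    def motif5(self, name: str, pos: int) -> str:
        return extract_motif(self, name, pos)


def load_reference(fasta_path: str | Path) -> ReferenceSet:
    """Load a FASTA file into a :class:`ReferenceSet` (T normalized to U)."""
    return ReferenceSet.from_fasta(fasta_path)


def extract_motif(reference: ReferenceSet, ref_name: str, pos: int) -> str:
    """Reference 5-mer centered on ``pos``, N-padded beyond the sequence ends."""
    seq = reference.sequence(ref_name)
    if not 0 <= pos < len(seq):
        raise IndexError(f"position {pos} outside reference {ref_name!r}")
    out = []
    for i in range(pos - 2, pos + 3):
        out.append(seq[i] if 0 <= i < len(seq) else "N")
    return "".join(out)


@dataclasses.dataclass(frozen=True)
class SiteCount:
    """Coverage and deletion counts for one reference position in one library.

    ``coverage`` counts every read whose alignment spans the position through
    M/=/X or D operations, i.e. reads deleted at the position are included in
    the denominator of the deletion rate.
    """

    ref_name: str
    pos: int
    ref_base: str
    coverage: int
    del_count: int
    motif5: str
    library_label: str = "treated"

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if not (0 <= self.del_count <= self.coverage):
            raise ValueError(
                f"del_count {self.del_count} outside [0, coverage={self.coverage}] "
                f"at {self.ref_name}:{self.pos}"
            )
        if len(self.motif5) != 5:
            raise ValueError(f"motif5 {self.motif5!r} is not a 5-mer")
        if self.motif5[2] != self.ref_base:
            raise ValueError(
                f"motif5 center {self.motif5[2]!r} != ref_base {self.ref_base!r}"
            )

    @property
    def rate(self) -> float:
        if self.coverage == 0:
            raise ZeroDivisionError("deletion rate undefined at coverage 0")
        return self.del_count / self.coverage


class CountTable:
    """Ordered per-position counts for one library, at most one row per site."""

    def __init__(self, df: pd.DataFrame, provenance: dict | None = None):
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        df = df.loc[:, COUNT_COLUMNS].reset_index(drop=True)
        for col in ("pos", "coverage", "del_count"):
            vals = df[col]
            if not np.all(np.equal(np.mod(vals, 1), 0)):
                raise ValueError(f"non-integer values in column {col!r}")
            df[col] = vals.astype(np.int64)
        if (df["del_count"] > df["coverage"]).any():
            bad = df[df["del_count"] > df["coverage"]].iloc[0]
            raise ValueError(
                f"del_count > coverage at {bad.ref_name}:{bad.pos}"
            )
        if (df["del_count"] < 0).any() or (df["pos"] < 0).any():
            raise ValueError("negative counts or positions")
        if df.duplicated(subset=["ref_name", "pos"]).any():
            dup = df[df.duplicated(subset=["ref_name", "pos"])].iloc[0]
            raise ValueError(f"duplicate record for {dup.ref_name}:{dup.pos}")
        self._df = df
        self.provenance = dict(provenance or {})
        self._index: dict[tuple[str, int], int] | None = None

    @classmethod
    def from_records(cls, records, provenance: dict | None = None) -> "CountTable":
        rows = [dataclasses.asdict(r) for r in records]
        df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
        return cls(df, provenance)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[SiteCount]:
        for row in self._df.itertuples(index=False):
            yield SiteCount(
                row.ref_name, int(row.pos), row.ref_base, int(row.coverage),
                int(row.del_count), row.motif5, row.library_label,
            )

    def lookup(self, ref_name: str, pos: int) -> SiteCount | None:
        if self._index is None:
            self._index = {
                (r, int(p)): i
                for i, (r, p) in enumerate(zip(self._df["ref_name"], self._df["pos"]))
            }
        i = self._index.get((ref_name, pos))
        if i is None:
            return None
        row = self._df.iloc[i]
        return SiteCount(
            row.ref_name, int(row.pos), row.ref_base, int(row.coverage),
            int(row.del_count), row.motif5, row.library_label,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self._df.equals(other._df)


def pileup_deletions(
    sam_path: str | Path,
    reference: ReferenceSet,
    min_flank: int = 2,
    mapq_min: int = 0,
    library_label: str = "treated",
) -> CountTable:
    """Pile up per-position coverage and internal-deletion counts from a SAM file.

    A read contributes to ``coverage`` at every reference position it spans via
    M/=/X or D CIGAR operations, and to ``del_count`` at every position deleted
    by a D operation that has at least ``min_flank`` aligned (M/=/X) reference
    bases on both sides within the same read.  End-proximal deletions are
    treated as alignment artifacts and excluded from the numerator (but the
    read still covers the deleted position).  Insertions and clips contribute
    nothing; unmapped, secondary and supplementary records are skipped.
    """
    if min_flank < 0:
        raise ValueError("min_flank must be >= 0")
    cov: dict[str, np.ndarray] = {}
    dels: dict[str, np.ndarray] = {}

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < mapq_min:
                continue
            name = read.reference_name
            if name not in reference:
                raise ValueError(f"alignment to unknown reference {name!r}")
            if name not in cov:
                n = reference.length(name)
                cov[name] = np.zeros(n, dtype=np.int64)
                dels[name] = np.zeros(n, dtype=np.int64)
            _accumulate_read(read, cov[name], dels[name], min_flank, name)

    records: list[SiteCount] = []
    for name in sorted(cov):
        covered = np.nonzero(cov[name])[0]
        for pos in covered:
            pos = int(pos)
            records.append(
                SiteCount(
                    ref_name=name,
                    pos=pos,
                    ref_base=reference.base(name, pos),
                    coverage=int(cov[name][pos]),
                    del_count=int(dels[name][pos]),
                    motif5=extract_motif(reference, name, pos),
                    library_label=library_label,
                )
            )
    return CountTable.from_records(
        records,
        provenance={"source": str(sam_path), "min_flank": min_flank,
                    "mapq_min": mapq_min},
    )


def _accumulate_read(read, cov: np.ndarray, dels: np.ndarray,
                     min_flank: int, name: str) -> None:
    ops = read.cigartuples
    if not ops:
        return
    ref_len = len(cov)
    ref_pos = read.reference_start
    # aligned (M/=/X) reference bases before/after each op, for the flank rule
    aligned_len = [ln if op in _CIGAR_ALIGNED else 0 for op, ln in ops]
    total_aligned = sum(aligned_len)
    aligned_before = 0
    for (op, ln), a in zip(ops, aligned_len):
        if op in _CIGAR_ALIGNED:
            end = ref_pos + ln
            if end > ref_len:
                raise ValueError(
                    f"CIGAR of read {read.query_name!r} runs past reference {name!r}"
                )
            cov[ref_pos:end] += 1
            ref_pos = end
            aligned_before += a
        elif op == _CIGAR_DEL:
            end = ref_pos + ln
            if end > ref_len:
                raise ValueError(
                    f"CIGAR of read {read.query_name!r} runs past reference {name!r}"
                )
            cov[ref_pos:end] += 1
            aligned_after = total_aligned - aligned_before
            if aligned_before >= min_flank and aligned_after >= min_flank:
                dels[ref_pos:end] += 1
            ref_pos = end
        elif op == _CIGAR_SKIP:
            ref_pos += ln
        # I, S, H, P: no reference consumption


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a count table as TSV with the canonical column order."""
    table.df.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV count table, validating schema and invariants."""
    df = pd.read_csv(path, sep="\t", dtype={"ref_name": str, "motif5": str,
                                            "library_label": str})
    if len(df.columns) == 1 and df.columns[0] not in COUNT_COLUMNS:
        raise ValueError(f"{path}: not a tab-separated count table")
    return CountTable(df, provenance={"source": str(path)})
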