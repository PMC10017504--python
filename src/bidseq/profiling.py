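"""Downstream Ψ profiling: writers, Ψ-strength, metagene, stop codons, tissues.

Operates on call tables and transcript models (BED12 or GTF).  All transcript
coordinates are 0-based half-open on the spliced, sense-strand transcript.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptModel",
    "FractionMatrix",
    "StopCodonAnnotation",
    "read_bed12_models",
    "read_gtf_models",
    "classify_writer",
    "psi_strength",
    "psi_strength_group",
    "metagene_position",
    "metagene_density",
    "annotate_stop_codon",
    "tissue_specificity",
    "motif_summary",
]

STOP_CODONS = {"UAA", "UAG", "UGA"}


@dataclasses.dataclass
class TranscriptModel:
    """Spliced transcript with 5'UTR / CDS / 3'UTR boundaries.

    ``cds_start``/``cds_end`` are transcript coordinates (0-based half-open);
    ``cds_start == cds_end`` marks a noncoding model.  The stop codon is the
    final three CDS bases.  ``sequence`` (optional, U-alphabet) enables
    stop-codon annotation.
    """

    transcript_id: str
    gene_id: str
    length: int
    cds_start: int
    cds_end: int
    sequence: str | None = None

    def __post_init__(self):
        if not (0 <= self.cds_start <= self.cds_end <= self.length):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"outside transcript of length {self.length}"
            )
        if self.sequence is not None:
            self.sequence = self.sequence.upper().replace("T", "U")
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"{self.transcript_id}: sequence length {len(self.sequence)} "
                    f"!= model length {self.length}"
                )

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start

    @property
    def has_utrs(self) -> bool:
        return self.is_coding and (self.cds_start > 0 or self.cds_end < self.length)

    @property
    def stop_codon_interval(self) -> tuple[int, int]:
        if not self.is_coding:
            raise ValueError(f"{self.transcript_id}: noncoding model has no stop codon")
        return self.cds_end - 3, self.cds_end


# ---------------------------------------------------------------------------
# annotation readers

def read_bed12_models(
    path: str | Path, sequences: Mapping[str, str] | None = None
) -> dict[str, TranscriptModel]:
    """Parse BED12 transcript models, projecting the thick (CDS) interval
    through the exon blocks into spliced transcript coordinates.

    The name field may be ``transcript_id|gene_id``; otherwise gene_id equals
    transcript_id.  ``sequences`` (optional) maps transcript_id to the spliced
    sense-strand sequence.
    """
    models: dict[str, TranscriptModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 fields")
            chrom_start = int(f[1])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(v) for v in f[10].rstrip(",").split(",")]
            starts = [int(v) for v in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            blocks = [
                (chrom_start + s, chrom_start + s + ln)
                for s, ln in zip(starts, sizes)
            ]
            length = sum(sizes)
            if "|" in name:
                tid, gid = name.split("|", 1)
            else:
                tid = gid = name
            if thick_start >= thick_end:
                cds = (0, 0)
            else:
                lo = _genomic_to_tx(blocks, thick_start, is_end=False, where=f"{path}:{lineno}")
                hi = _genomic_to_tx(blocks, thick_end, is_end=True, where=f"{path}:{lineno}")
                if strand == "-":
                    cds = (length - hi, length - lo)
                else:
                    cds = (lo, hi)
            seq = sequences.get(tid) if sequences else None
            if tid in models:
                raise ValueError(f"{path}: duplicate transcript {tid!r}")
            models[tid] = TranscriptModel(tid, gid, length, cds[0], cds[1], seq)
    return models


def _genomic_to_tx(blocks, gpos: int, is_end: bool, where: str) -> int:
    """Plus-strand spliced offset of a genomic boundary coordinate."""
    off = 0
    for b0, b1 in blocks:
        if is_end:
            if b0 < gpos <= b1:
                return off + (gpos - b0)
        else:
            if b0 <= gpos < b1:
                return off + (gpos - b0)
        off += b1 - b0
    raise ValueError(f"{where}: thick boundary {gpos} outside exon blocks")


def read_gtf_models(
    path: str | Path, sequences: Mapping[str, str] | None = None
) -> dict[str, TranscriptModel]:
    """Build transcript models from GTF exon/CDS/stop_codon records.

    GTF convention excludes the stop codon from CDS features; when stop_codon
    records are present the CDS is extended to include them.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    genes: dict[str, str] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise ValueError(f"{path}: {feat.featuretype} without transcript_id")
        genes.setdefault(tid, feat.attributes.get("gene_id", [tid])[0])
        rec = (feat.start - 1, feat.end, feat.strand)  # to 0-based half-open
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(rec)
        else:
            cds.setdefault(tid, []).append(rec)

    models: dict[str, TranscriptModel] = {}
    for tid, ex in exons.items():
        strand = ex[0][2]
        blocks = sorted((a, b) for a, b, _ in ex)
        length = sum(b - a for a, b in blocks)
        if tid in cds:
            lo = min(a for a, _, _ in cds[tid])
            hi = max(b for _, b, _ in cds[tid])
            t_lo = _genomic_to_tx(blocks, lo, is_end=False, where=f"{path}:{tid}")
            t_hi = _genomic_to_tx(blocks, hi, is_end=True, where=f"{path}:{tid}")
            cds_tx = (length - t_hi, length - t_lo) if strand == "-" else (t_lo, t_hi)
        else:
            cds_tx = (0, 0)
        seq = sequences.get(tid) if sequences else None
        models[tid] = TranscriptModel(tid, genes[tid], length, cds_tx[0], cds_tx[1], seq)
    return models


# ---------------------------------------------------------------------------
# writer assignment

def classify_writer(
    control_fraction: float,
    knockdown_fraction: float,
    rel_change_threshold: float = 0.5,
    eps: float = 1e-6,
) -> str:
    """Classify a site against a writer-enzyme knockdown.

    "hypo-regulated" when the fraction drops by at least the relative
    threshold on knockdown (the site depends on the enzyme), "hyper-regulated"
    when it rises by at least the threshold, else "independent".
    """
    xc, xk = control_fraction, knockdown_fraction
    if not (0 <= xc <= 1 and 0 <= xk <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if xc == 0 and xk == 0:
        raise ValueError("site unmodified in both conditions; not classifiable")
    if xc > 0 and (xc - xk) / xc >= rel_change_threshold:
        return "hypo-regulated"
    if (xk - xc) / max(xc, eps) >= rel_change_threshold:
        return "hyper-regulated"
    return "independent"


# ---------------------------------------------------------------------------
# per-gene Ψ-strength

def psi_strength(fractions: Iterable[float]) -> float:
    """Sum of Ψ fractions over all called sites of one gene."""
    return float(sum(fractions))


def psi_strength_group(strength: float, cutoff: float = 1.0) -> str:
    """Partition genes at the Ψ-strength cutoff (strictly above -> "high")."""
    return "high" if strength > cutoff else "low"


# ---------------------------------------------------------------------------
# metagene

def metagene_position(pos: int, model: TranscriptModel) -> tuple[str, float]:
    """Segment and within-segment normalized coordinate of a transcript position.

    Returns ("5'UTR" | "CDS" | "3'UTR", coord in [0, 1)); transcripts without
    annotated UTRs report ("CDS-only", coord over the whole transcript) and are
    excluded from metagene densities.
    """
    if not 0 <= pos < model.length:
        raise ValueError(
            f"position {pos} outside transcript {model.transcript_id} "
            f"(length {model.length})"
        )
    if not model.has_utrs:
        return "CDS-only", pos / model.length
    if pos < model.cds_start:
        return "5'UTR", pos / model.cds_start
    if pos < model.cds_end:
        return "CDS", (pos - model.cds_start) / (model.cds_end - model.cds_start)
    return "3'UTR", (pos - model.cds_end) / (model.length - model.cds_end)


def metagene_density(
    positions: Iterable[tuple[int, TranscriptModel]],
    bins: tuple[int, int, int] = (25, 50, 25),
) -> np.ndarray:
    """Histogram of call positions over a 1-2-1 (5'UTR-CDS-3'UTR) bin layout.

    Returns integer counts of length sum(bins); the total equals the number of
    annotated calls falling on transcripts with UTR annotation.
    """
    n5, nc, n3 = bins
    counts = np.zeros(n5 + nc + n3, dtype=np.int64)
    for pos, model in positions:
        segment, coord = metagene_position(pos, model)
        if segment == "5'UTR":
            b = min(int(coord * n5), n5 - 1)
        elif segment == "CDS":
            b = n5 + min(int(coord * nc), nc - 1)
        elif segment == "3'UTR":
            b = n5 + nc + min(int(coord * n3), n3 - 1)
        else:  # CDS-only models carry no segment information
            continue
        counts[b] += 1
    return counts


# ---------------------------------------------------------------------------
# stop codons

@dataclasses.dataclass(frozen=True)
class StopCodonAnnotation:
    """A Ψ inside a stop codon, rendered with Ψ at the modified uridine."""

    codon: str               # e.g. "ΨGA", "UΨA" for second-position Ψ in UAA... rendered per position
    position_in_codon: int   # 1-based: 1, 2 or 3
    next_stop_offset: int | None  # downstream in-frame stop, in codons (+1 = adjacent)


def annotate_stop_codon(pos: int, model: TranscriptModel) -> StopCodonAnnotation | None:
    """Annotate a called Ψ lying within the transcript's stop codon.

    Returns None for positions outside the stop codon.  For a Ψ at codon
    position ``i`` the codon string carries Ψ at that position (e.g. first-
    position U of UGA renders as ΨGA).  The 3'UTR is scanned in frame for the
    next UAA/UAG/UGA and its offset in codons is reported (None if absent).
    """
    if model.sequence is None:
        raise ValueError(f"{model.transcript_id}: sequence required for stop-codon annotation")
    if not model.is_coding:
        return None
    if (model.cds_end - model.cds_start) % 3 != 0:
        raise ValueError(f"{model.transcript_id}: CDS length not a multiple of 3")
    lo, hi = model.stop_codon_interval
    if not lo <= pos < hi:
        return None
    codon = model.sequence[lo:hi]
    offset = pos - lo
    if codon[offset] != "U":
        return None
    rendered = codon[:offset] + "Ψ" + codon[offset + 1:]
    next_stop = None
    k = 1
    for start in range(hi, model.length - 2, 3):
        if model.sequence[start:start + 3] in STOP_CODONS:
            next_stop = k
            break
        k += 1
    return StopCodonAnnotation(rendered, offset + 1, next_stop)


# ---------------------------------------------------------------------------
# tissue specificity

def tissue_specificity(
    fractions: Mapping[str, float],
    high: float = 0.5,
    detect: float = 0.10,
    shared_min_tissues: int = 4,
) -> str:
    """Label one site across tissues from its assayable fractions.

    "shared": fraction above ``high`` in at least one tissue AND detectable
    (above ``detect``) in at least ``shared_min_tissues`` tissues.
    "tissue-specific:<t>": above ``high`` in exactly one tissue and below
    ``detect`` in every other assayable tissue.  Otherwise "other".
    Only assayable tissues (keys present in ``fractions``) are considered.
    """
    if not fractions:
        return "other"
    vals = {t: float(v) for t, v in fractions.items()}
    for t, v in vals.items():
        if not 0 <= v <= 1:
            raise ValueError(f"fraction {v} for tissue {t!r} outside [0, 1]")
    n_detect = sum(v > detect for v in vals.values())
    high_tissues = [t for t, v in vals.items() if v > high]
    if high_tissues and n_detect >= shared_min_tissues:
        return "shared"
    if len(high_tissues) == 1:
        t0 = high_tissues[0]
        if all(v < detect for t, v in vals.items() if t != t0):
            return f"tissue-specific:{t0}"
    return "other"


class FractionMatrix:
    """Site x condition matrix of Ψ fractions with an assayability mask.

    Absence (mask False) means "not assayable there", which is distinct from a
    fraction of zero.
    """

    def __init__(self, fractions: pd.DataFrame, mask: pd.DataFrame | None = None):
        if mask is None:
            mask = fractions.notna()
        if not fractions.index.equals(mask.index) or not fractions.columns.equals(mask.columns):
            raise ValueError("fraction and mask tables must share index/columns")
        vals = fractions.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError("fractions outside [0, 1]")
        self.fractions = fractions
        self.mask = mask.astype(bool)

    @property
    def tissues(self) -> list[str]:
        return list(self.fractions.columns)

    def site_fractions(self, site) -> dict[str, float]:
        row = self.fractions.loc[site]
        m = self.mask.loc[site]
        return {t: float(row[t]) for t in self.fractions.columns
                if m[t] and not pd.isna(row[t])}

    def labels(self, high: float = 0.5, detect: float = 0.10,
               shared_min_tissues: int = 4) -> pd.Series:
        out = {
            site: tissue_specificity(
                self.site_fractions(site), high, detect, shared_min_tissues
            )
            for site in self.fractions.index
        }
        return pd.Series(out, name="label")

    def to_tsv(self, fractions_path: str | Path, mask_path: str | Path) -> None:
        self.fractions.to_csv(fractions_path, sep="\t", float_format="%.6g")
        self.mask.astype(int).to_csv(mask_path, sep="\t")

    @classmethod
    def from_tsv(cls, fractions_path: str | Path,
                 mask_path: str | Path | None = None) -> "FractionMatrix":
        fr = pd.read_csv(fractions_path, sep="\t", index_col=0)
        mask = None
        if mask_path is not None:
            mask = pd.read_csv(mask_path, sep="\t", index_col=0).astype(bool)
        return cls(fr, mask)


# ---------------------------------------------------------------------------
# motif summaries

def motif_summary(calls) -> pd.DataFrame:
    """Per-motif call count and mean estimated fraction.

    Accepts PsiCall objects or (motif5, fraction) pairs.  Ordered by count
    descending, then motif lexicographically.
    """
    pairs = []
    for c in calls:
        if hasattr(c, "motif5"):
            pairs.append((c.motif5, float(c.fraction)))
        else:
            m, f = c
            pairs.append((m, float(f)))
    if not pairs:
        return pd.DataFrame(columns=["motif5", "count", "mean_fraction"])
    df = pd.DataFrame(pairs, columns=["motif5", "fraction"])
    agg = (
        df.groupby("motif5")["fraction"]
        .agg(count="size", mean_fraction="mean")
        .reset_index()
    )
    agg = agg.sort_values(
        ["count", "motif5"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    agg["count"] = agg["count"].astype(np.int64)
    return agg
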