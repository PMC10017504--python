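"""Ψ site calling from paired treated/input count tables.

A candidate site must satisfy, with strict inequalities as phrased by the
filtering procedure:

  c1  treated deletion rate above 5% AND treated deletion count above 5
  c2  input (untreated) deletion rate below 1%
  c3  coverage above 20 in BOTH libraries
  c4  treated deletion rate above 1.5-fold the motif-specific background
      (measured on 0%-Ψ probes; missing motifs use a conservative floor)
  c5  not the immediate 5'/3' uridine neighbor of a known Ψ site
  c6  the reference base is U

In mRNA mode two further floors apply: estimated stoichiometry >= 10% and
(when expression is supplied) gene RPKM >= 1.5.  Passing sites whose treated
deletion count exceeds 10 are tiered "confident", the rest "candidate".
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .calibration import (
    DEFAULT_FALLBACK_PARAMS,
    CalibrationParams,
    invert_fraction,
    resolve_params,
)
from .pileup_io import CountTable, ReferenceSet, SiteCount

__all__ = [
    "CallConfig",
    "BackgroundTable",
    "PsiCall",
    "deletion_rate",
    "call_sites",
    "assign_tier",
    "rpkm",
    "reads_per_reference",
    "calls_to_dataframe",
    "write_calls_tsv",
    "write_calls_bed",
    "read_sites_bed",
    "read_background_table",
    "write_background_table",
]

CRITERIA = ("c1", "c2", "c3", "c4", "c5", "c6", "fraction_floor", "expression_floor")


@dataclasses.dataclass
class CallConfig:
    """Thresholds for site calling; defaults follow the published procedure."""

    min_del_rate_treated: float = 0.05
    min_del_count_treated: int = 5
    max_del_rate_input: float = 0.01
    min_coverage: int = 20
    min_fold_over_background: float = 1.5
    min_fraction_mrna: float = 0.10
    confident_del_count: int = 10
    rpkm_floor: float = 1.5
    mode: str = "mRNA"  # "mRNA" | "rRNA"
    calibration_fallback: CalibrationParams = DEFAULT_FALLBACK_PARAMS

    def __post_init__(self):
        if self.mode not in ("mRNA", "rRNA"):
            raise ValueError(f"mode must be mRNA or rRNA, got {self.mode!r}")
        for field in (
            "min_del_rate_treated", "min_del_count_treated", "max_del_rate_input",
            "min_coverage", "min_fold_over_background", "min_fraction_mrna",
            "confident_del_count", "rpkm_floor",
        ):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be >= 0")


class BackgroundTable:
    """Motif -> background deletion rate measured on 0%-Ψ probes.

    Motifs absent from the table resolve to ``default_floor`` so the
    fold-over-background criterion never compares against zero.
    """

    def __init__(self, rates: Mapping[str, float] | None = None,
                 default_floor: float = 0.01):
        self._rates = dict(rates or {})
        for m, r in self._rates.items():
            if not 0.0 <= r < 1.0:
                raise ValueError(f"background rate {r} for {m!r} outside [0, 1)")
        if default_floor <= 0:
            raise ValueError("default_floor must be > 0")
        self.default_floor = default_floor

    def rate(self, motif5: str) -> float:
        return max(self._rates.get(motif5, self.default_floor), self.default_floor)

    def __len__(self) -> int:
        return len(self._rates)

    def items(self):
        return self._rates.items()


@dataclasses.dataclass(frozen=True)
class PsiCall:
    """One called Ψ site with rates, stoichiometry estimate, flags and tier."""

    ref_name: str
    pos: int
    motif5: str
    treated_rate: float
    treated_coverage: int
    treated_del_count: int
    input_rate: float
    input_coverage: int
    fold_over_background: float
    fraction: float
    criteria: tuple[bool, ...]  # ordered as CRITERIA
    tier: str
    calibration_fallback: bool

    def __post_init__(self):
        if self.tier == "confident" and not self.criteria[CRITERIA.index("c1")]:
            raise ValueError("confident call failing c1 is inconsistent")

    @property
    def gene(self) -> str:
        return self.ref_name


def deletion_rate(site: SiteCount) -> float:
    """Deletion rate del_count / coverage; undefined at zero coverage."""
    if site.coverage == 0:
        raise ZeroDivisionError(
            f"deletion rate undefined at {site.ref_name}:{site.pos} (coverage 0)"
        )
    return site.del_count / site.coverage


def assign_tier(treated_del_count: int, config: CallConfig) -> str:
    """"confident" iff the treated deletion count strictly exceeds the cutoff."""
    return "confident" if treated_del_count > config.confident_del_count else "candidate"


def call_sites(
    treated: CountTable,
    input_table: CountTable,
    reference: ReferenceSet,
    calib: Mapping[str, CalibrationParams] | None = None,
    background: BackgroundTable | None = None,
    known_sites: Iterable[tuple[str, int]] | None = None,
    expression: Mapping[str, float] | None = None,
    config: CallConfig | None = None,
) -> list[PsiCall]:
    """Apply the full criterion stack and return passing sites, sorted.

    When ``known_sites`` is None the neighbor-U exclusion (c5) is applied
    reflexively: among otherwise-passing sites, any site immediately adjacent
    to a higher-rate passing site is dropped (exact tie keeps the 5'-most).
    A candidate that is itself in ``known_sites`` is never dropped by c5.
    """
    config = config or CallConfig()
    if config.mode == "mRNA" and calib is None:
        raise ValueError("mRNA mode requires a calibration table")
    background = background or BackgroundTable()
    known = set(known_sites) if known_sites is not None else None

    provisional: list[dict] = []
    for t in treated:
        if t.coverage == 0:
            continue
        i = input_table.lookup(t.ref_name, t.pos)
        in_cov = i.coverage if i is not None else 0
        in_rate = (i.del_count / i.coverage) if (i is not None and i.coverage > 0) else 0.0
        t_rate = t.del_count / t.coverage
        bg = background.rate(t.motif5)

        c1 = (t_rate > config.min_del_rate_treated
              and t.del_count > config.min_del_count_treated)
        c2 = in_rate < config.max_del_rate_input and in_cov > 0
        c3 = (t.coverage > config.min_coverage
              and in_cov > config.min_coverage)
        c4 = t_rate > config.min_fold_over_background * bg
        c6 = t.ref_base == "U"

        params, used_fallback = resolve_params(
            t.motif5, calib, config.calibration_fallback
        )
        frac = invert_fraction(t_rate, params)

        if config.mode == "mRNA":
            frac_floor = frac >= config.min_fraction_mrna
            if expression is not None:
                expr_floor = expression.get(t.ref_name, 0.0) >= config.rpkm_floor
            else:
                expr_floor = True
        else:
            frac_floor = True
            expr_floor = True

        if c1 and c2 and c3 and c4 and c6 and frac_floor and expr_floor:
            provisional.append(
                dict(site=t, rate=t_rate, in_rate=in_rate, in_cov=in_cov,
                     fold=t_rate / bg, frac=frac, fallback=used_fallback)
            )

    # criterion 5: neighbor-U exclusion
    if known is not None:
        passing = [
            p for p in provisional
            if (p["site"].ref_name, p["site"].pos) in known
            or not _neighbors_known(p["site"], known)
        ]
    else:
        by_pos = {(p["site"].ref_name, p["site"].pos): p for p in provisional}
        passing = []
        for p in provisional:
            s = p["site"]
            drop = False
            for dpos in (s.pos - 1, s.pos + 1):
                q = by_pos.get((s.ref_name, dpos))
                if q is None:
                    continue
                if q["rate"] > p["rate"]:
                    drop = True
                elif q["rate"] == p["rate"] and dpos < s.pos:
                    drop = True  # exact tie: keep the 5'-most site
            if not drop:
                passing.append(p)

    calls = []
    for p in passing:
        s = p["site"]
        calls.append(
            PsiCall(
                ref_name=s.ref_name,
                pos=s.pos,
                motif5=s.motif5,
                treated_rate=p["rate"],
                treated_coverage=s.coverage,
                treated_del_count=s.del_count,
                input_rate=p["in_rate"],
                input_coverage=p["in_cov"],
                fold_over_background=p["fold"],
                fraction=p["frac"],
                criteria=tuple(True for _ in CRITERIA),
                tier=assign_tier(s.del_count, config),
                calibration_fallback=p["fallback"],
            )
        )
    calls.sort(key=lambda c: (c.ref_name, c.pos))
    return calls


def _neighbors_known(site: SiteCount, known: set[tuple[str, int]]) -> bool:
    return ((site.ref_name, site.pos - 1) in known
            or (site.ref_name, site.pos + 1) in known)


# ---------------------------------------------------------------------------
# expression

def rpkm(
    read_counts: Mapping[str, int],
    lengths: Mapping[str, int] | ReferenceSet,
    total_reads: int | None = None,
) -> dict[str, float]:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM = reads * 1e9 / (total mapped reads * transcript length in bases).
    """
    if total_reads is None:
        total_reads = int(sum(read_counts.values()))
    if total_reads <= 0:
        raise ValueError("total mapped reads must be > 0")

    def length_of(name: str) -> int:
        if isinstance(lengths, ReferenceSet):
            return lengths.length(name)
        return int(lengths[name])

    return {
        name: (count * 1e9) / (total_reads * length_of(name))
        for name, count in read_counts.items()
    }


def reads_per_reference(sam_path: str | Path) -> dict[str, int]:
    """Primary mapped read count per reference name from a SAM file."""
    counts: dict[str, int] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            counts[read.reference_name] = counts.get(read.reference_name, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# output tables

_CALL_COLUMNS = [
    "ref_name", "pos", "pos_1based", "motif5", "treated_rate",
    "treated_coverage", "treated_del_count", "input_rate", "input_coverage",
    "fold_over_background", "fraction", "tier", "calibration_fallback",
]


def calls_to_dataframe(calls: Sequence[PsiCall]) -> pd.DataFrame:
    rows = [
        {
            "ref_name": c.ref_name,
            "pos": c.pos,
            "pos_1based": c.pos + 1,
            "motif5": c.motif5,
            "treated_rate": f"{c.treated_rate:.6g}",
            "treated_coverage": c.treated_coverage,
            "treated_del_count": c.treated_del_count,
            "input_rate": f"{c.input_rate:.6g}",
            "input_coverage": c.input_coverage,
            "fold_over_background": f"{c.fold_over_background:.6g}",
            "fraction": f"{c.fraction:.6g}",
            "tier": c.tier,
            "calibration_fallback": int(c.calibration_fallback),
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=_CALL_COLUMNS)


def write_calls_tsv(calls: Sequence[PsiCall], path: str | Path) -> None:
    calls_to_dataframe(calls).to_csv(path, sep="\t", index=False)


def write_calls_bed(calls: Sequence[PsiCall], path: str | Path) -> None:
    """BED6+ output: one width-1 interval per call, score = round(1000 * x)."""
    with open(path, "w") as fh:
        for c in calls:
            score = int(round(1000 * min(max(c.fraction, 0.0), 1.0)))
            extra = "\t".join([
                f"{c.treated_rate:.6g}", str(c.treated_coverage),
                str(c.treated_del_count), f"{c.input_rate:.6g}",
                str(c.input_coverage), f"{c.fraction:.6g}", c.tier,
                str(int(c.calibration_fallback)),
            ])
            fh.write(
                f"{c.ref_name}\t{c.pos}\t{c.pos + 1}\t{c.motif5}\t{score}\t+\t{extra}\n"
            )


def read_sites_bed(path: str | Path) -> set[tuple[str, int]]:
    """Known-sites BED (width-1 intervals) -> set of (ref_name, 0-based pos)."""
    sites: set[tuple[str, int]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            for pos in range(start, end):
                sites.add((chrom, pos))
    return sites


def write_background_table(table: BackgroundTable, path: str | Path) -> None:
    rows = [{"motif5": m, "rate": f"{r:.6g}"} for m, r in sorted(table.items())]
    pd.DataFrame(rows, columns=["motif5", "rate"]).to_csv(path, sep="\t", index=False)


def read_background_table(path: str | Path, default_floor: float = 0.01) -> BackgroundTable:
    df = pd.read_csv(path, sep="\t", dtype={"motif5": str})
    if "motif5" not in df.columns or "rate" not in df.columns:
        raise ValueError(f"{path}: background table needs motif5 and rate columns")
    return BackgroundTable(
        {r.motif5: float(r.rate) for r in df.itertuples(index=False)},
        default_floor=default_floor,
    )
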