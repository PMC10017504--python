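"""Synthetic BID-seq data with known ground truth.

Generates spike-in dilution ladders and treated/input read sets over a random
transcriptome, following the same generative mechanism the calibration curve
describes: at a site of stoichiometry x, a fragment is modified with
probability x; modified fragments drop out with probability A; surviving
modified reads delete the site with probability R, unmodified reads with the
background probability B.  Treated libraries additionally apply B at every
other uridine (bisulfite background is chemistry, not site-specific) and both
libraries carry uniform sequencing deletion errors.  Input libraries carry
errors only — no conversion chemistry.

An exact expectation oracle (`oracle_expected_rate`) computes the implied
deletion rate in rational arithmetic; it must agree with the calibration
module's closed form algebraically.

All randomness flows through one `numpy.random.Generator` seeded explicitly;
identical (config, seed) yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .calibration import SpikeInSeries
from .pileup_io import ReferenceSet, extract_motif

__all__ = [
    "DeletionModel",
    "SimConfig",
    "PlantedSite",
    "SimTruth",
    "SimResult",
    "oracle_expected_rate",
    "simulate_spikein_series",
    "simulate_transcriptome",
]

LADDER_FRACTIONS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclasses.dataclass(frozen=True)
class DeletionModel:
    """Generative deletion parameters: dropout A, background B, conversion R."""

    A: float = 0.2
    B: float = 0.01
    R: float = 0.8

    def __post_init__(self):
        for name in ("A", "B", "R"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def oracle_expected_rate(x: float, A: float, B: float, R: float) -> float:
    """Exact expected observed deletion rate by fragment enumeration.

    Of N fragments, x*N are modified; modified fragments survive dropout with
    probability 1-A and then delete with probability R; unmodified fragments
    delete with probability B.  Expected rate among surviving fragments:

        [x(1-A)R + (1-x)B] / [x(1-A) + (1-x)]

    computed in exact rational arithmetic.  Algebraically identical to the
    calibration closed form (B + (R - A*R - B)x) / (1 - A*x).
    """
    fx, fa, fb, fr = (Fraction(v) for v in (x, A, B, R))
    surviving = fx * (1 - fa) + (1 - fx)
    if surviving == 0:
        raise ZeroDivisionError("x=1 with A=1: no fragments survive")
    rate = (fx * (1 - fa) * fr + (1 - fx) * fb) / surviving
    return float(rate)


@dataclasses.dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted Ψ position, with per-fragment audit counts."""

    ref_name: str
    pos: int
    fraction: float
    A: float
    B: float
    R: float
    n_span: int = 0       # treated fragments overlapping the site
    n_modified: int = 0
    n_dropped: int = 0
    n_deleted: int = 0    # deletions written at the site (treated library)


@dataclasses.dataclass
class SimTruth:
    """Planted sites plus generative config; serializes to JSON losslessly.

    ``counts[lib][ref]`` additionally holds the simulator's raw per-position
    (coverage, deletion) arrays for audit against a pileup re-read; these are
    in-memory only.
    """

    sites: list[PlantedSite]
    config: dict
    seed: int
    counts: dict = dataclasses.field(default_factory=dict, compare=False, repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "config": self.config,
            "sites": [dataclasses.asdict(s) for s in self.sites],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        sites = [PlantedSite(**s) for s in payload["sites"]]
        return cls(sites=sites, config=payload["config"], seed=payload["seed"])


@dataclasses.dataclass
class SimConfig:
    """Study conditions for a synthetic transcriptome run.

    One Ψ site is planted per transcript (at a uridine in the window covered
    by every read), with true fractions cycled from ``fractions``.  ``depth``
    is the number of reads per transcript and, by construction, the coverage
    at each planted site before dropout.  Deletions (planted, background and
    sequencing error) are never placed within ``min_end_gap`` bases of a read
    end, so the pileup's internal-deletion rule at the default flank recovers
    every simulated event.
    """

    n_transcripts: int = 10
    transcript_length: int = 120
    read_length: int = 100
    depth: int = 500
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    params: DeletionModel = dataclasses.field(default_factory=DeletionModel)
    error_rate: float = 0.001
    gc: float = 0.5
    min_end_gap: int = 2
    treated_background: bool = True
    two_base_deletions: bool = False
    coverage_attenuation: Mapping[tuple[str, int], float] | None = None

    def __post_init__(self):
        if self.read_length > self.transcript_length:
            raise ValueError("read_length must not exceed transcript_length")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate outside [0, 1]")
        for x in self.fractions:
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"planted fraction {x} outside [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = dataclasses.asdict(self.params)
        d["fractions"] = list(self.fractions)
        if self.coverage_attenuation is not None:
            d["coverage_attenuation"] = {
                f"{r}:{p}": v for (r, p), v in self.coverage_attenuation.items()
            }
        return d


@dataclasses.dataclass
class SimResult:
    fasta_path: Path
    sam_paths: dict[str, Path]
    truth_path: Path
    truth: SimTruth
    reference: ReferenceSet


def simulate_spikein_series(
    motif5: str,
    params: DeletionModel,
    fractions: Sequence[float] = LADDER_FRACTIONS,
    coverage: int = 5000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SpikeInSeries, dict]:
    """Draw a spike-in dilution ladder under the generative mechanism.

    For each ladder level: modified-fragment count ~ Binomial(coverage, x),
    dropout ~ Binomial(n_modified, A); deletions ~ Binomial(survivors, R) +
    Binomial(n_unmodified, B).  Returns the observed series (coverage after
    dropout) and an audit dict of the latent counts.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or rng) is required for stochastic output")
        rng = np.random.default_rng(seed)
    points = []
    audit = {"motif5": motif5, "levels": []}
    for x in fractions:
        n_mod = int(rng.binomial(coverage, x))
        n_drop = int(rng.binomial(n_mod, params.A)) if n_mod else 0
        n_surv_mod = n_mod - n_drop
        n_unmod = coverage - n_mod
        d_mod = int(rng.binomial(n_surv_mod, params.R)) if n_surv_mod else 0
        d_unmod = int(rng.binomial(n_unmod, params.B)) if n_unmod else 0
        obs_cov = n_surv_mod + n_unmod
        points.append((float(x), obs_cov, d_mod + d_unmod))
        audit["levels"].append(
            {"x": float(x), "n_modified": n_mod, "n_dropped": n_drop,
             "n_del_modified": d_mod, "n_del_unmodified": d_unmod}
        )
    return SpikeInSeries(motif5, points), audit


# ---------------------------------------------------------------------------
# transcriptome simulation

_ALPHABET = np.array(list("ACGT"))


def _random_transcript(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_ALPHABET[rng.choice(4, size=length, p=p)])


def simulate_transcriptome(
    config: SimConfig,
    seed: int,
    out_dir: str | Path,
    libraries: Sequence[str] = ("treated", "input"),
    prefix: str = "sim",
) -> SimResult:
    """Generate a reference FASTA, one SAM per library, and a truth sidecar.

    Reads start uniformly over valid offsets; planted sites sit inside the
    window spanned by every read so their pre-dropout coverage equals
    ``config.depth`` exactly.  Dropped fragments are removed from the treated
    library entirely.  CIGARs encode each simulated deletion; the SAM is valid
    against the emitted FASTA.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cfg = config
    L, span, g = cfg.transcript_length, cfg.read_length, cfg.min_end_gap
    n_starts = L - span + 1
    # window of positions covered by every read, shrunk by the end gap
    win_lo, win_hi = (L - span) + g, span - g  # [win_lo, win_hi)
    if win_hi - win_lo < 5:
        raise ValueError("transcript_length/read_length leave no planting window")

    # --- references and planted sites
    seqs: dict[str, str] = {}
    planted: dict[str, list[tuple[int, float]]] = {}
    for i in range(cfg.n_transcripts):
        name = f"{prefix}_t{i + 1:03d}"
        seq = list(_random_transcript(rng, L, cfg.gc))
        x = float(cfg.fractions[i % len(cfg.fractions)])
        u_window = [p for p in range(win_lo, win_hi) if seq[p] == "T"]
        if not u_window:
            p = (win_lo + win_hi) // 2
            seq[p] = "T"
            u_window = [p]
        site = int(rng.choice(u_window))
        seqs[name] = "".join(seq)
        planted[name] = [(site, x)]

    fasta_path = out_dir / f"{prefix}.fa"
    with open(fasta_path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
    reference = ReferenceSet(seqs)

    model = cfg.params
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": L} for n in seqs],
    }
    sam_paths: dict[str, Path] = {}
    pysam_header = pysam.AlignmentHeader.from_dict(header)
    site_audit: dict[tuple[str, int], dict] = {
        (name, p): {"fraction": x, "n_span": 0, "n_modified": 0,
                    "n_dropped": 0, "n_deleted": 0}
        for name, sites in planted.items() for p, x in sites
    }
    counts: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}

    for lib in libraries:
        if lib not in ("treated", "input"):
            raise ValueError(f"unknown library {lib!r}")
        sam_path = out_dir / f"{prefix}.{lib}.sam"
        sam_paths[lib] = sam_path
        counts[lib] = {}
        with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
            for ref_id, (name, seq) in enumerate(seqs.items()):
                cov_arr = np.zeros(L, dtype=np.int64)
                del_arr = np.zeros(L, dtype=np.int64)
                n = _effective_depth(cfg, name, planted[name], lib)
                starts = np.sort(rng.integers(0, n_starts, size=n))
                deletions: dict[int, set[int]] = {}
                dropped = np.zeros(n, dtype=bool)

                if lib == "treated":
                    for p, x in planted[name]:
                        a = site_audit[(name, p)]
                        spans = (starts <= p - g) & (starts >= p - span + 1 + g)
                        idx = np.nonzero(spans)[0]
                        a["n_span"] += len(idx)
                        mod = rng.random(len(idx)) < x
                        drop = mod & (rng.random(len(idx)) < model.A)
                        survive_mod = mod & ~drop
                        delete = np.zeros(len(idx), dtype=bool)
                        delete[survive_mod] = rng.random(int(survive_mod.sum())) < model.R
                        unmod = ~mod
                        delete[unmod] = rng.random(int(unmod.sum())) < model.B
                        a["n_modified"] += int(mod.sum())
                        a["n_dropped"] += int(drop.sum())
                        dropped[idx[drop]] = True
                        for j in idx[delete & ~drop]:
                            _add_deletion(deletions, int(j), p, cfg)
                    if cfg.treated_background and model.B > 0:
                        planted_pos = {p for p, _ in planted[name]}
                        for q, base in enumerate(seq):
                            if base != "T" or q in planted_pos:
                                continue
                            spans = (starts <= q - g) & (starts >= q - span + 1 + g)
                            idx = np.nonzero(spans & ~dropped)[0]
                            if len(idx) == 0:
                                continue
                            hit = idx[rng.random(len(idx)) < model.B]
                            for j in hit:
                                _add_deletion(deletions, int(j), q, cfg)

                # sequencing deletion errors, both libraries, away from read ends
                if cfg.error_rate > 0:
                    m_eligible = span - 2 * g
                    k = rng.binomial(m_eligible, cfg.error_rate, size=n)
                    for j in np.nonzero((k > 0) & ~dropped)[0]:
                        offs = rng.choice(m_eligible, size=int(k[j]), replace=False)
                        for off in offs:
                            deletions.setdefault(int(j), set()).add(
                                int(starts[j]) + g + int(off)
                            )

                for j in range(n):
                    if dropped[j]:
                        continue
                    s = int(starts[j])
                    dels = sorted(d for d in deletions.get(j, ())
                                  if s <= d < s + span)
                    delset = set(dels)
                    cov_arr[s:s + span] += 1
                    for d in dels:
                        del_arr[d] += 1
                        if (name, d) in site_audit and lib == "treated":
                            site_audit[(name, d)]["n_deleted"] += 1
                    read = pysam.AlignedSegment(header=pysam_header)
                    read.query_name = f"{name}.{lib}.{j + 1}"
                    read.flag = 0
                    read.reference_id = ref_id
                    read.reference_start = s
                    read.mapping_quality = 60
                    read.cigartuples = _cigar_from_deletions(s, span, dels)
                    read.query_sequence = "".join(
                        seq[p] for p in range(s, s + span) if p not in delset
                    )
                    out.write(read)
                counts[lib][name] = (cov_arr, del_arr)

    truth = SimTruth(
        sites=[
            PlantedSite(
                ref_name=name, pos=p, fraction=a["fraction"],
                A=model.A, B=model.B, R=model.R,
                n_span=a["n_span"], n_modified=a["n_modified"],
                n_dropped=a["n_dropped"], n_deleted=a["n_deleted"],
            )
            for (name, p), a in sorted(site_audit.items())
        ],
        config=cfg.to_dict(),
        seed=seed,
        counts=counts,
    )
    truth_path = out_dir / f"{prefix}.truth.json"
    truth.to_json(truth_path)
    return SimResult(fasta_path, sam_paths, truth_path, truth, reference)


def _effective_depth(cfg: SimConfig, name: str, sites, lib: str) -> int:
    """Optional per-site coverage attenuation (dense-Ψ RT-stop loss model)."""
    n = cfg.depth
    if lib == "treated" and cfg.coverage_attenuation:
        for p, _ in sites:
            f = cfg.coverage_attenuation.get((name, p))
            if f is not None:
                n = int(round(n * f))
    return n


def _add_deletion(deletions: dict[int, set[int]], read_idx: int,
                  pos: int, cfg: SimConfig) -> None:
    s = deletions.setdefault(read_idx, set())
    s.add(pos)
    if cfg.two_base_deletions:
        s.add(pos + 1)


def _cigar_from_deletions(start: int, span: int, dels: list[int]) -> list[tuple[int, int]]:
    """CIGAR over reference window [start, start+span) with 1-base D runs merged."""
    ops: list[tuple[int, int]] = []
    pos = start
    for d in dels:
        if d > pos:
            ops.append((0, d - pos))       # M
        if ops and ops[-1][0] == 2:
            ops[-1] = (2, ops[-1][1] + 1)  # extend D run
        else:
            ops.append((2, 1))
        pos = d + 1
    if pos < start + span:
        ops.append((0, start + span - pos))
    return ops
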