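"""Spike-in calibration linking observed deletion rates to Ψ stoichiometry.

The generative model: of the transcript copies overlapping a site, a fraction
``x`` carry Ψ.  During library preparation a fraction ``A`` of the modified
fragments drops out; surviving modified reads show a deletion with probability
``R`` (the conversion-induced deletion ratio, near 1 for most 5-mer contexts)
while unmodified reads delete at the background rate ``B``.  The observed
deletion rate is therefore

    y = (B + (R - A*R - B) * x) / (1 - A * x)

which is fitted per sequence motif from a dilution ladder of synthetic probes
mixed at known Ψ fractions (0/20/40/60/80/100%), then inverted to estimate the
stoichiometry x at transcriptome sites:

    x = (y - B) / (R - A*R - B + A*y)

Estimates are clamped to [0, 1]; sampling noise routinely produces observed
rates slightly below B or above R.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CalibrationParams",
    "SpikeInSeries",
    "DEFAULT_FALLBACK_PARAMS",
    "UnidentifiableSeriesError",
    "predict_deletion",
    "invert_fraction",
    "fit_calibration",
    "resolve_params",
    "read_calibration_table",
    "write_calibration_table",
    "read_spikein_table",
    "write_spikein_table",
]


class UnidentifiableSeriesError(ValueError):
    """Raised when a spike-in series carries no usable signal (e.g. flat rates)."""


@dataclasses.dataclass(frozen=True)
class CalibrationParams:
    """Per-motif calibration triple (A, B, R) with fit diagnostics.

    A: dropout ratio of modified fragments, in [0, 1).
    B: background deletion rate at unmodified U, in [0, 1).
    R: conversion-induced deletion ratio at a fully modified site, in (0, 1].
    """

    motif5: str
    A: float
    B: float
    R: float
    rss: float = float("nan")
    n_points: int = 0

    def __post_init__(self):
        if not 0.0 <= self.A < 1.0:
            raise ValueError(f"A={self.A} outside [0, 1)")
        if not 0.0 <= self.B < self.R <= 1.0:
            raise ValueError(f"require 0 <= B < R <= 1, got B={self.B}, R={self.R}")


#: Conservative default for motifs without spike-in coverage.  Most 5-mer
#: contexts convert at well above 60% deletion at full stoichiometry, so this
#: R understates (never inflates) the estimated fraction.
DEFAULT_FALLBACK_PARAMS = CalibrationParams("NNUNN", A=0.0, B=0.005, R=0.6)


@dataclasses.dataclass
class SpikeInSeries:
    """Dilution-ladder observations for one motif.

    ``points`` holds (true_fraction, coverage, del_count) triples; fitting
    requires at least three distinct fractions.
    """

    motif5: str
    points: list[tuple[float, int, int]]

    def __post_init__(self):
        for x, cov, dels in self.points:
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"fraction {x} outside [0, 1]")
            if not 0 <= dels <= cov:
                raise ValueError(f"del_count {dels} outside [0, coverage={cov}]")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def rates(self) -> np.ndarray:
        return np.array(
            [dels / cov if cov else np.nan for _, cov, dels in self.points],
            dtype=float,
        )


def predict_deletion(x, params: CalibrationParams):
    """Expected observed deletion rate at Ψ fraction ``x`` (scalar or array)."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("fraction x must lie in [0, 1]")
    y = (params.B + (params.R - params.A * params.R - params.B) * x) / (
        1.0 - params.A * x
    )
    return float(y) if y.ndim == 0 else y


def invert_fraction(y, params: CalibrationParams):
    """Estimate Ψ fraction from an observed deletion rate, clamped to [0, 1]."""
    y = np.asarray(y, dtype=float)
    # for y >= B the denominator is >= (1-A)(R-B) > 0; sub-background
    # observations clamp to 0 before dividing
    denom = params.R - params.A * params.R - params.B + params.A * y
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (y - params.B) / denom
    x = np.where(y <= params.B, 0.0, np.clip(raw, 0.0, 1.0))
    x = np.asarray(x, dtype=float)
    return float(x) if x.ndim == 0 else x


def fit_calibration(
    series: SpikeInSeries,
    weights: str = "none",
) -> CalibrationParams:
    """Least-squares fit of (A, B, R) to a spike-in dilution series.

    Deterministic: initialization is B0 = rate at the smallest fraction,
    R0 = rate at the largest fraction, A0 = 0, with box bounds
    0 <= A <= 0.99, 0 <= B <= 1, 0 <= R <= 1.  ``weights="binomial"`` scales
    residuals by the inverse binomial standard error (off by default; the
    unweighted fit treats every ladder level equally).
    """
    x = series.fractions
    ydata = series.rates
    ok = ~np.isnan(ydata)
    x, ydata = x[ok], ydata[ok]
    if len(np.unique(x)) < 3:
        raise ValueError("fitting requires >= 3 distinct spike-in fractions")
    if float(np.ptp(ydata)) < 1e-9:
        raise UnidentifiableSeriesError(
            f"all observed rates equal ({ydata[0]:.4g}) for motif {series.motif5}"
        )
    covs = np.array([p[1] for p, keep in zip(series.points, ok) if keep], dtype=float)

    b0 = float(ydata[np.argmin(x)])
    r0 = float(ydata[np.argmax(x)])
    if r0 <= b0:
        r0 = min(1.0, b0 + 1e-3)
    x0 = np.array([0.0, b0, r0])

    if weights == "binomial":
        p = np.clip(ydata, 1e-6, 1 - 1e-6)
        w = np.sqrt(covs / (p * (1 - p)))
    elif weights == "none":
        w = np.ones_like(ydata)
    else:
        raise ValueError(f"unknown weights scheme {weights!r}")

    def resid(theta):
        a, b, r = theta
        pred = (b + (r - a * r - b) * x) / (1.0 - a * x)
        return w * (pred - ydata)

    sol = least_squares(
        resid,
        x0,
        bounds=([0.0, 0.0, 0.0], [0.99, 1.0, 1.0]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    a, b, r = (float(v) for v in sol.x)
    if not b < r:
        raise UnidentifiableSeriesError(
            f"fit degenerate (B={b:.4g} >= R={r:.4g}) for motif {series.motif5}"
        )
    # keep parameters strictly inside the open invariant bounds
    a = min(a, math.nextafter(1.0, 0.0) - 1e-12)
    rss = float(np.sum((resid(sol.x) / w) ** 2))
    return CalibrationParams(series.motif5, a, b, r, rss=rss, n_points=len(ydata))


def resolve_params(
    motif5: str,
    table: Mapping[str, CalibrationParams] | None,
    fallback: CalibrationParams | None = DEFAULT_FALLBACK_PARAMS,
) -> tuple[CalibrationParams, bool]:
    """Look up calibration for a motif; fall back to a global default.

    Returns ``(params, used_fallback)``.  Motifs containing N (reference
    edges) always resolve to the fallback.
    """
    table = table or {}
    if "N" not in motif5 and motif5 in table:
        return table[motif5], False
    if fallback is None:
        raise KeyError(f"no calibration for motif {motif5!r} and no fallback")
    return fallback, True


# ---------------------------------------------------------------------------
# TSV interfaces

def write_calibration_table(
    table: Mapping[str, CalibrationParams], path: str | Path
) -> None:
    rows = [
        {"motif5": m, "A": f"{p.A:.6g}", "B": f"{p.B:.6g}", "R": f"{p.R:.6g}"}
        for m, p in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["motif5", "A", "B", "R"]).to_csv(
        path, sep="\t", index=False
    )


def read_calibration_table(path: str | Path) -> dict[str, CalibrationParams]:
    df = pd.read_csv(path, sep="\t", dtype={"motif5": str})
    missing = [c for c in ("motif5", "A", "B", "R") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: calibration table missing columns {missing}")
    return {
        row.motif5: CalibrationParams(
            row.motif5, float(row.A), float(row.B), float(row.R)
        )
        for row in df.itertuples(index=False)
    }


def write_spikein_table(
    series: Sequence[SpikeInSeries], path: str | Path
) -> None:
    """Spike-in ladders as TSV: motif5, true_fraction, coverage, del_count."""
    rows = []
    for s in series:
        for x, cov, dels in s.points:
            rows.append(
                {"motif5": s.motif5, "true_fraction": f"{x:.6g}",
                 "coverage": cov, "del_count": dels}
            )
    pd.DataFrame(
        rows, columns=["motif5", "true_fraction", "coverage", "del_count"]
    ).to_csv(path, sep="\t", index=False)


def read_spikein_table(path: str | Path) -> list[SpikeInSeries]:
    df = pd.read_csv(path, sep="\t", dtype={"motif5": str})
    required = ["motif5", "true_fraction", "coverage", "del_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: spike-in table missing columns {missing}")
    out = []
    for motif, grp in df.groupby("motif5", sort=True):
        points = [
            (float(r.true_fraction), int(r.coverage), int(r.del_count))
            for r in grp.itertuples(index=False)
        ]
        out.append(SpikeInSeries(motif, points))
    return out
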