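"""Graphical recovery of apparent inhibition constants.

Dixon construction: 1/v versus [I] at several fixed substrate levels; the
abscissa of the common intersection is -Kic.  Cornish-Bowden construction:
[S]/v versus [I]; the common intersection abscissa is -Kiu.  Lines are fitted
by unweighted least squares and the common point is aggregated as the median
over all pairwise intersections; near-parallel pairs are excluded, and an
estimate where every pair is near-parallel is reported as unbounded.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

#: relative slope difference below which two lines count as parallel
PARALLEL_RTOL = 1e-3


class EstimationError(ValueError):
    """Raised when a rate table cannot support the graphical construction."""


@dataclass(frozen=True)
class LineFit:
    slope: float
    intercept: float
    residual_ss: float
    n_points: int

    def __post_init__(self):
        if self.n_points < 3:
            raise EstimationError("line fits need at least 3 points")

    def at(self, x):
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class KiEstimate:
    """Apparent inhibition constant; ``value=None`` means unbounded
    (all line pairs near-parallel, i.e. no detectable effect)."""

    value: float | None
    method: str
    pairwise_spread: float | None = None
    n_lines: int = 0

    @property
    def unbounded(self) -> bool:
        return self.value is None

    def to_dict(self) -> dict:
        return {
            "value_M": self.value,
            "method": self.method,
            "pairwise_spread": self.pairwise_spread,
            "n_lines": self.n_lines,
        }


@dataclass(frozen=True)
class InhibitionClassification:
    label: str
    kic: KiEstimate
    kiu: KiEstimate
    ratio: float | None  # Kic/Kiu when both bounded

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "kic": self.kic.to_dict(),
            "kiu": self.kiu.to_dict(),
            "kic_over_kiu": self.ratio,
        }


def fit_line(x, y) -> LineFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise EstimationError("need >= 3 points per series")
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return LineFit(float(coef[0]), float(coef[1]), float(resid @ resid), len(x))


def pairwise_intersections(lines):
    """Abscissae of all pairwise line intersections, skipping near-parallel pairs."""
    xs = []
    for a, b in itertools.combinations(lines, 2):
        scale = max(abs(a.slope), abs(b.slope))
        if scale == 0 or abs(a.slope - b.slope) < PARALLEL_RTOL * scale:
            continue
        xs.append((b.intercept - a.intercept) / (a.slope - b.slope))
    return xs


def _series(table, min_series=3, min_points=3):
    groups = list(table.substrate_series())
    if len(groups) < min_series:
        raise EstimationError(f"need >= {min_series} substrate series, got {len(groups)}")
    out = []
    for s, grp in groups:
        i = grp["inhibitor"].to_numpy(dtype=float)
        v = grp["velocity"].to_numpy(dtype=float)
        if len(i) < min_points:
            raise EstimationError(f"series at {s:g} M has < {min_points} points")
        if np.any(v <= 0):
            raise EstimationError(f"non-positive velocity in series at {s:g} M")
        out.append((s, i, v))
    return out


def _aggregate(xs, method, n_lines) -> KiEstimate:
    if not xs:
        return KiEstimate(None, method, None, n_lines)
    xs = np.asarray(xs, dtype=float)
    med = float(np.median(xs))
    q1, q3 = np.percentile(xs, [25, 75])
    spread = float((q3 - q1) / abs(med)) if med != 0 else math.inf
    value = -med
    if value <= 0:
        # intersection on the positive axis: no meaningful constant
        return KiEstimate(None, method, spread, n_lines)
    return KiEstimate(value, method, spread, n_lines)


def dixon_kic(table) -> KiEstimate:
    """Apparent competitive constant from the Dixon construction."""
    series = _series(table)
    lines = [fit_line(i, 1.0 / v) for _, i, v in series]
    return _aggregate(pairwise_intersections(lines), "dixon", len(lines))


def cornish_bowden_kiu(table) -> KiEstimate:
    """Apparent uncompetitive constant from the Cornish-Bowden construction."""
    series = _series(table)
    lines = [fit_line(i, s / v) for s, i, v in series]
    return _aggregate(pairwise_intersections(lines), "cornish_bowden", len(lines))


def estimate_ki(table):
    """Convenience: (dixon Kic, cornish-bowden Kiu) for one rate table."""
    return dixon_kic(table), cornish_bowden_kiu(table)


def classify_pattern(kic: KiEstimate, kiu: KiEstimate, pnc_window=(0.5, 2.0)) -> InhibitionClassification:
    """Label the inhibition pattern from the two apparent constants.

    Unbounded Kiu -> competitive; unbounded Kic -> uncompetitive; otherwise
    pure non-competitive when Kic/Kiu falls inside ``pnc_window``, else mixed
    with the dominant component named.
    """
    low, high = pnc_window
    if not 0 < low <= high:
        raise ValueError("pnc_window must satisfy 0 < low <= high")
    if kic.unbounded and kiu.unbounded:
        raise EstimationError("no inhibition signal: both constants unbounded")
    if kiu.unbounded:
        return InhibitionClassification("competitive", kic, kiu, None)
    if kic.unbounded:
        return InhibitionClassification("uncompetitive", kic, kiu, None)
    ratio = kic.value / kiu.value
    if low <= ratio <= high:
        label = "pure_noncompetitive"
    elif ratio < low:
        label = "mixed_competitive_dominant"
    else:
        label = "mixed_uncompetitive_dominant"
    return InhibitionClassification(label, kic, kiu, ratio)


def reciprocal_intersection(table):
    """Median pairwise intersection of the 1/v-versus-1/[S] lines across
    inhibitor series, as (1/S*, 1/v*).  Diagnostic for plot geometry."""
    groups = [
        (i, grp["substrate"].to_numpy(dtype=float), grp["velocity"].to_numpy(dtype=float))
        for i, grp in table.inhibitor_series()
    ]
    if len(groups) < 2:
        raise EstimationError("need >= 2 inhibitor series for the reciprocal plot")
    lines = []
    for i, s, v in groups:
        if np.any(v <= 0) or np.any(s <= 0):
            raise EstimationError("non-positive velocity or substrate")
        lines.append(fit_line(1.0 / s, 1.0 / v))
    xs, ys = [], []
    for a, b in itertools.combinations(lines, 2):
        scale = max(abs(a.slope), abs(b.slope))
        if scale == 0 or abs(a.slope - b.slope) < PARALLEL_RTOL * scale:
            continue
        x = (b.intercept - a.intercept) / (a.slope - b.slope)
        xs.append(x)
        ys.append(a.at(x))
    if not xs:
        raise EstimationError("all reciprocal-plot lines are parallel")
    return float(np.median(xs)), float(np.median(ys))
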