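"""Ground-truth synthetic inputs: Kic-Kiu mixtures, flat-file fixtures and
noisy rate tables.

All generators are pure functions of their inputs and a seed.  Inhibition
constants get multiplicative lognormal noise: positive quantities spanning
orders of magnitude with relative (graphical-analysis-like) error.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .assay_protocols import RateTable
from .ratio_statistics import CLASSES, RatioRecord
from .units import from_molar

#: base Kic values are drawn log-uniformly from this range (mol/L)
KIC_RANGE = (1e-8, 1e-3)


@dataclass(frozen=True)
class SyntheticMixSpec:
    """Three-class mixture of Kic-Kiu couples.

    ``weights`` orders as (competitive_dominant, pure_noncompetitive,
    uncompetitive_dominant); ``fold_distribution`` is the log-uniform range
    of the dominant-class fold; ``noise_cv`` the lognormal coefficient of
    variation applied independently to each constant.
    """

    n: int
    weights: tuple
    fold_distribution: tuple = (2.0, 100.0)
    noise_cv: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        w = tuple(float(x) for x in self.weights)
        if len(w) != 3 or any(x < 0 for x in w):
            raise ValueError("weights must be 3 non-negative numbers")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 within 1e-9")
        object.__setattr__(self, "weights", w)
        lo, hi = self.fold_distribution
        if not 1.0 <= lo <= hi:
            raise ValueError("fold_distribution must satisfy 1 <= lo <= hi")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _lognormal_factors(rng, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def synth_ratio_records(spec: SyntheticMixSpec):
    """Draw ``spec.n`` couples; the true class is recorded in the source_id
    (``synthetic:<class>:<index>``) so recovery can be scored exactly."""
    rng = np.random.default_rng(spec.seed)
    classes = rng.choice(3, size=spec.n, p=spec.weights)
    kic = np.exp(rng.uniform(*map(math.log, KIC_RANGE), size=spec.n))
    lo, hi = spec.fold_distribution
    folds = np.exp(rng.uniform(math.log(lo), math.log(hi), size=spec.n))
    kiu = np.where(classes == 0, kic * folds, np.where(classes == 2, kic / folds, kic))
    kic = kic * _lognormal_factors(rng, spec.noise_cv, spec.n)
    kiu = kiu * _lognormal_factors(rng, spec.noise_cv, spec.n)
    return [
        RatioRecord(float(kic[i]), float(kiu[i]), f"synthetic:{CLASSES[classes[i]]}:{i}")
        for i in range(spec.n)
    ]


def true_class(record: RatioRecord) -> str:
    """Generator ground-truth class stored in the record's source_id."""
    return record.source_id.split(":")[1]


# ---------------------------------------------------------------------------
# flat-file fixture generation
# ---------------------------------------------------------------------------

_PHRASES_PAIR = (
    "mixed inhibition",
    "mixed-type inhibition of the enzyme",
    "inhibition of the mixed type",
)
_PHRASES_COMP = (
    "competitive inhibition",
    "competitive versus the substrate",
)
_NAMES = ("aldonate", "bistramide", "cordycepin", "daphnetin", "emodin", "fisetin")


def _format_conc(value_m: float) -> str:
    """Pick the unit that keeps the mantissa in [1, 1000) and print 4 sig. digits."""
    for unit in ("M", "mM", "uM", "nM", "pM"):
        x = from_molar(value_m, unit)
        if 1.0 <= x < 1000.0:
            return f"{x:.4g} {unit}"
    return f"{from_molar(value_m, 'pM'):.4g} pM"


def synth_flatfile(records, seed: int = 0) -> str:
    """Emit the documented flat-file dialect, one entry per record.

    ``parse_flatfile`` recovers the records exactly (up to 4-significant-
    digit float formatting).  Records with unbounded Kiu are written as
    competitive entries carrying only a Kic.
    """
    rng = np.random.default_rng(seed)
    lines = []
    for i, r in enumerate(records):
        lines.append(f"ID\t1.1.1.{i + 1}")
        name = _NAMES[rng.integers(len(_NAMES))]
        ref = int(rng.integers(1, 99))
        if r.kiu is None:
            phrase = _PHRASES_COMP[rng.integers(len(_PHRASES_COMP))]
            comment = f"{phrase}, Kic = {_format_conc(r.kic)}"
        else:
            phrase = _PHRASES_PAIR[rng.integers(len(_PHRASES_PAIR))]
            comment = (
                f"{phrase}, Kic = {_format_conc(r.kic)}, "
                f"Kiu = {_format_conc(r.kiu)}"
            )
        lines.append(f"IN\t{name}\t(#{ref}# {comment} <{ref}>)")
        lines.append("///")
    return "\n".join(lines) + ("\n" if lines else "")


def noisy_rate_table(table: RateTable, cv: float, seed: int = 0) -> RateTable:
    """Rate table with velocities multiplied by independent mean-1 lognormal
    factors of the given coefficient of variation."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    df["velocity"] = df["velocity"].to_numpy() * _lognormal_factors(rng, cv, len(df))
    meta = dict(table.metadata)
    meta.update({"noise_cv": cv, "noise_seed": seed})
    return RateTable(df, meta)
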