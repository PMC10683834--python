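"""Closed-form kinetic predictions used as pipeline references and test oracles."""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

UNBOUNDED = math.inf


@dataclass(frozen=True)
class TightParams:
    """Michaelis-Menten enzyme with a competitive inhibitor potent enough to
    be depleted by binding (free != total)."""

    Km: float    # mol/L
    kcat: float  # 1/s
    Ki: float    # mol/L
    E0: float    # mol/L

    def __post_init__(self):
        if min(self.Km, self.kcat, self.Ki, self.E0) <= 0:
            raise ValueError("all TightParams fields must be > 0")


@dataclass(frozen=True)
class OrderedBiBiParams:
    """Compulsory-order ternary-complex (A before B) parameters."""

    Ks: float    # E.A dissociation constant, mol/L
    KmA: float   # mol/L
    KmB: float   # mol/L
    kcat: float  # 1/s
    Kic: float   # true E.I dissociation constant, mol/L

    def __post_init__(self):
        if min(self.Ks, self.KmA, self.KmB, self.kcat, self.Kic) <= 0:
            raise ValueError("all OrderedBiBiParams fields must be > 0")
        if self.Ks / self.KmA <= 1:
            raise ValueError("compulsory-order mechanism requires Ks/KmA > 1")


@dataclass(frozen=True)
class IsoParams:
    """Two-segment turnover: chemistry (net kchem) plus a free-enzyme
    isomerisation (net kiso) that returns the product-binding form to the
    substrate-binding form."""

    Kd: float            # inhibitor dissociation constant, mol/L
    kchem: float         # 1/s
    kiso: float          # 1/s
    kcat: float          # 1/s
    kFiso: float = None  # forward isomerisation, 1/s
    kRiso: float = None  # reverse isomerisation, 1/s
    k4: float = None     # microscopic forward iso step, 1/s
    km4: float = 0.0     # microscopic reverse iso step, 1/s

    def __post_init__(self):
        if min(self.Kd, self.kchem, self.kiso, self.kcat) <= 0:
            raise ValueError("Kd, kchem, kiso, kcat must be > 0")
        if self.kFiso is None:
            object.__setattr__(self, "kFiso", self.kiso)
        if self.kRiso is None:
            object.__setattr__(self, "kRiso", self.km4 if self.km4 > 0 else UNBOUNDED)
        if self.k4 is None:
            object.__setattr__(self, "k4", self.kiso)
        if all(map(math.isfinite, (self.kchem, self.kiso))):
            lhs, rhs = 1.0 / self.kcat, 1.0 / self.kchem + 1.0 / self.kiso
            if abs(lhs - rhs) > 1e-6 * lhs:
                raise ValueError("inconsistent segments: 1/kcat != 1/kchem + 1/kiso")


def mm_rate(Vmax: float, Km: float, S: float) -> float:
    """Plain Michaelis-Menten velocity."""
    return Vmax * S / (Km + S)


def mixed_rate_law(Vmax, Km, Kic, Kiu, S, I):
    """Steady-state linear mixed-inhibition rate law.

    v = Vmax*S / (Km*(1+I/Kic) + S*(1+I/Kiu)).  ``Kiu=UNBOUNDED`` (or None)
    gives the competitive law; ``Kic=UNBOUNDED`` the uncompetitive one.
    """
    kic = UNBOUNDED if Kic is None else Kic
    kiu = UNBOUNDED if Kiu is None else Kiu
    slope = 1.0 + (I / kic if math.isfinite(kic) else 0.0)
    icpt = 1.0 + (I / kiu if math.isfinite(kiu) else 0.0)
    return Vmax * S / (Km * slope + S * icpt)


def morrison_rate(p: TightParams, S: float, I0: float) -> float:
    """Equilibrium velocity of a competitive tight-binding inhibitor.

    The free/bound inhibitor partition is solved exactly from the binding
    quadratic with the substrate-corrected Ki_app = Ki*(1+S/Km); the velocity
    is the Michaelis-Menten rate of the unbound enzyme fraction.
    """
    if S < 0 or I0 < 0:
        raise ValueError("S and I0 must be >= 0")
    if I0 == 0:
        return mm_rate(p.kcat * p.E0, p.Km, S)
    k_app = p.Ki * (1.0 + S / p.Km)
    b = p.E0 + I0 + k_app
    disc = b * b - 4.0 * p.E0 * I0
    assert disc >= 0, "negative discriminant is impossible for valid inputs"
    ei = (b - math.sqrt(disc)) / 2.0
    return mm_rate(p.kcat * (p.E0 - ei), p.Km, S)


def apparent_ordered(p: OrderedBiBiParams, A: float):
    """Apparent (KIC, KIU) against the second substrate at fixed [A] for a
    dead-end inhibitor of the leading substrate in a compulsory-order
    ternary-complex mechanism: Kic*(1+A/Ks) and Kic*(1+A/KmA)."""
    if A < 0:
        raise ValueError("A must be >= 0")
    return p.Kic * (1.0 + A / p.Ks), p.Kic * (1.0 + A / p.KmA)


def apparent_random(Kic: float, Ks: float, A: float):
    """Apparent (KIC, KIU) for the random-order mechanism: both equal
    Kic*(1+A/Ks), so their ratio is identically 1."""
    if A < 0:
        raise ValueError("A must be >= 0")
    k = Kic * (1.0 + A / Ks)
    return k, k


def iso_constants(p: IsoParams):
    """(Kic, Kiu) for an inhibitor of the product-binding free-enzyme form:
    Kic = Kd*(k4+k-4)/k4 and Kiu = Kd*kiso/kcat."""
    kic = p.Kd * (p.k4 + p.km4) / p.k4
    kiu = p.Kd * p.kiso / p.kcat if math.isfinite(p.kiso) else UNBOUNDED
    return kic, kiu


def fiso(p: IsoParams, variant: str = "forward_only") -> float:
    """Kinetic significance of the isomerisation segment.

    ``forward_only``: kcat/kiso.  ``reversible``: kcat*(1/kFiso + 1/kRiso).
    """
    if variant == "forward_only":
        return p.kcat / p.kiso if math.isfinite(p.kiso) else 0.0
    if variant == "reversible":
        inv = (1.0 / p.kFiso if math.isfinite(p.kFiso) else 0.0) + (
            1.0 / p.kRiso if math.isfinite(p.kRiso) else 0.0
        )
        return p.kcat * inv
    raise ValueError(f"unknown fiso variant {variant!r}")


class RatioPrediction(NamedTuple):
    """Predicted apparent Kiu/Kic ratio; ``asymptotic`` marks limits that are
    approached rather than attained at finite settings."""

    value: float
    asymptotic: bool = False


def predicted_ratio(case_id: str, params=None, condition=None) -> RatioPrediction:
    """Closed-form apparent Kiu/Kic prediction for one mechanism/condition.

    ``condition`` is the case's control variable: fixed [A] for the bi-bi
    cases (None means the saturating-[A] limit), ignored for tight/slow,
    and unused for iso/exosite where ``params`` fixes Fiso.
    """
    if case_id in ("tight", "slow"):
        return RatioPrediction(1.0, asymptotic=True)
    if case_id == "ordered_bibi":
        if condition is None:
            return RatioPrediction(params.Ks / params.KmA, asymptotic=True)
        kic, kiu = apparent_ordered(params, condition)
        return RatioPrediction(kiu / kic)
    if case_id == "random_bibi":
        return RatioPrediction(1.0)
    if case_id in ("iso", "exosite"):
        f = fiso(params, "forward_only")
        return RatioPrediction(UNBOUNDED if f == 0 else 1.0 / f)
    raise ValueError(f"no closed-form ratio prediction for case {case_id!r}")
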