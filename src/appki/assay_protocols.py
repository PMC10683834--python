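"""Initial-rate assays: turn a mechanism spec into a velocity table.

Every (substrate, inhibitor) condition is an independent simulation from
t = 0 under the measurement protocol: either all reagents mixed at once
(``co_start``) or the enzyme pre-equilibrated with the inhibitor and the
reaction started by substrate addition (``preincubate``).  The velocity is
read at ``detection_time`` either as the instantaneous product-formation
rate or as accumulated product over elapsed time (``chord``).
"""
from __future__ import annotations

import io
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .reaction_core import (
    IntegrationError,
    ReactionNetwork,
    instantaneous_rate,
    integrate,
)

INITIATIONS = ("co_start", "preincubate")
VELOCITY_MODES = ("instantaneous", "chord")


@dataclass(frozen=True)
class AssayProtocol:
    """Measurement protocol for an initial-rate experiment.

    ``max_consumption`` is an optional initial-rate guard: when set, the
    enzyme load is scaled down (never up) so that the product formed by
    ``detection_time`` cannot exceed that fraction of the smallest varied
    substrate concentration.  Without the guard the printed enzyme loads
    consume a large share of the lowest substrate points within 60 s, which
    breaks the premise of the Dixon / Cornish-Bowden analysis.
    """

    detection_time: float = 60.0
    initiation: str = "co_start"
    velocity_mode: str = "instantaneous"
    max_consumption: float | None = None

    def __post_init__(self):
        if self.detection_time <= 0:
            raise ValueError("detection_time must be > 0")
        if self.initiation not in INITIATIONS:
            raise ValueError(f"initiation must be one of {INITIATIONS}")
        if self.velocity_mode not in VELOCITY_MODES:
            raise ValueError(f"velocity_mode must be one of {VELOCITY_MODES}")
        if self.max_consumption is not None and not 0 < self.max_consumption <= 1:
            raise ValueError("max_consumption must be in (0, 1]")


class RateTable:
    """Initial-rate records: (varied substrate, co-substrate, inhibitor, velocity)."""

    COLUMNS = ("substrate", "co_substrate", "inhibitor", "velocity")

    def __init__(self, records, metadata=None):
        df = pd.DataFrame(records, columns=self.COLUMNS)
        self.df = df.reset_index(drop=True)
        self.metadata = dict(metadata or {})

    def __len__(self):
        return len(self.df)

    @property
    def case_id(self):
        return self.metadata.get("case_id")

    def substrate_series(self):
        """Iterate (substrate_conc, sub-DataFrame sorted by inhibitor)."""
        for s, grp in self.df.groupby("substrate", sort=True):
            yield float(s), grp.sort_values("inhibitor")

    def inhibitor_series(self):
        for i, grp in self.df.groupby("inhibitor", sort=True):
            yield float(i), grp.sort_values("substrate")

    def scaled(self, factor: float) -> "RateTable":
        out = self.df.copy()
        out["velocity"] = out["velocity"] * factor
        return RateTable(out, dict(self.metadata))

    def validate(self, mono_rtol: float = 1e-6) -> None:
        """Check table invariants: non-negative velocities, an [I]=0 series,
        and velocity non-increasing in [I] at fixed substrate."""
        v = self.df["velocity"].to_numpy()
        if np.any(v < 0):
            raise ValueError("negative velocity in rate table")
        if not np.any(self.df["inhibitor"] == 0):
            raise ValueError("rate table lacks an [I]=0 series")
        for s, grp in self.substrate_series():
            vv = grp["velocity"].to_numpy()
            if np.any(np.diff(vv) > mono_rtol * vv.max()):
                raise ValueError(
                    f"velocity not non-increasing in [I] at substrate {s:g} M"
                )

    # -- CSV dialect --------------------------------------------------------
    def to_csv(self, path_or_buf) -> None:
        varied = self.metadata.get("varied", "S")
        out = pd.DataFrame(
            {
                "case_id": self.metadata.get("case_id", ""),
                f"{varied}_M": self.df["substrate"],
                "A_M": self.df["co_substrate"],
                "I_M": self.df["inhibitor"],
                "v_M_per_s": self.df["velocity"],
            }
        )
        if self.df["co_substrate"].isna().all():
            out = out.drop(columns=["A_M"])
        header = "# metadata " + json.dumps(self.metadata, default=str)
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(header + "\n")
            out.to_csv(path_or_buf, index=False)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(header + "\n")
                out.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "RateTable":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        metadata = {}
        lines = text.splitlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                if "metadata" in line:
                    metadata = json.loads(line.split("metadata", 1)[1])
                body_start = i + 1
            else:
                break
        df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])))
        sub_col = next(c for c in df.columns if c.endswith("_M") and c not in ("A_M", "I_M"))
        records = pd.DataFrame(
            {
                "substrate": df[sub_col],
                "co_substrate": df["A_M"] if "A_M" in df.columns else np.nan,
                "inhibitor": df["I_M"],
                "velocity": df["v_M_per_s"],
            }
        )
        if "case_id" in df.columns and "case_id" not in metadata and len(df):
            metadata["case_id"] = df["case_id"].iloc[0]
        if "varied" not in metadata:
            metadata["varied"] = sub_col[:-2]
        return cls(records, metadata)


def preincubate(network: ReactionNetwork, E0: float, I0: float):
    """Binding equilibrium of an enzyme-inhibitor incubation without substrate.

    Solves the tight-binding quadratic exactly for the single E + I <-> EI
    equilibrium found in the network and returns the concentrations as a
    dict {E: free enzyme, EI: complex, I: free inhibitor}.
    """
    if E0 <= 0:
        raise ValueError("E0 must be > 0")
    if I0 < 0:
        raise ValueError("I0 must be >= 0")
    for sp in network.species:
        if sp.role == "substrate" and sp.conc0 > 0:
            raise ValueError("substrate must be absent from the preincubation")
    pairs = []
    by_name = {s.name: s for s in network.species}
    for rx in network.reactions:
        if len(rx.reactants) == 2 and len(rx.products) == 1:
            roles = sorted(by_name[n].role for n in rx.reactants)
            if roles == ["enzyme_form", "inhibitor"]:
                enz = next(n for n in rx.reactants if by_name[n].role == "enzyme_form")
                inh = next(n for n in rx.reactants if by_name[n].role == "inhibitor")
                complex_ = rx.products[0]
                kon = rx.rate_const
                koff = next(
                    (r.rate_const for r in network.reactions
                     if r.reactants == (complex_,) and set(r.products) == set(rx.reactants)),
                    None,
                )
                if koff is not None:
                    pairs.append((enz, inh, complex_, koff / kon))
    if not pairs:
        raise ValueError("network has no E + I <-> EI binding step")
    if len(pairs) > 1:
        raise ValueError("ambiguous preincubation: several free-enzyme binding steps")
    enz, inh, complex_, kd = pairs[0]
    b = E0 + I0 + kd
    ei = (b - math.sqrt(b * b - 4.0 * E0 * I0)) / 2.0 if I0 > 0 else 0.0
    return {enz: E0 - ei, complex_: ei, inh: I0 - ei}


def _effective_e0(spec, substrate_grid) -> float:
    """Enzyme load after applying the protocol's initial-rate guard."""
    e0 = spec.params.get("E0")
    if e0 is None:
        e0 = max(sp.conc0 for sp in spec.network.species if sp.role == "enzyme_form")
    frac = spec.protocol.max_consumption
    if frac is None:
        return float(e0)
    kcat = getattr(spec.analytic_params, "kcat", None)
    if kcat is None and isinstance(spec.analytic_params, dict):
        kcat = spec.analytic_params.get("kcat")
    if not kcat:
        return float(e0)
    s_min = min(s for s in substrate_grid if s > 0)
    cap = frac * s_min / (kcat * spec.protocol.detection_time)
    return float(min(e0, cap))


def _velocity(network, protocol, state0, product) -> float:
    t_det = protocol.detection_time
    traj = integrate(network, t_det, state0=state0)
    if protocol.velocity_mode == "instantaneous":
        return instantaneous_rate(network, traj, product, t_det)
    p_idx = network.index(product)
    return float(traj.state_at(t_det)[p_idx] - traj.state_at(0.0)[p_idx]) / t_det


def run_inhibition_assay(spec, A_fixed: float | None = None) -> RateTable:
    """Simulate every grid condition of a mechanism spec into a RateTable.

    Bi-bi specs need the fixed co-substrate concentration, either from
    ``A_fixed`` or from the spec's ``A_fixed`` parameter.
    """
    protocol = spec.protocol
    varied_grid = spec.grids["B" if spec.is_bibi else "S"]
    i_grid = spec.grids["I"]
    if spec.is_bibi:
        a_fixed = float(A_fixed if A_fixed is not None else spec.params["A_fixed"])
        if a_fixed <= 0:
            raise ValueError("fixed co-substrate concentration must be > 0")
    elif A_fixed is not None:
        raise ValueError(f"case {spec.case_id!r} has no fixed co-substrate")
    e0 = _effective_e0(spec, varied_grid)
    enzyme0 = next(sp.name for sp in spec.network.species if sp.role == "enzyme_form" and sp.conc0 > 0)
    network = spec.network.with_conc0(**{enzyme0: e0})
    inhibitor = next(sp.name for sp in network.species if sp.role == "inhibitor")
    records = []
    for s in varied_grid:
        for i in i_grid:
            init = {spec.varied: float(s), inhibitor: float(i)}
            if spec.is_bibi:
                init[spec.co_substrate] = a_fixed
            if protocol.initiation == "preincubate":
                eq = preincubate(network.with_conc0(**{inhibitor: 0.0}), e0, float(i))
                init.update(eq)
                init[enzyme0] = eq[enzyme0]
            state0 = network.initial_state(init)
            try:
                v = _velocity(network, protocol, state0, spec.product)
            except IntegrationError as err:
                raise IntegrationError(
                    f"condition ({spec.varied}={s:g} M, I={i:g} M) failed: {err}",
                    state=err.state,
                ) from err
            records.append((float(s), a_fixed if spec.is_bibi else np.nan, float(i), max(v, 0.0)))
    return RateTable(
        records,
        metadata={
            "case_id": spec.case_id,
            "varied": spec.varied,
            "protocol": asdict(protocol),
            "E0_effective": e0,
            "A_fixed": a_fixed if spec.is_bibi else None,
        },
    )


def vary_fixed_substrate(spec, A_fixed: float) -> RateTable:
    """Initial-rate table of a bi-bi spec at one fixed leading-substrate level."""
    if not spec.is_bibi:
        raise ValueError(f"case {spec.case_id!r} is not a two-substrate mechanism")
    if A_fixed <= 0:
        raise ValueError("A_fixed must be > 0")
    return run_inhibition_assay(spec, A_fixed=A_fixed)
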