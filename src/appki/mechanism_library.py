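"""Ready-built mechanism specifications.

Each case is defined by a YAML document shipped as package data (printed
rate constants, concentration grids, measurement protocol) plus a network
topology assembled here.  ``case_spec`` returns a :class:`MechanismSpec`
bundling the mass-action network, the assay grids, the protocol and the
matching closed-form parameter set.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .analytic_models import IsoParams, OrderedBiBiParams, TightParams
from .assay_protocols import AssayProtocol
from .reaction_core import ReactionNetwork, Reaction, Species
from .units import to_molar

CASE_IDS = (
    "tight",
    "slow",
    "ordered_bibi",
    "random_bibi",
    "iso",
    "exosite",
    "two_site_reference",
)

#: (k2, k_2, k4, k_4) combinations indexed by the Fiso value they realise
#: (all four constants in 1/s; k_2 acts on a step that is second order in
#: the simulated network but carries no flux at [P] ~ 0).
FISO_TABLE = {
    0.0: (100.0, 100.0, 1.0e6, 1.0e6),
    0.1: (111.0, 111.0, 1000.0, 1000.0),
    0.2: (125.0, 125.0, 500.0, 500.0),
    0.5: (200.0, 200.0, 200.0, 200.0),
    0.7: (333.0, 333.0, 143.0, 143.0),
    1.0: (1.0e6, 1.0e6, 100.0, 100.0),
}


@dataclass(frozen=True)
class FisoVariant:
    """One column of the iso-mechanism rate-constant table."""

    fiso_label: float
    k2: float
    k_2: float
    k4: float
    k_4: float

    @classmethod
    def from_label(cls, label) -> "FisoVariant":
        key = float(label)
        if key not in FISO_TABLE:
            raise KeyError(
                f"unknown Fiso label {label!r}; known: {sorted(FISO_TABLE)}"
            )
        return cls(key, *FISO_TABLE[key])


@dataclass
class MechanismSpec:
    """A simulatable mechanism: network + grids + protocol + analytic params."""

    case_id: str
    network: ReactionNetwork
    grids: dict
    protocol: AssayProtocol
    analytic_params: object = None
    params: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)
    varied: str = "S"          # name of the varied-substrate species
    co_substrate: str = None   # fixed co-substrate species, bi-bi cases only
    product: str = "P"

    def __post_init__(self):
        for name, grid in self.grids.items():
            grid = np.asarray(grid, dtype=float)
            if grid.size == 0:
                raise ValueError(f"empty grid {name!r}")
            if name == "I":
                if np.any(grid < 0):
                    raise ValueError("inhibitor grid must be >= 0")
            elif np.any(grid <= 0):
                raise ValueError(f"grid {name!r} must be strictly positive")
            self.grids[name] = grid

    @property
    def is_bibi(self) -> bool:
        return self.co_substrate is not None


def _log_grid(lo: float, hi: float, n: int, prepend_zero: bool = False) -> np.ndarray:
    g = np.geomspace(lo, hi, n)
    return np.concatenate([[0.0], g]) if prepend_zero else g


def _load_case_doc(case_id: str) -> dict:
    try:
        text = resources.files("appki.data").joinpath(f"{case_id}.yaml").read_text()
    except FileNotFoundError:
        raise KeyError(f"unknown case_id {case_id!r}; known: {CASE_IDS}") from None
    return yaml.safe_load(text)


def _merge_params(doc: dict, overrides) -> dict:
    params = dict(doc["params"])
    grid_keys = {"S_grid", "I_grid", "B_grid"}
    for key, value in (overrides or {}).items():
        if key in grid_keys:
            continue
        if key not in params:
            raise KeyError(
                f"cannot override unknown parameter {key!r} of case "
                f"{doc['case_id']!r}; known: {sorted(params)}"
            )
        params[key] = to_molar(value) if isinstance(value, str) else value
    return params


def _protocol(doc: dict) -> AssayProtocol:
    return AssayProtocol(**doc["protocol"])


def _grid_from_doc(doc, name, overrides):
    if overrides and f"{name}_grid" in overrides:
        return np.asarray([to_molar(v) for v in overrides[f"{name}_grid"]], dtype=float)
    spec = doc["grids"][name]
    return _log_grid(spec["lo"], spec["hi"], spec["n"], spec.get("prepend_zero", False))


# ---------------------------------------------------------------------------
# per-case builders
# ---------------------------------------------------------------------------

def _tight_spec(doc, overrides):
    p = _merge_params(doc, overrides)
    i_center = p["i_over_e"] * p["E0"]
    ki = p["Ki"] if p["Ki"] is not None else i_center / 10.0
    network = ReactionNetwork(
        [
            Species("E", "enzyme_form", p["E0"]),
            Species("S", "substrate"),
            Species("ES", "complex"),
            Species("P", "product"),
            Species("I", "inhibitor"),
            Species("EI", "complex"),
        ],
        [
            Reaction(("E", "S"), ("ES",), p["k1"]),
            Reaction(("ES",), ("E", "S"), p["k_1"]),
            Reaction(("ES",), ("E", "P"), p["k2"]),
            Reaction(("E", "I"), ("EI",), p["kon_I"]),
            Reaction(("EI",), ("E", "I"), ki * p["kon_I"]),
        ],
    )
    km = (p["k_1"] + p["k2"]) / p["k1"]
    if overrides and "I_grid" in overrides:
        i_grid = np.asarray([to_molar(v) for v in overrides["I_grid"]], dtype=float)
    else:
        i_grid = np.concatenate(
            [[0.0], i_center * np.asarray(doc["grids"]["I_bracket"], dtype=float)]
        )
    return MechanismSpec(
        case_id="tight",
        network=network,
        grids={"S": _grid_from_doc(doc, "S", overrides), "I": i_grid},
        protocol=_protocol(doc),
        analytic_params=TightParams(Km=km, kcat=p["k2"], Ki=ki, E0=p["E0"]),
        params={**p, "Ki": ki},
        sweep=doc.get("sweep", {}),
    )


def _slow_spec(doc, overrides):
    p = _merge_params(doc, overrides)
    kon = p["koff"] / p["Kd_I"]
    network = ReactionNetwork(
        [
            Species("E", "enzyme_form", p["E0"]),
            Species("S", "substrate"),
            Species("ES", "complex"),
            Species("P", "product"),
            Species("I", "inhibitor"),
            Species("EI", "complex"),
        ],
        [
            Reaction(("E", "S"), ("ES",), p["k1"]),
            Reaction(("ES",), ("E", "S"), p["k_1"]),
            Reaction(("ES",), ("E", "P"), p["k2"]),
            Reaction(("E", "I"), ("EI",), kon),
            Reaction(("EI",), ("E", "I"), p["koff"]),
        ],
    )
    km = (p["k_1"] + p["k2"]) / p["k1"]
    return MechanismSpec(
        case_id="slow",
        network=network,
        grids={"S": _grid_from_doc(doc, "S", overrides), "I": _grid_from_doc(doc, "I", overrides)},
        protocol=_protocol(doc),
        analytic_params=TightParams(Km=km, kcat=p["k2"], Ki=p["Kd_I"], E0=p["E0"]),
        params=p,
        sweep=doc.get("sweep", {}),
    )


def _ordered_bibi_spec(doc, overrides):
    p = _merge_params(doc, overrides)
    network = ReactionNetwork(
        [
            Species("E", "enzyme_form", p["E0"]),
            Species("A", "substrate"),
            Species("EA", "complex"),
            Species("B", "substrate"),
            Species("EAB", "complex"),
            Species("P", "product"),
            Species("I", "inhibitor"),
            Species("EI", "complex"),
        ],
        [
            Reaction(("E", "A"), ("EA",), p["k1"]),
            Reaction(("EA",), ("E", "A"), p["k_1"]),
            Reaction(("EA", "B"), ("EAB",), p["k2"]),
            Reaction(("EAB",), ("EA", "B"), p["k_2"]),
            Reaction(("EAB",), ("E", "P"), p["kcat"]),
            Reaction(("E", "I"), ("EI",), p["kon_I"]),
            Reaction(("EI",), ("E", "I"), p["Ki"] * p["kon_I"]),
        ],
    )
    analytic = OrderedBiBiParams(
        Ks=p["k_1"] / p["k1"],
        KmA=p["kcat"] / p["k1"],
        KmB=(p["k_2"] + p["kcat"]) / p["k2"],
        kcat=p["kcat"],
        Kic=p["Ki"],
    )
    return MechanismSpec(
        case_id="ordered_bibi",
        network=network,
        grids={
            "B": _grid_from_doc(doc, "B", overrides),
            "I": _grid_from_doc(doc, "I", overrides),
        },
        protocol=_protocol(doc),
        analytic_params=analytic,
        params=p,
        sweep=doc.get("sweep", {}),
        varied="B",
        co_substrate="A",
    )


def _random_bibi_spec(doc, overrides):
    p = _merge_params(doc, overrides)
    network = ReactionNetwork(
        [
            Species("E", "enzyme_form", p["E0"]),
            Species("A", "substrate"),
            Species("EA", "complex"),
            Species("B", "substrate"),
            Species("EB", "complex"),
            Species("EAB", "complex"),
            Species("P", "product"),
            Species("I", "inhibitor"),
            Species("EI", "complex"),
            Species("EBI", "complex"),
        ],
        [
            Reaction(("E", "A"), ("EA",), p["k1"]),
            Reaction(("EA",), ("E", "A"), p["k_1"]),
            Reaction(("E", "B"), ("EB",), p["k2"]),
            Reaction(("EB",), ("E", "B"), p["k_2"]),
            Reaction(("EA", "B"), ("EAB",), p["k2"]),
            Reaction(("EAB",), ("EA", "B"), p["k_2"]),
            Reaction(("EB", "A"), ("EAB",), p["k1"]),
            Reaction(("EAB",), ("EB", "A"), p["k_1"]),
            Reaction(("EAB",), ("E", "P"), p["kcat"]),
            # the dead-end inhibitor occupies the A site: binds E and EB
            Reaction(("E", "I"), ("EI",), p["kon_I"]),
            Reaction(("EI",), ("E", "I"), p["Ki"] * p["kon_I"]),
            Reaction(("EB", "I"), ("EBI",), p["kon_I"]),
            Reaction(("EBI",), ("EB", "I"), p["Ki"] * p["kon_I"]),
        ],
    )
    analytic = OrderedBiBiParams(
        Ks=p["k_1"] / p["k1"],
        KmA=p["kcat"] / p["k1"],
        KmB=(p["k_2"] + p["kcat"]) / p["k2"],
        kcat=p["kcat"],
        Kic=p["Ki"],
    )
    return MechanismSpec(
        case_id="random_bibi",
        network=network,
        grids={
            "B": _grid_from_doc(doc, "B", overrides),
            "I": _grid_from_doc(doc, "I", overrides),
        },
        protocol=_protocol(doc),
        analytic_params=analytic,
        params=p,
        sweep=doc.get("sweep", {}),
        varied="B",
        co_substrate="A",
    )


def _iso_params(p) -> IsoParams:
    kchem, kiso = p["k2"], p["k4"]
    kcat = 1.0 / (1.0 / kchem + 1.0 / kiso)
    return IsoParams(
        Kd=p["Kd"], kchem=kchem, kiso=kiso, kcat=kcat,
        kFiso=p["k4"], kRiso=p["k_4"], k4=p["k4"], km4=p["k_4"],
    )


def _iso_spec(doc, overrides):
    p = _merge_params(doc, overrides)
    network = ReactionNetwork(
        [
            Species("E", "enzyme_form", p["E0"]),
            Species("S", "substrate"),
            Species("ES", "complex"),
            Species("F", "enzyme_form"),
            Species("P", "product"),
            Species("I", "inhibitor"),
            Species("EI", "complex"),
            Species("FI", "complex"),
        ],
        [
            Reaction(("E", "S"), ("ES",), p["k1"]),
            Reaction(("ES",), ("E", "S"), p["k_1"]),
            Reaction(("ES",), ("F", "P"), p["k2"]),
            Reaction(("F", "P"), ("ES",), p["k_2"]),
            Reaction(("F",), ("E",), p["k4"]),
            Reaction(("E",), ("F",), p["k_4"]),
            # the active-site inhibitor binds both free-enzyme isomers
            Reaction(("E", "I"), ("EI",), p["kon_I"]),
            Reaction(("EI",), ("E", "I"), p["Kd"] * p["kon_I"]),
            Reaction(("F", "I"), ("FI",), p["kon_I"]),
            Reaction(("FI",), ("F", "I"), p["Kd"] * p["kon_I"]),
        ],
    )
    return MechanismSpec(
        case_id="iso",
        network=network,
        grids={"S": _grid_from_doc(doc, "S", overrides), "I": _grid_from_doc(doc, "I", overrides)},
        protocol=_protocol(doc),
        analytic_params=_iso_params(p),
        params=p,
        sweep=doc.get("sweep", {}),
    )


def _exosite_params(p) -> IsoParams:
    k2, k_2, k3 = p["k2"], p["k_2"], p["k3"]
    kiso = k2 * k3 / (k_2 + k3)          # net SE -> ES
    kcat = k2 * k3 / (k2 + k_2 + k3)
    return IsoParams(
        Kd=p["Kd"], kchem=k3, kiso=kiso, kcat=kcat, kFiso=k2, kRiso=k_2,
    )


def _exosite_spec(doc, overrides):
    p = _merge_params(doc, overrides)
    network = ReactionNetwork(
        [
            Species("E", "enzyme_form", p["E0"]),
            Species("S", "substrate"),
            Species("SE", "complex"),
            Species("ES", "complex"),
            Species("P", "product"),
            Species("I", "inhibitor"),
            Species("EI", "complex"),
            Species("SEI", "complex"),
        ],
        [
            Reaction(("E", "S"), ("SE",), p["k1"]),
            Reaction(("SE",), ("E", "S"), p["k_1"]),
            Reaction(("SE",), ("ES",), p["k2"]),
            Reaction(("ES",), ("SE",), p["k_2"]),
            Reaction(("ES",), ("E", "P"), p["k3"]),
            # active-site inhibitor: binds E and the encounter complex SE
            Reaction(("E", "I"), ("EI",), p["kon_I"]),
            Reaction(("EI",), ("E", "I"), p["Kd"] * p["kon_I"]),
            Reaction(("SE", "I"), ("SEI",), p["kon_I"]),
            Reaction(("SEI",), ("SE", "I"), p["Kd"] * p["kon_I"]),
        ],
    )
    return MechanismSpec(
        case_id="exosite",
        network=network,
        grids={"S": _grid_from_doc(doc, "S", overrides), "I": _grid_from_doc(doc, "I", overrides)},
        protocol=_protocol(doc),
        analytic_params=_exosite_params(p),
        params=p,
        sweep=doc.get("sweep", {}),
    )


def _two_site_spec(doc, overrides):
    p = _merge_params(doc, overrides)
    return two_site_reference_spec(
        Kic=p["Kic"],
        Kiu=p["Kiu"],
        Km=p["Km"],
        kcat=p["kcat"],
        E0=p["E0"],
        k1=p["k1"],
        kon_I=p["kon_I"],
        doc=doc,
        overrides=overrides,
    )


_BUILDERS = {
    "tight": _tight_spec,
    "slow": _slow_spec,
    "ordered_bibi": _ordered_bibi_spec,
    "random_bibi": _random_bibi_spec,
    "iso": _iso_spec,
    "exosite": _exosite_spec,
    "two_site_reference": _two_site_spec,
}


def case_spec(case_id: str, overrides: dict | None = None) -> MechanismSpec:
    """Build the default mechanism spec for one case, with optional parameter
    overrides (unknown parameter names are rejected)."""
    if case_id not in _BUILDERS:
        raise KeyError(f"unknown case_id {case_id!r}; known: {CASE_IDS}")
    doc = _load_case_doc(case_id)
    return _BUILDERS[case_id](doc, overrides)


def iso_variant_spec(fiso_label, overrides: dict | None = None) -> MechanismSpec:
    """Iso-mechanism spec with the rate-constant column of the given Fiso label."""
    variant = FisoVariant.from_label(fiso_label)
    merged = {
        "k2": variant.k2,
        "k_2": variant.k_2,
        "k4": variant.k4,
        "k_4": variant.k_4,
        "fiso_label": variant.fiso_label,
        **(overrides or {}),
    }
    return case_spec("iso", merged)


def exosite_variant_spec(k2: float, overrides: dict | None = None) -> MechanismSpec:
    """Exo-site spec at one point of the mirrored k2/k3 sweep (k2*k3 = 5e7)."""
    merged = {"k2": float(k2), "k3": 5.0e7 / float(k2), **(overrides or {})}
    return case_spec("exosite", merged)


def two_site_reference_spec(
    Kic: float,
    Kiu: float | None,
    Km: float = 1.0e-5,
    kcat: float = 100.0,
    E0: float = 1.0e-12,
    k1: float = 1.0e8,
    kon_I: float = 1.0e8,
    doc: dict | None = None,
    overrides: dict | None = None,
) -> MechanismSpec:
    """Formal two-site mixed mechanism with known ground-truth (Kic, Kiu).

    ``Kiu=None`` builds the purely competitive topology (no ESI species).
    """
    for name, value in (("Kic", Kic), ("Km", Km), ("kcat", kcat), ("E0", E0)):
        if value is None or value <= 0:
            raise ValueError(f"{name} must be > 0")
    if Kiu is not None and Kiu <= 0:
        raise ValueError("Kiu must be > 0 or None (competitive topology)")
    k_1 = Km * k1 - kcat
    if k_1 <= 0:
        raise ValueError("Km too small for the chosen k1/kcat")
    species = [
        Species("E", "enzyme_form", E0),
        Species("S", "substrate"),
        Species("ES", "complex"),
        Species("P", "product"),
        Species("I", "inhibitor"),
        Species("EI", "complex"),
    ]
    reactions = [
        Reaction(("E", "S"), ("ES",), k1),
        Reaction(("ES",), ("E", "S"), k_1),
        Reaction(("ES",), ("E", "P"), kcat),
        Reaction(("E", "I"), ("EI",), kon_I),
        Reaction(("EI",), ("E", "I"), Kic * kon_I),
    ]
    if Kiu is not None and math.isfinite(Kiu):
        species.append(Species("ESI", "complex"))
        reactions += [
            Reaction(("ES", "I"), ("ESI",), kon_I),
            Reaction(("ESI",), ("ES", "I"), Kiu * kon_I),
        ]
    network = ReactionNetwork(species, reactions)
    doc = doc or _load_case_doc("two_site_reference")
    bounded = [k for k in (Kic, Kiu) if k is not None and math.isfinite(k)]
    if overrides and "I_grid" in overrides:
        i_grid = np.asarray([to_molar(v) for v in overrides["I_grid"]], dtype=float)
    else:
        i_grid = _log_grid(
            0.3 * min(bounded), 3.0 * max(bounded), int(doc["grids"]["n_I"]),
            prepend_zero=True,
        )
    return MechanismSpec(
        case_id="two_site_reference",
        network=network,
        grids={"S": _grid_from_doc(doc, "S", overrides), "I": i_grid},
        protocol=_protocol(doc),
        analytic_params={"Vmax": kcat * E0, "Km": Km, "Kic": Kic, "Kiu": Kiu, "kcat": kcat},
        params={"k1": k1, "Km": Km, "kcat": kcat, "Kic": Kic, "Kiu": Kiu, "kon_I": kon_I, "E0": E0},
        sweep=doc.get("sweep", {}),
    )
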