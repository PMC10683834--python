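"""Mass-action reaction networks and deterministic stiff integration.

A :class:`ReactionNetwork` is a validated set of :class:`Species` and
uni-/bi-molecular :class:`Reaction` objects from which a mass-action ODE
right-hand side (and its analytic Jacobian) is derived.  Integration is
deterministic: the same network always yields bit-identical trajectories.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .units import to_molar

ROLES = frozenset({"enzyme_form", "substrate", "product", "inhibitor", "complex"})
#: roles whose members carry one enzyme moiety each
ENZYME_ROLES = frozenset({"enzyme_form", "complex"})

#: pseudo-species name accepted by :func:`instantaneous_rate`
ENZYME_TOTAL = "enzyme_total"

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-15  # mol/L
CONSERVATION_RTOL = 1e-6


class NetworkError(ValueError):
    """Raised for malformed network definitions."""


class IntegrationError(RuntimeError):
    """Raised when integration fails or violates physical invariants."""

    def __init__(self, message: str, state=None):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class Species:
    """A chemical species: unique name, role tag and initial concentration (M)."""

    name: str
    role: str = "substrate"
    conc0: float = 0.0

    def __post_init__(self):
        if self.role not in ROLES:
            raise NetworkError(f"unknown species role {self.role!r}")
        if not np.isfinite(self.conc0) or self.conc0 < 0:
            raise NetworkError(f"conc0 of {self.name!r} must be >= 0")


@dataclass(frozen=True)
class Reaction:
    """An elementary reaction with 1-2 reactants and 0-2 products.

    ``rate_const`` is s^-1 for unimolecular and M^-1 s^-1 for bimolecular
    reactions.
    """

    reactants: tuple
    products: tuple
    rate_const: float

    def __post_init__(self):
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))
        if not 1 <= len(self.reactants) <= 2:
            raise NetworkError(f"molecularity must be 1 or 2, got {len(self.reactants)}")
        if len(self.products) > 2:
            raise NetworkError("at most 2 products per elementary reaction")
        if not np.isfinite(self.rate_const) or self.rate_const < 0:
            raise NetworkError("rate_const must be finite and >= 0")


class ReactionNetwork:
    """Validated mass-action network with derived ODE right-hand side."""

    def __init__(self, species, reactions):
        species = list(species)
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise NetworkError(f"duplicate species names: {dupes}")
        declared = set(names)
        for rx in reactions:
            for n in rx.reactants + rx.products:
                if n not in declared:
                    raise NetworkError(f"reaction references undeclared species {n!r}")
        self.species = tuple(species)
        self.reactions = tuple(reactions)
        self._index = {n: i for i, n in enumerate(names)}
        self._compile()

    # -- construction ------------------------------------------------------
    def _compile(self):
        n_sp, n_rx = len(self.species), len(self.reactions)
        self._k = np.array([r.rate_const for r in self.reactions], dtype=float)
        self._r1 = np.empty(n_rx, dtype=np.intp)
        self._r2 = np.empty(n_rx, dtype=np.intp)  # -1 for unimolecular
        stoich = np.zeros((n_sp, n_rx))
        for j, rx in enumerate(self.reactions):
            idx = [self._index[n] for n in rx.reactants]
            self._r1[j] = idx[0]
            self._r2[j] = idx[1] if len(idx) == 2 else -1
            for i in idx:
                stoich[i, j] -= 1
            for n in rx.products:
                stoich[self._index[n], j] += 1
        self._stoich = stoich
        self._bimol = self._r2 >= 0

    # -- basic accessors ---------------------------------------------------
    @property
    def names(self):
        return tuple(s.name for s in self.species)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise NetworkError(f"unknown species {name!r}") from None

    def initial_state(self, overrides=None) -> np.ndarray:
        """Initial concentration vector, optionally overriding per-species values."""
        c0 = np.array([s.conc0 for s in self.species], dtype=float)
        for name, value in (overrides or {}).items():
            c0[self.index(name)] = to_molar(value)
        return c0

    def with_conc0(self, **conc0) -> "ReactionNetwork":
        """Copy of the network with some initial concentrations replaced (mol/L)."""
        new = [
            Species(s.name, s.role, float(conc0.get(s.name, s.conc0)))
            for s in self.species
        ]
        return ReactionNetwork(new, self.reactions)

    # -- mass action -------------------------------------------------------
    def rates(self, c: np.ndarray) -> np.ndarray:
        r = self._k * c[self._r1]
        if self._bimol.any():
            r[self._bimol] *= c[self._r2[self._bimol]]
        return r

    def rhs(self, t, c):
        return self._stoich @ self.rates(np.asarray(c, dtype=float))

    def jacobian(self, t, c):
        c = np.asarray(c, dtype=float)
        n_sp = len(self.species)
        drate = np.zeros((len(self.reactions), n_sp))
        for j in range(len(self.reactions)):
            i1, i2 = self._r1[j], self._r2[j]
            if i2 < 0:
                drate[j, i1] += self._k[j]
            else:
                drate[j, i1] += self._k[j] * c[i2]
                drate[j, i2] += self._k[j] * c[i1]
        return self._stoich @ drate

    # -- conservation ------------------------------------------------------
    def enzyme_conservation_group(self):
        """Names of enzyme-carrying species whose total is structurally conserved.

        Returns an empty tuple when the stoichiometry does not conserve the
        candidate group (e.g. a scheme that synthesises enzyme).
        """
        group = [s.name for s in self.species if s.role in ENZYME_ROLES]
        if not group:
            return ()
        idx = [self._index[n] for n in group]
        net = self._stoich[idx, :].sum(axis=0)
        if np.any(np.abs(net) > 0):
            return ()
        return tuple(group)

    def conserved_total(self, c) -> float:
        group = self.enzyme_conservation_group()
        if not group:
            return 0.0
        c = np.asarray(c, dtype=float)
        return float(sum(c[self._index[n]] for n in group))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "species": [
                {"name": s.name, "role": s.role, "conc0": s.conc0, "unit": "M"}
                for s in self.species
            ],
            "reactions": [
                {
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "k": r.rate_const,
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ReactionNetwork":
        species = [
            Species(
                d["name"],
                d.get("role", "substrate"),
                to_molar(d.get("conc0", 0.0), d.get("unit")),
            )
            for d in doc["species"]
        ]
        reactions = [
            Reaction(tuple(d["reactants"]), tuple(d.get("products", ())), float(d["k"]))
            for d in doc["reactions"]
        ]
        return cls(species, reactions)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ReactionNetwork":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ReactionNetwork":
        return cls.from_dict(json.loads(text))

    def __eq__(self, other):
        return (
            isinstance(other, ReactionNetwork)
            and self.species == other.species
            and self.reactions == other.reactions
        )

    def __repr__(self):
        return (
            f"ReactionNetwork({len(self.species)} species, "
            f"{len(self.reactions)} reactions)"
        )


def build_network(species, reactions) -> ReactionNetwork:
    """Validate and compile a mass-action network."""
    return ReactionNetwork(species, reactions)


@dataclass
class Trajectory:
    """Deterministic concentration time courses on [0, t_end]."""

    times: np.ndarray
    concs: np.ndarray  # shape (n_times, n_species)
    species: tuple
    _interp: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concs = np.asarray(self.concs, dtype=float)
        if self.times.ndim != 1 or self.times[0] != 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing and start at 0")

    def conc(self, name: str) -> np.ndarray:
        return self.concs[:, self.species.index(name)]

    def state_at(self, t: float) -> np.ndarray:
        if not self.times[0] <= t <= self.times[-1]:
            raise ValueError(f"t={t} outside trajectory span")
        if self._interp is not None:
            return np.asarray(self._interp(t), dtype=float)
        out = np.empty(self.concs.shape[1])
        for i in range(self.concs.shape[1]):
            out[i] = np.interp(t, self.times, self.concs[:, i])
        return out

    def to_csv(self, path) -> None:
        header = ",".join(["time_s"] + list(self.species))
        data = np.column_stack([self.times, self.concs])
        np.savetxt(path, data, delimiter=",", header=header, comments="")


def integrate(
    network: ReactionNetwork,
    t_end: float,
    t_eval=None,
    *,
    state0=None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the network ODEs to ``t_end`` with a stiff-capable solver.

    Raises :class:`IntegrationError` on solver failure, on loss of enzyme
    conservation beyond 1e-6 relative, or on concentrations more negative
    than ``-10 * atol``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if t_eval is not None:
        t_eval = np.asarray(t_eval, dtype=float)
        if t_eval.min() < 0 or t_eval.max() > t_end:
            raise ValueError("t_eval must lie within [0, t_end]")
        if t_eval[0] != 0:
            t_eval = np.concatenate([[0.0], t_eval])
    c0 = network.initial_state() if state0 is None else np.asarray(state0, dtype=float)
    sol = solve_ivp(
        network.rhs,
        (0.0, float(t_end)),
        c0,
        method=method,
        t_eval=t_eval,
        jac=network.jacobian,
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}", state=sol.y[:, -1] if sol.y.size else c0)
    concs = sol.y.T
    if concs.min() < -10 * atol:
        raise IntegrationError(
            f"negative concentration {concs.min():.3e} beyond tolerance", state=concs
        )
    traj = Trajectory(sol.t, concs, network.names, _interp=sol.sol)
    group = network.enzyme_conservation_group()
    if group:
        idx = [network.index(n) for n in group]
        totals = concs[:, idx].sum(axis=1)
        if totals[0] > 0:
            drift = np.max(np.abs(totals - totals[0])) / totals[0]
            if drift > CONSERVATION_RTOL:
                raise IntegrationError(
                    f"enzyme conservation violated: relative drift {drift:.2e}",
                    state=concs,
                )
    return traj


def instantaneous_rate(network: ReactionNetwork, trajectory: Trajectory, species: str, t: float) -> float:
    """Mass-action derivative of one species at the trajectory state at time t.

    This evaluates the rate law at the interpolated state (not a finite
    difference of stored points).  The pseudo-species ``"enzyme_total"``
    returns the summed derivative over the conservation group.
    """
    state = trajectory.state_at(t)
    dc = network.rhs(t, state)
    if species == ENZYME_TOTAL:
        group = network.enzyme_conservation_group()
        return float(sum(dc[network.index(n)] for n in group))
    return float(dc[network.index(species)])
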