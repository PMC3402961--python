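"""Kinetic metabolic models: structure, rate laws and the ODE right-hand side.

A model is the tuple (metabolites, reactions, A, B, P, x0) behind the ODE

    dX/dt = A . R(X, P) + B(X, P)

where ``X`` is the vector of dynamic metabolite concentrations (mM), ``R``
collects all reaction rate laws (mM/s), ``A`` is the signed stoichiometric
matrix over the dynamic metabolites, and ``B`` holds extra per-metabolite
terms (transport inflow, growth dilution, drain to unmodelled pathways).
External species (boundary substrates, co-metabolites) carry fixed
concentrations and do not contribute ODE states.

Units are mM for concentrations and seconds for time throughout.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .expressions import CompiledExpression, ExpressionError

__all__ = [
    "Metabolite",
    "Reaction",
    "KineticModel",
    "ModelValidationError",
    "ModelParseError",
    "load_model",
    "save_model",
    "knockout",
]

#: tolerance below which slightly negative concentrations are clipped to zero
NEGATIVE_TOL = 1e-6


class ModelValidationError(ValueError):
    """A structural invariant of the model is violated."""


class ModelParseError(ValueError):
    """The model-definition file does not conform to the schema."""


@dataclass
class Metabolite:
    """A chemical species.

    ``dynamic`` species carry an ODE state; ``external`` species are boundary
    metabolites or co-metabolites held at a fixed concentration (``value``).
    The two flags are mutually exclusive.
    """

    id: str
    name: str = ""
    dynamic: bool = True
    external: bool = False
    value: float | None = None  # fixed concentration for external species, mM
    role_tags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.role_tags = set(self.role_tags)
        if self.dynamic and self.external:
            raise ModelValidationError(
                f"metabolite {self.id!r}: dynamic and external are mutually exclusive"
            )
        if self.external and self.value is None:
            raise ModelValidationError(
                f"external metabolite {self.id!r} needs a fixed concentration value"
            )


@dataclass
class Reaction:
    """A reaction with a declarative rate law.

    ``substrates``/``products`` are (metabolite-id, stoichiometric
    coefficient) pairs with strictly positive coefficients. ``vmax_params``
    names the maximal-rate parameter(s) of the rate law; an in-silico
    knockout sets exactly these to zero. ``is_lumped`` marks aggregate
    transport/biosynthesis steps that are not knockout targets.
    """

    id: str
    enzyme_name: str = ""
    substrates: list[tuple[str, float]] = field(default_factory=list)
    products: list[tuple[str, float]] = field(default_factory=list)
    modifiers: list[tuple[str, str]] = field(default_factory=list)  # (id, inhibitor|activator)
    rate_law: str = "0.0"
    vmax_params: list[str] = field(default_factory=list)
    is_lumped: bool = False

    def __post_init__(self) -> None:
        self.substrates = [(str(m), float(c)) for m, c in self.substrates]
        self.products = [(str(m), float(c)) for m, c in self.products]
        self.modifiers = [(str(m), str(k)) for m, k in self.modifiers]
        for m, c in self.substrates + self.products:
            if c <= 0:
                raise ModelValidationError(
                    f"reaction {self.id!r}: stoichiometric coefficient of {m!r} must be > 0"
                )
        for m, kind in self.modifiers:
            if kind not in ("inhibitor", "activator"):
                raise ModelValidationError(
                    f"reaction {self.id!r}: modifier kind {kind!r} invalid"
                )

    @property
    def participant_ids(self) -> set[str]:
        return {m for m, _ in self.substrates} | {m for m, _ in self.products}


class KineticModel:
    """A validated kinetic metabolic model.

    Parameters
    ----------
    metabolites, reactions:
        Model structure. Order is preserved; the dynamic metabolites in
        their listed order define the state-vector layout.
    parameters:
        Named kinetic parameters ``P`` (maximal rates, Michaelis constants).
    external_terms:
        Optional per-dynamic-metabolite expressions for the ``B`` term.
    initial_state:
        Default initial concentrations ``x0`` for dynamic metabolites (mM).
    """

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        parameters: Mapping[str, float],
        external_terms: Mapping[str, str] | None = None,
        initial_state: Mapping[str, float] | None = None,
        name: str = "",
        nonnegative: bool = True,
    ):
        self.name = name
        #: concentrations are physically non-negative; abstract ODE fixtures
        #: (normal-form systems) switch this off so states may cross zero
        self.nonnegative = bool(nonnegative)
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.parameters = {str(k): float(v) for k, v in parameters.items()}
        self.external_terms = {str(k): str(v) for k, v in (external_terms or {}).items()}
        self.initial_state = {str(k): float(v) for k, v in (initial_state or {}).items()}
        self.deleted_enzymes: list[str] = []
        self._validate_and_index()

    # ------------------------------------------------------------------ setup

    def _validate_and_index(self) -> None:
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite id(s): {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction id(s): {dup}")

        self.met_by_id = {m.id: m for m in self.metabolites}
        self.rxn_by_id = {r.id: r for r in self.reactions}
        self.dynamic_ids: list[str] = [m.id for m in self.metabolites if m.dynamic]
        self._dyn_index = {mid: k for k, mid in enumerate(self.dynamic_ids)}
        self.external_values = {
            m.id: float(m.value) for m in self.metabolites if m.external
        }

        for r in self.reactions:
            for mid in sorted(r.participant_ids | {m for m, _ in r.modifiers}):
                if mid not in self.met_by_id:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references unknown metabolite {mid!r}"
                    )

        # stoichiometric matrix over dynamic metabolites
        n, m = len(self.dynamic_ids), len(self.reactions)
        A = np.zeros((n, m))
        for j, r in enumerate(self.reactions):
            for mid, c in r.substrates:
                if mid in self._dyn_index:
                    A[self._dyn_index[mid], j] -= c
            for mid, c in r.products:
                if mid in self._dyn_index:
                    A[self._dyn_index[mid], j] += c
        self.A = A

        # compile rate laws and external terms; check parameter closure
        known = (
            set(self.parameters) | set(self.met_by_id) | {"t"}
        )
        self._rate_exprs: list[CompiledExpression] = []
        for r in self.reactions:
            expr = CompiledExpression(r.rate_law)
            missing = expr.names - known
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r}: unknown symbol(s) {sorted(missing)} in rate law"
                )
            for p in r.vmax_params:
                if p not in self.parameters:
                    raise ModelValidationError(
                        f"reaction {r.id!r}: vmax parameter {p!r} not in parameter set"
                    )
            self._rate_exprs.append(expr)
        self._ext_exprs: dict[str, CompiledExpression] = {}
        for mid, src in self.external_terms.items():
            if mid not in self._dyn_index:
                raise ModelValidationError(
                    f"external term given for non-dynamic metabolite {mid!r}"
                )
            expr = CompiledExpression(src)
            missing = expr.names - known
            if missing:
                raise ModelValidationError(
                    f"external term for {mid!r}: unknown symbol(s) {sorted(missing)}"
                )
            self._ext_exprs[mid] = expr

        for mid, v in self.initial_state.items():
            if mid not in self._dyn_index:
                raise ModelValidationError(
                    f"initial state given for non-dynamic metabolite {mid!r}"
                )
            if v < 0:
                raise ModelValidationError(f"initial concentration of {mid!r} is negative")

    # ------------------------------------------------------------- properties

    @property
    def n_dynamic(self) -> int:
        return len(self.dynamic_ids)

    @property
    def enzyme_ids(self) -> list[str]:
        """Ids of non-lumped (knockout-eligible) reactions."""
        return [r.id for r in self.reactions if not r.is_lumped]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def state_index(self, metabolite_id: str) -> int:
        return self._dyn_index[metabolite_id]

    @property
    def x0(self) -> np.ndarray:
        """Default initial state in dynamic-metabolite order (mM)."""
        return np.array([self.initial_state.get(mid, 0.0) for mid in self.dynamic_ids])

    # ------------------------------------------------------------- evaluation

    def _env(self, x: np.ndarray, t: float) -> dict[str, float]:
        env = dict(self.parameters)
        env.update(self.external_values)
        for mid, k in self._dyn_index.items():
            env[mid] = x[k]
        env["t"] = t
        return env

    def evaluate_rates(self, x: Iterable[float], t: float = 0.0) -> np.ndarray:
        """Evaluate all reaction rate laws at state ``x`` (mM/s)."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_dynamic,):
            raise ModelValidationError(
                f"state vector has shape {x.shape}, expected ({self.n_dynamic},)"
            )
        if self.nonnegative:
            if np.any(x < -NEGATIVE_TOL):
                bad = self.dynamic_ids[int(np.argmin(x))]
                raise ExpressionError(f"concentration of {bad!r} is negative beyond tolerance")
            x = np.maximum(x, 0.0)
        env = self._env(x, t)
        return np.array([expr.evaluate(env) for expr in self._rate_exprs])

    def external_term(self, x: Iterable[float], t: float = 0.0) -> np.ndarray:
        """Evaluate the ``B`` vector at state ``x`` (mM/s)."""
        x = np.asarray(x, dtype=float)
        if self.nonnegative:
            x = np.maximum(x, 0.0)
        env = self._env(x, t)
        b = np.zeros(self.n_dynamic)
        for mid, expr in self._ext_exprs.items():
            b[self._dyn_index[mid]] = expr.evaluate(env)
        return b

    def rhs(self, x: Iterable[float], t: float = 0.0) -> np.ndarray:
        """The ODE right-hand side A.R(x,P) + B(x,P) at state ``x``."""
        rates = self.evaluate_rates(x, t)
        return self.A @ rates + self.external_term(x, t)

    # ------------------------------------------------------------- operations

    def knockout(self, enzyme_id: str) -> "KineticModel":
        """Return a copy with the enzyme's maximal-rate parameter(s) set to 0.

        The ODE dimension is unchanged so knockout and wild-type trajectories
        stay comparable; only the named reaction's rate becomes identically
        zero. Lumped transport/biosynthesis steps are refused.
        """
        if enzyme_id not in self.rxn_by_id:
            raise LookupError(f"unknown enzyme/reaction id {enzyme_id!r}")
        rxn = self.rxn_by_id[enzyme_id]
        if rxn.is_lumped:
            raise ModelValidationError(
                f"{enzyme_id!r} is a lumped transport/biosynthesis step, not a knockout target"
            )
        if not rxn.vmax_params:
            raise ModelValidationError(
                f"reaction {enzyme_id!r} declares no maximal-rate parameter to zero"
            )
        # shared maximal-rate parameters would silence other reactions too
        for other, expr in zip(self.reactions, self._rate_exprs):
            if other.id != enzyme_id and set(rxn.vmax_params) & expr.names:
                raise ModelValidationError(
                    f"maximal-rate parameter of {enzyme_id!r} is shared with {other.id!r}"
                )
        new = self.copy()
        for p in rxn.vmax_params:
            new.parameters[p] = 0.0
        if enzyme_id not in new.deleted_enzymes:
            new.deleted_enzymes.append(enzyme_id)
        return new

    def copy(self) -> "KineticModel":
        new = KineticModel(
            copy.deepcopy(self.metabolites),
            copy.deepcopy(self.reactions),
            dict(self.parameters),
            dict(self.external_terms),
            dict(self.initial_state),
            name=self.name,
            nonnegative=self.nonnegative,
        )
        new.deleted_enzymes = list(self.deleted_enzymes)
        return new

    # ---------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "nonnegative": self.nonnegative,
            "metabolites": [
                {
                    "id": m.id,
                    "name": m.name,
                    "dynamic": m.dynamic,
                    "external": m.external,
                    **({"value": m.value} if m.external else {}),
                    "role_tags": sorted(m.role_tags),
                }
                for m in self.metabolites
            ],
            "reactions": [
                {
                    "id": r.id,
                    "enzyme_name": r.enzyme_name,
                    "substrates": [[m, c] for m, c in r.substrates],
                    "products": [[m, c] for m, c in r.products],
                    "modifiers": [[m, k] for m, k in r.modifiers],
                    "rate_law": r.rate_law,
                    "vmax_params": list(r.vmax_params),
                    "lumped": r.is_lumped,
                }
                for r in self.reactions
            ],
            "parameters": dict(self.parameters),
            "external_terms": dict(self.external_terms),
            "initial_state": dict(self.initial_state),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticModel":
        try:
            mets = [
                Metabolite(
                    id=str(m["id"]),
                    name=str(m.get("name", "")),
                    dynamic=bool(m.get("dynamic", not m.get("external", False))),
                    external=bool(m.get("external", False)),
                    value=m.get("value"),
                    role_tags=set(m.get("role_tags", [])),
                )
                for m in d.get("metabolites", [])
            ]
            rxns = [
                Reaction(
                    id=str(r["id"]),
                    enzyme_name=str(r.get("enzyme_name", "")),
                    substrates=[(s[0], s[1]) for s in r.get("substrates", [])],
                    products=[(s[0], s[1]) for s in r.get("products", [])],
                    modifiers=[(s[0], s[1]) for s in r.get("modifiers", [])],
                    rate_law=str(r.get("rate_law", "0.0")),
                    vmax_params=list(r.get("vmax_params", [])),
                    is_lumped=bool(r.get("lumped", False)),
                )
                for r in d.get("reactions", [])
            ]
        except (KeyError, TypeError, IndexError) as exc:
            raise ModelParseError(f"malformed model definition: {exc}") from exc
        return cls(
            mets,
            rxns,
            d.get("parameters", {}),
            d.get("external_terms", {}),
            d.get("initial_state", {}),
            name=str(d.get("name", "")),
            nonnegative=bool(d.get("nonnegative", True)),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KineticModel):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def __repr__(self) -> str:  # pragma: no cover
        n_enz = len(self.enzyme_ids)
        n_lump = len(self.reactions) - n_enz
        return (
            f"<KineticModel {self.name!r}: {len(self.metabolites)} metabolites "
            f"({self.n_dynamic} dynamic), {n_enz} enzymes + {n_lump} lumped reactions>"
        )


def load_model(path: str | Path) -> KineticModel:
    """Load and validate a model-definition YAML file."""
    path = Path(path)
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ModelParseError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ModelParseError(f"{path} does not contain a model mapping")
    model = KineticModel.from_dict(raw)
    if not model.name:
        model.name = path.stem
    return model


def save_model(model: KineticModel, path: str | Path) -> None:
    """Write a model to YAML such that load(save(m)) == m."""
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)


def knockout(model: KineticModel, enzyme_id: str) -> KineticModel:
    """Functional alias for :meth:`KineticModel.knockout`."""
    return model.knockout(enzyme_id)
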