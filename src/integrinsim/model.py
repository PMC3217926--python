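"""The concrete integrin-activation model.

Six molecule types (ligand, integrin, talin, Dok1, Src, PIPKI), the rule set
R1–R17b, nine observables and a 37-entry parameter table of which 33 entries
are sampled over log-uniform fold ranges.  The bundled text files
``model/integrin.bngl`` and ``model/parameters.tsv`` are the single source of
truth; this module only loads, validates and serves them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

from . import bngl
from .engine import ReactionNetwork, generate_network, match

__all__ = [
    "ParameterEntry",
    "ParameterSet",
    "ModelSpec",
    "build_default_model",
    "default_parameters",
    "knockout",
    "TOTAL_OF_MOLECULE",
]

#: total-concentration parameter backing each molecule type
TOTAL_OF_MOLECULE = {
    "INT": "INT_tot",
    "TAL": "TAL_tot",
    "DOK": "DOK_tot",
    "SRC": "SRC_tot",
    "PIPKI": "PIPKI_tot",
    "L": "L_tot",
}

_ROLES = {
    "equilibrium-constant",
    "off-rate",
    "first-order-rate",
    "total-concentration",
}


@dataclass(frozen=True)
class ParameterEntry:
    symbol: str
    role: str
    base_value: float
    fold: float | str  # numeric fold or "fixed"
    evidence: str
    provenance: str
    rule_ids: tuple[str, ...]
    description: str = ""

    def __post_init__(self):
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.symbol}")
        if self.base_value <= 0:
            raise ValueError(f"{self.symbol}: base value must be positive")
        if self.fold != "fixed" and float(self.fold) not in (2.0, 5.0, 10.0):
            raise ValueError(f"{self.symbol}: fold must be fixed, 2, 5 or 10")

    @property
    def sampled(self) -> bool:
        return self.fold != "fixed"


class ParameterSet(dict):
    """A concrete symbol -> value mapping (a plain dict with provenance)."""

    def with_values(self, **overrides: float) -> "ParameterSet":
        out = ParameterSet(self)
        out.update(overrides)
        return out


@dataclass
class ModelSpec:
    """The parsed model: molecules, rules, parameters, observables, seeds."""

    parsed: bngl.ParsedModel
    entries: list[ParameterEntry]
    overrides: dict[str, float] = field(default_factory=dict)

    # -- structure ----------------------------------------------------------

    @property
    def molecules(self):
        return self.parsed.molecules

    @property
    def rules(self):
        return self.parsed.rules

    @property
    def observables(self):
        return self.parsed.observables

    @property
    def seeds(self):
        return self.parsed.seeds

    @property
    def compartment_volumes(self) -> dict[str, float]:
        return dict(self.parsed.compartments)

    def entry(self, symbol: str) -> ParameterEntry:
        for e in self.entries:
            if e.symbol == symbol:
                return e
        raise KeyError(symbol)

    def parameters(self) -> ParameterSet:
        """Base parameter values (plus any knockout/config overrides)."""
        ps = ParameterSet({e.symbol: e.base_value for e in self.entries})
        ps["k7b"] = 0.0  # cross-talk Src activation; protocols switch it on
        ps.update(self.overrides)
        return ps

    def rate_symbols(self) -> set[str]:
        import sympy

        out: set[str] = set()
        for rule in self.rules:
            out |= {str(s) for s in sympy.sympify(rule.rate).free_symbols}
        return out

    def validate(self) -> None:
        known = set(self.parameters())
        missing = self.rate_symbols() - known
        if missing:
            raise ValueError(f"rules reference unknown parameters: {sorted(missing)}")
        if len(self.molecules) != 6:
            raise ValueError("the integrin model has six molecule types")
        for mol in TOTAL_OF_MOLECULE:
            if mol not in self.molecules:
                raise ValueError(f"missing molecule {mol}")

    # -- network ------------------------------------------------------------

    def generate_network(self, max_species: int = 10_000) -> ReactionNetwork:
        seeds = [s.species for s in self.seeds]
        return generate_network(self.molecules, self.rules, seeds, max_species)

    def observable_matrix(self, network: ReactionNetwork) -> np.ndarray:
        """W[o, i] = number of embeddings of observable o's patterns in species i."""
        W = np.zeros((len(self.observables), len(network.species)))
        for oi, obs in enumerate(self.observables):
            for pat in obs.patterns:
                for si, sp in enumerate(network.species):
                    W[oi, si] += len(match(pat, sp, self.molecules))
        return W

    @property
    def observable_names(self) -> list[str]:
        return [o.name for o in self.observables]

    def seed_amounts(self, params: Mapping[str, float]) -> dict[str, float]:
        """Canonical seed label -> initial amount under ``params``."""
        import sympy

        out = {}
        for seed in self.seeds:
            val = float(sympy.sympify(seed.amount_expr).subs(dict(params)))
            out[seed.species.label] = val
        return out


def _load_entries(text: str) -> list[ParameterEntry]:
    entries = []
    header: list[str] | None = None
    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split("\t")
        if header is None:
            header = cells
            continue
        row = dict(zip(header, cells))
        fold: float | str = row["fold"]
        if fold != "fixed":
            fold = float(fold)
        rule_ids = tuple(r for r in row["rule_ids"].split(",") if r and r != "-")
        entries.append(
            ParameterEntry(
                symbol=row["symbol"],
                role=row["role"],
                base_value=float(row["value"]),
                fold=fold,
                evidence=row["evidence"],
                provenance=row["provenance"],
                rule_ids=rule_ids,
                description=row.get("description", ""),
            )
        )
    return entries


def _read_packaged(name: str) -> str:
    return (resources.files("integrinsim") / "model" / name).read_text()


def build_default_model(
    model_text: str | None = None, parameter_text: str | None = None
) -> ModelSpec:
    """Load and validate the packaged integrin model (or explicit texts)."""
    parsed = bngl.parse_model(model_text or _read_packaged("integrin.bngl"))
    entries = _load_entries(parameter_text or _read_packaged("parameters.tsv"))
    spec = ModelSpec(parsed=parsed, entries=entries)
    spec.validate()
    return spec


def default_parameters(spec: ModelSpec | None = None) -> ParameterSet:
    """The packaged base parameter values."""
    if spec is None:
        spec = build_default_model()
    return spec.parameters()


def knockout(spec: ModelSpec, molecule: str) -> ModelSpec:
    """A copy of ``spec`` with one molecule's total concentration set to zero.

    Only the initial condition changes; the reaction network is unchanged.
    """
    if molecule not in TOTAL_OF_MOLECULE:
        raise KeyError(f"unknown molecule {molecule!r}")
    if molecule == "INT":
        raise KeyError("integrin knockout is not a modeled perturbation")
    overrides = dict(spec.overrides)
    overrides[TOTAL_OF_MOLECULE[molecule]] = 0.0
    return ModelSpec(parsed=spec.parsed, entries=spec.entries, overrides=overrides)
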